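"""Linear SVM detection model, exhaustive subset search, and the fixed
published detection-index equation.

The detection index of a sample is the decision value of a linear
soft-margin SVM over a subset of the 15 features.  The variable subset is
chosen by enumerating every nonempty combination, scoring each by the AUC of
pooled leave-one-out decision values, and keeping the best-scoring subset
whose full-training-set refit has strictly positive weights on every
variable (hypermethylation and elevated cfDNA should only ever push a
sample toward the cancer call).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .ddmsp import _rank_auc

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinearDetectionModel:
    """Linear detection-index model: index = w·x + b, positive iff index > cutoff."""

    variable_names: tuple[str, ...]
    weights: tuple[float, ...]
    intercept: float
    decision_cutoff: float = -0.07923

    def __post_init__(self) -> None:
        if len(self.variable_names) != len(self.weights):
            raise ValueError("one weight per variable required")

    def detection_index(self, features) -> float | pd.Series:
        """Evaluate the index for a mapping/Series (scalar) or DataFrame (per row)."""
        w = np.asarray(self.weights, dtype=float)
        if isinstance(features, pd.DataFrame):
            missing = [v for v in self.variable_names if v not in features.columns]
            if missing:
                raise KeyError(f"feature table lacks model variables: {missing}")
            x = features[list(self.variable_names)].to_numpy(dtype=float)
            return pd.Series(x @ w + self.intercept, index=features.index, name="detection_index")
        try:
            x = np.array([float(features[v]) for v in self.variable_names])
        except KeyError as e:
            raise KeyError(f"feature vector lacks model variable {e}") from e
        return float(x @ w + self.intercept)

    def classify(self, index) -> bool | pd.Series:
        """Cancer call: strictly above the decision cutoff."""
        return classify(index, self.decision_cutoff)

    def to_dict(self) -> dict:
        return {
            "variable_names": list(self.variable_names),
            "weights": list(self.weights),
            "intercept": self.intercept,
            "decision_cutoff": self.decision_cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearDetectionModel":
        return cls(
            variable_names=tuple(d["variable_names"]),
            weights=tuple(float(w) for w in d["weights"]),
            intercept=float(d["intercept"]),
            decision_cutoff=float(d["decision_cutoff"]),
        )


def detection_index(model: LinearDetectionModel, features):
    return model.detection_index(features)


def classify(index, cutoff: float = -0.07923):
    """Positive (cancer) iff index > cutoff; the cutoff itself is negative."""
    if isinstance(index, pd.Series):
        return index > cutoff
    return bool(index > cutoff)


#: The published six-variable model with its verbatim coefficients and the
#: ROC-derived decision cutoff.
FIXED_PUBLISHED_MODEL = LinearDetectionModel(
    variable_names=("RASGRF1", "CPXM1", "HOXA10", "DACH1", "Mean12", "IC"),
    weights=(0.62449, 0.78110, 0.12115, 0.36760, 0.65288, 2.44704),
    intercept=-6.98073,
    decision_cutoff=-0.07923,
)


def _as_xy(features: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(pd.Series(labels).reindex(features.index) if isinstance(labels, (pd.Series, dict)) else labels)
    y = np.asarray([1 if v in (1, True, "BC") else 0 for v in y], dtype=int)
    x = features.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("feature table contains missing values")
    return x, y


def fit_linear_svm(
    features: pd.DataFrame,
    labels,
    c_param: float = 1.0,
    standardize: bool = True,
) -> LinearDetectionModel:
    """Fit a linear soft-margin SVM; weights are reported on the original
    feature scale.

    Labels may be {0,1}, booleans or {"HV","BC"}; the positive (cancer)
    class always gets the positive decision direction.  By default features
    are z-scored for the fit and the weights and intercept transformed back
    to the original scale: log10-concentration features have small spread
    around a large offset, which otherwise leaves the (w, b) objective
    nearly flat along the offset direction and makes fold-to-fold intercepts
    erratic.  ``standardize=False`` fits the raw feature scale directly.
    """
    x, y = _as_xy(features, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit the SVM")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    if standardize:
        sd = np.where(sd == 0, 1.0, sd)
        clf = SVC(kernel="linear", C=c_param)
        clf.fit((x - mu) / sd, y)
        w_std = clf.coef_[0]
        w = w_std / sd
        b = clf.intercept_[0] - float(np.dot(w_std, mu / sd))
    else:
        clf = SVC(kernel="linear", C=c_param)
        clf.fit(x, y)
        w = clf.coef_[0]
        b = float(clf.intercept_[0])
    return LinearDetectionModel(
        variable_names=tuple(features.columns),
        weights=tuple(float(v) for v in w),
        intercept=float(b),
        decision_cutoff=0.0,
    )


def loocv_scores(
    features: pd.DataFrame,
    labels,
    variables: tuple[str, ...] | list[str] | None = None,
    c_param: float = 1.0,
    standardize: bool = True,
) -> pd.Series:
    """Out-of-fold decision values: sample i scored by the SVM fit without i.

    Standardisation, when enabled, is fold-local (mean/sd from the n−1
    training samples only) so no information leaks from the held-out sample.
    """
    cols = list(variables) if variables is not None else list(features.columns)
    x, y = _as_xy(features[cols], labels)
    n = len(y)
    if min(np.bincount(y, minlength=2)) < 3:
        raise ValueError("LOOCV needs at least 3 samples per class")
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        if len(np.unique(y[mask])) < 2:
            raise ValueError(f"fold {i} leaves a single-class training set")
        xt = x[mask]
        xi = x[i : i + 1]
        if standardize:
            mu = xt.mean(axis=0)
            sd = xt.std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
            xt = (xt - mu) / sd
            xi = (xi - mu) / sd
        clf = SVC(kernel="linear", C=c_param)
        clf.fit(xt, y[mask])
        scores[i] = clf.decision_function(xi)[0]
    return pd.Series(scores, index=features.index, name="loocv_score")


def loocv_auc(features: pd.DataFrame, labels, variables=None, c_param: float = 1.0,
              standardize: bool = True) -> float:
    """AUC of the pooled out-of-fold decision values."""
    scores = loocv_scores(features, labels, variables, c_param, standardize)
    _, y = _as_xy(features, labels)
    return _rank_auc(scores.to_numpy(), y)


def variable_subsets(variables: list[str]):
    """Yield every nonempty subset (2^V − 1) in lexicographic mask order."""
    v = len(variables)
    if not 1 <= v <= 15:
        raise ValueError("between 1 and 15 variables supported")
    for size in range(1, v + 1):
        for combo in combinations(range(v), size):
            yield tuple(variables[i] for i in combo)


@dataclass
class SearchResult:
    """Outcome of the exhaustive variable-combination search."""

    records: pd.DataFrame  # variables, n_variables, loocv_auc, all_weights_positive
    best: LinearDetectionModel
    best_loocv_auc: float
    constraint_satisfied: bool


def exhaustive_search(
    features: pd.DataFrame,
    labels,
    variables: list[str] | None = None,
    c_param: float = 1.0,
    standardize: bool = True,
    progress: bool = False,
) -> SearchResult:
    """Enumerate all nonempty variable subsets and pick the detection model.

    Each subset is scored by pooled-LOOCV AUC; its full-data refit is
    checked for strictly positive weights.  The winner is the
    highest-scoring subset passing the positivity check, ties resolved
    toward fewer variables and then lexicographic subset order.  If no
    subset passes, the unconstrained best is returned with
    ``constraint_satisfied=False``.
    """
    if variables is None:
        variables = list(features.columns)
    _, y = _as_xy(features[variables], labels)

    rows = []
    total = 2 ** len(variables) - 1
    for i, subset in enumerate(variable_subsets(variables)):
        scores = loocv_scores(features, labels, subset, c_param, standardize)
        auc = _rank_auc(scores.to_numpy(), y)
        refit = fit_linear_svm(features[list(subset)], labels, c_param, standardize)
        positive = all(w > 0 for w in refit.weights)
        rows.append(
            {
                "variables": subset,
                "n_variables": len(subset),
                "loocv_auc": auc,
                "all_weights_positive": positive,
            }
        )
        if progress and (i + 1) % 500 == 0:
            log.info("search: %d/%d subsets scored", i + 1, total)

    records = pd.DataFrame(rows)
    assert len(records) == total

    pool = records[records["all_weights_positive"]]
    constraint_satisfied = len(pool) > 0
    if not constraint_satisfied:
        log.warning("no subset satisfies the positive-weight constraint; "
                    "returning the unconstrained best")
        pool = records
    best_auc = pool["loocv_auc"].max()
    winners = pool[pool["loocv_auc"] >= best_auc - 1e-12]
    # fewer variables first, then lexicographic subset order (enumeration
    # order within a size is already lexicographic; idxmin-style first hit)
    winners = winners.sort_values(["n_variables"], kind="mergesort")
    best_vars = winners.iloc[0]["variables"]

    best_model = fit_linear_svm(features[list(best_vars)], labels, c_param, standardize)
    # decision cutoff for the refit model: Youden-optimal on LOOCV scores
    from .evaluation import youden_cutoff  # local import to avoid a cycle

    oof = loocv_scores(features, labels, best_vars, c_param, standardize)
    cutoff = youden_cutoff(oof.to_numpy(), y)
    best_model = LinearDetectionModel(
        variable_names=best_model.variable_names,
        weights=best_model.weights,
        intercept=best_model.intercept,
        decision_cutoff=cutoff,
    )
    return SearchResult(
        records=records,
        best=best_model,
        best_loocv_auc=float(best_auc),
        constraint_satisfied=constraint_satisfied,
    )


# ---------------------------------------------------------------------------
# persistence

def save_model_state(path: str | Path, model: LinearDetectionModel, extra: dict | None = None) -> None:
    payload = {"model": model.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model_state(path: str | Path) -> tuple[LinearDetectionModel, dict]:
    payload = json.loads(Path(path).read_text())
    model = LinearDetectionModel.from_dict(payload.pop("model"))
    return model, payload
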