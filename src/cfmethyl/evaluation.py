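"""Evaluation statistics for the detection model.

ROC/AUC (Mann–Whitney with tie correction), confusion-matrix metrics at the
decision cutoff, per-stage and per-subtype subgroup analyses, the
Jonckheere–Terpstra trend test across ordered stages, Kruskal–Wallis across
subtypes, the age-bias correlation, and the stratified training/validation
split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

STAGES = ("0", "I", "IIA", "IIB", "III", "IV")
DEFAULT_STAGE_BUCKETS: dict[str, tuple[str, ...]] = {
    "0-I": ("0", "I"),
    "IIA": ("IIA",),
    "IIB-III": ("IIB", "III"),
    "MBC": ("IV",),
}


# ---------------------------------------------------------------------------
# ROC / confusion

def roc_auc(scores, labels) -> float:
    """Mann–Whitney AUC of scores for the positive class; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    return np.asarray([1 if v in (1, True, "BC") else 0 for v in arr], dtype=int)


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionMetrics:
    """Confusion-matrix metrics with the strict ``score > cutoff`` call rule."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    pos = scores > cutoff
    tp = int((pos & (y == 1)).sum())
    fn = int((~pos & (y == 1)).sum())
    tn = int((~pos & (y == 0)).sum())
    fp = int((pos & (y == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    acc = (tp + tn) / len(y)
    return ConfusionMetrics(tp, fn, tn, fp, sens, spec, ppv, npv, acc)


def youden_cutoff(scores, labels) -> float:
    """Cutoff maximising sensitivity + specificity − 1 over score midpoints."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0])
    mids = (uniq[:-1] + uniq[1:]) / 2
    best_j, best_cut = -np.inf, mids[0]
    for cut in mids:
        m = confusion_at_cutoff(scores, y, cut)
        j = m.sensitivity + m.specificity - 1
        if j > best_j + 1e-12:
            best_j, best_cut = j, cut
    return float(best_cut)


# ---------------------------------------------------------------------------
# Jonckheere–Terpstra trend test

def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i][:, None], groups[j][None, :]
            jt += float((a < b).sum()) + 0.5 * float((a == b).sum())
    return jt


def _jt_null_moments(groups: list[np.ndarray]) -> tuple[float, float]:
    ns = np.array([len(g) for g in groups], dtype=float)
    n = ns.sum()
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)

    mean = (n * n - (ns ** 2).sum()) / 4.0
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = (
        (ns * (ns - 1) * (ns - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
    ) / (36.0 * n * (n - 1) * (n - 2))
    term3 = ((ns * (ns - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * n * (n - 1))
    return mean, term1 + term2 + term3


def _exact_jt_pvalue(groups: list[np.ndarray], observed: float, alternative: str) -> float:
    """Permutation-exact p by enumerating assignments of values to groups."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    mean, _ = _jt_null_moments(groups)

    stats_count = 0
    total = 0

    def assign(remaining: tuple[int, ...], gs: list[np.ndarray]) -> None:
        nonlocal stats_count, total
        g_i = len(gs)
        if g_i == len(sizes) - 1:
            gs_full = gs + [pooled[list(remaining)]]
            jt = _jt_statistic(gs_full)
            total += 1
            if alternative == "increasing":
                stats_count += jt >= observed - 1e-9
            elif alternative == "decreasing":
                stats_count += jt <= observed + 1e-9
            else:
                stats_count += abs(jt - mean) >= abs(observed - mean) - 1e-9
            return
        for combo in combinations(remaining, sizes[g_i]):
            rest = tuple(i for i in remaining if i not in combo)
            assign(rest, gs + [pooled[list(combo)]])

    assign(tuple(range(len(pooled))), [])
    return stats_count / total


@dataclass
class TrendTestResult:
    statistic: float
    pvalue: float
    method: str
    alternative: str


def jonckheere_terpstra(
    groups: list, alternative: str = "increasing", method: str = "auto"
) -> TrendTestResult:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    The statistic is the sum of pairwise Mann–Whitney counts over ordered
    group pairs (ties counted 1/2).  ``method='normal'`` uses the
    tie-corrected normal approximation; ``'exact'`` enumerates label
    permutations; ``'auto'`` is exact for total n ≤ 12 (and fewer than
    200 000 distinct orderings) and normal otherwise.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("at least two ordered groups required")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    jt = _jt_statistic(groups)
    n = sum(len(g) for g in groups)

    if method == "auto":
        n_orderings = math.factorial(n)
        for g in groups:
            n_orderings //= math.factorial(len(g))
        method = "exact" if (n <= 12 and n_orderings <= 200_000) else "normal"

    if method == "exact":
        p = _exact_jt_pvalue(groups, jt, alternative)
        return TrendTestResult(jt, float(p), "exact", alternative)

    mean, var = _jt_null_moments(groups)
    if var <= 0:
        return TrendTestResult(jt, 1.0, "normal", alternative)
    sd = math.sqrt(var)
    # continuity correction: JT is discrete (half-integer steps under ties)
    if alternative == "increasing":
        p = stats.norm.sf((jt - 0.5 - mean) / sd)
    elif alternative == "decreasing":
        p = stats.norm.cdf((jt + 0.5 - mean) / sd)
    else:
        p = 2 * stats.norm.sf((abs(jt - mean) - 0.5) / sd)
    p = min(max(float(p), 0.0), 1.0)
    return TrendTestResult(jt, p, "normal", alternative)


# ---------------------------------------------------------------------------
# stratified train/validation split

def stratified_split(
    roster: pd.DataFrame,
    train_fraction: float | dict = 0.6,
    seed: int = 0,
    train_counts: dict | None = None,
) -> pd.DataFrame:
    """Assign each roster row to the training or validation split.

    Strata are (class, stage) cells.  ``train_fraction`` may be a scalar or
    a per-stratum mapping; ``train_counts`` overrides with exact per-stratum
    training counts (used by the published-cohort preset).  Deterministic
    for a fixed seed; singleton strata go to training with a warning.
    """
    rng = np.random.default_rng(seed)
    out = roster.copy()
    out["split"] = "unassigned"
    strata = out.groupby(["class", "stage"], dropna=False, sort=True)
    for key, sub in strata:
        idx = sub.index.to_numpy()
        n = len(idx)
        if train_counts is not None:
            k = int(train_counts[key])
        else:
            frac = train_fraction[key] if isinstance(train_fraction, dict) else train_fraction
            k = int(round(n * frac))
        k = min(max(k, 0), n)
        if n == 1:
            log.warning("stratum %s has a single sample; assigned to training", key)
            k = 1
        chosen = rng.permutation(n)[:k]
        out.loc[idx, "split"] = "validation"
        out.loc[idx[chosen], "split"] = "train"
    return out


#: Exact per-stratum training counts of the published 278-sample cohort
#: (training n = 167, validation n = 111).
TABLE1_TRAIN_COUNTS: dict[tuple[str, str], int] = {
    ("HV", "none"): 80,
    ("BC", "0"): 3,
    ("BC", "I"): 27,
    ("BC", "IIA"): 19,
    ("BC", "IIB"): 11,
    ("BC", "III"): 8,
    ("BC", "IV"): 19,
}


# ---------------------------------------------------------------------------
# subgroup analyses and the full report

@dataclass
class EvaluationReport:
    auc: float
    metrics: ConfusionMetrics
    per_stage: pd.DataFrame
    per_subtype: pd.DataFrame
    trend_test: TrendTestResult
    subtype_test_p: float
    age_correlation: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "metrics": asdict(self.metrics),
            "per_stage": self.per_stage.to_dict(orient="records"),
            "per_subtype": self.per_subtype.to_dict(orient="records"),
            "trend_test": asdict(self.trend_test),
            "subtype_test_p": self.subtype_test_p,
            "age_correlation": {"r": self.age_correlation[0], "p": self.age_correlation[1]},
            "metadata": self.metadata,
        }


def subgroup_report(
    scores: pd.Series,
    roster: pd.DataFrame,
    cutoff: float,
    stage_buckets: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float, tuple[float, float]]:
    """Per-stage-bucket and per-subtype tables plus subtype/age tests.

    Stage-bucket AUCs compare that bucket's cancer samples against all
    healthy samples present in ``roster`` (i.e. split-specific healthy
    controls).  Returns (per_stage, per_subtype, kruskal_p, (pearson_r, p)).
    """
    if stage_buckets is None:
        stage_buckets = DEFAULT_STAGE_BUCKETS
    df = roster.copy()
    df["score"] = scores.reindex(df.index)
    if df["score"].isna().any():
        raise ValueError("scores missing for some roster samples")
    hv_scores = df.loc[df["class"] == "HV", "score"].to_numpy()
    bc = df[df["class"] == "BC"]

    stage_rows = []
    for bucket, members in stage_buckets.items():
        sub = bc[bc["stage"].isin(members)]
        row = {"bucket": bucket, "n": len(sub)}
        if len(sub) == 0:
            row.update(sensitivity=float("nan"), auc=float("nan"))
            log.warning("stage bucket %s is empty", bucket)
        else:
            s = sub["score"].to_numpy()
            row["sensitivity"] = float((s > cutoff).mean())
            pooled = np.concatenate([s, hv_scores])
            lab = np.concatenate([np.ones(len(s), int), np.zeros(len(hv_scores), int)])
            row["auc"] = roc_auc(pooled, lab) if len(hv_scores) else float("nan")
        stage_rows.append(row)
    per_stage = pd.DataFrame(stage_rows, columns=["bucket", "n", "sensitivity", "auc"])

    subtype_rows = []
    subtype_groups = []
    for subtype, sub in bc.groupby("subtype", sort=True):
        s = sub["score"].to_numpy()
        pooled = np.concatenate([s, hv_scores])
        lab = np.concatenate([np.ones(len(s), int), np.zeros(len(hv_scores), int)])
        subtype_rows.append(
            {
                "subtype": subtype,
                "n": len(sub),
                "sensitivity": float((s > cutoff).mean()),
                "auc": roc_auc(pooled, lab) if len(hv_scores) else float("nan"),
            }
        )
        if len(s) >= 2:
            subtype_groups.append(s)
    per_subtype = pd.DataFrame(subtype_rows, columns=["subtype", "n", "sensitivity", "auc"])

    if len(subtype_groups) >= 2:
        try:
            kw_p = float(stats.kruskal(*subtype_groups).pvalue)
        except ValueError:  # all values identical
            kw_p = float("nan")
    else:
        kw_p = float("nan")

    if len(bc) >= 3 and bc["age"].nunique() > 1 and bc["score"].nunique() > 1:
        r, p = stats.pearsonr(bc["age"].to_numpy(float), bc["score"].to_numpy(float))
        age_corr = (float(r), float(p))
    else:
        age_corr = (float("nan"), float("nan"))

    return per_stage, per_subtype, kw_p, age_corr


def evaluate(
    scores: pd.Series,
    roster: pd.DataFrame,
    cutoff: float,
    stage_buckets: dict[str, tuple[str, ...]] | None = None,
) -> EvaluationReport:
    """Full evaluation of detection-index scores against a sample roster."""
    df = roster.copy()
    df["score"] = scores.reindex(df.index)
    y = _binary_labels(df["class"])
    auc = roc_auc(df["score"].to_numpy(), y)
    metrics = confusion_at_cutoff(df["score"].to_numpy(), y, cutoff)

    per_stage, per_subtype, kw_p, age_corr = subgroup_report(scores, roster, cutoff, stage_buckets)

    bc = df[df["class"] == "BC"]
    ordered = [g for g in [bc.loc[bc["stage"] == s, "score"].to_numpy() for s in STAGES] if len(g)]
    if len(ordered) >= 2:
        trend = jonckheere_terpstra(ordered, alternative="increasing", method="normal")
    else:
        trend = TrendTestResult(float("nan"), float("nan"), "normal", "increasing")

    return EvaluationReport(
        auc=auc,
        metrics=metrics,
        per_stage=per_stage,
        per_subtype=per_subtype,
        trend_test=trend,
        subtype_test_p=kw_p,
        age_correlation=age_corr,
        metadata={"stage_auc_controls": "split-specific healthy volunteers"},
    )
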