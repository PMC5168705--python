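"""Candidate marker selection from Infinium-style methylation array data.

A probe is a candidate cfDNA marker when it is essentially unmethylated in
all non-cancer material (``meanNC < 0.05`` — blood leukocytes dominate cfDNA,
so any blood methylation destroys specificity) and hypermethylated in tumour
tissue.  Four independent top-k conditions are applied to balanced group
means:

    (a) widest gap between meanBC and meanNC          (common markers)
    (b) lowest meanNC among probes with meanBC > 0.6  (common markers)
    (c) largest meanLum - meanTN                      (luminal-dominant)
    (d) largest meanTN - meanLum                      (TN-dominant)

Because the proportions of cell-line and FFPE samples differ between the
luminal and triple-negative groups, a pooled mean would be biased toward the
larger stratum; tumour group means are therefore the unweighted average of
the cell-line-stratum mean and the FFPE-stratum mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GROUPS = ("BC-luminal", "BC-TN", "BC-other", "non-BC")
MATERIALS = ("cell-line", "FFPE", "blood", "epithelia")

CONDITIONS = ("a", "b", "c", "d")


@dataclass
class ArrayDataset:
    """β-value matrix (probes × samples) with group/material annotations."""

    beta: pd.DataFrame  # index: probe_id, columns: sample_id
    sample_groups: pd.Series  # sample_id -> group
    sample_materials: pd.Series  # sample_id -> material

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("β matrix contains missing values")
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("β values must lie in [0, 1]")
        for s in self.beta.columns:
            if s not in self.sample_groups.index or s not in self.sample_materials.index:
                raise ValueError(f"sample {s!r} lacks group/material annotation")
        bad = set(self.sample_groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {bad}")
        bad = set(self.sample_materials.unique()) - set(MATERIALS)
        if bad:
            raise ValueError(f"unknown materials: {bad}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    def samples_in(self, group: str | None = None, material: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.beta.columns)
        if group is not None:
            mask &= self.sample_groups.reindex(self.beta.columns) == group
        if material is not None:
            mask &= self.sample_materials.reindex(self.beta.columns) == material
        return list(self.beta.columns[mask])

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_files(cls, beta_tsv: str | Path, sample_sheet_csv: str | Path) -> "ArrayDataset":
        beta = pd.read_csv(beta_tsv, sep="\t", index_col=0)
        sheet = pd.read_csv(sample_sheet_csv, index_col="sample_id")
        return cls(beta, sheet["group"], sheet["material"])

    def to_files(self, beta_tsv: str | Path, sample_sheet_csv: str | Path) -> None:
        self.beta.to_csv(beta_tsv, sep="\t")
        sheet = pd.DataFrame(
            {"group": self.sample_groups, "material": self.sample_materials}
        )
        sheet.index.name = "sample_id"
        sheet.to_csv(sample_sheet_csv)


def _balanced_mean(
    data: ArrayDataset, groups: tuple[str, ...], label: str
) -> pd.Series:
    """Average of the cell-line-stratum mean and the FFPE-stratum mean.

    Falls back to the single available stratum (with a warning) when a
    stratum is empty.
    """
    cell = [s for g in groups for s in data.samples_in(group=g, material="cell-line")]
    ffpe = [s for g in groups for s in data.samples_in(group=g, material="FFPE")]
    strata = []
    if cell:
        strata.append(data.beta[cell].mean(axis=1))
    if ffpe:
        strata.append(data.beta[ffpe].mean(axis=1))
    if not strata:
        raise ValueError(f"no cell-line or FFPE samples available for {label}")
    if len(strata) == 1:
        log.warning(
            "%s: only one of the cell-line/FFPE strata is populated; "
            "using the single-stratum mean",
            label,
        )
        return strata[0]
    return (strata[0] + strata[1]) / 2.0


@dataclass
class GroupMeans:
    """Per-probe group mean β-values used by the selection conditions."""

    table: pd.DataFrame  # columns: meanNC, meanBC, meanLum, meanTN

    def __post_init__(self) -> None:
        expected = {"meanNC", "meanBC", "meanLum", "meanTN"}
        if set(self.table.columns) != expected:
            raise ValueError(f"GroupMeans needs columns {expected}")
        vals = self.table.to_numpy()
        if np.isnan(vals).any() or vals.min() < 0 or vals.max() > 1:
            raise ValueError("group means must be defined and in [0, 1]")

    def __getitem__(self, key: str) -> pd.Series:
        return self.table[key]


def compute_group_means(data: ArrayDataset, balanced_bc: bool = True) -> GroupMeans:
    """Compute meanNC, meanBC, meanLum and meanTN for every probe.

    meanNC is the plain mean over all non-BC samples (blood, normal
    epithelia and non-BC cell lines pooled).  meanLum and meanTN are
    balanced cell-line/FFPE averages; meanBC is balanced the same way by
    default (``balanced_bc=False`` gives the pooled mean over all BC
    samples instead).
    """
    nc_samples = data.samples_in(group="non-BC")
    if not nc_samples:
        raise ValueError("no non-BC samples; meanNC undefined")
    mean_nc = data.beta[nc_samples].mean(axis=1)

    bc_groups = ("BC-luminal", "BC-TN", "BC-other")
    if balanced_bc:
        mean_bc = _balanced_mean(data, bc_groups, "meanBC")
    else:
        bc_samples = [s for g in bc_groups for s in data.samples_in(group=g)]
        mean_bc = data.beta[bc_samples].mean(axis=1)
    mean_lum = _balanced_mean(data, ("BC-luminal",), "meanLum")
    mean_tn = _balanced_mean(data, ("BC-TN",), "meanTN")

    return GroupMeans(
        pd.DataFrame(
            {"meanNC": mean_nc, "meanBC": mean_bc, "meanLum": mean_lum, "meanTN": mean_tn}
        )
    )


@dataclass
class CandidateSet:
    """Per-condition candidate tables plus the deduplicated locus list."""

    table: pd.DataFrame  # probe_id, condition, rank, means, criterion value
    shortfalls: dict[str, int] = field(default_factory=dict)

    @property
    def unique_loci(self) -> list[str]:
        return sorted(self.table["probe_id"].unique())

    def probes_for(self, condition: str) -> list[str]:
        sub = self.table[self.table["condition"] == condition]
        return list(sub.sort_values("rank")["probe_id"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _top_k(values: pd.Series, k: int, ascending: bool) -> pd.Index:
    """Top-k probe ids by criterion value, ties broken by probe id."""
    order = sorted(values.index, key=lambda p: (values[p] if ascending else -values[p], p))
    return pd.Index(order[:k])


def select_candidates(
    means: GroupMeans,
    k_a: int = 20,
    k_b: int = 20,
    k_c: int = 50,
    k_d: int = 50,
    beta_bc_floor: float = 0.6,
    nc_ceiling: float = 0.05,
) -> CandidateSet:
    """Apply the four top-k selection conditions on the eligible pool.

    Eligibility is ``meanNC < nc_ceiling``.  Each condition is evaluated
    independently; a probe may appear under several conditions but counts
    once in :attr:`CandidateSet.unique_loci`.  Ties at the k-th rank are
    broken by lexicographic probe id.  If a condition's pool is smaller
    than its k, all eligible probes are returned and the shortfall is
    recorded.
    """
    t = means.table
    eligible = t[t["meanNC"] < nc_ceiling]

    criteria: dict[str, tuple[pd.Series, int, bool]] = {
        "a": (eligible["meanBC"] - eligible["meanNC"], k_a, False),
        "b": (
            eligible.loc[eligible["meanBC"] > beta_bc_floor, "meanNC"],
            k_b,
            True,
        ),
        "c": (eligible["meanLum"] - eligible["meanTN"], k_c, False),
        "d": (eligible["meanTN"] - eligible["meanLum"], k_d, False),
    }

    rows = []
    shortfalls: dict[str, int] = {}
    for cond, (values, k, ascending) in criteria.items():
        chosen = _top_k(values, k, ascending)
        if len(chosen) < k:
            shortfalls[cond] = k - len(chosen)
            log.warning(
                "condition (%s): only %d eligible probes for k=%d", cond, len(chosen), k
            )
        for rank, probe in enumerate(chosen, start=1):
            rows.append(
                {
                    "probe_id": probe,
                    "condition": cond,
                    "rank": rank,
                    "criterion_value": values[probe],
                    "meanNC": t.at[probe, "meanNC"],
                    "meanBC": t.at[probe, "meanBC"],
                    "meanLum": t.at[probe, "meanLum"],
                    "meanTN": t.at[probe, "meanTN"],
                }
            )

    columns = [
        "probe_id", "condition", "rank", "criterion_value",
        "meanNC", "meanBC", "meanLum", "meanTN",
    ]
    table = pd.DataFrame(rows, columns=columns)
    if len(table) and (table["meanNC"] >= nc_ceiling).any():
        raise AssertionError("selected candidate violates the meanNC ceiling")
    return CandidateSet(table=table, shortfalls=shortfalls)


def attach_welch_tests(candidates: CandidateSet, data: ArrayDataset) -> CandidateSet:
    """Annotate each candidate row with a Welch t test.

    Common-marker conditions (a, b) compare all BC samples against all
    non-BC samples; subtype conditions (c, d) compare luminal against TN
    samples.
    """
    bc = [s for g in ("BC-luminal", "BC-TN", "BC-other") for s in data.samples_in(group=g)]
    nc = data.samples_in(group="non-BC")
    lum = data.samples_in(group="BC-luminal")
    tn = data.samples_in(group="BC-TN")

    t_vals, p_vals = [], []
    for _, row in candidates.table.iterrows():
        probe = row["probe_id"]
        if row["condition"] in ("a", "b"):
            x, y = data.beta.loc[probe, bc], data.beta.loc[probe, nc]
        else:
            x, y = data.beta.loc[probe, lum], data.beta.loc[probe, tn]
        try:
            tt, pp = welch_t(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        except ValueError:
            tt, pp = np.nan, np.nan
        t_vals.append(tt)
        p_vals.append(pp)
    out = candidates.table.copy()
    out["welch_t"] = t_vals
    out["welch_p"] = p_vals
    return CandidateSet(table=out, shortfalls=dict(candidates.shortfalls))


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t statistic with a two-sided p value.

    Raises ``ValueError`` for groups of fewer than two values or when both
    groups are constant (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t test needs at least two values per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # identical constant groups: no evidence of difference
            return 0.0, 1.0
        raise ValueError("both groups have zero variance; t undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)
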