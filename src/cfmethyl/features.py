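"""The 15-variable per-sample feature table.

Variables: the log10 copies/ml of each of the 12 methylation markers, their
mean (Mean12), the log10 geometric mean of the four internal-control
concentrations (IC — the sample's total cfDNA concentration), and the count
of methylation-positive markers (Npos).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ddmsp import DEFAULT_VOLUMES, VolumeSet
from .panel import MarkerPanel, DEFAULT_PANEL

log = logging.getLogger(__name__)

MEAN12 = "Mean12"
IC = "IC"
NPOS = "Npos"


def default_epsilon(volumes: VolumeSet = DEFAULT_VOLUMES) -> float:
    """Pseudo-concentration for logging zeros: 0.5 copies per reaction,
    expressed as copies/ml plasma under the given volume chain."""
    return 0.5 * volumes.partitions_to_plasma


def count_positive_markers(calls) -> int:
    """Count positive calls among exactly 12 methylation markers."""
    calls = list(calls)
    if len(calls) != 12:
        raise ValueError(f"expected 12 positivity calls, got {len(calls)}")
    return int(sum(bool(c) for c in calls))


def feature_names(panel: MarkerPanel = DEFAULT_PANEL) -> list[str]:
    """The 15 model variable names, in canonical order."""
    return list(panel.methylation_markers) + [MEAN12, IC, NPOS]


def build_feature_table(
    quants: pd.DataFrame,
    panel: MarkerPanel = DEFAULT_PANEL,
    epsilon: float | None = None,
    mean12_scale: str = "log",
) -> pd.DataFrame:
    """Build the 15-variable feature table from quantification records.

    ``quants`` is the long-format output of :func:`cfmethyl.ddmsp.quantify_cohort`
    (columns sample_id, marker_id, concentration, positive_call).  Methylation
    marker variables are log10(concentration + ε); IC is the mean of the four
    log10 internal-control concentrations (each floored at ε), i.e. the log10
    geometric mean.  ``mean12_scale`` picks whether Mean12 averages the log10
    values ("log", default) or log-transforms the average concentration
    ("linear").  Samples missing any of the 16 markers are dropped with a
    logged reason.
    """
    if epsilon is None:
        epsilon = default_epsilon()
    if mean12_scale not in ("log", "linear"):
        raise ValueError("mean12_scale must be 'log' or 'linear'")

    conc = quants.pivot_table(index="sample_id", columns="marker_id", values="concentration")
    calls = quants.pivot_table(
        index="sample_id", columns="marker_id", values="positive_call", aggfunc="first"
    )

    needed = list(panel.all_markers)
    missing_cols = [m for m in needed if m not in conc.columns]
    if missing_cols:
        raise ValueError(f"quantification records lack markers: {missing_cols}")

    complete = conc[needed].notna().all(axis=1)
    for sample_id in conc.index[~complete]:
        absent = [m for m in needed if pd.isna(conc.at[sample_id, m])]
        log.warning("dropping sample %s: missing markers %s", sample_id, absent)
    conc = conc.loc[complete]
    calls = calls.loc[conc.index]

    meth = list(panel.methylation_markers)
    ics = list(panel.internal_controls)

    table = pd.DataFrame(index=conc.index)
    for m in meth:
        table[m] = np.log10(conc[m] + epsilon)
    if mean12_scale == "log":
        table[MEAN12] = table[meth].mean(axis=1)
    else:
        table[MEAN12] = np.log10(conc[meth].mean(axis=1) + epsilon)
    table[IC] = np.log10(conc[ics].clip(lower=epsilon)).mean(axis=1)
    table[NPOS] = calls[meth].astype(bool).sum(axis=1).astype(int)

    assert table.shape[1] == 15
    assert not table.isna().any().any()
    table.index.name = "sample_id"
    return table


def write_feature_csv(table: pd.DataFrame, path: str | Path, labels: pd.Series | None = None) -> None:
    out = table.copy()
    if labels is not None:
        out["class"] = labels.reindex(out.index)
    out.to_csv(path)


def read_feature_csv(path: str | Path) -> tuple[pd.DataFrame, pd.Series | None]:
    df = pd.read_csv(path, index_col="sample_id")
    labels = None
    if "class" in df.columns:
        labels = df.pop("class")
    return df, labels
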