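"""Absolute quantification of methylated DNA from droplet digital MSP data.

Droplet digital PCR partitions a reaction into ~10^4 droplets; template
molecules distribute into droplets approximately Poisson, so the mean number
of copies per droplet is recovered from the fraction of PCR-positive
droplets as λ = −ln(1 − n_pos/n_total).  A droplet is called positive when
its end-point fluorescence amplitude lies in a half-open window
(lower, upper]; the window is fitted per marker by maximising the ROC AUC of
the resulting per-sample concentrations against the cancer/healthy labels of
the training cohort.  Concentrations are scaled to copies per ml plasma
through the extraction/loading volume chain, and each marker gets a
positivity cutoff (copies/ml) maximising the Youden index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumeSet:
    """Volumes linking droplet counts to copies per ml plasma.

    Defaults: 0.85 nl droplets, 2 µl of eluate loaded per 20 µl reaction,
    20 µl elution volume, 0.9 ml plasma input.
    """

    droplet_volume_nl: float = 0.85
    reaction_template_volume_ul: float = 2.0
    elution_volume_ul: float = 20.0
    plasma_volume_ml: float = 0.9

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def partitions_to_plasma(self) -> float:
        """copies-in-partitions → copies per ml plasma multiplier."""
        return (self.elution_volume_ul / self.reaction_template_volume_ul) / self.plasma_volume_ml


DEFAULT_VOLUMES = VolumeSet()


@dataclass
class DropletWell:
    """Droplet amplitudes for one sample × marker reaction."""

    sample_id: str
    marker_id: str
    amplitudes: np.ndarray
    channel: str = "FAM"
    well: str = "A01"
    volumes: VolumeSet = field(default_factory=VolumeSet)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.size == 0:
            raise ValueError("a droplet well must contain at least one droplet")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("droplet amplitudes must be finite")

    @property
    def n_droplets(self) -> int:
        return int(self.amplitudes.size)


@dataclass(frozen=True)
class AmplitudeThresholds:
    """Fitted amplitude window and the training AUC it achieved."""

    lower: float
    upper: float
    achieved_auc: float = float("nan")

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower threshold must be below upper threshold")


@dataclass
class PoissonResult:
    lambda_: float
    copies_in_partitions: float
    copies_per_ul_reaction: float
    concentration: float  # copies/ml plasma


@dataclass
class MarkerQuant:
    """Per sample × marker quantification record."""

    sample_id: str
    marker_id: str
    n_pos: int
    n_total: int
    lambda_: float
    concentration: float
    log10_concentration: float
    positive_call: bool
    cutoff_used: float


@dataclass
class MarkerCutoff:
    cutoff: float
    youden_j: float
    informative: bool


class SaturationError(ValueError):
    """All droplets positive: λ is unbounded without a continuity correction."""


def count_positive_droplets(well: DropletWell, thr: AmplitudeThresholds) -> int:
    """Number of droplets with amplitude in the half-open window (lower, upper]."""
    a = well.amplitudes
    return int(np.count_nonzero((a > thr.lower) & (a <= thr.upper)))


def poisson_concentration(
    n_pos: int,
    n_total: int,
    volumes: VolumeSet = DEFAULT_VOLUMES,
    saturation_correction: bool = False,
) -> PoissonResult:
    """Poisson-corrected absolute concentration from a positive-droplet count.

    λ = −ln(1 − n_pos/n_total); copies in the measured partitions are
    λ·n_total; copies/ml plasma follow from the elution/loading/plasma
    volume chain.  A fully saturated well (n_pos == n_total) raises
    :class:`SaturationError` unless ``saturation_correction`` substitutes
    (n_pos − 0.5)/n_total.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValueError("n_pos must lie in [0, n_total]")
    if n_pos == n_total:
        if not saturation_correction:
            raise SaturationError(
                f"all {n_total} droplets positive; λ unbounded "
                "(pass saturation_correction=True for a continuity correction)"
            )
        frac = (n_pos - 0.5) / n_total
    else:
        frac = n_pos / n_total
    lam = -np.log1p(-frac)
    copies_in_partitions = lam * n_total
    copies_per_ul = lam / (volumes.droplet_volume_nl * 1e-3)
    concentration = copies_in_partitions * volumes.partitions_to_plasma
    return PoissonResult(float(lam), float(copies_in_partitions), float(copies_per_ul), float(concentration))


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC (ties count 1/2) of scores for labels == 1."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise Mann–Whitney AUC for a (n_rows × n_samples) score matrix."""
    ranks = stats.rankdata(scores, axis=1)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return (ranks[:, labels == 1].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)


def pool_wells(wells: list[DropletWell]) -> DropletWell:
    """Merge all wells of one sample × marker into a single virtual well."""
    if not wells:
        raise ValueError("no wells to pool")
    first = wells[0]
    for w in wells[1:]:
        if (w.sample_id, w.marker_id) != (first.sample_id, first.marker_id):
            raise ValueError("can only pool wells of one sample × marker")
    return DropletWell(
        sample_id=first.sample_id,
        marker_id=first.marker_id,
        amplitudes=np.concatenate([w.amplitudes for w in wells]),
        channel=first.channel,
        well="pooled",
        volumes=first.volumes,
    )


def optimize_amplitude_thresholds(
    wells: dict[str, list[DropletWell]],
    labels: dict[str, int],
    n_grid: int = 64,
    grid: np.ndarray | None = None,
) -> AmplitudeThresholds:
    """Fit the amplitude window maximising single-marker training AUC.

    ``wells`` maps sample id to that sample's wells for one marker;
    ``labels`` maps sample id to 1 (cancer) / 0 (healthy).  Candidate
    thresholds are ``n_grid`` pooled-amplitude quantiles, which makes the
    achieved AUC invariant to any strictly monotone amplitude rescaling;
    an explicit ``grid`` of candidate threshold values overrides the
    quantile grid.  Ties are broken toward the smallest lower and then the
    largest upper threshold.
    """
    sample_ids = sorted(wells)
    y = np.array([labels[s] for s in sample_ids], dtype=int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("threshold optimisation needs ≥2 samples per class")

    pooled = [pool_wells(wells[s]) for s in sample_ids]
    all_amp = np.concatenate([w.amplitudes for w in pooled])
    if grid is None:
        # Positive droplets are typically a small upper tail of the pooled
        # amplitude distribution, so half the quantile levels are spent on
        # the upper tail (log-spaced) and half uniformly; levels are fixed,
        # keeping the search invariant to monotone amplitude rescaling.
        half = max(n_grid // 2, 2)
        levels = np.concatenate(
            [np.linspace(0.0, 1.0, half), 1.0 - np.logspace(-5, np.log10(0.5), n_grid - half)]
        )
        levels = np.unique(np.clip(levels, 0.0, 1.0))
        grid = np.unique(np.quantile(all_amp, levels))
    else:
        grid = np.unique(np.asarray(grid, dtype=float))
    if grid.size < 2:
        log.warning("all droplet amplitudes identical; degenerate thresholds returned")
        a = float(grid[0])
        return AmplitudeThresholds(a - 1.0, a, achieved_auc=float("nan"))

    # counts of amplitudes ≤ g for every grid point, per sample
    cum = np.empty((len(pooled), grid.size), dtype=np.int64)
    totals = np.empty(len(pooled), dtype=np.int64)
    for i, w in enumerate(pooled):
        srt = np.sort(w.amplitudes)
        cum[i] = np.searchsorted(srt, grid, side="right")
        totals[i] = srt.size

    lo_idx, up_idx = np.triu_indices(grid.size, k=1)
    n_pos = cum[:, up_idx] - cum[:, lo_idx]  # samples × pairs
    frac = n_pos / totals[:, None]
    # continuity-cap saturated fractions so λ stays finite for ranking
    frac = np.minimum(frac, (totals[:, None] - 0.5) / totals[:, None])
    lam = -np.log1p(-frac)
    conc = lam * totals[:, None] * np.array([w.volumes.partitions_to_plasma for w in pooled])[:, None]

    aucs = _auc_rows(conc.T, y)
    best = np.max(aucs)
    candidates = np.flatnonzero(aucs >= best - 1e-12)
    # smallest lower, then largest upper
    order = np.lexsort((-up_idx[candidates], lo_idx[candidates]))
    pick = candidates[order[0]]
    return AmplitudeThresholds(
        lower=float(grid[lo_idx[pick]]),
        upper=float(grid[up_idx[pick]]),
        achieved_auc=float(best),
    )


def determine_marker_cutoff(
    concentrations: np.ndarray, labels: np.ndarray
) -> MarkerCutoff:
    """Youden-optimal positivity cutoff over midpoints of sorted unique values.

    Positivity is ``concentration > cutoff``; ties in J are broken toward
    the lower cutoff.  A cutoff with J = 0 is flagged non-informative.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("cutoff determination needs both classes")
    uniq = np.unique(concentrations)
    if uniq.size == 1:
        return MarkerCutoff(cutoff=float(uniq[0]), youden_j=0.0, informative=False)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n1 = labels.sum()
    n0 = len(labels) - n1
    best_j, best_cut = -np.inf, None
    for cut in mids:
        pos = concentrations > cut
        sens = (pos & (labels == 1)).sum() / n1
        spec = (~pos & (labels == 0)).sum() / n0
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_cut = j, cut
    return MarkerCutoff(cutoff=float(best_cut), youden_j=float(best_j), informative=best_j > 0)


def quantify_sample_marker(
    wells: list[DropletWell],
    thr: AmplitudeThresholds,
    cutoff: float,
    epsilon: float = 0.0,
    saturation_correction: bool = True,
) -> MarkerQuant:
    """Pool a sample × marker's wells and produce its quantification record."""
    pooled = pool_wells(wells)
    n_pos = count_positive_droplets(pooled, thr)
    res = poisson_concentration(
        n_pos, pooled.n_droplets, pooled.volumes, saturation_correction=saturation_correction
    )
    return MarkerQuant(
        sample_id=pooled.sample_id,
        marker_id=pooled.marker_id,
        n_pos=n_pos,
        n_total=pooled.n_droplets,
        lambda_=res.lambda_,
        concentration=res.concentration,
        log10_concentration=float(np.log10(res.concentration + epsilon)) if res.concentration + epsilon > 0 else float("-inf"),
        positive_call=res.concentration > cutoff,
        cutoff_used=float(cutoff),
    )


# ---------------------------------------------------------------------------
# cohort-level driver + persistence

@dataclass
class QuantModelState:
    """Training-derived thresholds/cutoffs, reusable on a validation cohort."""

    thresholds: dict[str, AmplitudeThresholds]
    cutoffs: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": {
                m: {"lower": t.lower, "upper": t.upper, "achieved_auc": t.achieved_auc}
                for m, t in self.thresholds.items()
            },
            "cutoffs": self.cutoffs,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "QuantModelState":
        payload = json.loads(Path(path).read_text())
        thr = {
            m: AmplitudeThresholds(d["lower"], d["upper"], d.get("achieved_auc", float("nan")))
            for m, d in payload["thresholds"].items()
        }
        return cls(thresholds=thr, cutoffs={m: float(c) for m, c in payload["cutoffs"].items()})


def fit_quantification(
    wells_by_marker: dict[str, dict[str, list[DropletWell]]],
    labels: dict[str, int],
    n_grid: int = 64,
) -> QuantModelState:
    """Fit per-marker amplitude windows and concentration cutoffs on training data."""
    thresholds: dict[str, AmplitudeThresholds] = {}
    cutoffs: dict[str, float] = {}
    for marker, sample_wells in wells_by_marker.items():
        thr = optimize_amplitude_thresholds(sample_wells, labels, n_grid=n_grid)
        thresholds[marker] = thr
        sample_ids = sorted(sample_wells)
        conc = np.array(
            [
                quantify_sample_marker(sample_wells[s], thr, cutoff=0.0).concentration
                for s in sample_ids
            ]
        )
        y = np.array([labels[s] for s in sample_ids], dtype=int)
        cutoffs[marker] = determine_marker_cutoff(conc, y).cutoff
    return QuantModelState(thresholds=thresholds, cutoffs=cutoffs)


def quantify_cohort(
    wells_by_marker: dict[str, dict[str, list[DropletWell]]],
    state: QuantModelState,
) -> pd.DataFrame:
    """Quantify every sample × marker with fitted thresholds and cutoffs."""
    records = []
    for marker, sample_wells in wells_by_marker.items():
        thr = state.thresholds[marker]
        cut = state.cutoffs[marker]
        for sample_id in sorted(sample_wells):
            q = quantify_sample_marker(sample_wells[sample_id], thr, cut)
            records.append(vars(q))
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# droplet CSV I/O (QuantaSoft-style long export)

DROPLET_COLUMNS = ["sample_id", "marker", "well", "channel", "amplitude"]


def read_droplet_csv(
    path: str | Path, volumes: VolumeSet = DEFAULT_VOLUMES
) -> dict[str, dict[str, list[DropletWell]]]:
    """Read a long-format droplet CSV into marker → sample → wells."""
    df = pd.read_csv(path)
    missing = set(DROPLET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"droplet CSV lacks columns: {sorted(missing)}")
    out: dict[str, dict[str, list[DropletWell]]] = {}
    grouped = df.groupby(["marker", "sample_id", "well"], sort=True)
    for (marker, sample_id, well), sub in grouped:
        out.setdefault(marker, {}).setdefault(sample_id, []).append(
            DropletWell(
                sample_id=sample_id,
                marker_id=marker,
                amplitudes=sub["amplitude"].to_numpy(dtype=float),
                channel=str(sub["channel"].iloc[0]),
                well=str(well),
                volumes=volumes,
            )
        )
    return out


def write_droplet_csv(
    wells_by_marker: dict[str, dict[str, list[DropletWell]]], path: str | Path
) -> None:
    chunks = []
    for marker in sorted(wells_by_marker):
        for sample_id in sorted(wells_by_marker[marker]):
            for w in wells_by_marker[marker][sample_id]:
                chunks.append(
                    pd.DataFrame(
                        {
                            "sample_id": sample_id,
                            "marker": marker,
                            "well": w.well,
                            "channel": w.channel,
                            "amplitude": w.amplitudes,
                        }
                    )
                )
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False)
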