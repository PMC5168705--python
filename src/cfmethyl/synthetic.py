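"""Synthetic data generators with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs:

* :func:`gen_array_dataset` — a β-value matrix over cell-line/FFPE/blood
  strata with planted hypermethylated probes for each selection condition
  on a low-background (β < 0.05) non-cancer baseline;
* :func:`gen_roster` — a case/control cohort with stage, subtype, age and
  plasma volume;
* :func:`gen_droplet_dataset` — droplet amplitude data per sample × marker,
  with two amplitude clusters, "rain" between them, and Poisson occupancy
  of droplets by template copies.

Every generator is deterministic for a fixed seed and emits a ground-truth
manifest so downstream recovery can be checked against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arrays import ArrayDataset
from .ddmsp import DropletWell, VolumeSet
from .panel import MarkerPanel, DEFAULT_PANEL

# ---------------------------------------------------------------------------
# methylation array simulation


@dataclass(frozen=True)
class ArraySimConfig:
    """Configuration for the planted-probe β-matrix generator.

    Sample-count defaults mirror the discovery design: a handful of luminal
    cell lines, a large luminal FFPE stratum, many TN cell lines, a smaller
    TN FFPE stratum, blood from healthy volunteers and pooled normal
    epithelia.
    """

    n_probes: int = 2000
    n_lum_cell: int = 7
    n_lum_ffpe: int = 42
    n_tn_cell: int = 18
    n_tn_ffpe: int = 11
    n_nc_blood: int = 29
    n_nc_epithelia: int = 2
    n_planted_a: int = 20
    n_planted_b: int = 20
    n_planted_c: int = 50
    n_planted_d: int = 50
    background_beta_mean: float = 0.02
    background_beta_sd: float = 0.01
    # planted β means: (BC-high, NC) for common classes; (dominant, recessive)
    # for the subtype classes
    beta_a: tuple[float, float] = (0.80, 0.02)
    beta_b: tuple[float, float] = (0.70, 0.003)
    beta_dominant: float = 0.85
    beta_recessive: float = 0.02
    planted_beta_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_beta_mean >= 0.05:
            raise ValueError("background β mean must stay below the 0.05 NC ceiling")
        if self.n_total_planted > self.n_probes:
            raise ValueError(
                f"{self.n_total_planted} planted probes exceed n_probes={self.n_probes}"
            )
        for n in (self.n_lum_cell, self.n_lum_ffpe, self.n_tn_cell, self.n_tn_ffpe,
                  self.n_nc_blood):
            if n < 0:
                raise ValueError("sample counts must be non-negative")

    @property
    def n_total_planted(self) -> int:
        return self.n_planted_a + self.n_planted_b + self.n_planted_c + self.n_planted_d


def _clipped_beta(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=size), 0.0, 1.0)


def gen_array_dataset(cfg: ArraySimConfig) -> tuple[ArrayDataset, dict[str, list[str]]]:
    """Generate a planted β-value matrix and its ground-truth manifest.

    The manifest maps each selection condition ('a', 'b', 'c', 'd') to the
    probes planted to win it; the four lists are disjoint.
    """
    rng = np.random.default_rng(cfg.seed)

    strata = [
        ("BC-luminal", "cell-line", cfg.n_lum_cell, "LumCL"),
        ("BC-luminal", "FFPE", cfg.n_lum_ffpe, "LumFFPE"),
        ("BC-TN", "cell-line", cfg.n_tn_cell, "TnCL"),
        ("BC-TN", "FFPE", cfg.n_tn_ffpe, "TnFFPE"),
        ("non-BC", "blood", cfg.n_nc_blood, "Blood"),
        ("non-BC", "epithelia", cfg.n_nc_epithelia, "Epi"),
    ]
    sample_ids, groups, materials = [], [], []
    for group, material, n, prefix in strata:
        for i in range(n):
            sample_ids.append(f"{prefix}_{i + 1:03d}")
            groups.append(group)
            materials.append(material)

    probe_ids = [f"cg{i + 1:08d}" for i in range(cfg.n_probes)]
    planted_idx = rng.choice(cfg.n_probes, size=cfg.n_total_planted, replace=False)
    bounds = np.cumsum([cfg.n_planted_a, cfg.n_planted_b, cfg.n_planted_c, cfg.n_planted_d])
    idx_a, idx_b, idx_c, idx_d = np.split(planted_idx, bounds[:-1])
    manifest = {
        "a": sorted(probe_ids[i] for i in idx_a),
        "b": sorted(probe_ids[i] for i in idx_b),
        "c": sorted(probe_ids[i] for i in idx_c),
        "d": sorted(probe_ids[i] for i in idx_d),
    }

    beta = _clipped_beta(
        rng, cfg.background_beta_mean, cfg.background_beta_sd,
        (cfg.n_probes, len(sample_ids)),
    )
    groups_arr = np.array(groups)
    is_bc = groups_arr != "non-BC"
    is_lum = groups_arr == "BC-luminal"
    is_tn = groups_arr == "BC-TN"
    is_nc = ~is_bc
    sd = cfg.planted_beta_sd

    for idx, (bc_mean, nc_mean) in ((idx_a, cfg.beta_a), (idx_b, cfg.beta_b)):
        for i in idx:
            beta[i, is_bc] = _clipped_beta(rng, bc_mean, sd, is_bc.sum())
            beta[i, is_nc] = _clipped_beta(rng, nc_mean, nc_mean / 2 + 1e-3, is_nc.sum())
    for i in idx_c:
        beta[i, is_lum] = _clipped_beta(rng, cfg.beta_dominant, sd, is_lum.sum())
        beta[i, is_tn] = _clipped_beta(rng, cfg.beta_recessive, sd / 3, is_tn.sum())
    for i in idx_d:
        beta[i, is_tn] = _clipped_beta(rng, cfg.beta_dominant, sd, is_tn.sum())
        beta[i, is_lum] = _clipped_beta(rng, cfg.beta_recessive, sd / 3, is_lum.sum())

    dataset = ArrayDataset(
        beta=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        sample_groups=pd.Series(groups, index=sample_ids),
        sample_materials=pd.Series(materials, index=sample_ids),
    )
    return dataset, manifest


# ---------------------------------------------------------------------------
# cohort roster simulation


STAGES = ("0", "I", "IIA", "IIB", "III", "IV")
SUBTYPES = ("luminal", "TN", "HER2", "luminal-HER2", "DCIS-unassessed")


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration for the cohort/droplet generators.

    Stage and subtype compositions, age ranges, the class/stage-dependent
    cfDNA concentration model (cfDNA is elevated in cancer, increasingly so
    at later stages), the per-marker methylated-fraction model, and droplet
    reader characteristics.
    """

    n_hv: int = 133
    n_bc: int = 145
    stage_dist: dict[str, float] = field(
        default_factory=lambda: {
            "0": 4 / 145, "I": 47 / 145, "IIA": 31 / 145,
            "IIB": 22 / 145, "III": 9 / 145, "IV": 32 / 145,
        }
    )
    subtype_dist: dict[str, float] = field(
        default_factory=lambda: {
            "luminal": 98 / 145, "TN": 25 / 145, "HER2": 10 / 145,
            "luminal-HER2": 8 / 145, "DCIS-unassessed": 4 / 145,
        }
    )
    age_range_hv: tuple[float, float] = (22, 70)
    age_range_bc: tuple[float, float] = (36, 81)
    plasma_volume_ml: float = 0.9

    # log10 copies/ml of total cfDNA
    cfdna_hv_log10_mean: float = 3.0
    cfdna_hv_log10_sd: float = 0.22
    cfdna_bc_log10_sd: float = 0.28
    cfdna_stage_shift: dict[str, float] = field(
        default_factory=lambda: {
            "0": 0.32, "I": 0.32, "IIA": 0.40, "IIB": 0.45, "III": 0.45, "IV": 0.60,
        }
    )
    ic_marker_log10_sd: float = 0.08

    # methylated-fraction model for the 12 methylation markers
    shed_prob_common: float = 0.45
    shed_prob_dominant: float = 0.55
    shed_prob_recessive: float = 0.15
    shed_prob_other_subtype: float = 0.30
    hv_background_prob: float = 0.05
    frac_log10_mean: float = -1.7
    frac_log10_sd: float = 0.5
    hv_frac_log10_mean: float = -3.0
    hv_frac_log10_sd: float = 0.3
    stage_fraction_mult: dict[str, float] = field(
        default_factory=lambda: {
            "0": 0.5, "I": 0.7, "IIA": 1.0, "IIB": 1.3, "III": 1.5, "IV": 2.5,
        }
    )

    # droplet reader model
    n_droplets: int = 12000
    n_droplets_cv: float = 0.08  # well-to-well accepted-droplet count variation
    neg_amplitude_mean: float = 1000.0
    neg_amplitude_sd: float = 120.0
    pos_amplitude_mean: float = 8000.0
    pos_amplitude_sd: float = 400.0
    rain_fraction: float = 0.10
    volumes: VolumeSet = field(default_factory=VolumeSet)

    seed: int = 0

    def __post_init__(self) -> None:
        for dist, name in ((self.stage_dist, "stage"), (self.subtype_dist, "subtype")):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        if self.pos_amplitude_mean <= self.neg_amplitude_mean:
            raise ValueError("positive amplitude cluster must sit above the negative one")
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if not 0 <= self.rain_fraction < 1:
            raise ValueError("rain_fraction must lie in [0, 1)")


def _largest_remainder_counts(dist: dict[str, float], n: int) -> dict[str, int]:
    keys = list(dist)
    exact = np.array([dist[k] * n for k in keys])
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def gen_roster(cfg: CohortSimConfig) -> pd.DataFrame:
    """Generate a sample roster: class, stage, subtype, age, plasma volume.

    Stage and subtype counts follow the configured proportions exactly
    (largest-remainder apportionment); in-situ-only samples (the
    DCIS-unassessed subtype) are forced to stage 0 when counts allow,
    mirroring how in-situ disease presents.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for i in range(cfg.n_hv):
        rows.append(
            {
                "sample_id": f"HV_{i + 1:04d}",
                "class": "HV",
                "stage": "none",
                "subtype": "none",
                "age": float(rng.uniform(*cfg.age_range_hv)),
                "plasma_volume": cfg.plasma_volume_ml,
                "split": "unassigned",
            }
        )

    stage_counts = _largest_remainder_counts(cfg.stage_dist, cfg.n_bc)
    subtype_counts = _largest_remainder_counts(cfg.subtype_dist, cfg.n_bc)
    stages = [s for s, c in stage_counts.items() for _ in range(c)]
    subtypes = [s for s, c in subtype_counts.items() for _ in range(c)]
    rng.shuffle(stages)
    rng.shuffle(subtypes)
    # pair DCIS-unassessed with stage 0 where possible
    dcis_pos = [i for i, s in enumerate(subtypes) if s == "DCIS-unassessed"]
    stage0_pos = [i for i, s in enumerate(stages) if s == "0"]
    for d, z in zip(dcis_pos, stage0_pos):
        stages[d], stages[z] = stages[z], stages[d]

    for i in range(cfg.n_bc):
        rows.append(
            {
                "sample_id": f"BC_{i + 1:04d}",
                "class": "BC",
                "stage": stages[i],
                "subtype": subtypes[i],
                "age": float(rng.uniform(*cfg.age_range_bc)),
                "plasma_volume": cfg.plasma_volume_ml,
                "split": "unassigned",
            }
        )
    roster = pd.DataFrame(rows).set_index("sample_id", drop=False)
    roster.index.name = None
    return roster


def table1_cohort_config(seed: int = 0, **overrides) -> CohortSimConfig:
    """The published-cohort preset: 133 HV / 145 BC with its stage and
    subtype composition."""
    return replace(CohortSimConfig(seed=seed), **overrides)


def small_cohort_config(seed: int = 0, n_hv: int = 30, n_bc: int = 30, **overrides) -> CohortSimConfig:
    """Reduced preset for end-to-end runs: same composition and effect
    sizes, fewer samples and droplets."""
    fields = {"n_hv": n_hv, "n_bc": n_bc, "n_droplets": 2000}
    fields.update(overrides)
    return replace(CohortSimConfig(seed=seed), **fields)


# ---------------------------------------------------------------------------
# droplet-level simulation


def _true_marker_concentrations(
    roster: pd.DataFrame, panel: MarkerPanel, cfg: CohortSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-sample true concentrations (copies/ml plasma) for all markers."""
    records = []
    for _, row in roster.iterrows():
        is_bc = row["class"] == "BC"
        if is_bc:
            mu = cfg.cfdna_hv_log10_mean + cfg.cfdna_stage_shift[row["stage"]]
            cfdna = 10 ** rng.normal(mu, cfg.cfdna_bc_log10_sd)
        else:
            cfdna = 10 ** rng.normal(cfg.cfdna_hv_log10_mean, cfg.cfdna_hv_log10_sd)

        for marker in panel.all_markers:
            klass = panel.dominance_class(marker)
            if klass == "ic":
                conc = cfdna * 10 ** rng.normal(0.0, cfg.ic_marker_log10_sd)
            elif not is_bc:
                if rng.random() < cfg.hv_background_prob:
                    conc = cfdna * 10 ** rng.normal(cfg.hv_frac_log10_mean, cfg.hv_frac_log10_sd)
                else:
                    conc = 0.0
            else:
                subtype = row["subtype"]
                if klass == "common":
                    p = cfg.shed_prob_common if subtype in ("luminal", "TN") else cfg.shed_prob_other_subtype
                elif klass == "luminal":
                    p = {
                        "luminal": cfg.shed_prob_dominant,
                        "luminal-HER2": cfg.shed_prob_dominant,
                        "TN": cfg.shed_prob_recessive,
                    }.get(subtype, cfg.shed_prob_other_subtype)
                else:  # tn-dominant
                    p = {
                        "TN": cfg.shed_prob_dominant,
                        "luminal": cfg.shed_prob_recessive,
                    }.get(subtype, cfg.shed_prob_other_subtype)
                if rng.random() < p:
                    frac = 10 ** rng.normal(cfg.frac_log10_mean, cfg.frac_log10_sd)
                    frac *= cfg.stage_fraction_mult[row["stage"]]
                    conc = cfdna * min(frac, 1.0)
                elif rng.random() < cfg.hv_background_prob:
                    conc = cfdna * 10 ** rng.normal(cfg.hv_frac_log10_mean, cfg.hv_frac_log10_sd)
                else:
                    conc = 0.0
            records.append(
                {
                    "sample_id": row["sample_id"],
                    "marker": marker,
                    "true_concentration": float(conc),
                    "true_cfdna": float(cfdna),
                }
            )
    return pd.DataFrame(records)


def _occupied_droplets(rng: np.random.Generator, n_copies: int, n_droplets: int) -> int:
    """Number of distinct droplets occupied by n_copies uniform template copies."""
    if n_copies == 0:
        return 0
    return int(np.unique(rng.integers(0, n_droplets, size=n_copies)).size)


def simulate_well(
    rng: np.random.Generator,
    sample_id: str,
    marker: str,
    lam: float,
    cfg: CohortSimConfig,
    channel: str = "FAM",
    well: str = "A01",
) -> DropletWell:
    """Simulate one well at mean copies-per-droplet ``lam``.

    Copies are drawn Poisson(λ·N) and assigned to droplets uniformly, so the
    positive fraction concentrates on 1 − e^(−λ).  A ``rain_fraction`` of
    positive droplets lands uniformly between the two amplitude cluster
    means instead of in the positive cluster.  The accepted-droplet count N
    varies well to well (coefficient of variation ``n_droplets_cv``), as it
    does on a real droplet reader.
    """
    n = cfg.n_droplets
    if cfg.n_droplets_cv > 0:
        n = max(200, int(round(rng.normal(n, cfg.n_droplets_cv * n))))
    n_copies = int(rng.poisson(lam * n))
    n_pos = _occupied_droplets(rng, n_copies, n)
    n_rain = int(rng.binomial(n_pos, cfg.rain_fraction)) if n_pos else 0
    n_full_pos = n_pos - n_rain
    n_neg = n - n_pos

    amps = np.concatenate(
        [
            rng.normal(cfg.neg_amplitude_mean, cfg.neg_amplitude_sd, n_neg),
            rng.normal(cfg.pos_amplitude_mean, cfg.pos_amplitude_sd, n_full_pos),
            rng.uniform(cfg.neg_amplitude_mean, cfg.pos_amplitude_mean, n_rain),
        ]
    )
    rng.shuffle(amps)
    amps = np.clip(amps, 1.0, None)
    vols = replace(cfg.volumes, plasma_volume_ml=cfg.plasma_volume_ml)
    return DropletWell(
        sample_id=sample_id, marker_id=marker, amplitudes=amps,
        channel=channel, well=well, volumes=vols,
    )


def gen_droplet_dataset(
    roster: pd.DataFrame,
    panel: MarkerPanel = DEFAULT_PANEL,
    cfg: CohortSimConfig | None = None,
) -> tuple[dict[str, dict[str, list[DropletWell]]], pd.DataFrame]:
    """Simulate droplet wells for every sample × marker.

    Returns (wells_by_marker, manifest) where the manifest records each
    sample × marker's true concentration and the per-droplet λ implied by
    the volume chain.
    """
    if cfg is None:
        cfg = CohortSimConfig()
    if roster.empty:
        raise ValueError("roster is empty")
    rng = np.random.default_rng(cfg.seed + 1)

    truth = _true_marker_concentrations(roster, panel, cfg, rng)
    vols = replace(cfg.volumes, plasma_volume_ml=cfg.plasma_volume_ml)
    truth["lambda_true"] = (
        truth["true_concentration"] / vols.partitions_to_plasma / cfg.n_droplets
    )

    wells: dict[str, dict[str, list[DropletWell]]] = {m: {} for m in panel.all_markers}
    for _, row in truth.iterrows():
        marker = row["marker"]
        w = simulate_well(
            rng,
            sample_id=row["sample_id"],
            marker=marker,
            lam=row["lambda_true"],
            cfg=cfg,
            channel=DEFAULT_PANEL.channel_map.get(marker, "FAM"),
        )
        wells[marker].setdefault(row["sample_id"], []).append(w)
    return wells, truth
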