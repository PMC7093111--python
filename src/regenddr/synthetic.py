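"""Synthetic inputs with planted ground truth.

Generates every table the pipeline consumes — timecourse expression
matrices with planted up/down/mixed/none regulation classes, anchor-set
matrices with planted positively/negatively associated genes, per-cell
γ-H2AX foci tables with genotype- and EdU-dependent density distributions,
and the ancillary densitometry / skeletal / comet tables — so each
downstream stage can be tested against known labels without external data.

Noise is multiplicative log-normal with a configurable coefficient of
variation (expression values are strictly positive); at ``noise_cv = 0``
every planted label is recoverable exactly by the downstream rules. Focus
counts are Poisson with mean density x area, the simplest count model
consistent with per-nucleus focus counting. Class counts follow the largest
remainder rule, so planted proportions are preserved deterministically.

Each generator op draws from its own pseudo-random stream (seed + a fixed
per-op offset), so adding one generator to a run never perturbs another's
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytometry import CellFociRecord, FociBinConfig, bin_density
from .errors import ConfigurationError, DegenerateAnchorError
from .morphology import FULL_PATTERN
from .timecourse import DEFAULT_TIMEPOINTS, TimecourseExpressionSet

# per-op offsets added to the base seed (one independent stream per op)
_STREAM_TIMECOURSE = 0
_STREAM_ANCHOR = 1
_STREAM_CELLS = 2
_STREAM_ANCILLARY = 3

REGULATION_CLASSES = ("up", "down", "mixed", "none")

_DEFAULT_PROPORTIONS = {"up": 0.25, "down": 0.25, "mixed": 0.25, "none": 0.25}

# per-(genotype, EdU) mean density and gamma shape; densities in the same
# 1e6-magnitude units as the default bin thresholds
_DEFAULT_DENSITY_PARAMS = {
    ("wildtype", False): {"mean": 4.0e6, "shape": 2.0},
    ("wildtype", True): {"mean": 1.2e7, "shape": 3.0},
    ("mutant", False): {"mean": 8.0e6, "shape": 2.0},
    ("mutant", True): {"mean": 2.2e7, "shape": 3.0},
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic generators.

    ``fold_effect`` is the planted fold excursion of regulated genes
    (>= 2, default 4 — a margin over the fold-2 calling threshold so that
    recovery under noise reflects the noise, not boundary coincidence);
    ``noise_cv`` the multiplicative log-normal coefficient of variation;
    ``zero_density_fraction`` the fraction of cells planted with exactly
    zero focus density (the Zero bin).
    """

    seed: int = 0
    n_genes: int = 2000
    timepoints_dpa: tuple[int, ...] = DEFAULT_TIMEPOINTS
    class_proportions: dict = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    fold_effect: float = 4.0
    noise_cv: float = 0.1
    anchor_set_sizes: dict = field(
        default_factory=lambda: {"positive": 100, "negative": 100}
    )
    n_cells_per_group: int = 500
    density_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_DENSITY_PARAMS.items()}
    )
    zero_density_fraction: float = 0.1
    mean_nucleus_area: float = 3.0e-6

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.get(c, 0.0) for c in REGULATION_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class proportions sum to {total}, expected 1"
            )
        if any(p < 0 for p in self.class_proportions.values()):
            raise ConfigurationError("class proportions must be nonnegative")
        tps = tuple(self.timepoints_dpa)
        if 0 not in tps or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ConfigurationError(
                "timepoints must be strictly increasing and contain 0"
            )
        if any(t < 0 for t in tps):
            raise ConfigurationError("timepoints must be nonnegative")
        if self.fold_effect < 2:
            raise ConfigurationError("fold_effect must be at least 2")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be nonnegative")
        if self.n_genes < 0 or self.n_cells_per_group < 0:
            raise ConfigurationError("counts must be nonnegative")
        if not (0 <= self.zero_density_fraction <= 1):
            raise ConfigurationError("zero_density_fraction must be in [0, 1]")
        if not self.mean_nucleus_area > 0:
            raise ConfigurationError("mean_nucleus_area must be positive")
        for key, par in self.density_params.items():
            if par["mean"] < 0 or par["shape"] <= 0:
                raise ConfigurationError(f"bad density params for group {key}")


@dataclass
class PlantedTruth:
    """Ground-truth labels for generated objects (exactly one per object)."""

    gene_regulation: dict[str, str] = field(default_factory=dict)
    gene_anchor_class: dict[str, str] = field(default_factory=dict)
    cell_bin: dict[str, str] = field(default_factory=dict)


def largest_remainder_counts(n: int, proportions: dict[str, float],
                             order: tuple[str, ...]) -> dict[str, int]:
    """Apportion n into integer class counts by the largest remainder rule.

    Ties in the fractional remainders are broken by the fixed class order.
    """
    quotas = {c: n * proportions.get(c, 0.0) for c in order}
    counts = {c: int(np.floor(quotas[c])) for c in order}
    short = n - sum(counts.values())
    by_remainder = sorted(
        order, key=lambda c: (-(quotas[c] - counts[c]), order.index(c))
    )
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def generate_timecourse(
    config: SimulationConfig,
) -> tuple[TimecourseExpressionSet, PlantedTruth]:
    """Expression matrix with planted regulation classes.

    Planted "up" genes carry an expected excursion of ``fold_effect`` x
    intact at one to three regeneration timepoints; "down" genes the
    reciprocal; "mixed" genes one up and one down excursion at distinct
    timepoints; "none" genes stay within a safe interior band (expected
    ratios in [0.8, 1.25]) so they cannot cross the fold-2 thresholds at
    zero noise.
    """
    rng = np.random.default_rng(config.seed + _STREAM_TIMECOURSE)
    tps = list(config.timepoints_dpa)
    later = [t for t in tps if t != 0]
    counts = largest_remainder_counts(
        config.n_genes, config.class_proportions, REGULATION_CLASSES
    )
    labels = [c for c in REGULATION_CLASSES for _ in range(counts[c])]

    n = config.n_genes
    gene_ids = [f"gene{str(i).zfill(len(str(max(n - 1, 1))))}" for i in range(n)]
    intact = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n)
    ratios = np.empty((n, len(tps)))
    for i, label in enumerate(labels):
        row = dict.fromkeys(tps, None)
        row[0] = 1.0
        base = rng.uniform(0.8, 1.25, size=len(later))
        for j, t in enumerate(later):
            row[t] = base[j]
        if label == "up":
            for t in rng.choice(later, size=rng.integers(1, 4), replace=False):
                row[t] = config.fold_effect
        elif label == "down":
            for t in rng.choice(later, size=rng.integers(1, 4), replace=False):
                row[t] = 1.0 / config.fold_effect
        elif label == "mixed":
            t_up, t_down = rng.choice(later, size=2, replace=False)
            row[t_up] = config.fold_effect
            row[t_down] = 1.0 / config.fold_effect
        ratios[i] = [row[t] for t in tps]

    values = intact[:, None] * ratios
    noise = _lognormal_noise(rng, config.noise_cv, values.shape)
    # the intact reference stays noise-free so planted ratios are exact at
    # the effect timepoints; regeneration timepoints carry the noise
    noise[:, tps.index(0)] = 1.0
    values = values * noise

    expr = TimecourseExpressionSet(
        pd.DataFrame(values, index=gene_ids, columns=tps), platform="rnaseq"
    )
    truth = PlantedTruth(gene_regulation=dict(zip(gene_ids, labels)))
    return expr, truth


def generate_anchor_set(
    config: SimulationConfig,
    anchor_profile: np.ndarray,
    anchor_gene: str = "anchor",
) -> tuple[TimecourseExpressionSet, PlantedTruth]:
    """Expression matrix with genes planted around an anchor profile.

    Planted positives are affine transforms of the anchor with positive
    gain (plus noise), planted negatives with negative gain (offset so all
    values stay positive), and the remaining genes are drawn independently
    of the anchor. The anchor itself is included as row ``anchor_gene``.
    """
    rng = np.random.default_rng(config.seed + _STREAM_ANCHOR)
    anchor = np.asarray(anchor_profile, dtype=float)
    tps = list(config.timepoints_dpa)
    if anchor.shape != (len(tps),):
        raise ConfigurationError(
            f"anchor profile length {anchor.shape} != timepoints {len(tps)}"
        )
    if np.ptp(anchor) == 0:
        raise DegenerateAnchorError("anchor profile is constant")

    n_pos = int(config.anchor_set_sizes.get("positive", 0))
    n_neg = int(config.anchor_set_sizes.get("negative", 0))
    if n_pos + n_neg > config.n_genes:
        raise ConfigurationError("anchor set sizes exceed n_genes")
    n_una = config.n_genes - n_pos - n_neg

    rows, labels, gene_ids = [], [], []
    width = len(str(max(config.n_genes - 1, 1)))
    for i in range(n_pos):
        gain = rng.uniform(0.5, 3.0)
        intercept = rng.uniform(0.0, 20.0)
        rows.append(intercept + gain * anchor)
        labels.append("positive")
        gene_ids.append(f"pos{str(i).zfill(width)}")
    for i in range(n_neg):
        gain = -rng.uniform(0.5, 3.0)
        intercept = -gain * anchor.max() * rng.uniform(1.05, 1.5)
        rows.append(intercept + gain * anchor)
        labels.append("negative")
        gene_ids.append(f"neg{str(i).zfill(width)}")
    for i in range(n_una):
        rows.append(rng.lognormal(mean=np.log(50.0), sigma=0.5, size=len(tps)))
        labels.append("unassociated")
        gene_ids.append(f"rnd{str(i).zfill(width)}")

    values = np.asarray(rows) if rows else np.empty((0, len(tps)))
    values = values * _lognormal_noise(rng, config.noise_cv, values.shape)
    values = np.vstack([values, anchor[None, :]])
    gene_ids.append(anchor_gene)

    expr = TimecourseExpressionSet(
        pd.DataFrame(values, index=gene_ids, columns=tps), platform="rnaseq"
    )
    truth = PlantedTruth(
        gene_anchor_class=dict(zip(gene_ids[:-1], labels))
    )
    return expr, truth


def generate_cells(
    config: SimulationConfig, bin_config: FociBinConfig | None = None
) -> tuple[list[CellFociRecord], PlantedTruth]:
    """Per-cell foci tables with genotype- and EdU-dependent densities.

    For each (genotype, EdU) group, ``n_cells_per_group`` cells are drawn:
    a fraction ``zero_density_fraction`` is planted at exactly zero density,
    the rest with gamma-distributed planted densities (mean and shape from
    ``density_params``). Nucleus areas are log-normal around
    ``mean_nucleus_area``. Focus counts are Poisson with mean density x
    area; at ``noise_cv = 0`` the count is instead the rounded expectation
    and the planted truth bin is recomputed from the realized count/area,
    so binning recovers the truth exactly.
    """
    rng = np.random.default_rng(config.seed + _STREAM_CELLS)
    bin_config = bin_config or FociBinConfig()
    cells: list[CellFociRecord] = []
    truth = PlantedTruth()
    for (genotype, edu), par in sorted(config.density_params.items()):
        n = config.n_cells_per_group
        n_zero = int(round(config.zero_density_fraction * n))
        dens = np.concatenate([
            np.zeros(n_zero),
            rng.gamma(shape=par["shape"], scale=par["mean"] / par["shape"],
                      size=n - n_zero) if n > n_zero else np.empty(0),
        ])
        rng.shuffle(dens)
        areas = config.mean_nucleus_area * _lognormal_noise(rng, 0.2, n)
        mu = dens * areas
        if config.noise_cv == 0:
            counts = np.round(mu).astype(int)
        else:
            counts = rng.poisson(mu)
        for i in range(n):
            cid = f"{genotype}_{'edu+' if edu else 'edu-'}_{i:04d}"
            cells.append(
                CellFociRecord(
                    cell_id=cid,
                    sample_id=f"{genotype}_{'edu+' if edu else 'edu-'}",
                    genotype=genotype,
                    nucleus_area=float(areas[i]),
                    foci_count=int(counts[i]),
                    edu_positive=bool(edu),
                )
            )
            planted = (
                counts[i] * bin_config.scale / areas[i]
                if config.noise_cv == 0
                else dens[i]
            )
            truth.cell_bin[cid] = bin_density(float(planted), bin_config)
    return cells, truth


def generate_ancillary(
    config: SimulationConfig,
    comet_percents: tuple[float, ...] = (50.0, 30.0, 10.0, 5.0, 5.0),
    n_comet_cells: int = 100,
    n_limbs_per_genotype: int = 18,
    n_complete: dict[str, int] | None = None,
    planted_py142: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Band-intensity, skeletal-count and comet-count tables.

    Skeletal tables default to the study design (18 limbs per genotype,
    3 complete wild-type limbs, 0 complete mutant limbs); comet counts
    realize the planted stage distribution exactly by largest-remainder
    apportionment.
    """
    rng = np.random.default_rng(config.seed + _STREAM_ANCILLARY)
    n_complete = n_complete or {"wildtype": 3, "mutant": 0}

    # densitometry: dual intensity = gamma + planted pY142 (relative units)
    band_rows = []
    for s in range(4):
        ref = rng.uniform(800.0, 1200.0)
        rel_gamma = rng.uniform(0.2, 0.6)
        rel_dual = rel_gamma + planted_py142
        group = "blastema" if s >= 2 else "intact"
        for target, rel in (
            ("H2AX", 1.0),
            ("gammaH2AX", rel_gamma),
            ("dualS139Y142", rel_dual),
        ):
            band_rows.append(
                {
                    "sample_id": f"s{s}",
                    "target": target,
                    "intensity": rel * ref,
                    "reference_intensity": ref,
                    "group": group,
                }
            )
    bands = pd.DataFrame(band_rows)

    skel_rows = []
    full = FULL_PATTERN
    for genotype in sorted(n_complete):
        k = n_complete[genotype]
        for i in range(n_limbs_per_genotype):
            if i < k:
                digits, pm, carp = full["digits"], full["phalanges_metacarpals"], full["carpals"]
            else:
                digits = int(rng.integers(2, 5))
                pm = int(rng.integers(4, 9))
                carp = int(rng.integers(3, 8))
            skel_rows.append(
                {
                    "limb_id": f"{genotype}_limb{i:02d}",
                    "genotype": genotype,
                    "digits": digits,
                    "phalanges_metacarpals": pm,
                    "carpals": carp,
                }
            )
    skeletal = pd.DataFrame(skel_rows)

    stage_order = tuple(f"stage{s}" for s in range(5))
    props = {s: p / 100.0 for s, p in zip(stage_order, comet_percents)}
    counts = largest_remainder_counts(n_comet_cells, props, stage_order)
    comet = pd.DataFrame(
        [{"sample_id": "sim", **counts}]
    )
    return bands, skeletal, comet
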