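"""Timecourse regulation classification and composite DDR scoring.

A gene is called **up-regulated** on RNA-seq data when at any regeneration
timepoint its expression is at least ``fold_threshold`` times the intact
(0 dpa) value, **down-regulated** when at any timepoint it is at most the
intact value divided by ``fold_threshold``, **mixed** when both kinds of
evidence occur (necessarily at different timepoints), and **none** otherwise.
On microarray data the thresholds are ``intact_mean +/- sd_multiplier * sd``
with strict inequalities.

The composite score for a curated gene set (e.g. the positive regulators of
DNA repair, "+DDR") is the per-timepoint mean of each member gene's
expression relative to its own intact value; it equals 1 at 0 dpa by
construction. Genes not expressed in intact tissue are excluded, because
their relative expression is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateDispersionError,
    EmptyInputError,
    MalformedInputError,
    NormalizationError,
)
from .timecourse import TimecourseExpressionSet

CATEGORIES = ("up", "down", "mixed", "none")


@dataclass(frozen=True)
class RegulationRuleConfig:
    """Thresholds for the regulation caller.

    ``fold_threshold`` (> 1, default 2) is the fold-change cutoff for the
    RNA-seq rule; ``sd_multiplier`` (default 1) the dispersion multiple for
    the microarray rule. ``intact_zero_policy`` controls genes silent in
    intact tissue: ``"exclude"`` (default) flags them unclassifiable,
    ``"call_up_if_any_positive"`` calls them up if any later timepoint is
    positive.
    """

    fold_threshold: float = 2.0
    sd_multiplier: float = 1.0
    intact_zero_policy: str = "exclude"

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ConfigurationError("fold_threshold must exceed 1")
        if not self.sd_multiplier > 0:
            raise ConfigurationError("sd_multiplier must be positive")
        if self.intact_zero_policy not in ("exclude", "call_up_if_any_positive"):
            raise ConfigurationError(
                f"unknown intact_zero_policy {self.intact_zero_policy!r}"
            )


@dataclass(frozen=True)
class RegulationCall:
    """Per-gene regulation category with the evidence timepoints."""

    gene_id: str
    category: str
    up_timepoints: tuple[int, ...] = ()
    down_timepoints: tuple[int, ...] = ()
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.excluded:
            return
        has_up, has_down = bool(self.up_timepoints), bool(self.down_timepoints)
        expected = {
            (True, True): "mixed",
            (True, False): "up",
            (False, True): "down",
            (False, False): "none",
        }[(has_up, has_down)]
        if self.category != expected:
            raise MalformedInputError(
                f"category {self.category!r} inconsistent with evidence "
                f"(up={self.up_timepoints}, down={self.down_timepoints})"
            )


def _categorize(up: list[int], down: list[int]) -> str:
    if up and down:
        return "mixed"
    if up:
        return "up"
    if down:
        return "down"
    return "none"


def classify_rnaseq_gene(
    gene_id: str,
    profile: pd.Series,
    rules: RegulationRuleConfig | None = None,
) -> RegulationCall:
    """Classify one RNA-seq timecourse profile by fold change versus intact.

    ``profile`` maps dpa -> expression and must contain timepoint 0.
    Up evidence at t: value(t) >= fold_threshold * value(0); down evidence:
    value(t) <= value(0) / fold_threshold (inclusive thresholds: "at least").
    """
    rules = rules or RegulationRuleConfig()
    if 0 not in profile.index:
        raise MalformedInputError(f"gene {gene_id!r}: no intact (0 dpa) value")
    intact = float(profile[0])
    later = profile.drop(index=0)
    if intact == 0.0:
        if rules.intact_zero_policy == "exclude":
            return RegulationCall(gene_id, "none", excluded=True)
        up = [int(t) for t, v in later.items() if v > 0]
        return RegulationCall(gene_id, _categorize(up, []), tuple(up), ())
    up = [int(t) for t, v in later.items() if v >= rules.fold_threshold * intact]
    down = [int(t) for t, v in later.items() if v <= intact / rules.fold_threshold]
    return RegulationCall(gene_id, _categorize(up, down), tuple(up), tuple(down))


def classify_microarray_gene(
    gene_id: str,
    profile: pd.Series,
    intact_mean: float,
    intact_sd: float,
    rules: RegulationRuleConfig | None = None,
) -> RegulationCall:
    """Classify one microarray profile by dispersion around the intact mean.

    Up evidence at t: value(t) > mean + k*sd; down: value(t) < mean - k*sd
    (strict: "more than one standard deviation"). ``intact_sd`` must be
    positive; how it is estimated (intact replicates, or the whole series as
    a fallback) is the caller's choice — see :func:`classify_expression_set`.
    """
    rules = rules or RegulationRuleConfig()
    if not intact_sd > 0:
        raise DegenerateDispersionError(
            f"gene {gene_id!r}: intact_sd must be positive, got {intact_sd}"
        )
    later = profile.drop(index=0) if 0 in profile.index else profile
    hi = intact_mean + rules.sd_multiplier * intact_sd
    lo = intact_mean - rules.sd_multiplier * intact_sd
    up = [int(t) for t, v in later.items() if v > hi]
    down = [int(t) for t, v in later.items() if v < lo]
    return RegulationCall(gene_id, _categorize(up, down), tuple(up), tuple(down))


def classify_expression_set(
    expr: TimecourseExpressionSet,
    rules: RegulationRuleConfig | None = None,
) -> list[RegulationCall]:
    """Classify every gene of an expression set under its platform's rule.

    For microarray data the per-gene SD is taken across intact replicate
    values when the set carries them; otherwise the SD across the whole time
    series is used as a fallback (the basis is not standardised — both are
    supported).
    """
    rules = rules or RegulationRuleConfig()
    if expr.platform == "rnaseq":
        return _classify_rnaseq_matrix(expr, rules)
    calls: list[RegulationCall] = []
    for gid in expr.gene_ids:
        prof = expr.profile(gid)
        if expr.intact_replicates is not None:
            reps = expr.intact_replicates.loc[gid]
            mean, sd = float(reps.mean()), float(reps.std(ddof=1))
        else:
            mean = float(prof[0])
            sd = float(prof.std(ddof=1))
        calls.append(classify_microarray_gene(gid, prof, mean, sd, rules))
    return calls


def _classify_rnaseq_matrix(
    expr: TimecourseExpressionSet, rules: RegulationRuleConfig
) -> list[RegulationCall]:
    """Matrix-level application of the fold rule (same rule as
    :func:`classify_rnaseq_gene`, vectorized over genes)."""
    tps = np.array(expr.timepoints)
    later_mask = tps != 0
    later_tps = tps[later_mask]
    vals = expr.values.to_numpy()
    intact = expr.values[0].to_numpy()
    later = vals[:, later_mask]
    with np.errstate(invalid="ignore"):
        up_ev = later >= rules.fold_threshold * intact[:, None]
        down_ev = later <= intact[:, None] / rules.fold_threshold
    calls: list[RegulationCall] = []
    for i, gid in enumerate(expr.gene_ids):
        if intact[i] == 0.0:
            if rules.intact_zero_policy == "exclude":
                calls.append(RegulationCall(gid, "none", excluded=True))
            else:
                up = tuple(int(t) for t in later_tps[later[i] > 0])
                calls.append(RegulationCall(gid, _categorize(list(up), []), up, ()))
            continue
        up = tuple(int(t) for t in later_tps[up_ev[i]])
        down = tuple(int(t) for t in later_tps[down_ev[i]])
        calls.append(
            RegulationCall(gid, _categorize(list(up), list(down)), up, down)
        )
    return calls


def summarize_categories(
    calls: list[RegulationCall],
) -> dict[str, tuple[int, float]]:
    """Category -> (count, fraction) over classified (non-excluded) calls.

    Fractions are reported at full precision; rounding to integer percent
    belongs to the reporting layer.
    """
    kept = [c for c in calls if not c.excluded]
    if not kept:
        raise EmptyInputError("no classified calls to summarize")
    n = len(kept)
    out: dict[str, tuple[int, float]] = {}
    for cat in CATEGORIES:
        k = sum(1 for c in kept if c.category == cat)
        out[cat] = (k, k / n)
    return out


def composite_relative_score(
    expr: TimecourseExpressionSet, gene_set: list[str]
) -> pd.Series:
    """Composite relative score of a gene set per timepoint.

    score(t) = mean over member genes of value(t)/value(0); exactly 1 at
    0 dpa. Genes with intact value 0 are excluded before scoring (their
    relative expression is undefined — they are not expressed in the intact
    limb).
    """
    missing = [g for g in gene_set if g not in expr.values.index]
    if missing:
        raise MalformedInputError(f"genes absent from expression set: {missing}")
    sub = expr.values.loc[gene_set]
    sub = sub[sub[0] > 0]
    if sub.empty:
        raise EmptyInputError(
            "gene set empty after excluding genes with no intact expression"
        )
    rel = sub.div(sub[0], axis=0)
    score = rel.mean(axis=0)
    score.name = "composite_score"
    return score


@dataclass(frozen=True)
class VolcanoConfig:
    """Cutoffs for differential-expression gene selection (strict: genes
    must lie beyond them)."""

    q_cutoff: float = 0.05
    fold_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.q_cutoff < 1):
            raise ConfigurationError("q_cutoff must be in (0, 1)")
        if not self.fold_cutoff > 0:
            raise ConfigurationError("fold_cutoff must be positive")


def volcano_select(
    stats_table: pd.DataFrame, config: VolcanoConfig | None = None
) -> tuple[set[str], set[str]]:
    """Split genes into up/down sets by q-value and fold change.

    ``stats_table`` is indexed by gene id with columns ``q_value`` and
    ``fold_change`` (ratio group A / group B, strictly positive). Both
    cutoffs are strict: q < q_cutoff and FC > fold_cutoff (up) or
    FC < 1/fold_cutoff (down); boundary genes select into neither set.
    """
    config = config or VolcanoConfig()
    fc = stats_table["fold_change"]
    if (fc <= 0).any():
        bad = stats_table.index[fc <= 0].tolist()
        raise MalformedInputError(f"nonpositive fold changes for genes: {bad}")
    sig = stats_table["q_value"] < config.q_cutoff
    up = set(stats_table.index[sig & (fc > config.fold_cutoff)])
    down = set(stats_table.index[sig & (fc < 1.0 / config.fold_cutoff)])
    return up, down


@dataclass(frozen=True)
class QpcrStandardCurve:
    """Linear standard curve Ct = slope * log10(quantity) + intercept.

    ``slope`` is Ct per decade of template (negative; ~-3.32 at 100%
    efficiency); ``intercept`` is the Ct of one quantity unit.
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ConfigurationError("standard-curve slope must be negative")


def qpcr_quantify(
    ct: float,
    curve: QpcrStandardCurve,
    reference_quantity: float,
    minus_rt_quantity: float = 0.0,
) -> float:
    """Absolute qPCR quantification against a standard curve.

    Raw quantity = 10**((ct - intercept)/slope); the -RT control quantity is
    subtracted (floored at zero) to remove genomic contamination, and the
    result is normalized by the reference gene's quantity (ef1a in the
    source protocol).
    """
    if not reference_quantity > 0:
        raise NormalizationError("reference quantity must be positive")
    if minus_rt_quantity < 0:
        raise MalformedInputError("-RT quantity cannot be negative")
    raw = math.pow(10.0, (ct - curve.intercept) / curve.slope)
    return max(raw - minus_rt_quantity, 0.0) / reference_quantity
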