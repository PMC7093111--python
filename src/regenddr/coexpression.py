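"""Anchor-gene co-expression screen.

Every gene's timecourse profile is compared to a chosen anchor gene's
profile (eya2-style screen): Pearson r over paired timepoints, R² = r², and
the ordinary-least-squares slope of gene-on-anchor. Genes with R² above the
cutoff are partitioned by slope sign into positively and negatively
associated sets; everything else (including constant profiles, whose
correlation is undefined) is unassociated.

Correlation is computed on expression values as given; an optional log
transform (log2(x+1)) is available but off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateAnchorError, InsufficientDataError
from .timecourse import TimecourseExpressionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationConfig:
    """Screen parameters: R² cutoff (strict, default 0.8), minimum shared
    timepoints, optional log2(x+1) transform."""

    r2_cutoff: float = 0.8
    min_timepoints: int = 3
    log_transform: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.r2_cutoff <= 1):
            raise ConfigurationError("r2_cutoff must be in (0, 1]")
        if self.min_timepoints < 3:
            raise ConfigurationError("min_timepoints must be at least 3")


@dataclass(frozen=True)
class AnchorCorrelation:
    """Per-gene association with the anchor profile.

    ``pearson_r``/``r_squared``/``slope`` are NaN for constant profiles.
    ``anchor_class`` is one of ``positive``/``negative``/``unassociated``.
    """

    gene_id: str
    pearson_r: float
    r_squared: float
    slope: float
    anchor_class: str


def _pearson_and_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form Pearson r and OLS slope of y on x. NaN if y is constant."""
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if syy == 0.0 or sxx == 0.0:
        return math.nan, math.nan
    return sxy / math.sqrt(sxx * syy), sxy / sxx


def correlate_profiles(
    anchor: np.ndarray, gene: np.ndarray
) -> tuple[float, float, float]:
    """(r, R², slope) of one gene profile against the anchor profile."""
    r, slope = _pearson_and_slope(np.asarray(anchor, float), np.asarray(gene, float))
    return r, r * r, slope


def anchor_correlation(
    expr: TimecourseExpressionSet,
    anchor_gene: str,
    config: CorrelationConfig | None = None,
) -> list[AnchorCorrelation]:
    """Screen every gene (except the anchor) against the anchor profile.

    Profiles with missing timepoints are correlated over the shared
    timepoints when at least ``min_timepoints`` remain, otherwise the gene
    is reported unassociated with a warning.
    """
    config = config or CorrelationConfig()
    if anchor_gene not in expr.values.index:
        raise KeyError(f"anchor gene {anchor_gene!r} not in expression set")
    mat = expr.values
    if config.log_transform:
        mat = np.log2(mat + 1.0)
    anchor = mat.loc[anchor_gene]
    a_valid = anchor.notna()
    if int(a_valid.sum()) < config.min_timepoints:
        raise InsufficientDataError(
            f"anchor has {int(a_valid.sum())} timepoints; "
            f"need {config.min_timepoints}"
        )
    if float(anchor[a_valid].std()) == 0.0:
        raise DegenerateAnchorError(
            f"anchor {anchor_gene!r} is constant across timepoints"
        )

    results: list[AnchorCorrelation] = []
    for gid in expr.gene_ids:
        if gid == anchor_gene:
            continue
        prof = mat.loc[gid]
        shared = a_valid & prof.notna()
        if int(shared.sum()) < config.min_timepoints:
            logger.warning(
                "gene %s: only %d shared timepoints (< %d); marked unassociated",
                gid, int(shared.sum()), config.min_timepoints,
            )
            results.append(
                AnchorCorrelation(gid, math.nan, math.nan, math.nan, "unassociated")
            )
            continue
        x = anchor[shared].to_numpy(float)
        y = prof[shared].to_numpy(float)
        r, slope = _pearson_and_slope(x, y)
        if math.isnan(r):
            results.append(
                AnchorCorrelation(gid, math.nan, math.nan, math.nan, "unassociated")
            )
            continue
        r2 = r * r
        if r2 > config.r2_cutoff and slope > 0:
            cls = "positive"
        elif r2 > config.r2_cutoff and slope < 0:
            cls = "negative"
        else:
            cls = "unassociated"
        results.append(AnchorCorrelation(gid, r, r2, slope, cls))
    return results


def partition(
    correlations: list[AnchorCorrelation],
    config: CorrelationConfig | None = None,
) -> tuple[set[str], set[str], set[str]]:
    """Three disjoint gene sets (positive, negative, unassociated) covering
    the input. Membership is strictly R² > cutoff plus the slope sign; an
    R² exactly at the cutoff is unassociated."""
    config = config or CorrelationConfig()
    pos: set[str] = set()
    neg: set[str] = set()
    una: set[str] = set()
    for c in correlations:
        if (
            not math.isnan(c.r_squared)
            and c.r_squared > config.r2_cutoff
            and c.slope > 0
        ):
            pos.add(c.gene_id)
        elif (
            not math.isnan(c.r_squared)
            and c.r_squared > config.r2_cutoff
            and c.slope < 0
        ):
            neg.add(c.gene_id)
        else:
            una.add(c.gene_id)
    return pos, neg, una


def correlations_frame(correlations: list[AnchorCorrelation]) -> pd.DataFrame:
    """Tabular view (gene_id, r, r_squared, slope, anchor_class)."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in correlations],
            "r": [c.pearson_r for c in correlations],
            "r_squared": [c.r_squared for c in correlations],
            "slope": [c.slope for c in correlations],
            "anchor_class": [c.anchor_class for c in correlations],
        }
    ).set_index("gene_id")
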