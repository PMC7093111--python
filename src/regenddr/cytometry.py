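"""Per-cell γ-H2AX focus-density statistics.

Each nucleus contributes a focus count and a nucleus area (from the DAPI
mask); the focus density is count/area, optionally rescaled to reproduce
the 1e6-magnitude numbers of typical reports without fixing the area unit.
Densities are binned as Zero (exactly 0), Low, Med and High; the upper Low
and Med boundaries default to 10x10^6 and 20x10^6 in density units.

Boundary convention: the published bin definitions are open on both sides,
which leaves the exact boundary values unassigned; this module uses
half-open bins — Low = (0, low_upper), Med = [low_upper, med_upper),
High = [med_upper, inf) — so every nonnegative density maps to exactly one
bin. A density exactly at a boundary falls in the upper bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, EmptyInputError, MalformedInputError

BINS = ("Zero", "Low", "Med", "High")


@dataclass(frozen=True)
class FociBinConfig:
    low_upper: float = 10e6
    med_upper: float = 20e6
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.low_upper < self.med_upper):
            raise ConfigurationError("need 0 < low_upper < med_upper")
        if not self.scale > 0:
            raise ConfigurationError("scale must be positive")


@dataclass
class CellFociRecord:
    """One nucleus: area, γ-H2AX focus count, EdU status, genotype, sample."""

    cell_id: str
    sample_id: str
    genotype: str
    nucleus_area: float
    foci_count: int
    edu_positive: bool

    def __post_init__(self) -> None:
        if not self.nucleus_area > 0:
            raise MalformedInputError(
                f"cell {self.cell_id!r}: nucleus_area must be positive"
            )
        if self.foci_count < 0 or int(self.foci_count) != self.foci_count:
            raise MalformedInputError(
                f"cell {self.cell_id!r}: foci_count must be a nonnegative integer"
            )


def foci_density(record: CellFociRecord, config: FociBinConfig | None = None) -> float:
    """scale x foci_count / nucleus_area. Zero iff the count is zero."""
    config = config or FociBinConfig()
    return config.scale * record.foci_count / record.nucleus_area


def bin_density(density: float, config: FociBinConfig | None = None) -> str:
    """Assign a density to its bin (Zero / Low / Med / High)."""
    config = config or FociBinConfig()
    if density < 0:
        raise MalformedInputError(f"negative density {density}")
    if density == 0:
        return "Zero"
    if density < config.low_upper:
        return "Low"
    if density < config.med_upper:
        return "Med"
    return "High"


def cells_frame(
    cells: list[CellFociRecord], config: FociBinConfig | None = None
) -> pd.DataFrame:
    """Per-cell table with derived density and bin columns appended."""
    config = config or FociBinConfig()
    if not cells:
        raise EmptyInputError("no cells")
    rows = []
    for c in cells:
        d = foci_density(c, config)
        rows.append(
            {
                "cell_id": c.cell_id,
                "sample_id": c.sample_id,
                "genotype": c.genotype,
                "nucleus_area": c.nucleus_area,
                "foci_count": c.foci_count,
                "edu_positive": c.edu_positive,
                "density": d,
                "bin": bin_density(d, config),
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def percent_in_bins(
    cells: list[CellFociRecord],
    stratify_by: tuple[str, ...] = (),
    config: FociBinConfig | None = None,
) -> pd.DataFrame:
    """Percent of cells per density bin, within each stratum.

    ``stratify_by`` is a subset of {"genotype", "edu_positive", "sample_id"}.
    Each row (stratum) sums to 100. With no stratification a single row
    labelled "all" is returned.
    """
    allowed = {"genotype", "edu_positive", "sample_id"}
    bad = set(stratify_by) - allowed
    if bad:
        raise ConfigurationError(f"cannot stratify by {sorted(bad)}")
    df = cells_frame(cells, config)
    if stratify_by:
        grouped = df.groupby(list(stratify_by), sort=True)
    else:
        grouped = df.assign(_all="all").groupby("_all")
    pct = (
        grouped["bin"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(BINS), fill_value=0.0)
        * 100.0
    )
    pct.columns.name = None
    return pct


def percent_positive(n_positive: int, n_total: int) -> float:
    """100 x n_positive / n_total (e.g. percent EdU+ cells, percent fully
    patterned limbs). Full precision; round at the reporting layer."""
    if n_total <= 0:
        raise EmptyInputError("n_total must be positive")
    if not (0 <= n_positive <= n_total):
        raise MalformedInputError(
            f"n_positive={n_positive} outside [0, n_total={n_total}]"
        )
    return 100.0 * n_positive / n_total


def line_peak_intensity(profile) -> float:
    """Maximum intensity along one line profile drawn across the skin."""
    values = list(profile)
    if not values:
        raise EmptyInputError("empty line profile")
    return float(max(values))
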