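"""Densitometry arithmetic for H2AX phospho-states.

H2AX carries two phospho-sites of interest: S139 (γ-H2AX when
phosphorylated) and Y142. Antibodies report γ-H2AX (pS139, with or without
pY142) and the dual state pS139/Y142; no antibody reports pY142 alone, so
the relative pY142 level is derived as the dual-phospho relative signal
minus the γ relative signal, each first normalized to total H2AX (or to a
loading control, depending on blot design). The subtraction is performed
per lane, before any group averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, EmptyInputError, NormalizationError

NORMALIZATION_MODES = ("total_h2ax", "loading_control")

TARGETS = ("H2AX", "gammaH2AX", "dualS139Y142", "CDK2", "CCNB1", "pCDC2")


@dataclass(frozen=True)
class BandMeasurement:
    """One band: densitometric intensity plus its normalization reference."""

    sample_id: str
    target: str
    intensity: float
    reference_intensity: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ConfigurationError("band intensity cannot be negative")
        if not self.reference_intensity > 0:
            raise NormalizationError("reference intensity must be positive")


@dataclass(frozen=True)
class PhosphoState:
    """Per-sample relative phospho levels; rel_pY142 = rel_dual - rel_gamma.

    ``below_zero`` flags a negative derived pY142 (reported as-is, not
    floored, so group means stay unbiased).
    """

    sample_id: str
    rel_gamma: float
    rel_dual: float
    rel_pY142: float
    group: str = ""
    below_zero: bool = False


def relative_band(measure: BandMeasurement) -> float:
    """Band intensity over its reference (total H2AX or loading control)."""
    return measure.intensity / measure.reference_intensity


def derive_pY142(rel_dual: float, rel_gamma: float) -> tuple[float, bool]:
    """Relative pY142 = rel_dual - rel_gamma; (value, below_zero_flag)."""
    if not (math.isfinite(rel_dual) and math.isfinite(rel_gamma)):
        raise ConfigurationError("phospho ratios must be finite")
    value = rel_dual - rel_gamma
    return value, value < 0


def phospho_states(
    measurements: list[BandMeasurement],
) -> list[PhosphoState]:
    """Assemble per-sample phospho states from band measurements.

    Each sample must contribute a ``gammaH2AX`` and a ``dualS139Y142`` band;
    the normalization reference travels with each band measurement.
    """
    by_sample: dict[str, dict[str, BandMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, {})[m.target] = m
    states = []
    for sid, bands in sorted(by_sample.items()):
        if "gammaH2AX" not in bands or "dualS139Y142" not in bands:
            raise EmptyInputError(
                f"sample {sid!r}: need both gammaH2AX and dualS139Y142 bands"
            )
        rel_g = relative_band(bands["gammaH2AX"])
        rel_d = relative_band(bands["dualS139Y142"])
        py142, flagged = derive_pY142(rel_d, rel_g)
        states.append(
            PhosphoState(
                sample_id=sid,
                rel_gamma=rel_g,
                rel_dual=rel_d,
                rel_pY142=py142,
                group=bands["gammaH2AX"].group,
                below_zero=flagged,
            )
        )
    return states


def group_summary(states: list[PhosphoState]) -> pd.DataFrame:
    """Per-group mean and SEM (sd/sqrt(n)) of each phospho ratio.

    Groups of size one report NaN SEM (undefined with a single lane).
    """
    if not states:
        raise EmptyInputError("no phospho states to summarize")
    df = pd.DataFrame(
        {
            "group": [s.group for s in states],
            "rel_gamma": [s.rel_gamma for s in states],
            "rel_dual": [s.rel_dual for s in states],
            "rel_pY142": [s.rel_pY142 for s in states],
        }
    )
    grouped = df.groupby("group", sort=True)
    mean = grouped.mean()
    sem = grouped.sem(ddof=1)
    n = grouped.size()
    out = mean.join(sem, lsuffix="_mean", rsuffix="_sem")
    out["n"] = n
    return out
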