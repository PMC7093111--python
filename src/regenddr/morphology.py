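"""Skeletal-pattern scoring, comet-stage tabulation and exact contingency
testing.

A regenerated axolotl forelimb is *fully patterned* when it carries the
complete autopod element count: exactly 4 digits, 9 phalanges/metacarpals
and 8 carpals. Supernumerary elements do not count as fully patterned; the
rule is exact equality on all three counts.

``fisher_exact`` implements the exact conditional test for a general r x c
count table: with both margins fixed, table probabilities follow the
multivariate hypergeometric law

    P(table) = (prod_i r_i!)(prod_j c_j!) / (N! prod_ij n_ij!)

and the two-sided p-value is the total probability of all margin-preserving
tables no more probable than the one observed (the probability-ordering
rule, the standard generalization beyond 2 x 2). Enumeration is a recursive
margin-constrained fill with log-factorial accumulation, exact for the
small tables this test is meant for (total count <= 500 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .cytometry import percent_positive
from .errors import (
    DegenerateTableError,
    EmptyInputError,
    EnumerationLimitError,
    MalformedInputError,
)

COMET_STAGES = (0, 1, 2, 3, 4)

FULL_PATTERN = {"digits": 4, "phalanges_metacarpals": 9, "carpals": 8}


@dataclass(frozen=True)
class SkeletalCounts:
    """Element counts of one (regenerated) limb."""

    limb_id: str
    genotype: str
    digits: int
    phalanges_metacarpals: int
    carpals: int

    def __post_init__(self) -> None:
        for name in ("digits", "phalanges_metacarpals", "carpals"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise MalformedInputError(
                    f"limb {self.limb_id!r}: {name} must be a nonnegative integer"
                )


def is_fully_patterned(counts: SkeletalCounts) -> bool:
    """True iff the limb has exactly 4 digits, 9 phalanges/metacarpals and
    8 carpals."""
    return (
        counts.digits == FULL_PATTERN["digits"]
        and counts.phalanges_metacarpals == FULL_PATTERN["phalanges_metacarpals"]
        and counts.carpals == FULL_PATTERN["carpals"]
    )


def percent_fully_patterned(limbs: list[SkeletalCounts]) -> pd.DataFrame:
    """Per-genotype count and percent of fully patterned limbs."""
    if not limbs:
        raise EmptyInputError("no limbs")
    rows = []
    genotypes = sorted({l.genotype for l in limbs})
    for g in genotypes:
        group = [l for l in limbs if l.genotype == g]
        n_full = sum(is_fully_patterned(l) for l in group)
        rows.append(
            {
                "genotype": g,
                "n_limbs": len(group),
                "n_fully_patterned": n_full,
                "percent_fully_patterned": percent_positive(n_full, len(group)),
            }
        )
    return pd.DataFrame(rows).set_index("genotype")


def relative_zeugopod(zeugopod_length: float, animal_length: float) -> float:
    """Zeugopod length normalized by animal size (same units)."""
    if not (zeugopod_length > 0 and animal_length > 0):
        raise MalformedInputError("lengths must be positive")
    return zeugopod_length / animal_length


@dataclass(frozen=True)
class CometCountTable:
    """Cells per comet stage (0 = no detectable damage ... 4 = maximal) for
    one sample; typically ~100 scored cells."""

    sample_id: str
    counts: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.counts) != len(COMET_STAGES):
            raise MalformedInputError("need exactly five stage counts (stages 0-4)")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise MalformedInputError("stage counts must be nonnegative integers")
        if sum(self.counts) == 0:
            raise EmptyInputError(f"sample {self.sample_id!r}: no scored cells")


def comet_distribution(table: CometCountTable) -> pd.Series:
    """Percent of cells in each comet stage; sums to 100."""
    total = sum(table.counts)
    return pd.Series(
        [100.0 * c / total for c in table.counts],
        index=[f"stage{s}" for s in COMET_STAGES],
        name=table.sample_id,
    )


# --- exact contingency test ---------------------------------------------


@dataclass
class ContingencyTable:
    """Small r x c nonnegative integer count table."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    column_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise MalformedInputError("contingency table must be 2-dimensional")
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise MalformedInputError("contingency table must be at least 2 x 2")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise MalformedInputError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise MalformedInputError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise MalformedInputError("table total must be positive")


# Relative tie tolerance: tables whose probability is within this relative
# margin of the observed table's count as "no more probable".
_TIE_RTOL = 1e-12


@lru_cache(maxsize=4096)
def _fiber_logprobs(
    rows: tuple[int, ...], cols: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted log-probabilities of every table with the given margins, plus
    the cumulative probability up to each entry. Cached per margin pair."""
    n_total = sum(rows)
    lg = [math.lgamma(k + 1) for k in range(n_total + 1)]
    const = sum(lg[r] for r in rows) + sum(lg[c] for c in cols) - lg[n_total]
    r, c = len(rows), len(cols)
    out: list[float] = []

    def fill(i: int, col_rem: list[int], acc: float) -> None:
        if i == r - 1:
            # last row forced by the remaining column margins
            out.append(acc - sum(lg[x] for x in col_rem))
            return
        ri = rows[i]

        def fill_row(j: int, rem: int, col_rem: list[int], acc: float) -> None:
            if j == c - 1:
                if rem <= col_rem[j]:
                    col_rem2 = col_rem.copy()
                    col_rem2[j] -= rem
                    fill(i + 1, col_rem2, acc - lg[rem])
                return
            for x in range(min(rem, col_rem[j]) + 1):
                col_rem2 = col_rem.copy()
                col_rem2[j] -= x
                fill_row(j + 1, rem - x, col_rem2, acc - lg[x])

        fill_row(0, ri, col_rem, acc)

    fill(0, list(cols), const)
    logp = np.sort(np.asarray(out))
    cum = np.cumsum(np.exp(logp))
    return logp, cum


def _table_logprob(counts: np.ndarray) -> float:
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n_total = int(counts.sum())
    return (
        sum(math.lgamma(r + 1) for r in rows)
        + sum(math.lgamma(c + 1) for c in cols)
        - math.lgamma(n_total + 1)
        - sum(math.lgamma(x + 1) for x in counts.ravel())
    )


def enumerate_table_probabilities(
    row_margins: tuple[int, ...], col_margins: tuple[int, ...]
) -> np.ndarray:
    """Sorted probabilities of every table with the given margins (sums to
    1); exposed for audit of the exact-test distribution."""
    logp, _ = _fiber_logprobs(tuple(row_margins), tuple(col_margins))
    return np.exp(logp)


def fisher_exact(table: ContingencyTable | np.ndarray, max_total: int = 500) -> float:
    """Two-sided exact test p-value for an r x c contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table (ties
    resolved with a 1e-12 relative tolerance). The table total is capped at
    ``max_total`` to keep full enumeration tractable.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    n_total = int(counts.sum())
    if n_total > max_total:
        raise EnumerationLimitError(
            f"table total {n_total} exceeds enumeration limit {max_total}"
        )
    logp_sorted, cum = _fiber_logprobs(tuple(int(r) for r in rows),
                                       tuple(int(c) for c in cols))
    logp_obs = _table_logprob(counts)
    k = int(np.searchsorted(logp_sorted, logp_obs + math.log1p(_TIE_RTOL),
                            side="right"))
    if k >= len(logp_sorted):
        return 1.0  # observed table is (tied for) modal: all tables qualify
    p = float(cum[k - 1]) if k > 0 else 0.0
    return min(p, 1.0)
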