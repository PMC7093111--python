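"""Timecourse expression container.

A :class:`TimecourseExpressionSet` holds one summarized expression value per
gene per timepoint of a regeneration timecourse, with day 0 (the intact limb)
as the reference column. Bulk RNA-seq values are TPM; microarray values are
normalized probe intensities. Optional per-replicate intact values support
dispersion-based (microarray) regulation calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MalformedInputError, SchemaError

DEFAULT_TIMEPOINTS = (0, 3, 5, 7, 10, 14, 21, 28)


@dataclass
class TimecourseExpressionSet:
    """Gene x timepoint expression matrix with an intact (0 dpa) reference.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one integer ``dpa`` column per
        timepoint. Must include column ``0`` and contain no negative values.
    platform
        ``"rnaseq"`` or ``"microarray"``; selects the regulation rule.
    intact_replicates
        Optional DataFrame (same gene index) of per-replicate intact values,
        used for the microarray standard-deviation rule.
    """

    values: pd.DataFrame
    platform: str = "rnaseq"
    intact_replicates: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.platform not in ("rnaseq", "microarray"):
            raise SchemaError(f"unknown platform {self.platform!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate gene ids: {dups}")
        try:
            self.values.columns = [int(c) for c in self.values.columns]
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-integer timepoint column: {exc}") from exc
        if 0 not in self.values.columns:
            raise SchemaError("timepoint 0 (intact reference) missing")
        if (self.values.to_numpy() < 0).any():
            raise MalformedInputError("negative expression values are not allowed")
        self.values = self.values.sort_index(axis=1)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[int]:
        return [int(c) for c in self.values.columns]

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def profile(self, gene_id: str) -> pd.Series:
        """Per-timepoint values of one gene, indexed by dpa."""
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in expression set")
        return self.values.loc[gene_id]

    def relative_to_intact(self) -> pd.DataFrame:
        """value(t) / value(0) per gene; genes with intact 0 yield inf/nan."""
        intact = self.values[0].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = self.values.to_numpy() / intact[:, None]
        return pd.DataFrame(rel, index=self.values.index, columns=self.values.columns)
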