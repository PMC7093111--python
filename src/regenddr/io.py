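"""Table readers/writers and the pipeline configuration.

One dialect throughout: UTF-8, ``.`` decimal separator, TSV for expression
matrices and result tables, CSV for per-cell / densitometry / skeletal /
comet inputs. Expression matrices carry their timepoints in the column
names (``dpa0``, ``dpa14``, optionally ``dpa0_rep1`` for intact
replicates), so a single file is self-describing.

Result tables are written atomically (temp file + rename) with a stable
column order, floats at six significant digits and a trailing newline;
expression matrices round-trip at full precision. Malformed cells abort
with their row/column location — nothing is silently coerced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import re
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cytometry import CellFociRecord, FociBinConfig
from .errors import SchemaError
from .morphology import COMET_STAGES, CometCountTable, ContingencyTable, SkeletalCounts
from .phospho import BandMeasurement
from .timecourse import TimecourseExpressionSet

logger = logging.getLogger(__name__)

_DPA_COL = re.compile(r"^dpa(\d+)(?:_rep(\d+))?$")


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_expression_table(path: str | Path) -> TimecourseExpressionSet:
    """Read a TSV expression matrix (gene_id + dpa<k>[_rep<j>] columns).

    Replicate columns are averaged into the summarized per-timepoint value;
    intact (dpa0) replicates are additionally retained for dispersion-based
    calls. Duplicate gene ids and non-numeric cells are rejected with the
    offending location.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, float_precision="round_trip")
    if df.columns[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be 'gene_id', got "
                          f"{df.columns[0]!r}")
    parsed: dict[str, tuple[int, int | None]] = {}
    for col in df.columns[1:]:
        m = _DPA_COL.match(col)
        if not m:
            raise SchemaError(f"{path}: column {col!r} is not dpa<k>[_rep<j>]")
        parsed[col] = (int(m.group(1)), int(m.group(2)) if m.group(2) else None)
    if not any(tp == 0 for tp, _ in parsed.values()):
        raise SchemaError(f"{path}: no dpa0 (intact reference) column")
    dup = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dup:
        raise SchemaError(f"{path}: duplicate gene ids: {dup}")

    numeric = {}
    for col in df.columns[1:]:
        try:
            # astype(float) parses via strtod and round-trips exactly
            numeric[col] = df[col].astype(float)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise SchemaError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at "
                f"gene {df.loc[row, 'gene_id']!r}, column {col!r}"
            ) from None
    values = pd.DataFrame(numeric)
    values.index = pd.Index(df["gene_id"].to_numpy())

    by_tp: dict[int, list[str]] = {}
    for col, (tp, _) in parsed.items():
        by_tp.setdefault(tp, []).append(col)
    summarized = pd.DataFrame(
        {tp: values[cols].mean(axis=1) for tp, cols in sorted(by_tp.items())}
    )
    intact_reps = None
    if len(by_tp[0]) > 1:
        intact_reps = values[by_tp[0]]
    return TimecourseExpressionSet(summarized, intact_replicates=intact_reps)


def write_expression_table(expr: TimecourseExpressionSet, path: str | Path) -> None:
    """Write an expression matrix at full precision (round-trips exactly)."""
    df = expr.values.copy()
    df.columns = [f"dpa{c}" for c in df.columns]
    df.index.name = "gene_id"
    _atomic_write_text(path, df.to_csv(sep="\t", float_format="%.17g"))


def write_table(df: pd.DataFrame, path: str | Path,
                index: bool = True) -> Path:
    """Write a result table atomically; TSV or CSV by file extension,
    floats at six significant digits, trailing newline."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    _atomic_write_text(path, df.to_csv(sep=sep, float_format="%.6g", index=index))
    return path


def write_gene_list(genes, path: str | Path) -> Path:
    """One gene id per line (input format for enrichment tools)."""
    path = Path(path)
    _atomic_write_text(path, "".join(f"{g}\n" for g in sorted(genes)))
    return path


def write_truth_labels(labels: dict[str, str], path: str | Path) -> Path:
    """Sidecar TSV of ground-truth labels (columns id, label)."""
    path = Path(path)
    lines = ["id\tlabel\n"] + [f"{k}\t{v}\n" for k, v in labels.items()]
    _atomic_write_text(path, "".join(lines))
    return path


def read_truth_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["id"], df["label"]))


def read_cells_table(path: str | Path) -> list[CellFociRecord]:
    """Per-cell CSV: cell_id, sample_id, genotype, nucleus_area, foci_count,
    edu_positive."""
    df = pd.read_csv(path)
    required = ["cell_id", "sample_id", "genotype", "nucleus_area",
                "foci_count", "edu_positive"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        edu = row["edu_positive"]
        if isinstance(edu, str):
            edu = edu.strip().lower() in ("true", "1", "yes", "+")
        records.append(
            CellFociRecord(
                cell_id=str(row["cell_id"]),
                sample_id=str(row["sample_id"]),
                genotype=str(row["genotype"]),
                nucleus_area=float(row["nucleus_area"]),
                foci_count=int(row["foci_count"]),
                edu_positive=bool(edu),
            )
        )
    return records


def write_cells_table(cells: list[CellFociRecord], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "sample_id": c.sample_id,
                "genotype": c.genotype,
                "nucleus_area": c.nucleus_area,
                "foci_count": c.foci_count,
                "edu_positive": c.edu_positive,
            }
            for c in cells
        ]
    )
    path = Path(path)
    _atomic_write_text(path, df.to_csv(index=False, float_format=repr))
    return path


def read_bands_table(path: str | Path) -> list[BandMeasurement]:
    """Densitometry CSV: sample_id, target, intensity, reference_intensity,
    group."""
    df = pd.read_csv(path)
    return [
        BandMeasurement(
            sample_id=str(r["sample_id"]),
            target=str(r["target"]),
            intensity=float(r["intensity"]),
            reference_intensity=float(r["reference_intensity"]),
            group=str(r.get("group", "")),
        )
        for _, r in df.iterrows()
    ]


def read_skeletal_table(path: str | Path) -> list[SkeletalCounts]:
    df = pd.read_csv(path)
    return [
        SkeletalCounts(
            limb_id=str(r["limb_id"]),
            genotype=str(r["genotype"]),
            digits=int(r["digits"]),
            phalanges_metacarpals=int(r["phalanges_metacarpals"]),
            carpals=int(r["carpals"]),
        )
        for _, r in df.iterrows()
    ]


def read_comet_table(path: str | Path) -> list[CometCountTable]:
    df = pd.read_csv(path)
    cols = [f"stage{s}" for s in COMET_STAGES]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return [
        CometCountTable(
            sample_id=str(r["sample_id"]),
            counts=tuple(int(r[c]) for c in cols),
        )
        for _, r in df.iterrows()
    ]


def read_contingency_table(path: str | Path) -> ContingencyTable:
    """Small CSV grid with a header row and a leading label column."""
    df = pd.read_csv(path, index_col=0)
    return ContingencyTable(
        counts=df.to_numpy(),
        row_labels=tuple(str(i) for i in df.index),
        column_labels=tuple(str(c) for c in df.columns),
    )


@dataclass
class PipelineConfig:
    """Stage parameters plus the global seed, loadable from YAML.

    Defaults mirror the study's stated parameters: fold 2, one SD, R² 0.8,
    q 0.05, FC 2, density bins at 10e6 / 20e6.
    """

    seed: int = 0
    fold_threshold: float = 2.0
    sd_multiplier: float = 1.0
    r2_cutoff: float = 0.8
    q_cutoff: float = 0.05
    fold_cutoff: float = 2.0
    low_upper: float = 10e6
    med_upper: float = 20e6
    scale: float = 1.0
    normalization_mode: str = "total_h2ax"
    n_genes: int = 2000
    noise_cv: float = 0.1
    anchor_gene: str = "anchor"
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def bin_config(self) -> FociBinConfig:
        return FociBinConfig(low_upper=self.low_upper, med_upper=self.med_upper,
                             scale=self.scale)
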