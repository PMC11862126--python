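"""Readers and writers for the plain-text formats the pipeline touches.

Peptide/PSM quant tables are tab-separated with one row per peptide (or PSM)
per TMT set.  The required columns are::

    peptide_id  sequence  genes  cell_line  condition  replicate  set_id
    channel_1 ... channel_N

``genes`` holds one or more gene symbols joined by a delimiter (semicolon by
default); multi-gene mappings are preserved verbatim as ambiguous peptides.
Channel columns map to temperatures through a :class:`TemperatureGrid`
supplied by configuration, never inferred from headers.  Empty cells or
``NA`` denote missing measurements; zero is a valid intensity.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, List, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import ComplexSet, PeptideQuantRecord, SampleKey, TemperatureGrid

META_COLUMNS = [
    "peptide_id",
    "sequence",
    "genes",
    "cell_line",
    "condition",
    "replicate",
    "set_id",
]

NA_VALUES = ["", "NA", "NaN", "nan"]


class FormatError(ValueError):
    """A file does not satisfy the declared format contract."""


def channel_columns(n: int) -> List[str]:
    return [f"channel_{i}" for i in range(1, n + 1)]


def read_peptide_table(
    path, grid: TemperatureGrid, gene_delimiter: str = ";"
) -> List[PeptideQuantRecord]:
    """Parse a peptide/PSM quant TSV into records, order-preserving.

    Raises :class:`FormatError` naming the first missing column, and
    ``ValueError`` with the offending row index for negative intensities.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    chan_cols = channel_columns(len(grid))
    for col in META_COLUMNS + chan_cols:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    records: List[PeptideQuantRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        vals = []
        for col in chan_cols:
            cell = row[col].strip()
            if cell in NA_VALUES:
                vals.append(np.nan)
                continue
            v = float(cell)
            if v < 0:
                raise ValueError(
                    f"{path.name}: negative intensity {v} in row {idx}, column {col}"
                )
            vals.append(v)
        genes = frozenset(
            g.strip() for g in row["genes"].split(gene_delimiter) if g.strip()
        )
        if not genes:
            raise ValueError(f"{path.name}: empty gene field in row {idx}")
        records.append(
            PeptideQuantRecord(
                peptide_id=row["peptide_id"],
                sequence=row["sequence"],
                gene_symbols=genes,
                sample_key=SampleKey(
                    row["cell_line"], row["condition"], int(row["replicate"])
                ),
                set_id=row["set_id"],
                intensities=np.array(vals, float),
            )
        )
    return records


def records_to_frame(
    records: Iterable[PeptideQuantRecord], gene_delimiter: str = ";"
) -> pd.DataFrame:
    """Long-form DataFrame view of quant records (one row per record)."""
    rows = []
    for r in records:
        row = {
            "peptide_id": r.peptide_id,
            "sequence": r.sequence,
            "genes": gene_delimiter.join(sorted(r.gene_symbols)),
            "cell_line": r.sample_key.cell_line,
            "condition": r.sample_key.condition,
            "replicate": r.sample_key.replicate,
            "set_id": r.set_id,
        }
        for i, v in enumerate(r.intensities, start=1):
            row[f"channel_{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_peptide_table(records, path, gene_delimiter: str = ";") -> None:
    df = records_to_frame(records, gene_delimiter)
    write_results_table(df, path)


def read_fasta(path) -> Mapping[str, str]:
    """FASTA to {identifier: uppercase sequence}; duplicate headers rejected."""
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path.name}: duplicate FASTA identifier {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace(" ", "")
    if not out:
        raise FormatError(f"{path.name}: no FASTA records found")
    return out


def read_gmt(path) -> List[ComplexSet]:
    """GMT gene sets: name, description (ignored), then member symbols."""
    path = Path(path)
    sets: List[ComplexSet] = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}: line {ln + 1} has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            if name in seen:
                raise FormatError(f"{path.name}: duplicate gene-set name {name!r}")
            seen.add(name)
            members = frozenset(m for m in fields[2:] if m)
            sets.append(ComplexSet(name=name, members=members))
    return sets


def write_results_table(df: pd.DataFrame, path) -> None:
    """Write a results TSV with enough precision for a lossless round trip."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
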