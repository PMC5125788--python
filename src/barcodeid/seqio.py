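"""FASTA and metadata-table input/output.

FASTA is read and written through Biopython; metadata travels in a single
TSV dialect with the fixed header ``id family genus species morphotype
life_stage role`` joined to sequences by record id.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import BarcodeRecord, Lineage, RecordError, check_unique_ids

METADATA_COLUMNS = ["id", "family", "genus", "species", "morphotype",
                    "life_stage", "role"]

FASTA_WRAP = 70


def read_fasta(path: os.PathLike | str) -> list[BarcodeRecord]:
    """Read barcodes from FASTA (sequence + id only; no lineage).

    Duplicate ids, empty sequences and non-IUPAC symbols are rejected with
    the offending record named.
    """
    records = [
        BarcodeRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    check_unique_ids(records)
    return records


def write_fasta(records: Iterable[BarcodeRecord], path: os.PathLike | str) -> None:
    """Write records as FASTA wrapped at 70 columns."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=FASTA_WRAP)
    writer.write_file(seqs)


def read_metadata(path: os.PathLike | str) -> pd.DataFrame:
    """Read the metadata TSV and validate its header and lineage rows."""
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise RecordError(f"metadata is missing required columns {missing}")
    if meta["id"].duplicated().any():
        dup = meta.loc[meta["id"].duplicated(), "id"].iloc[0]
        raise RecordError(f"duplicate metadata id {dup!r}")
    for _, row in meta.iterrows():
        _row_lineage(row)  # raises with the lineage invariant named
    return meta


def _row_lineage(row) -> Lineage:
    return Lineage(
        family=row["family"] or None,
        genus=row["genus"] or None,
        species=row["species"] or None,
    )


def attach_metadata(
    records: Sequence[BarcodeRecord], meta: pd.DataFrame
) -> tuple[list[BarcodeRecord], list[str]]:
    """Join metadata onto records by id.

    Returns the annotated records plus the ids of metadata rows that
    matched no sequence (reported, not fatal). Records without a metadata
    row keep their defaults.
    """
    table = meta.set_index("id")
    out = []
    for rec in records:
        if rec.id not in table.index:
            out.append(rec)
            continue
        row = table.loc[rec.id]
        out.append(BarcodeRecord(
            id=rec.id,
            sequence=rec.sequence,
            lineage=_row_lineage(row),
            morphotype=row["morphotype"] or None,
            life_stage=row["life_stage"] or None,
            role=row["role"] or "query",
        ))
    seq_ids = {r.id for r in records}
    unmatched = [i for i in table.index if i not in seq_ids]
    return out, unmatched


def write_metadata(records: Iterable[BarcodeRecord], path: os.PathLike | str) -> None:
    rows = [
        {
            "id": r.id,
            "family": r.lineage.family or "",
            "genus": r.lineage.genus or "",
            "species": r.lineage.species or "",
            "morphotype": r.morphotype or "",
            "life_stage": r.life_stage or "",
            "role": r.role,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)
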