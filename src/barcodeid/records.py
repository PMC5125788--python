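"""Core record types: a barcode sequence with its taxonomic lineage and role.

A :class:`BarcodeRecord` is the unit every stage of the pipeline consumes:
one COI nucleotide sequence (IUPAC codes, optionally gapped) together with
the taxonomy it is believed to belong to, an optional morphotype label from
morphological identification, an optional life stage, and its role in the
analysis (``query``, ``reference`` or ``outgroup``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")
GAP = "-"
_VALID_SYMBOLS = IUPAC_NUCLEOTIDES | {GAP}

LIFE_STAGES = ("larva", "metamorphosing", "juvenile", "adult")
ROLES = ("query", "reference", "outgroup")


class RecordError(ValueError):
    """Raised when a record or metadata row violates an invariant."""


@dataclass(frozen=True)
class Lineage:
    """Taxonomic lineage restricted to the ranks the tier rule can grant.

    Ranks must be filled top-down: a species requires a genus, a genus
    requires a family.
    """

    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if self.species and not self.genus:
            raise RecordError(
                f"lineage invariant violated: species {self.species!r} set "
                "without a genus"
            )
        if self.genus and not self.family:
            raise RecordError(
                f"lineage invariant violated: genus {self.genus!r} set "
                "without a family"
            )

    def truncated(self, rank: str) -> "Lineage":
        """Return the lineage cut down to ``rank`` (species/genus/family)."""
        if rank == "species":
            return self
        if rank == "genus":
            return Lineage(family=self.family, genus=self.genus)
        if rank == "family":
            return Lineage(family=self.family)
        return Lineage()

    def name_at(self, rank: str) -> Optional[str]:
        return getattr(self, rank, None)

    def __str__(self) -> str:
        parts = [p for p in (self.family, self.genus, self.species) if p]
        return ";".join(parts)


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcode sequence with metadata.

    Sequences are stored uppercase. Validation enforces a non-empty
    sequence over IUPAC nucleotide symbols (plus ``-`` for gaps).
    """

    id: str
    sequence: str
    lineage: Lineage = field(default_factory=Lineage)
    morphotype: Optional[str] = None
    life_stage: Optional[str] = None
    role: str = "query"

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("record id must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise RecordError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _VALID_SYMBOLS
        if bad:
            raise RecordError(
                f"record {self.id!r}: non-IUPAC symbols {sorted(bad)!r}"
            )
        if self.life_stage is not None and self.life_stage not in LIFE_STAGES:
            raise RecordError(
                f"record {self.id!r}: unknown life stage {self.life_stage!r}"
            )
        if self.role not in ROLES:
            raise RecordError(f"record {self.id!r}: unknown role {self.role!r}")

    @property
    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")

    def with_sequence(self, sequence: str) -> "BarcodeRecord":
        return replace(self, sequence=sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def check_unique_ids(records: Sequence[BarcodeRecord]) -> None:
    """Raise :class:`RecordError` naming the first duplicated id, if any."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise RecordError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def by_id(records: Iterable[BarcodeRecord]) -> dict[str, BarcodeRecord]:
    out = {}
    for rec in records:
        if rec.id in out:
            raise RecordError(f"duplicate record id {rec.id!r}")
        out[rec.id] = rec
    return out
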