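"""Functional-barcode quality control.

A COI barcode from a real mitochondrial gene is a coding sequence: it has
a reading frame with no internal stop codon and no frame-breaking indel.
Pseudogene copies (NUMTs) and sequencing errors violate these properties,
so the screen here checks each barcode for (i) an internal stop codon
under the vertebrate mitochondrial genetic code (translation table 2,
stops TAA/TAG/AGA/AGG) in its best-supported frame and (ii) an internal
indel relative to a reference barcode.

Frame detection is stop-minimisation: the reported frame is the one with
the fewest internal stops; the terminal (possibly partial) codon never
counts, and IUPAC ambiguity codes never count as stops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .records import BarcodeRecord, GAP
from .simulate import STOP_CODONS

_STOPS = frozenset(STOP_CODONS)
_UNAMBIGUOUS = frozenset("ACGT")

QC_COLUMNS = ["id", "frame", "has_internal_stop", "indel_flag", "length",
              "ambiguous_fraction"]


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCReport:
    """Per-record QC outcome. ``frame`` is 0/1/2 or ``'undetermined'``."""

    id: str
    frame: object
    has_internal_stop: bool
    indel_flag: bool
    length: int
    ambiguous_fraction: float


def count_internal_stops(sequence: str, frame: int) -> int:
    """Number of internal stop codons reading ``sequence`` in ``frame``.

    The terminal codon (complete or partial) is excluded: a stop there is
    a legitimate end of an ORF, not evidence of a pseudogene.
    """
    seq = sequence.upper()
    codons = [seq[i: i + 3] for i in range(frame, len(seq) - 2, 3)]
    if codons and frame + 3 * len(codons) == len(seq):
        codons = codons[:-1]  # final complete codon is terminal
    return sum(c in _STOPS for c in codons)


def detect_reading_frame(record: BarcodeRecord) -> tuple[object, dict[int, int]]:
    """Infer the reading frame by stop-codon minimisation.

    Returns ``(frame, stops_per_frame)``. A frame with zero internal
    stops wins (ties broken toward the lowest frame); if every frame has
    stops and all three counts tie, the frame is ``'undetermined'``.
    """
    seq = record.sequence
    if GAP in seq:
        raise QCError(f"record {record.id!r}: frame detection needs an "
                      "ungapped sequence")
    if len(seq) < 60:
        raise QCError(f"record {record.id!r}: sequence too short for frame "
                      f"detection ({len(seq)} < 60)")
    stops = {f: count_internal_stops(seq, f) for f in (0, 1, 2)}
    best = min(stops.values())
    if best > 0 and len(set(stops.values())) == 1:
        return "undetermined", stops
    frame = min(f for f, s in stops.items() if s == best)
    return frame, stops


def _frame_restored(query: BarcodeRecord, reference: BarcodeRecord):
    """Project ``query`` onto the reference's coordinates.

    Globally aligns the pair, then drops query bases inserted relative to
    the reference and replaces deleted positions with N. The result has
    the reference's length and frame, so stop screening is insulated from
    indel-induced frameshifts. Returns (projected sequence, internal-gap
    flag).
    """
    from .distances import align_pair  # local import: avoids module cycle

    pair = align_pair(reference, query)
    ref_row, qry_row = pair.seq_a, pair.seq_b
    # trim terminal-gap columns: overhang is missing data, not an indel
    left, right = 0, len(ref_row)
    while left < right and (ref_row[left] == GAP or qry_row[left] == GAP):
        left += 1
    while right > left and (ref_row[right - 1] == GAP or qry_row[right - 1] == GAP):
        right -= 1
    if left >= right:  # no aligned overlap at all
        return query.ungapped, False
    internal_gap = any(
        ref_row[i] == GAP or qry_row[i] == GAP for i in range(left, right)
    )
    projected = "".join(
        ("N" if q == GAP else q)
        for r, q in zip(ref_row, qry_row)
        if r != GAP
    )
    return projected, internal_gap


def qc_barcode(
    record: BarcodeRecord,
    best_reference: Optional[BarcodeRecord] = None,
    modal_length_mod3: Optional[int] = None,
) -> QCReport:
    """QC one barcode; always returns a report.

    With ``best_reference`` supplied, the indel flag comes from an
    internal gap in the global alignment against it, and the stop screen
    runs on the frame-restored projection so that a frameshift does not
    masquerade as a stop-codon problem. Without a reference, the indel
    fallback flags a length whose ``mod 3`` class differs from the modal
    class of its dataset (pass ``modal_length_mod3``).
    """
    seq = record.ungapped
    ambiguous = sum(c not in _UNAMBIGUOUS for c in seq) / len(seq)
    if best_reference is not None:
        projected, indel = _frame_restored(record, best_reference)
        frame, stops = detect_reading_frame(record.with_sequence(projected))
    else:
        indel = (modal_length_mod3 is not None
                 and len(seq) % 3 != modal_length_mod3)
        frame, stops = detect_reading_frame(record.with_sequence(seq))
    has_stop = (stops[frame] if frame != "undetermined"
                else min(stops.values())) > 0
    return QCReport(
        id=record.id,
        frame=frame,
        has_internal_stop=bool(has_stop),
        indel_flag=bool(indel),
        length=len(seq),
        ambiguous_fraction=ambiguous,
    )


def qc_dataset(
    records: Sequence[BarcodeRecord],
    references: Optional[dict[str, BarcodeRecord]] = None,
) -> pd.DataFrame:
    """QC every record; ``references`` maps record id -> best reference.

    Records without a reference fall back to the modal length-class
    heuristic computed over the whole dataset.
    """
    lengths = pd.Series([len(r.ungapped) % 3 for r in records])
    modal = int(lengths.mode().iloc[0]) if len(lengths) else 0
    reports = []
    for rec in records:
        ref = references.get(rec.id) if references else None
        rep = qc_barcode(rec, best_reference=ref,
                         modal_length_mod3=None if ref else modal)
        reports.append(rep.__dict__)
    return pd.DataFrame(reports, columns=QC_COLUMNS)
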