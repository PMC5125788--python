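"""Pairwise alignment, uncorrected p-distances and group distance tables.

The whole identification logic runs on the uncorrected p-distance: the
proportion of differing sites among compared positions, with *pairwise
deletion* — for each pair of sequences, only alignment columns where both
carry an unambiguous base (A/C/G/T) are compared; gap and ambiguity
columns are dropped for that pair alone. The similarity value used by the
tier rule is its complement on a percent scale, SV = 100 x (1 - p).

Unaligned inputs are put in register by global pairwise alignment with
free end gaps (match +1, mismatch -1, internal gap open -5, extension -2
per additional gapped position), so a short query aligned to a full-length
barcode pays nothing for its terminal overhang. Kimura two-parameter
distances are provided for comparison only; p-distances are the default
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from skbio import DistanceMatrix

from .records import BarcodeRecord, GAP

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_ACGT = frozenset("ACGT")


class UndefinedDistance(ValueError):
    """A pair with zero compared sites has no defined distance."""


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedPair:
    """Two gapped rows of equal length plus the alignment score."""

    seq_a: str
    seq_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise AlignmentError("aligned rows must have equal length")

    @property
    def columns(self) -> int:
        return len(self.seq_a)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_internal_gap_score = GAP_OPEN
    aligner.extend_internal_gap_score = GAP_EXTEND
    aligner.end_gap_score = 0.0  # free terminal gaps
    return aligner


_ALIGNER = _make_aligner()


def align_pair(a: BarcodeRecord, b: BarcodeRecord) -> AlignedPair:
    """Optimal global alignment (free end gaps) of two ungapped records.

    The aligner's first optimal traceback is used, which is deterministic
    for a given pair of sequences.
    """
    sa, sb = a.sequence, b.sequence
    if GAP in sa or GAP in sb:
        raise AlignmentError("align_pair expects ungapped sequences")
    if not sa or not sb:
        raise AlignmentError("cannot align an empty sequence")
    if len(sa) == len(sb):
        # gapless fast path: when the ungapped pairing already achieves the
        # optimal score, it is an optimal alignment — use it directly
        xa = np.frombuffer(sa.encode(), dtype=np.uint8)
        xb = np.frombuffer(sb.encode(), dtype=np.uint8)
        matches = int((xa == xb).sum())
        gapless = (MATCH_SCORE * matches
                   + MISMATCH_SCORE * (len(sa) - matches))
        if _ALIGNER.score(sa, sb) == gapless:
            return AlignedPair(seq_a=sa, seq_b=sb, score=float(gapless))
    aln = _ALIGNER.align(sa, sb)[0]
    rows = np.array(aln)
    return AlignedPair(
        seq_a=rows[0].tobytes().decode(),
        seq_b=rows[1].tobytes().decode(),
        score=float(aln.score),
    )


def _compared_columns(pair: AlignedPair) -> list[tuple[str, str]]:
    return [
        (x, y)
        for x, y in zip(pair.seq_a, pair.seq_b)
        if x in _ACGT and y in _ACGT
    ]


def p_distance(pair: AlignedPair) -> float:
    """Uncorrected p-distance with pairwise deletion.

    Columns containing a gap or a non-ACGT symbol in either row are
    excluded. Raises :class:`UndefinedDistance` when no column remains.
    """
    cols = _compared_columns(pair)
    if not cols:
        raise UndefinedDistance("no compared sites between the two sequences")
    mism = sum(x != y for x, y in cols)
    return mism / len(cols)


def k2p_distance(pair: AlignedPair) -> float:
    """Kimura two-parameter distance (comparison only, never the default).

    Raises :class:`UndefinedDistance` on zero overlap or when saturation
    makes a logarithm undefined.
    """
    cols = _compared_columns(pair)
    if not cols:
        raise UndefinedDistance("no compared sites between the two sequences")
    n = len(cols)
    ts = sum(x != y and frozenset((x, y)) in _TRANSITIONS for x, y in cols)
    tv = sum(x != y and frozenset((x, y)) not in _TRANSITIONS for x, y in cols)
    P, Q = ts / n, tv / n
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise UndefinedDistance("K2P undefined: saturated pair")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def similarity_value(a: BarcodeRecord, b: BarcodeRecord) -> float:
    """Percent similarity SV = 100 x (1 - p) over the aligned overlap.

    Terminal-gap columns are excluded automatically by pairwise deletion,
    so a query fragment is scored only on the region it covers.
    """
    return 100.0 * (1.0 - p_distance(align_pair(a, b)))


# ---------------------------------------------------------------------------
# distance matrices

def _encode(sequences: Sequence[str]) -> np.ndarray:
    """(n, L) uint8 matrix; 0-3 = ACGT, 255 = gap/ambiguity."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise AlignmentError("encoded sequences must share one length")
    arr = np.frombuffer("".join(sequences).upper().encode(), dtype=np.uint8)
    arr = arr.reshape(len(sequences), -1)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for i, base in enumerate(b"ACGT"):
        out[arr == base] = i
    return out


def p_distance_matrix_from_alignment(
    encoded: np.ndarray, ids: Sequence[str]
) -> DistanceMatrix:
    """All pairwise p-distances over the columns of a fixed alignment.

    ``encoded`` is the matrix from :func:`_encode`. Pairwise deletion is
    applied per pair of rows.
    """
    n = encoded.shape[0]
    valid = (encoded != 255)
    matches = np.zeros((n, n))
    for b in range(4):
        x = (encoded == b).astype(np.float64)
        matches += x @ x.T
    v = valid.astype(np.float64)
    compared = v @ v.T
    off = ~np.eye(n, dtype=bool)
    if np.any(compared[off] == 0):
        raise UndefinedDistance("a sequence pair shares no compared sites")
    with np.errstate(invalid="ignore"):
        p = np.where(compared > 0, (compared - matches) / np.maximum(compared, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(p, ids=list(ids))


def distance_matrix(
    records: Sequence[BarcodeRecord], aligned: Union[bool, str] = "auto"
) -> DistanceMatrix:
    """Pairwise p-distance matrix over ``records``.

    ``aligned=True`` treats the sequences as rows of one multiple
    alignment (they must share a length); ``aligned=False`` aligns every
    pair globally first. The default ``'auto'`` picks the aligned route
    when all sequences already share one length — the situation for
    simulated libraries and pre-aligned barcode sets.
    """
    if len(records) < 2:
        raise AlignmentError("need at least two records for a matrix")
    ids = [r.id for r in records]
    if aligned == "auto":
        aligned = len({len(r.sequence) for r in records}) == 1
    if aligned:
        return p_distance_matrix_from_alignment(
            _encode([r.sequence for r in records]), ids
        )
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = p_distance(align_pair(records[i], records[j]))
    return DistanceMatrix(mat, ids=ids)


# ---------------------------------------------------------------------------
# within/between group distances (MEGA group-mean convention)

@dataclass(frozen=True)
class GroupDistanceTable:
    """Mean within-group and between-group p-distances.

    ``within`` columns: group, n, mean_within (NaN for singleton groups —
    undefined, never 0), max_within. ``between`` columns: group_a,
    group_b, mean_between, min_between, one row per unordered group pair.
    """

    within: pd.DataFrame
    between: pd.DataFrame

    def nearest(self, group: str) -> pd.Series:
        """The between-row for ``group``'s closest other group (by mean)."""
        rows = self.between[(self.between.group_a == group)
                            | (self.between.group_b == group)]
        if rows.empty:
            raise KeyError(f"group {group!r} has no between-group rows")
        return rows.loc[rows.mean_between.idxmin()]


def group_distances(
    matrix: DistanceMatrix, grouping: Mapping[str, str]
) -> GroupDistanceTable:
    """Within/between group means from a distance matrix.

    ``grouping`` maps every matrix id to a group label (e.g. species or
    morphotype). Within-group mean is the arithmetic mean over unordered
    in-group pairs; between-group mean over all cross pairs.
    """
    ids = list(matrix.ids)
    missing = [i for i in ids if i not in grouping]
    if missing:
        raise KeyError(f"grouping does not cover ids {missing[:5]!r}")
    groups = sorted({grouping[i] for i in ids})
    members = {g: [i for i in ids if grouping[i] == g] for g in groups}
    data = matrix.data
    index = {label: k for k, label in enumerate(ids)}

    def block(g1, g2):
        rows = [index[i] for i in members[g1]]
        cols = [index[i] for i in members[g2]]
        return data[np.ix_(rows, cols)]

    within_rows = []
    for g in groups:
        n = len(members[g])
        if n < 2:
            within_rows.append((g, n, np.nan, np.nan))
        else:
            b = block(g, g)
            iu = np.triu_indices(n, k=1)
            within_rows.append((g, n, float(b[iu].mean()), float(b[iu].max())))
    between_rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            b = block(g1, g2)
            between_rows.append((g1, g2, float(b.mean()), float(b.min())))
    return GroupDistanceTable(
        within=pd.DataFrame(
            within_rows, columns=["group", "n", "mean_within", "max_within"]
        ),
        between=pd.DataFrame(
            between_rows,
            columns=["group_a", "group_b", "mean_between", "min_between"],
        ),
    )


# ---------------------------------------------------------------------------
# serialization

def write_distance_matrix(matrix: DistanceMatrix, path) -> None:
    """Square TSV with a label header row and label first column."""
    df = pd.DataFrame(matrix.data, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a labelled square TSV; PHYLIP square format also accepted."""
    with open(path) as fh:
        first = fh.readline()
    if first.strip().isdigit():  # PHYLIP: leading taxon count, space-separated
        n = int(first)
        df = pd.read_csv(path, sep=r"\s+", skiprows=1, header=None, index_col=0)
        if len(df) != n:
            raise AlignmentError(f"PHYLIP matrix announces {n} taxa, has {len(df)}")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])
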