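"""Taxonomic assignment: similarity tiers, diagnostic characters, MOTUs.

Three complementary lines of evidence turn barcode distances into
identifications, mirroring standard DNA-barcoding practice:

* **Similarity tiers** — a query is granted the rank its best similarity
  value (SV) supports: species at SV >= 98 %, genus at 92 <= SV < 98,
  family at 85 <= SV < 92, otherwise unassigned. The intervals are
  half-open and cover [0, 100] exactly once.
* **Diagnostic characters** — a species is callable when it carries a set
  of alignment positions at which all of its members share a state found
  in no other species; a query is called only when it matches the full
  diagnostic set of exactly one species.
* **MOTU congruence** — within- versus between-group p-distances plus
  tree monophyly decide whether a named group behaves as a distinct
  molecular operational taxonomic unit, shows a merged signal with its
  nearest neighbour, or is ambiguous.

The two classifiers follow scikit-learn estimator conventions (``fit`` /
``predict`` / ``get_params``), taking lists of :class:`BarcodeRecord`
(or plain sequences, for the character classifier) as ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .records import BarcodeRecord, Lineage
from .distances import similarity_value, UndefinedDistance

DEFAULT_TIERS = (98.0, 92.0, 85.0)
RANKS = ("species", "genus", "family", "unassigned")

HIT_COLUMNS = ["reference_id", "sv", "family", "genus", "species"]


class AssignmentError(ValueError):
    pass


@dataclass(frozen=True)
class HitList:
    """Ranked similarity hits for one query (descending SV, then id)."""

    query_id: str
    hits: pd.DataFrame  # HIT_COLUMNS, sorted

    def best(self) -> pd.Series:
        if self.hits.empty:
            raise AssignmentError(f"query {self.query_id!r} has no hits")
        return self.hits.iloc[0]


@dataclass(frozen=True)
class RankAssignment:
    query_id: str
    rank: str
    taxon: Lineage
    best_sv: float
    n_supporting_hits: int
    best_hit_id: Optional[str] = None

    @property
    def taxon_name(self) -> Optional[str]:
        if self.rank == "unassigned":
            return None
        return self.taxon.name_at(self.rank)


def best_hits(
    query: BarcodeRecord, library: Sequence[BarcodeRecord], k: int = 5
) -> HitList:
    """Top-``k`` references by SV; ties broken by reference id.

    References whose overlap with the query is empty (undefined SV) are
    skipped. ``k`` larger than the library returns the full ranking.
    """
    if not library:
        raise AssignmentError("reference library is empty")
    rows = []
    for ref in library:
        try:
            sv = similarity_value(query, ref)
        except UndefinedDistance:
            continue
        lin = ref.lineage
        rows.append((ref.id, sv, lin.family or "", lin.genus or "",
                     lin.species or ""))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    df = df.sort_values(["sv", "reference_id"], ascending=[False, True],
                        kind="mergesort").head(k).reset_index(drop=True)
    return HitList(query_id=query.id, hits=df)


def rank_from_sv(sv: float, tiers: Sequence[float] = DEFAULT_TIERS) -> str:
    """Map one SV to its rank under the half-open tier intervals."""
    t_sp, t_gen, t_fam = tiers
    if not (0 < t_fam < t_gen < t_sp <= 100):
        raise AssignmentError(f"tier thresholds must strictly decrease: {tiers}")
    if sv >= t_sp:
        return "species"
    if sv >= t_gen:
        return "genus"
    if sv >= t_fam:
        return "family"
    return "unassigned"


def assign_rank(
    hits: HitList, tiers: Sequence[float] = DEFAULT_TIERS
) -> RankAssignment:
    """Tiered rank assignment from a hit list.

    The granted taxon is the best hit's lineage truncated to the granted
    rank (single best hit, no consensus). ``n_supporting_hits`` counts
    hits inside the granted tier that agree with that taxon.
    """
    if hits.hits.empty:
        return RankAssignment(hits.query_id, "unassigned", Lineage(), 0.0, 0)
    top = hits.best()
    rank = rank_from_sv(float(top.sv), tiers)
    lineage = Lineage(
        family=top.family or None, genus=top.genus or None,
        species=top.species or None,
    )
    if rank == "unassigned":
        return RankAssignment(hits.query_id, rank, Lineage(), float(top.sv), 0,
                              best_hit_id=str(top.reference_id))
    taxon = lineage.truncated(rank)
    threshold = dict(zip(("species", "genus", "family"), tiers))[rank]
    name = taxon.name_at(rank)
    support = int(sum(
        row.sv >= threshold and getattr(row, rank) == name
        for row in hits.hits.itertuples()
    ))
    return RankAssignment(hits.query_id, rank, taxon, float(top.sv), support,
                          best_hit_id=str(top.reference_id))


class ThresholdTaxonClassifier(ClassifierMixin, BaseEstimator):
    """Similarity-tier taxonomic assigner (scikit-learn style).

    ``fit`` takes the reference library (a sequence of
    :class:`BarcodeRecord` with lineages); ``predict`` returns, per
    query, the granted taxon name at the granted rank (empty string when
    unassigned). :meth:`assign` returns the full per-query table.

    Parameters
    ----------
    tiers : (species, genus, family) SV thresholds in percent.
    k : hits retained per query.
    """

    def __init__(self, tiers: tuple = DEFAULT_TIERS, k: int = 5):
        self.tiers = tiers
        self.k = k

    def fit(self, X: Sequence[BarcodeRecord], y=None):
        if not len(X):
            raise AssignmentError("reference library is empty")
        rank_from_sv(100.0, self.tiers)  # validates thresholds
        self.references_ = list(X)
        self.classes_ = np.array(sorted(
            {r.lineage.species for r in X if r.lineage.species}
        ))
        return self

    def hit_lists(self, X: Sequence[BarcodeRecord]) -> list[HitList]:
        self._check_fitted()
        return [best_hits(q, self.references_, k=self.k) for q in X]

    def assignments(self, X: Sequence[BarcodeRecord]) -> list[RankAssignment]:
        return [assign_rank(h, self.tiers) for h in self.hit_lists(X)]

    def assign(self, X: Sequence[BarcodeRecord]) -> pd.DataFrame:
        """Per-query table: ``query_id rank taxon best_sv n_hits``."""
        rows = [
            (a.query_id, a.rank, str(a.taxon), a.best_sv, a.n_supporting_hits,
             a.best_hit_id or "")
            for a in self.assignments(X)
        ]
        return pd.DataFrame(rows, columns=[
            "query_id", "rank", "taxon", "best_sv", "n_hits", "best_hit_id",
        ])

    def predict(self, X: Sequence[BarcodeRecord]) -> np.ndarray:
        return np.array([a.taxon_name or "" for a in self.assignments(X)],
                        dtype=object)

    def predict_rank(self, X: Sequence[BarcodeRecord]) -> np.ndarray:
        return np.array([a.rank for a in self.assignments(X)], dtype=object)

    def _check_fitted(self):
        if not hasattr(self, "references_"):
            raise AssignmentError("classifier is not fitted")


def _as_sequences(X) -> list[str]:
    return [x.sequence if isinstance(x, BarcodeRecord) else str(x) for x in X]


class DiagnosticCharacterClassifier(ClassifierMixin, BaseEstimator):
    """Pure single-position diagnostic-character species classifier.

    ``fit`` takes aligned training sequences (equal length; records or
    strings) and their species labels, and learns, per species, every
    alignment column whose state is fixed within the species and absent
    from all other species (only unambiguous A/C/G/T states qualify).
    ``predict`` calls the unique species whose complete diagnostic set a
    query matches, and returns an empty string (no-call) when zero or
    several species match — including for species that have no
    diagnostic column at all, which are listed in ``undiagnosable_``.
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        seqs = _as_sequences(X)
        labels = [str(s) for s in y]
        if len(seqs) != len(labels):
            raise AssignmentError("X and y lengths differ")
        if len(set(labels)) < 2:
            raise AssignmentError("need at least two species to train")
        if len({len(s) for s in seqs}) != 1:
            raise AssignmentError("training sequences must be aligned "
                                  "(equal length)")
        length = len(seqs[0])
        by_species: dict[str, list[str]] = {}
        for s, lab in zip(seqs, labels):
            by_species.setdefault(lab, []).append(s.upper())
        diagnostics: dict[str, list[tuple[int, str]]] = {
            sp: [] for sp in by_species
        }
        for col in range(length):
            states = {sp: {s[col] for s in members}
                      for sp, members in by_species.items()}
            for sp, own in states.items():
                if len(own) != 1:
                    continue
                state = next(iter(own))
                if state not in "ACGT":
                    continue
                others = set().union(*(v for o, v in states.items() if o != sp))
                if state not in others:
                    diagnostics[sp].append((col, state))
        self.diagnostics_ = diagnostics
        self.alignment_length_ = length
        self.undiagnosable_ = sorted(
            sp for sp, d in diagnostics.items() if not d
        )
        self.classes_ = np.array(sorted(by_species))
        self._verify(by_species)
        return self

    def _verify(self, by_species) -> None:
        # re-check the purity invariant after construction
        for sp, diag in self.diagnostics_.items():
            for col, state in diag:
                assert all(s[col] == state for s in by_species[sp])
                assert all(
                    s[col] != state
                    for o, members in by_species.items() if o != sp
                    for s in members
                )

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "diagnostics_"):
            raise AssignmentError("classifier is not fitted")
        out = []
        for seq in _as_sequences(X):
            seq = seq.upper()
            if len(seq) != self.alignment_length_:
                raise AssignmentError(
                    "query length differs from the training alignment"
                )
            matches = [
                sp for sp, diag in self.diagnostics_.items()
                if diag and all(seq[col] == state for col, state in diag)
            ]
            out.append(matches[0] if len(matches) == 1 else "")
        return np.array(out, dtype=object)


# ---------------------------------------------------------------------------
# MOTU congruence

MOTU_VERDICTS = ("distinct", "ambiguous", "merged-signal")


def motu_verdict(
    mean_within: Optional[float],
    mean_between: float,
    max_within: Optional[float] = None,
    min_between: Optional[float] = None,
    ratio: float = 5.0,
    zero_within_cutoff: float = 0.02,
) -> str:
    """Barcode-gap verdict for one group against its nearest neighbour.

    ``distinct`` when the gap is clean (minimum between-distance above the
    maximum within-distance, where both are known) and the between mean is
    at least ``ratio`` times the within mean; ``merged-signal`` when the
    between mean sits below that multiple of the within mean — the
    situation where congeners are no further apart than conspecifics;
    ``ambiguous`` otherwise, including exact equality. A zero or undefined
    within-distance switches to an absolute cutoff: distinct when the
    between mean reaches ``zero_within_cutoff``.
    """
    if mean_between < 0:
        raise AssignmentError("between-group distance must be >= 0")
    undefined_within = mean_within is None or np.isnan(mean_within)
    if undefined_within or mean_within == 0:
        return "distinct" if mean_between >= zero_within_cutoff else "ambiguous"
    if mean_between == mean_within:
        return "ambiguous"
    lo_between = mean_between if min_between is None else min_between
    hi_within = mean_within if max_within is None else max_within
    if lo_between > hi_within and mean_between >= ratio * mean_within:
        return "distinct"
    if mean_between < ratio * mean_within:
        return "merged-signal"
    return "ambiguous"


def motu_congruence(
    groups, tree, grouping: Mapping[str, str], ratio: float = 5.0
) -> pd.DataFrame:
    """Per-group MOTU report from group distances and an NJ tree.

    ``groups`` is a :class:`~barcodeid.distances.GroupDistanceTable`,
    ``grouping`` maps tip ids to group labels (to evaluate monophyly).
    Columns: group, n, mean_within, max_within, nearest_group,
    mean_between, min_between, gap_ratio, within_undefined, verdict,
    monophyletic.
    """
    from .njtree import is_monophyletic

    tip_names = {t.name for t in tree.tips()}
    rows = []
    for w in groups.within.itertuples():
        g = w.group
        try:
            near = groups.nearest(g)
        except KeyError:
            continue  # single-group table: nothing to compare against
        nearest_group = near.group_b if near.group_a == g else near.group_a
        undefined = bool(np.isnan(w.mean_within)) if w.n >= 1 else True
        verdict = motu_verdict(
            None if undefined else w.mean_within,
            near.mean_between,
            max_within=None if undefined else w.max_within,
            min_between=near.min_between,
            ratio=ratio,
        )
        if undefined or w.max_within == 0:
            gap_ratio = np.nan  # reported separately via within fields
        else:
            gap_ratio = near.min_between / w.max_within
        tips = {i for i, lab in grouping.items() if lab == g} & tip_names
        mono = bool(tips) and is_monophyletic(tree, tips)
        rows.append((g, w.n, w.mean_within, w.max_within, nearest_group,
                     near.mean_between, near.min_between, gap_ratio,
                     undefined, verdict, mono))
    return pd.DataFrame(rows, columns=[
        "group", "n", "mean_within", "max_within", "nearest_group",
        "mean_between", "min_between", "gap_ratio", "within_undefined",
        "verdict", "monophyletic",
    ])
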