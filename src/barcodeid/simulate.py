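"""Seedable synthetic COI reference libraries with known truth.

The generator emulates the hierarchical structure of a barcode reference
library (families > genera > species > specimens) with calibrated
divergence tiers, so that the similarity-tier identification rule, the QC
screens and the tree/MOTU stages can all be exercised offline against a
known truth table.

Model
-----
Sequences are ~657 bp coding fragments in frame 0 under the vertebrate
mitochondrial genetic code (stop codons TAA, TAG, AGA, AGG). Divergence is
realized on a star topology per tier: a stop-free root sequence is mutated
into one ancestor per family, each family ancestor into genus ancestors,
and so on down to specimens. Each branch applies per-site substitutions at
the Jukes-Cantor-like rate (equal probability of the three alternative
bases), with per-codon rejection of substitutions that would create an
in-frame stop. Branch substitution proportions are chosen so the expected
pairwise p-distance between two sequences whose most recent common
ancestor sits at a given tier equals that tier's target:

    specimen branch  = d_within_species / 2
    species branch   = (d_within_genus  - d_within_species) / 2
    genus branch     = (d_within_family - d_within_genus)   / 2
    family branch    = (d_between_family - d_within_family) / 2

Multiple hits deflate realized distances slightly below the nominal
targets (a few percent at the default tier values), well inside the
+/-30 % calibration band the generator promises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import BarcodeRecord, Lineage

#: index -> base for the internal uint8 encoding
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {c: i for i, c in enumerate("ACGT")}

#: vertebrate mitochondrial stop codons, as base-index triplets
STOP_CODONS = ("TAA", "TAG", "AGA", "AGG")
_STOP_CODES = frozenset(
    16 * _BASE_INDEX[c[0]] + 4 * _BASE_INDEX[c[1]] + _BASE_INDEX[c[2]]
    for c in STOP_CODONS
)

TRUTH_COLUMNS = [
    "id", "family", "genus", "species", "expected_rank", "has_indel", "has_stop",
]


class SimulationError(ValueError):
    """Raised for impossible simulation specifications."""


@dataclass(frozen=True)
class TaxonomySpec:
    """Shape of the simulated reference library."""

    n_families: int = 5
    genera_per_family: int = 2
    species_per_genus: int = 3
    specimens_per_species: int = 4
    name_prefix: str = "SIM"

    def __post_init__(self) -> None:
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "specimens_per_species"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")

    @property
    def total_specimens(self) -> int:
        return (self.n_families * self.genera_per_family
                * self.species_per_genus * self.specimens_per_species)


@dataclass(frozen=True)
class DivergenceSpec:
    """Tier targets: expected pairwise p-distance at each lineage depth.

    ``d_within_species`` is the expected distance between two conspecific
    specimens, ``d_within_genus`` between congeneric species, and so on.
    Defaults straddle the similarity tiers of the identification rule
    (species >= 98 %, genus >= 92 %, family >= 85 %).
    """

    d_within_species: float = 0.005
    d_within_genus: float = 0.05
    d_within_family: float = 0.10
    d_between_family: float = 0.15
    seq_length: int = 657
    seed: int = 0

    def __post_init__(self) -> None:
        d = (self.d_within_species, self.d_within_genus,
             self.d_within_family, self.d_between_family)
        if not (0 <= d[0] < d[1] < d[2] < d[3] < 0.75):
            raise SimulationError(
                "divergence tiers must satisfy "
                "0 <= within-species < within-genus < within-family "
                f"< between-family < 0.75, got {d}"
            )
        if self.seq_length < 60 or self.seq_length % 3:
            raise SimulationError("seq_length must be >= 60 and a multiple of 3")

    @property
    def branch_proportions(self) -> tuple[float, float, float, float]:
        """Per-branch substitution proportions (family, genus, species,
        specimen), from the star-topology tier calibration."""
        return (
            (self.d_between_family - self.d_within_family) / 2,
            (self.d_within_family - self.d_within_genus) / 2,
            (self.d_within_genus - self.d_within_species) / 2,
            self.d_within_species / 2,
        )


# ---------------------------------------------------------------------------
# sequence-level helpers (uint8 base-index arrays)

def _codon_codes(seq: np.ndarray) -> np.ndarray:
    n = len(seq) // 3
    c = seq[: 3 * n].reshape(n, 3)
    return 16 * c[:, 0] + 4 * c[:, 1] + c[:, 2]


def _stop_mask(seq: np.ndarray) -> np.ndarray:
    codes = _codon_codes(seq)
    mask = np.zeros(len(codes), dtype=bool)
    for code in _STOP_CODES:
        mask |= codes == code
    return mask


def random_coding_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random sequence with no stop codon in frame 0."""
    seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    while True:
        bad = np.flatnonzero(_stop_mask(seq))
        if not len(bad):
            return seq
        for i in bad:
            seq[3 * i: 3 * i + 3] = rng.integers(0, 4, size=3, dtype=np.uint8)


def mutate(seq: np.ndarray, proportion: float,
           rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``proportion`` (uniform over
    the three alternative bases), rejecting codons that become stops."""
    out = seq.copy()
    hit = rng.random(len(seq)) < proportion
    idx = np.flatnonzero(hit)
    if not len(idx):
        return out
    out[idx] = (out[idx] + rng.integers(1, 4, size=len(idx), dtype=np.uint8)) % 4
    # redraw substitutions inside any codon that turned into a stop
    while True:
        bad = np.flatnonzero(_stop_mask(out))
        if not len(bad):
            return out
        for c in bad:
            span = np.arange(3 * c, min(3 * c + 3, len(seq)))
            mutated = span[hit[span]]
            out[mutated] = (
                seq[mutated]
                + rng.integers(1, 4, size=len(mutated), dtype=np.uint8)
            ) % 4


def to_string(seq: np.ndarray) -> str:
    return BASES[seq].tobytes().decode()


def from_string(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.empty(len(arr), dtype=np.uint8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    known = np.isin(arr, BASES)
    if not known.all():
        raise SimulationError("sequence contains non-ACGT symbols")
    return out


# ---------------------------------------------------------------------------
# library generation

def simulate_library(
    taxonomy: TaxonomySpec = TaxonomySpec(),
    divergence: DivergenceSpec = DivergenceSpec(),
) -> tuple[list[BarcodeRecord], pd.DataFrame]:
    """Generate a reference library plus its truth table.

    Returns ``(records, truth)`` where every record carries its full
    lineage and ``role='reference'``, and ``truth`` has one row per record
    with the TSV schema ``id family genus species expected_rank has_indel
    has_stop``. Identical specs (the seed lives in ``divergence``) give
    byte-identical output.
    """
    rng = np.random.default_rng(divergence.seed)
    m_fam, m_gen, m_sp, m_ind = divergence.branch_proportions
    root = random_coding_sequence(divergence.seq_length, rng)
    p = taxonomy.name_prefix

    records: list[BarcodeRecord] = []
    rows = []
    for fi in range(taxonomy.n_families):
        fam_name = f"{p}-F{fi + 1:02d}"
        fam_seq = mutate(root, m_fam, rng)
        for gi in range(taxonomy.genera_per_family):
            gen_name = f"{fam_name}G{gi + 1:02d}"
            gen_seq = mutate(fam_seq, m_gen, rng)
            for si in range(taxonomy.species_per_genus):
                sp_name = f"{gen_name}S{si + 1:02d}"
                sp_seq = mutate(gen_seq, m_sp, rng)
                lin = Lineage(family=fam_name, genus=gen_name, species=sp_name)
                for ki in range(taxonomy.specimens_per_species):
                    seq = mutate(sp_seq, m_ind, rng)
                    rec_id = f"{sp_name}-{ki + 1:02d}"
                    records.append(BarcodeRecord(
                        id=rec_id, sequence=to_string(seq), lineage=lin,
                        morphotype=sp_name, role="reference",
                    ))
                    rows.append((rec_id, fam_name, gen_name, sp_name,
                                 "species", False, False))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return records, truth


def simulate_queries(
    library: Sequence[BarcodeRecord],
    n_conspecific: int = 30,
    n_novel_species: int = 15,
    n_novel_genus: int = 15,
    seed: int = 0,
    divergence: DivergenceSpec = DivergenceSpec(),
) -> tuple[list[BarcodeRecord], pd.DataFrame]:
    """Generate query barcodes in the three identification situations.

    * conspecific — a mutated copy of a library specimen at the
      within-species tier; expected rank ``species``.
    * novel species — diverged from a library specimen at the
      within-genus tier; expected rank ``genus``.
    * novel genus — diverged at the within-family tier; expected rank
      ``family``.

    Sources are drawn with replacement; each query is an independent
    mutation. The truth table records the expected rank and the lineage
    truncated to it.
    """
    if not library:
        raise SimulationError("library must be non-empty")
    for n in (n_conspecific, n_novel_species, n_novel_genus):
        if n < 0:
            raise SimulationError("query counts must be >= 0")
    with_species = [r for r in library if r.lineage.species]
    if (n_conspecific or n_novel_species) and not with_species:
        raise SimulationError(
            "request exceeds available taxa: no species-labelled references"
        )
    with_family = [r for r in library if r.lineage.family]
    if n_novel_genus and not with_family:
        raise SimulationError(
            "request exceeds available taxa: no family-labelled references"
        )

    rng = np.random.default_rng(seed)
    records: list[BarcodeRecord] = []
    rows = []

    def emit(tag, k, sources, proportion, rank):
        for i in range(k):
            src = sources[rng.integers(len(sources))]
            seq = mutate(from_string(src.ungapped), proportion, rng)
            lin = src.lineage.truncated(rank)
            if rank == "species":
                morph = lin.species
            elif rank == "genus":
                morph = f"{lin.genus} sp."
            else:
                morph = f"{lin.family} gen. sp."
            rec_id = f"Q-{tag}-{i + 1:03d}"
            records.append(BarcodeRecord(
                id=rec_id, sequence=to_string(seq), lineage=lin,
                morphotype=morph, life_stage="larva", role="query",
            ))
            rows.append((rec_id, lin.family or "", lin.genus or "",
                         lin.species or "", rank, False, False))

    emit("CON", n_conspecific, with_species, divergence.d_within_species,
         "species")
    emit("NSP", n_novel_species, with_species, divergence.d_within_genus,
         "genus")
    emit("NGE", n_novel_genus, with_family, divergence.d_within_family,
         "family")
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return records, truth


# ---------------------------------------------------------------------------
# QC artifact injection

def _inject_stop(seq: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Create one internal in-frame stop by a single-base substitution.

    Returns the corrupted sequence and the codon index hit.
    """
    n_codons = len(seq) // 3
    # internal codons only: never the first or the terminal codon
    candidates = rng.permutation(np.arange(1, n_codons - 1))
    for c in candidates:
        codon = seq[3 * c: 3 * c + 3]
        options = [(pos, b)
                   for pos in range(3) for b in range(4)
                   if b != codon[pos]
                   and (16 * (b if pos == 0 else codon[0])
                        + 4 * (b if pos == 1 else codon[1])
                        + (b if pos == 2 else codon[2])) in _STOP_CODES]
        if options:
            pos, b = options[rng.integers(len(options))]
            out = seq.copy()
            out[3 * c + pos] = b
            return out, int(c)
    raise SimulationError("no single-substitution stop available")  # pragma: no cover


def inject_artifacts(
    records: Sequence[BarcodeRecord],
    indel_rate: float = 0.0,
    stop_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[BarcodeRecord], pd.DataFrame]:
    """Corrupt a random subset of records with QC artifacts.

    Each record independently receives, with the stated probabilities, a
    single-base internal indel (insertion or deletion, breaking the codon
    frame) and/or a single substitution creating an in-frame stop codon.
    An injected indel never touches the codon carrying an injected stop,
    so the two truth flags stay independently detectable. Returns the new
    records and a flags table (``id has_indel has_stop``).
    """
    if not (0 <= indel_rate <= 1 and 0 <= stop_rate <= 1):
        raise SimulationError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[BarcodeRecord] = []
    rows = []
    for rec in records:
        seq = from_string(rec.ungapped)
        do_stop = rng.random() < stop_rate
        do_indel = rng.random() < indel_rate
        stop_codon = -1
        if do_stop:
            seq, stop_codon = _inject_stop(seq, rng)
        if do_indel:
            lo, hi = 3, len(seq) - 3
            while True:
                pos = int(rng.integers(lo, hi))
                if stop_codon < 0 or not (3 * stop_codon <= pos < 3 * stop_codon + 3):
                    break
            if rng.random() < 0.5:
                seq = np.delete(seq, pos)
            else:
                seq = np.insert(seq, pos, rng.integers(0, 4, dtype=np.uint8))
        out.append(rec.with_sequence(to_string(seq)))
        rows.append((rec.id, bool(do_indel), bool(do_stop)))
    flags = pd.DataFrame(rows, columns=["id", "has_indel", "has_stop"])
    return out, flags
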