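"""End-to-end identification runs: QC -> similarity -> trees -> MOTUs.

One call wires the stages together the way a barcoding study uses them:
queries are QC-screened, matched against the reference library, granted a
rank by the similarity tiers, cross-checked with the diagnostic-character
classifier, placed on a bootstrapped NJ tree, and summarised per
morphotype with a morphology-versus-molecule congruence verdict.

Every stage persists its artifact in the output directory as TSV or
Newick, and the run is fully reproducible from the config plus seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .records import BarcodeRecord, Lineage
from . import seqio
from .qc import qc_dataset, _frame_restored
from .distances import (
    distance_matrix, group_distances, write_distance_matrix,
)
from .classify import (
    ThresholdTaxonClassifier, DiagnosticCharacterClassifier,
    motu_congruence, DEFAULT_TIERS,
)
from .njtree import bootstrap_support, root_on_outgroup, write_newick

logger = logging.getLogger("barcodeid")

REPORT_COLUMNS = [
    "query_id", "morphotype", "qc_frame", "qc_has_stop", "qc_indel",
    "best_hit_id", "best_sv", "rank", "taxon", "character_call",
    "nj_monophyletic", "congruence",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All knobs of one identification run."""

    queries: str = ""
    library: str = ""
    meta: str = ""
    out: str = "barcodeid_out"
    tiers: tuple = DEFAULT_TIERS
    bootstrap: int = 1000
    motu_ratio: float = 5.0
    seed: int = 0
    outgroup: Optional[str] = None
    hits_k: int = 5

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.tiers)
        if not (0 < t[2] < t[1] < t[0] <= 100):
            raise PipelineError(
                f"tier thresholds must strictly decrease within (0, 100]: {t}"
            )
        object.__setattr__(self, "tiers", t)
        if self.bootstrap < 1:
            raise PipelineError("bootstrap replicates must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read ``key = value`` lines; '#' starts a comment."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "tiers":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("bootstrap", "seed", "hits_k"):
                kwargs[key] = int(value)
            elif key == "motu_ratio":
                kwargs[key] = float(value)
            elif key == "outgroup":
                kwargs[key] = value or None
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name == "tiers":
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name} = {'' if value is None else value}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PipelineResult:
    report: pd.DataFrame
    summary: pd.DataFrame
    qc: pd.DataFrame
    assignments: pd.DataFrame
    motu: pd.DataFrame
    tree: object
    out_dir: Optional[Path] = None


def _project_all(records: Sequence[BarcodeRecord], anchor: BarcodeRecord
                 ) -> list[BarcodeRecord]:
    """Bring records onto the anchor's coordinates (pairwise projection).

    Records already matching the anchor's length are kept as-is; others
    are globally aligned to the anchor, insertions dropped and deletions
    padded with N — the pairwise-to-reference stand-in for a multiple
    alignment that this pipeline uses by design.
    """
    out = []
    for rec in records:
        if len(rec.sequence) == len(anchor.sequence):
            out.append(rec)
        else:
            projected, _ = _frame_restored(rec, anchor)
            out.append(rec.with_sequence(projected))
    return out


def run(
    queries: Sequence[BarcodeRecord],
    references: Sequence[BarcodeRecord],
    outgroup: Optional[BarcodeRecord] = None,
    config: Optional[RunConfig] = None,
) -> PipelineResult:
    """Run the full identification workflow in memory.

    ``references`` carry lineages; ``queries`` carry morphotype labels
    (and, when morphology proposed a taxon, a lineage used only for the
    congruence verdict). Artifacts are written when ``config.out`` is
    set by :func:`run_pipeline`; this function only computes.
    """
    cfg = config or RunConfig()
    if not queries or not references:
        raise PipelineError("stage load: need non-empty queries and references")
    out_dir = Path(cfg.out) if cfg.out else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def persist(df: pd.DataFrame, name: str) -> None:
        if out_dir is not None:
            df.to_csv(out_dir / name, sep="\t", index=False,
                      float_format="%.6f")

    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        log_lines.append(line)
        logger.info(line)

    log("load", f"queries={len(queries)} references={len(references)} "
                f"outgroup={outgroup.id if outgroup else '-'} seed={cfg.seed}")

    # --- similarity search and tier assignment -----------------------------
    try:
        clf = ThresholdTaxonClassifier(tiers=cfg.tiers, k=cfg.hits_k)
        clf.fit(references)
        hit_lists = clf.hit_lists(queries)
        assignments = [  # keep objects; table persisted below
            a for a in (clf.assignments(queries))
        ]
        assign_df = clf.assign(queries)
    except Exception as exc:
        raise PipelineError(f"stage similarity: {exc}") from exc
    persist(assign_df, "assignments.tsv")
    hits_df = pd.concat(
        [h.hits.assign(query_id=h.query_id) for h in hit_lists],
        ignore_index=True,
    )
    persist(hits_df, "hits.tsv")
    log("similarity", f"assigned ranks: {assign_df['rank'].value_counts().to_dict()}")

    # --- QC (never excludes a query; failures are flagged) ------------------
    try:
        ref_by_id = {r.id: r for r in references}
        best_ref = {
            a.query_id: ref_by_id[a.best_hit_id]
            for a in assignments if a.best_hit_id in ref_by_id
        }
        qc_df = qc_dataset(queries, references=best_ref)
    except Exception as exc:
        raise PipelineError(f"stage qc: {exc}") from exc
    persist(qc_df, "qc.tsv")
    n_flagged = int((qc_df.has_internal_stop | qc_df.indel_flag).sum())
    log("qc", f"{n_flagged}/{len(qc_df)} queries flagged")

    # --- character-based classification ------------------------------------
    try:
        anchor = references[0]
        refs_aligned = _project_all(references, anchor)
        queries_aligned = _project_all(queries, anchor)
        species_labels = [r.lineage.species or "" for r in refs_aligned]
        trainable = [
            (r, s) for r, s in zip(refs_aligned, species_labels) if s
        ]
        char_calls = {q.id: "" for q in queries}
        if len({s for _, s in trainable}) >= 2:
            dcc = DiagnosticCharacterClassifier()
            dcc.fit([r for r, _ in trainable], [s for _, s in trainable])
            for q, call in zip(queries, dcc.predict(queries_aligned)):
                char_calls[q.id] = call
            log("characters",
                f"diagnosable species: "
                f"{len(dcc.classes_) - len(dcc.undiagnosable_)}/{len(dcc.classes_)}")
        else:
            log("characters", "skipped: fewer than two labelled species")
    except Exception as exc:
        raise PipelineError(f"stage characters: {exc}") from exc

    # --- distances, tree, bootstrap ----------------------------------------
    try:
        everyone = list(refs_aligned) + list(queries_aligned)
        if outgroup is not None:
            everyone = everyone + _project_all([outgroup], anchor)
        dm = distance_matrix(everyone, aligned=True)
        tree = bootstrap_support(everyone, n_reps=cfg.bootstrap, seed=cfg.seed)
        if outgroup is not None:
            tree = root_on_outgroup(tree, outgroup.id)
        log("tree", f"{len(everyone)} tips, {cfg.bootstrap} bootstrap replicates")
    except Exception as exc:
        raise PipelineError(f"stage tree: {exc}") from exc
    if out_dir is not None:
        write_distance_matrix(dm, out_dir / "distances.tsv")
        write_newick(tree, out_dir / "tree.nwk")

    # --- group distances and MOTU congruence --------------------------------
    try:
        grouping = {}
        for r in references:
            grouping[r.id] = r.lineage.species or r.lineage.genus \
                or r.lineage.family or "unlabelled-reference"
        for q in queries:
            grouping[q.id] = q.morphotype or str(q.lineage) or "unlabelled-query"
        if outgroup is not None:
            grouping[outgroup.id] = "OUTGROUP"
        gdt = group_distances(dm, grouping)
        motu = motu_congruence(gdt, tree, grouping, ratio=cfg.motu_ratio)
    except Exception as exc:
        raise PipelineError(f"stage motu: {exc}") from exc
    persist(gdt.within, "group_within.tsv")
    persist(gdt.between, "group_between.tsv")
    persist(motu, "motu.tsv")
    log("motu", f"verdicts: {motu.verdict.value_counts().to_dict()}")

    # --- per-query report ----------------------------------------------------
    mono_by_group = dict(zip(motu.group, motu.monophyletic))
    qc_by_id = qc_df.set_index("id")
    rows = []
    for q, a in zip(queries, assignments):
        qrow = qc_by_id.loc[q.id]
        morph = q.morphotype or ""
        congruence = _congruence(q.lineage, a)
        rows.append((
            q.id, morph, qrow.frame, bool(qrow.has_internal_stop),
            bool(qrow.indel_flag), a.best_hit_id or "", round(a.best_sv, 3),
            a.rank, a.taxon_name or "", char_calls[q.id],
            bool(mono_by_group.get(grouping[q.id], False)), congruence,
        ))
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    persist(report, "report.tsv")

    summary = summary_table(report)
    persist(summary, "summary.tsv")
    log("report", f"{len(report)} queries, {len(summary)} morphotypes")

    if out_dir is not None:
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        report=report, summary=summary, qc=qc_df, assignments=assign_df,
        motu=motu, tree=tree, out_dir=out_dir,
    )


def _congruence(morph_lineage: Lineage, assignment) -> str:
    """match / mismatch / indeterminate at the granted rank."""
    if assignment.rank == "unassigned":
        return "indeterminate"
    expected = morph_lineage.name_at(assignment.rank)
    got = assignment.taxon_name
    if not expected or not got:
        return "indeterminate"
    return "match" if expected == got else "mismatch"


def summary_table(report: pd.DataFrame) -> pd.DataFrame:
    """Per-morphotype summary in the style of a barcoding results table.

    One row per morphotype: N, the modal molecular match and its rank,
    the SV spread (min/median/max), the modal character-classifier call
    (NA when the classifier never called), NJ monophyly, and the modal
    congruence verdict.
    """
    rows = []
    for morph, grp in report.groupby("morphotype", sort=True):
        taxa = grp.loc[grp.taxon != "", "taxon"]
        match = taxa.mode().iloc[0] if not taxa.empty else ""
        rank = grp.loc[grp.taxon == match, "rank"].mode().iloc[0] \
            if match else "unassigned"
        chars = grp.loc[grp.character_call != "", "character_call"]
        char_result = chars.mode().iloc[0] if not chars.empty else "NA"
        rows.append((
            morph, len(grp), match, rank,
            round(grp.best_sv.min(), 2), round(grp.best_sv.median(), 2),
            round(grp.best_sv.max(), 2), char_result,
            bool(grp.nj_monophyletic.all()),
            grp.congruence.mode().iloc[0],
        ))
    return pd.DataFrame(rows, columns=[
        "morphotype", "n", "molecular_match", "rank", "sv_min", "sv_median",
        "sv_max", "character_result", "nj_monophyletic", "congruence",
    ])


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs per the config, run the workflow, persist artifacts."""
    try:
        lib_records = seqio.read_fasta(config.library)
        query_records = seqio.read_fasta(config.queries)
        if config.meta:
            meta = seqio.read_metadata(config.meta)
            lib_records, _ = seqio.attach_metadata(lib_records, meta)
            query_records, _ = seqio.attach_metadata(query_records, meta)
    except Exception as exc:
        raise PipelineError(f"stage load: {exc}") from exc

    outgroup = None
    references = []
    for rec in lib_records:
        if rec.role == "outgroup" or rec.id == config.outgroup:
            outgroup = rec
        else:
            references.append(
                rec if rec.role == "reference"
                else dataclasses.replace(rec, role="reference")
            )
    queries = [q for q in query_records if q.id != config.outgroup]

    result = run(queries, references, outgroup=outgroup, config=config)
    if result.out_dir is not None:
        config.to_file(result.out_dir / "config.txt")
    return result
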