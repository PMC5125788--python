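# Methods

## Scope and model

`barcodeid` identifies unknown COI barcodes against a reference library
and reconciles the outcome with prior morphological identifications. The
statistical core is deliberately simple and transparent: uncorrected
*p*-distances, a threshold rule on percent similarity, neighbour-joining
trees with nonparametric bootstrap, pure diagnostic characters, and a
declared heuristic for barcode-gap (MOTU) verdicts. Nothing is
model-fitted; every decision is reproducible from the inputs, the
parameters and one integer seed.

## Distances and similarity

For a pair of sequences, the *p*-distance is the proportion of differing
sites among **compared** sites: alignment columns where both sequences
carry an unambiguous A/C/G/T. Columns with a gap or an IUPAC ambiguity
code in either sequence are excluded for that pair only (*pairwise
deletion*). A pair with zero compared sites has no distance; the package
raises an explicit `UndefinedDistance` rather than returning 0.

Unaligned pairs are put in register by optimal global alignment with free
end gaps: match +1, mismatch −1, internal gap −5 for the first gapped
position and −2 for each additional one, terminal gap runs free. Free end
gaps matter because queries are routinely fragments of full-length
barcodes: overhang is missing data, not mismatch. Among co-optimal
alignments the aligner's first traceback is used, which is deterministic
for a given pair; when the gapless pairing of two equal-length sequences
already achieves the optimal score it is used directly (this is an
optimality-preserving shortcut, verified against the aligner's score on
every pair it is applied to).

The similarity value is SV = 100 × (1 − *p*) on the compared-site
support, so SV + 100·*p* = 100 by construction. Kimura-2-parameter
distances (`k2p_distance`) are available for comparison but are never
used by the pipeline: at barcode-scale divergences the correction is
smaller than the sampling noise, and *p*-distances keep the tier rule and
the distance tables on one scale.

Group distance tables follow the MEGA group-mean convention: the within
mean averages over unordered in-group pairs, the between mean over all
cross pairs. A singleton group's within mean is **undefined** and
reported as NaN — never as 0, which would fabricate a perfect barcode
gap.

## Tier rule

A query's rank comes from its best SV: species at SV ≥ 98, genus at
92 ≤ SV < 98, family at 85 ≤ SV < 92, unassigned below 85. The intervals
are half-open and partition [0, 100]; boundary behaviour is pinned by
tests (98.0 → species, 92.0 → genus, 85.0 → family, 84.999 →
unassigned). The granted taxon is the best hit's lineage truncated to the
granted rank; ties in SV break lexicographically by reference id so runs
are reproducible. The thresholds are configurable (`RunConfig.tiers`) for
markers or taxa where the canonical COI values are inappropriate.

## Quality control

A functional mitochondrial COI fragment has a reading frame free of
internal stops. Frame detection counts, for each offset 0/1/2, the stop
codons (vertebrate mitochondrial code: TAA, TAG, AGA, AGG) over complete
codons, never counting the terminal codon — a stop there is a legitimate
ORF end. The frame with the fewest stops is reported (lowest frame on a
zero tie); if all three frames tie with stops the frame is
`undetermined`. Ambiguity codes never count as stops.

Indels are only detectable relative to something. With a best-hit
reference supplied, the QC aligns the query to it and flags any internal
gap; the stop screen then runs on the *frame-restored projection* (query
bases inserted relative to the reference dropped, deleted positions
padded with N) so that a frameshift does not additionally masquerade as a
stop-codon defect — the two flags stay independent evidence. Without a
reference the fallback flags sequences whose length mod 3 deviates from
the dataset's modal class; this is a weaker heuristic and is only used
when no reference is available.

QC never excludes a query from identification; it annotates. Assignment
and QC are independent evidence streams, and the report carries both.

## Neighbour joining and bootstrap

NJ follows Saitou–Nei with the standard Q-criterion. Two conventions are
pinned because they affect outputs: (i) when several pairs minimise Q,
the pair whose cluster labels (each cluster labelled by its smallest tip
id) sort lowest is joined, making topologies on degenerate matrices
reproducible; (ii) negative limb estimates — routine with *p*-distances
from small samples — are clamped to zero with the deficit moved to the
sibling limb (Kuhner–Felsenstein), preserving the joined pair's distance.
The result is unrooted (trifurcating root node); rooting places a new
root at the midpoint of the outgroup's pendant edge.

Bootstrap supports resample alignment columns with replacement, recompute
the *p*-distance matrix under the same pairwise-deletion rule, rebuild
the NJ tree, and score each internal edge of the original tree by the
percentage of replicate trees containing the same bipartition. Supports
survive rerooting by bipartition matching, not positional copying — the
annotated edge, not the node object, is the unit that carries support. A
group is monophyletic when some edge bipartition separates exactly its
tips (on a rooted tree, when it forms a clade).

The default of 1000 replicates matches common practice for publication
trees; tests and the acceptance script use 25–100 replicates, which is
ample to rank clean splits and keeps runs fast.

## Diagnostic characters

The character classifier is intentionally the purest form of the idea:
for each species, collect every alignment column at which all members
share one unambiguous state that appears in no other species; call a
query for a species only when it matches that species' complete set and
no other species' set. Species without any pure diagnostic column are
recorded as undiagnosable and can never be called — mirroring the NA
outcomes a character-based tool returns when reference coverage is thin.
No Boolean combinations of positions are mined; that richer family of
rules trades transparency for recall and is out of scope.

## MOTU verdicts

The barcode-gap verdict for a group against its nearest neighbour group:

* within mean = 0 or undefined → `distinct` iff between mean ≥ 0.02
  (an absolute floor: ~2 % divergence, below which a zero-within group is
  not credibly separate);
* between mean exactly equal to within mean → `ambiguous`;
* `distinct` when the minimum between-distance exceeds the maximum
  within-distance **and** between mean ≥ R × within mean (default R = 5);
* `merged-signal` when between mean < R × within mean;
* `ambiguous` otherwise.

R = 5 separates the two canonical situations a barcoding survey meets: a
nominal species pair whose between-group distances sit at within-species
magnitude (e.g. means 0.009 vs 0.004 → `merged-signal`) versus a tight
cluster far from every named neighbour (within 0.000, between
0.059–0.070 → `distinct`). The rule is a declared, tunable heuristic —
not a delimitation model — and the report always carries the raw
means/extremes and the monophyly flag next to the verdict.

## Synthetic libraries

The generator emulates a hierarchical reference library on a star
topology per tier: a stop-free random coding sequence is mutated into
family ancestors, then genus, species and specimen sequences. Branch
substitution proportions are set so expected pairwise distances hit the
tier targets (defaults 0.005 within species, 0.05 within genus, 0.10
within family, 0.15 between families — chosen to straddle the 98/92/85
tier boundaries, with conspecific queries expected near SV 99.5,
unsampled congeners near 95, unsampled genera near 90). Substitutions are
per-site, equal-rate among the three alternative bases, with per-codon
rejection of in-frame stops; fragments default to 657 bp, the codon
multiple nearest a full-length 5′ COI barcode. Multiple hits deflate
realized distances a few percent below nominal at these values — inside
the generator's ±30 % calibration contract, which the tests measure from
the generator's own output.

What the simulation does **not** emulate: codon-position rate
heterogeneity, transition/transversion bias, base-composition skew,
population structure within species, and missing data patterns of real
chromatograms. Passing tests therefore demonstrate the *logic* of the
pipeline (thresholds, screens, trees, verdicts) under controlled
divergence, not field performance on any particular taxon.

Artifact injection adds, per record and independently, a single-base
internal indel and/or a single substitution creating an in-frame stop.
An injected indel never lands inside an injected stop codon, keeping the
two truth flags independently detectable by a correct QC — which is the
property the QC tests assert exactly.

## Numerical and degenerate-input choices

* All stochastic draws flow from one `numpy` Generator per operation,
  seeded explicitly; identical inputs and seed give byte-identical
  outputs (FASTA, TSV, Newick).
* Distance matrices are symmetrised exactly (`(M + M.T) / 2`) after the
  vectorised computation to eliminate float-order noise.
* Newick output fixes branch lengths at six decimals and supports as
  integer labels, so write → read → write is byte-stable.
* Sequences of equal length are treated as pre-aligned by
  `distance_matrix`'s default route (the situation for simulated
  libraries and barcode sets trimmed to a common region); mixed-length
  sets are pairwise-aligned, and the pipeline projects all records onto
  its first reference's coordinates — the declared pairwise-to-reference
  stand-in for multiple alignment, adequate for indel-sparse coding
  fragments and not for markers with frequent indels.
* Empty hit lists, singleton groups, zero-overlap pairs and saturated
  K2P pairs all return explicit undefined signals or documented
  fallbacks rather than zeros.

## Problem sizes

Tests and the acceptance script run on a 120-specimen default library
(5 families × 2 genera × 3 species × 4 specimens), 60 mixed queries, 200
random additive matrices of 4–6 taxa for the NJ consistency check, and
100 bootstrap replicates — sizes chosen to mirror a small survey while
keeping a full run in tens of seconds.

## Known limitations

* Threshold-based identification inherits every known failure mode of
  fixed similarity cutoffs: recently diverged species pairs fall below
  the species tier and introgression or incomplete lineage sorting can
  push non-conspecifics above it. The MOTU verdict and monophyly flags
  exist precisely to surface those cases, not to resolve them.
* The character classifier requires the query to be projectable onto the
  training alignment; heavily truncated queries yield no-calls.
* NJ is a point estimate; only bootstrap supports qualify it. No
  likelihood or Bayesian machinery is included by design.
* The MOTU rule is a heuristic with two tunables (R, absolute floor); it
  is not a substitute for coalescent-based delimitation.
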