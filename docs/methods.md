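# Methods

## Scope and model

`scaffcheck` evaluates an assembly, it never builds one. It consumes the
outputs that standard tools produce around a hybrid single-individual
assembly workflow — mapped Hi-C pairs (`.pairs`), the scaffold layout (AGP),
an alignment-derived per-base depth track (BEDGRAPH from
`bedtools genomecov -bga`), a reference annotation (GFF3), and phased
variants (VCF with `PS` phase sets) — and quantifies four things: whether
scaffold joins are physically supported, how complex the sequencing
libraries are, how much of each annotation class the assembly captures, and
how accurate the phasing is against parental truth.

All internal coordinates are 0-based half-open; 1-based formats (AGP,
`.pairs`, GFF3, VCF) are converted only at the I/O boundary.

## Misjoin detection

The insulation score at scaffold point *p* with window *W* is the number of
contact pairs with one end in `[max(0, p−W), p)` and the other in
`[p, min(L, p+W))`. It is deliberately left as a raw count rather than a
normalized boundary-strength ratio: the decision rule compares the same
metric between observed junctions and artificial false-joins, so a common
raw scale suffices and avoids inventing a normalization.

The null is built by sampling `n_null` ordered pairs of distinct contigs
that do not share a scaffold, forming a virtual junction from the first
contig's right end to the second's left end, and counting contacts between
the two end windows (truncated to the contig if it is shorter than *W*).
Contig orientation is not randomized because end-window counting is
invariant to it. A junction is flagged when its score is at or below the
empirical `q`-quantile of the null sample (`q` = 0.95 by default) — i.e.
when it is consistent with the false-join distribution. `W` = 1 Mb matches
the window used in practice for fly-scale genomes; `n_null` = 1000 and `q`
are exposed because no canonical values exist. Windows are truncated rather
than skipped at scaffold ends, and the truncation is recorded on each
result so callers may filter.

Known limitation: with `q` = 0.95 the rule is intentionally conservative
toward breaking — any junction whose support is within the bulk of the
false-join distribution is flagged, so a true join in a contact desert
(e.g. a centromere at low coverage) can be broken. Breaking a true join
costs contiguity only; the downstream scaffolder can rejoin it.

## Library QC

Duplicates are exact matches on both endpoints and both strands — no fuzzy
window, since no tolerance is published and exact matching is reproducible.
Depth statistics use the base-weighted population variance (the track is
the full population of bases, not a sample). The dispersion index `σ²/μ`
is 1 in expectation under uniform Poisson sampling; amplified low-input
libraries sit far above 1 (the regime emulated by the defaults: mean 39.7,
variance 1038). Predicted coverage is reported unrounded
(`reads × length × (2 if paired) / genome size`); display layers round to
an integer fold.

## Completeness

"Captured" means depth ≥ 1 in the assembly-to-reference alignment track;
the alignment itself is consumed, not computed, which keeps the module
alignment-tool-agnostic. Elements are counted per annotated span as they
appear in the GFF3 — discontinuous spans sharing an `ID` are not merged,
because merging policy is convention-dependent; any aggregation of type
labels (e.g. several repeat types into one class) is left to the caller.
Strand is ignored (depth is strandless). The capture threshold τ defaults
to 0.90 ("at least 90% of the element's bases captured"). The bimodality
summary (10-bin histogram plus the fraction of elements with covered
fraction ≤ 0.1 or ≥ 0.9) quantifies the all-or-nothing capture pattern
typical of collapsed repeats.

## Phasing evaluation

Polarization assigns each allele of a heterozygous site to a parent. The
synthetic path uses the construction truth table directly. The alignment
path walks the cs tag of a parent-to-assembly PAF: a site inside an
identity run means the parent carries the assembly (REF) base; a
substitution supplies the parent base explicitly; sites under deletions,
outside alignments, or covered by more than one alignment stay
unpolarized; sites where neither allele matches the parent base are tallied
as inconsistent and excluded. Only SNPs are polarized via PAF; indels pass
through typing but need the truth-table path.

Error decomposition per block: build the 0/1 disagreement vector between
the block's haplotype-0 alleles and the parent-A truth; evaluate both
global orientations and keep the one with fewer total errors (ties go to
the orientation agreeing at the first site — deterministic because the two
orientations always differ there). Within the chosen orientation, an
isolated disagreeing site flanked by agreement or a block edge is one
mismatch; a maximal disagreeing run of length ≥ 2 contributes one switch
per change-point with an agreeing neighbor — two for an interior run, one
for a run touching a block edge. Counting both change-points of an
interior run is what makes the estimator consistent: a planted
per-adjacency switch process with rate σ toggles the running orientation
at each event, and every toggle is exactly one change-point, so the
recovered switch count equals the planted event count up to two small,
quantified corrections: adjacent toggle pairs collapse into an isolated
site and are reclassified as one mismatch (expected fraction ≈ 2σ of
events), and a toggle at a block's final adjacency yields a single-site
run, also a mismatch (≈ 1/(block length − 1) of events). At the default
regimes these biases are ~1–3% of the rate, well inside the 3-binomial-SE
acceptance bands. Rates divide by truth-labeled phased sites; blocks with
fewer than two labeled sites contribute sites but no errors; unpolarized
sites are excluded from denominators since errors are undefined without
truth.

Depth filtering drops sites strictly below the empirical 10th or strictly
above the 90th percentile (linear interpolation); the convention is stated
because "bottom/top 10%" alone does not fix one.

The block-join estimator multiplies the per-site switch-rate increase
attributable to a long-range data type by the mean short-read block length:
each pre-existing block contributes ≈ 1 join, i.e. ≈ 1/mean-length joins
per site, so the product estimates the probability a join introduces a
switch.

## Synthetic data

The generators define the study conditions; their defaults are the
emulated regime, not tuning knobs: heterozygosity θ = 0.005 (an
inter-strain *Drosophila* cross), decay exponent α = 1 with a 1 kb minimum
separation (the generic Hi-C decay regime; no decay model is published for
this data), trans rate 1%, duplication rate 12%, depth moments
(39.7, 1038), 14-variant blocks with a 0.00147/site error budget.

Design choices made where the design was genuinely open:

- Depth is i.i.d. per base and run-length encoded rather than read-level:
  consumers only use moment structure, and read placement would add
  complexity without testing anything new. Consequently the track has no
  spatial autocorrelation, so passing moment-recovery tests says nothing
  about locally structured coverage artifacts in real data.
- F1 differences are SNP-only, keeping parental coordinate systems
  identical and the truth table exact by construction; an indel mode is an
  extension point, so indel-realignment artifacts are untested.
- Trans contacts pick an ordered pair of distinct references uniformly
  (equal expected count per pair), endpoints uniform within each. Small
  contigs are therefore trans-dense per base, like the short-contig noise
  tail of real assemblies.
- The planted-misjoin benchmark joins two unlinked 3 Mb contigs in one
  scaffold and adds a 6 Mb contiguous control sequence represented as two
  adjacent 3 Mb contigs plus two unlinked 1 Mb filler contigs. The fillers
  anchor the false-join null with geometries whose end windows cover the
  whole contig, placing the null's upper quantiles well above the trans
  background at the planted junction; the control junction's cis support
  sits orders of magnitude above both. The flag/no-flag outcome is then
  driven by structure, not by a 5% tail coin-flip, which is what makes
  20/20-seed sensitivity and specificity a meaningful property.
- Duplicates re-emit already-emitted records until the requested fraction
  of records are copies, so the recovered rate is exact up to birthday
  collisions among independent pairs (negligible at the simulated sizes).

Every generator draws from one `numpy` Generator seeded per call, so all
emitted files are byte-identical under a fixed seed. Sub-seeds for
multi-stream runs come from `derive_seed`, which spawns independent
`SeedSequence` streams and stays below 2^31.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale chosen to make the
statistical assertions sharp but cheap: 100k pairs for duplication
recovery (3 binomial SE ≈ 0.3 points), 100k–200k sites for phasing-rate
recovery, 1 Mb tracks for depth moments (±5%), and the full-size misjoin
benchmark (2 × 3 Mb contigs, 200k cis pairs each, 1% trans) across 20
seeds. Empirical quantiles use numpy's default linear interpolation.
Degenerate inputs are errors, not silent results: empty depth tracks,
breaks at scaffold ends, null sampling without two unlinked contigs, and
τ outside (0, 1] all raise.

## Known limitations

- The misjoin scan scores contig-contig junctions (plus an optional
  fixed-stride scan); it does not produce matrix-based insulation profiles
  or TAD calls, and it does not re-scaffold after breaking.
- Coverage/completeness consumes externally produced alignments; results
  inherit the aligner's mapping bias.
- The phase evaluator requires truth haplotypes; it measures supplied
  phase sets and performs no phasing inference.
- Real-data headline numbers of the emulated workflow (scaffold N50,
  BUSCO, reference-comparison tables) require the original raw data and
  external assemblers and are out of scope; the acceptance surface is
  worked examples and parameter-recovery under the stated conditions.
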