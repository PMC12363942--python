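# Methods

`amyloc` reimplements, as a reusable and fully tested pipeline, the kinds of
bespoke analyses used to reconstruct the structural and regulatory evolution
of a tandemly duplicated gene cluster (the primate amylase locus is the
motivating system): locating the locus between flanking single-copy anchors,
resolving orthology and duplication polarity among paralogs, diagnosing
non-allelic homologous recombination (NAHR) from mosaic duplicons and dating
duplications on a calibrated phylogeny, quantifying transposable-element (TE)
enrichment with phylogenetically corrected regression, measuring
paralog-specific expression from allele-diagnostic coding polymorphisms, and
scanning promoter windows for transcription-factor binding motifs.

Every stage runs on synthetic data with construction-time ground truth, so
the whole pipeline is testable offline.

## Locus extraction

Two anchor sequences flanking the locus are searched against every contig of
an assembly with a seed-and-extend local search: exact 15-mer seeds are
grouped by diagonal and each diagonal cluster is extended by a local
alignment with +1/−1 match/mismatch scores and linear −2 gap costs.  The
substitution matrix treats N as a mismatch against everything (including N),
so assembly gaps can never inflate identity.  Hits must reach 85% identity
and 80% query coverage by default; both thresholds are explicit configuration
— the anchor-mapping literature rarely states them, so they are recorded in
logs rather than inferred.

Where the best-scoring consistent pair of 5′/3′ hits co-locates on a single
contig, the locus is extracted flank-to-flank (anchor outer edges inclusive)
and reverse complemented on minus-strand placements so the 5′ anchor always
leads; extraction is byte-identical between an assembly and its
reverse-complemented mirror (a tested invariant).  Anchors on different
contigs give `fragmented`, a missing anchor gives `absent`, and anchors on
one contig with inconsistent orientation are flagged `fragmented` with a
logged warning, never silently.

Gene copies are counted by placing CDS queries with the same search and
keeping placements greedily by score; a placement may overlap an
already-kept one by at most 10% of the shorter interval, which tolerates
tandem copies sharing a short identical tail while rejecting duplicate
placements.  Spliced alignment is out of scope: placements are contiguous
high-identity matches.

## Orthology and duplication polarity

All-vs-all global alignments between the gene sets of two species yield a
score matrix.  A pair that are each other's unique top hit is a one-to-one
ortholog pair.  A one-to-many pattern (duplication in the "many" lineage)
is a gene *a* together with the group of genes whose unique top hit is *a*,
provided every top hit of *a* lies inside that group.  Ties are handled
conservatively but not destructively: a tie among members of the same group
is tolerated (two young paralogs are often exactly equidistant from their
ortholog), whereas a tie reaching outside a group, or any tie in a would-be
one-to-one pair, leaves the genes unresolved — never arbitrarily assigned.
Genes claimed by candidate patterns in both directions are unresolved as
genuinely ambiguous.  The rule set is verified against a brute-force oracle
over every 3×2 integer score matrix with entries in {1..4}.

## Duplicon architecture

**Segmentation.** The locus is tiled into one segment per gene copy with
internal boundaries at the midpoints of inter-gene gaps, plus flank
segments.  Midpoints stand in for lncRNA termini (the natural anatomical
boundary in the real locus) because synthetic data carry no lncRNA
annotation; the boundary rule is configurable.

**Mosaic breakpoints.** A derived duplicon produced by NAHR matches one
donor over its 5′ part and another over its 3′ part.  The derived sequence
is globally aligned to each donor; for each split point *k* the objective
matches(derived[0:k], donorA) + matches(derived[k:], donorB) is evaluated by
prefix sums.  The crossover interval is the plateau of split points
attaining the optimum — exactly the run of columns over which the two
donors agree with each other, within which the breakpoint is
unidentifiable.  Support values are the flank identities outside the
plateau; both must reach 0.8.  Gaps count as mismatches; N positions in the
derived sequence are masked from all counts and reported.  Identical donors
produce a whole-sequence plateau and an `unresolved` call.  The final NAHR
label additionally requires direct-orientation homologous flanking segments
and a crossover narrower than 20% of the derived segment.

**Age bracketing.** Given an ultrametric tree with node ages and the set of
tips carrying a duplicate, the duplication age is bracketed by
[age of the carriers' MRCA, age of the split from the nearest non-carrier
lineage].  A single carrier tip gives a lower bound of 0; if every tip is a
carrier the upper bound is +∞.  Carriers must be monophyletic — secondary
loss is deliberately not modeled, and violations raise an error listing the
offending tips.  Ultrametricity is checked to a relative 10⁻⁶.

## TE landscape and phylogenetic regression

RepeatMasker `.out` tables are parsed (three header lines, whitespace
columns, 1-based inclusive query coordinates converted to 0-based
half-open; the class is the part of the class/family column before "/",
bucketed into SINE/LINE/LTR/DNA/other).  TE content is the proportion of
masked bases — the length of the *union* of annotation intervals divided by
region length, so overlapping annotations are never double-counted.
Locus-vs-genome enrichment is log2((p_locus+ψ)/(p_genome+ψ)) with
pseudocount ψ = 10⁻⁴ (0.01 percentage points) to keep absent families
finite.

Cross-species enrichment is tested with a two-sided Wilcoxon signed-rank
test: zeros discarded, tied magnitudes mid-ranked, exact for n ≤ 25 via
convolution of the doubled-rank distribution (identical to enumerating all
2ⁿ sign assignments), and a normal approximation with tie correction and
0.5 continuity correction above.  P-values across families are adjusted by
Benjamini–Hochberg step-up.  The N50-style confound check is a Spearman
correlation plus a rank partial correlation (residuals after regressing
ranks on the ranks of the confounder; t-approximation with n−3 df).

PGLS fits y = a + b·x with errors N(0, σ²·C(λ)), where C(1) is the
Brownian-motion shared-path-length matrix and C(λ) scales off-diagonal
entries by λ ∈ [0, 1].  λ is estimated by bounded 1-D maximum likelihood
(tolerance 10⁻⁶, endpoints checked explicitly) with (a, b, σ²) profiled
analytically by GLS via Cholesky whitening at each λ.  R² is computed in
the whitened space against the GLS intercept-only model; the slope test
uses the unbiased residual variance with n−2 df; the λ = 0
likelihood-ratio test uses a plain χ²(1) reference, which is conservative
at the boundary (a ½χ²₀+½χ²₁ mixture would be anti-conservative to ignore
in the other direction).  Copy number is treated as a Gaussian response —
a documented simplification.  On a star phylogeny the fit reduces to OLS to
10⁻⁸, and simulated Brownian data (λ=1, b=2, 100 tips, 200 replicates)
recover the slope within ±0.1 with mean λ̂ ≥ 0.9.

## Paralog-specific expression

Diagnostic sites are gap-free alignment columns with ≥2 alleles.  Selection
mirrors the two-proximal + two-distal design: in each half of the
alignment, the most extreme candidate anchors a cluster that is grown with
partners maximizing joint discrimination (ties broken toward the anchor),
until the cluster distinguishes every paralog or candidates run out; among
equally discriminating clusters the most extreme wins.  `max_cluster_span`
(typically the read length) constrains each cluster so a single read can
span it — the published site pairs are 18 bp and 16 bp apart for exactly
this reason.  If the joint patterns still fail to identify every paralog,
further columns are added greedily by partition refinement; total failure
raises an error naming the indistinguishable paralogs.

Reads are placed on a column-majority consensus by exact 20-mer seeds with
a cap on mismatches outside diagnostic sites (default 2 for near-identical
paralogs; raised for more diverged simulations — a wrong placement incurs
~25% mismatches, so a generous cap is safe).  A read is counted only when
it fully covers a selected site cluster and matches exactly one paralog's
alleles at all covered cluster sites; reads compatible with several
paralogs are discarded, never fractionally allocated (a fractional mode
exists only as an explicit choice).  Requiring full cluster coverage makes
the probability that a read is countable a function of its position alone,
identical across paralogs, so assigned counts are an unbiased sample of the
mixture — with partial-coverage counting, single biallelic sites
systematically favor their minority-allele paralog.

Count post-processing: genes with fewer than 10 reads summed across samples
are dropped (boundary inclusive); size factors follow the median-of-ratios
rule (reference = per-gene geometric mean over genes with no zero count;
factor = median ratio).  Size-factor ratios are equivariant under scaling a
single sample; absolute factors are only identified up to the geometric-mean
normalization.  Log2 fold changes use group means of normalized counts with
a 0.5 prior; proportional expression normalizes non-negative per-paralog
values to sum to one.

## Promoter motif scanning

Promoter windows span 100 bp upstream to 70 bp downstream of the TSS
(170 bp; the TSS, the 0-based index of the +1 base, is the 101st base of
the window), reverse complemented on minus-strand genes so windows always
read in transcription orientation; windows overhanging the source sequence
raise rather than pad.

PWMs (JASPAR-style counts, A/C/G/T rows) are column-normalized with
pseudocount 0.01 against a uniform background by default; the per-position
log-odds is log2((f+ψ)/(bg·(1+4ψ))).  Both strands are scanned at every
offset; N scores as the worst allele of its column, so an all-N window
yields nothing.  Match p-values P(score ≥ s) are exact under the i.i.d.
background, computed by dynamic-programming convolution of the per-column
score distributions on a 10⁻³-bit integer grid; they agree with exhaustive
4^L enumeration to ≤10⁻⁴ for L ≤ 6 and are monotone in score.  Hits below
the threshold (default 10⁻⁴; note a length-6 motif's best achievable p is
4⁻⁶ ≈ 2.4×10⁻⁴, so short-motif scans need a looser threshold) are all
reported — no overlap masking, since downstream bias classification counts
TF presence, not hit multiplicity.  TF bias labels are pure set logic:
salivary-biased = in any salivary set and absent from the pancreatic set;
pancreatic-biased = the converse; everything else (including TFs in both)
is core.

## Synthetic data

All generators are pure functions of (parameters, seed) through a single
`numpy` Generator per scenario.

* **NAHR locus** — anchor5 · (spacer · gene block)ⁿ · spacer · anchor3
  embedded in a padded contig.  Paralogs carry marker SNVs at rate
  `divergence` (default 2%, a typical Old World monkey paralog divergence
  scale); each event inserts donor5-prefix + donor3-suffix at a stated
  crossover, optionally preceded by a synthetic LTR-like cassette (50 bp
  terminal direct repeats around a 400 bp body — minimal structure for
  junction-proximity logic, no real element sequence).  Derived blocks
  receive post-duplication private SNVs (default 0.5%) because an exact
  chimera is undetectable by diagnostic sites; breakpoint-recovery tests
  switch this off to isolate crossover localization.
* **Brownian traits** — x and the residual are multivariate normal with
  covariance σ²C(λ); y = a + b·x + residual + independent noise.
* **Reads** — mixture-chosen paralog, uniform start, uniform substitution
  errors; the source of every read is recorded.
* **Counts** — negative-binomial with mean sⱼ·μ_g (log-uniform gene means)
  and dispersion α (Poisson at α = 0).

What the generators do *not* emulate: indels and structural micro-variants
between paralogs (alignments are gap-free at diagnostic sites), spliced
transcripts, read quality profiles and strand-flipped reads, lineage-specific
repeat families, and assembly collapse.  Passing tests therefore demonstrate
correctness of the algorithms under these idealized conditions, not
robustness to every artifact of real assemblies and libraries.

## Problem sizes and numerical choices

The test and acceptance suites use sizes chosen to make Monte-Carlo noise
negligible while keeping a laptop-scale run: 200 replicates × 100 tips for
PGLS recovery, 100 seeded simulations for breakpoint containment, 10,000
reads for mixture recovery (250 bp paralogs, so ~30% of reads span a site
cluster), 2,000 genes for size-factor recovery, full 4^L enumeration for
PWM p-values up to L = 6.  Determinism: every stochastic test and the demo
pipeline take explicit integer seeds; reruns are byte-identical.

## Known limitations

* The seed-and-extend search needs one exact 15-mer seed; anchors more
  diverged than ~1 difference per 15 bp everywhere can be missed even above
  the identity threshold.
* Mosaic calling assumes a single crossover; double crossovers / gene
  conversion tracts produce wide or misplaced plateaus (reported as
  `unresolved` when supports fail).
* Age bracketing assumes single origin and no loss; a duplicate lost in a
  nested lineage errors rather than widening the bracket.
* PGLS treats integer copy number as Gaussian; a phylogenetic count model
  is out of scope.
* Read assignment is single-end and orientation-aware only in the forward
  sense, matching the simulator.
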