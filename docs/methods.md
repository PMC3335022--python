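# Methods

This note documents the models, estimators, numerical conventions and known
limitations behind each `sagkit` module, and what the synthetic-data
generators do and do not emulate.

## Cytometry counting and abundance

Events are points in (log10 side scatter, log10 green fluorescence); gates
are named simple polygons in that space, supplied in the pipeline config
(no automatic gate inference — gates are drawn by the analyst, as in
practice).  Point-in-polygon is ray casting with an explicit boundary test:
events exactly on an edge or vertex count as inside, so edge events are
deterministic rather than dependent on floating-point crossing parity.

The absolute abundance of gated cells uses bead internal standards of known
concentration C_beads (taken as given input; in practice it is itself
measured microscopically):

    abundance = (cells_gated / beads_gated) · C_beads · dilution_factor

`dilution_factor > 1` means the sample was diluted before acquisition.  For
the 95 % interval, both gated counts are treated as Poisson; conditioning on
their total makes cells ~ Binomial(cells + beads, p), a Clopper–Pearson
interval on p is computed and transformed through r = p/(1−p) · C_beads ·
dilution.  This is the standard exact interval for a ratio of Poisson
intensities; it is conservative (measured coverage ≈ 95–98 % on the
generator, within the 90–99 % band the tests require).  Fold differences
between treatments divide point estimates and combine the interval
endpoints; a zero-control ratio is reported as flagged infinity, never as a
number.

Design note: a labeled population at 0.1 % of ~10⁵ events yields ~100 gated
cells per acquisition, but a 60-fold-attenuated killed control yields only
~2, so any single-acquisition fold estimate is dominated by killed-count
shot noise.  The demo pipeline therefore pools replicate acquisitions
(60 × 10⁵ events) before forming the fold difference, putting ~100 expected
events in the killed numerator.

## MDA kinetics QC

The critical point Cp of an MDA reaction is the time to half-maximal
fluorescence.  Conventions: baseline = median of the first three reads
(robust to a noisy first cycle); fmax = curve maximum; half level =
baseline + (fmax − baseline)/2; Cp = first crossing of the half level,
linearly interpolated between the bracketing samples.  Crossings are
searched on the running maximum of the curve — MDA fluorescence is
physically non-decreasing, so transient dips after amplification cannot
create spurious re-crossings.  Wells with fmax − baseline below an
amplitude floor (default 10 % of the plate-wide maximum amplitude, or an
absolute value from config) are reported `no_amplification`; a curve
already above the half level at the first read is `saturated_at_start`.
The half level is baseline-relative, which makes Cp invariant under affine
rescaling of the fluorescence axis when the floor is rescaled accordingly.

Plate QC tests whether 1-cell wells amplified earlier than 0-cell controls
with a Wilcoxon rank-sum test (one-sided by default, "1-cell lower";
configurable, since the direction convention of the original analyses is
not standardized).  The test uses exact null enumeration when the pooled
sample is ≤ 20 with no ties, otherwise the normal approximation with
midranks, tie correction and continuity correction (delegated to
`scipy.stats.mannwhitneyu`; the test suite checks the exact branch against
full enumeration).  1-cell wells slower than the 0-cell median are listed
as contamination suspects — a reporting convention of this package, so it
is labeled as such in reports.

## Phylotyping

Pairwise identity uses a global alignment with free end gaps (match +1,
mismatch −1, gap open −2, gap extend −1), because partial Sanger reads of
different lengths must not be penalized for non-overlap.  Identity =
matches / aligned columns, excluding columns where either end is a terminal
gap and counting internal gap columns as mismatches.  IUPAC ambiguity codes
match when their base sets intersect (Sanger convention).  The alignment
itself is computed by Biopython's PairwiseAligner with a custom
set-intersection substitution matrix.

Clustering is greedy centroid (UCLUST-style): sequences are processed
longest-first (ties broken by id), each joins the first existing centroid
with identity ≥ threshold (default 99 %), else founds a new phylotype.
This is deterministic, independent of input order, and guarantees the
member-to-centroid ≥ threshold invariant by construction (re-asserted at
run time).  A complete-linkage "grouping" would also be defensible; greedy
was chosen for determinism and the testable centroid invariant.  Note that
identity here is pairwise, not computed on a curated multiple alignment —
values can differ slightly from alignment-database similarities.

## Diversity

Jukes–Cantor: d = −(3/4)·ln(1 − 4p/3) for mismatch proportion p < 0.75;
p ≥ 0.75 raises a saturation error rather than returning infinity.

Neighbor joining is the Saitou–Nei algorithm with Q-matrix selection.  Ties
in Q are broken by the lexicographically smallest pair of subtree labels,
so the topology is invariant to input row order.  Negative estimated branch
lengths (possible on non-additive input) are clamped to zero with the
deficit moved to the sister branch, preserving the joined pair's path
length.  On additive matrices the algorithm is exact (path lengths
reproduce the input to < 1e−9 in the tests).

Weighted UniFrac between two samples on a tree: u_raw = Σ_branches
b_i·|p_i − q_i| with p_i, q_i the fractions of each sample's total
abundance descending from branch i.  The normalized variant (default)
divides by D = Σ_leaves d_j·(p_j + q_j) with d_j the root-to-leaf distance,
bounding the distance to [0, 1]; u_raw is also available via
`normalized=False`.  Computing branch-wise descendant sets requires a
rooted tree: an unrooted (trifurcating) input is midpoint-rooted by
default, or rooted at a named outgroup when one is supplied — mirroring the
archaeal-outgroup convention of 16S analyses.  The implementation is
cross-checked against scikit-bio's weighted UniFrac in the tests.

PCoA is classical metric scaling: eigendecomposition of the double-centered
−D²/2 matrix, axes sorted by descending eigenvalue, axes with negative
eigenvalues dropped (all eigenvalues still reported), and each axis
oriented so its first nonzero loading is positive, which fixes the sign
convention across runs.

## Genome comparison

**Tetranucleotide signatures.**  4-, 3- and 2-mer counts are pooled over
all contigs and both strands (overlapping windows, step 1; windows with
non-ACGT symbols skipped), making the signature exactly reverse-complement
symmetric.  Expected 4-mer counts come from the maximal-order Markov model,
E(n₁n₂n₃n₄) = N(n₁n₂n₃)·N(n₂n₃n₄)/N(n₂n₃), with variance
E·(N(n₂n₃) − N(n₁n₂n₃))·(N(n₂n₃) − N(n₂n₃n₄))/N(n₂n₃)²; z = (N_obs − E)/√Var.
Tetramers whose trinucleotide context is absent (or whose variance
degenerates) are flagged undefined — NaN, excluded from correlations, never
zeroed.  Signature similarity is the Pearson correlation over jointly
defined entries (≥ 10 required).

**Fragment ANI.**  The query is cut into consecutive 1020 bp fragments
(final short fragment dropped; fragment length and filters follow the
fragment-BLAST ANI convention and are exposed in config).  Each fragment is
placed on the reference by exact 15-mer seeds sampled every 15 bp on both
strands (reference k-mer index; highly repetitive seeds capped), the best
seed diagonal selects a reference window (±2 bands of 32 bp), and the
fragment is gap-aligned to that window with edlib (bit-parallel,
infix mode).  The resulting alignment is trimmed to its maximal-scoring
contiguous segment (match +1, mismatch/gap −2), which converts the banded
semi-global alignment into a local one: spurious placements of unrelated
sequence collapse to short segments.  A fragment is retained iff trimmed
identity ≥ 30 % over a query span ≥ 70 % of the fragment; ANI is the mean
identity (matches / alignment columns, gaps included) of retained
fragments, reported in both directions.  When no fragment passes, ANI is
undefined and flagged — not 0.  Note the filters' intent: unrelated genomes
fail on *coverage* (local alignments are short), not on the 30 % identity
floor, which forced global alignments of random DNA would exceed.

**Scaffold PCA screen.**  Each scaffold ≥ 2 kb contributes a 256-dim vector
of relative tetramer frequencies (both strands).  After PCA on the centered
vectors, a scaffold is flagged when its score on any of the first 8
components lies more than 3 robust standard deviations (1.4826 × MAD) from
that component's median; median/MAD is used because contamination itself
corrupts mean and SD.  Finite-sample caveat: with only ~50 scaffolds the
MAD's sampling noise (relative SE ≈ 0.17) multiplies the nominal 3σ
Gaussian tail severalfold, so the realized false-flag rate on clean
assemblies is ~5–7 % rather than the ~2 % an exact scale would give; with
hundreds of scaffolds the rate approaches nominal.  Scaffolds of very
unequal lengths add further heteroscedastic inflation (short scaffolds have
noisier frequency vectors).  Flags are therefore candidates for inspection,
not verdicts — matching how such screens are used in practice (extreme
scaffolds get examined, e.g. by BLAST against reference databases).

## Completeness and gene statistics

A CSCG (conserved single-copy gene) set is derived from a gene-family ×
reference copy-count matrix: strict mode (default) keeps families with copy
count exactly 1 in every reference; a relaxed mode (≥ 1 copy everywhere) is
available and the mode is recorded in output metadata.  Detection of CSCGs
in a SAG is an input (a set of family ids) — homology search is out of
scope; the synthetic pipeline supplies detection truth by coordinate
bookkeeping (a family is detected iff its gene interval is fully covered by
a retained assembly segment).

Recovery R_CSCG = |detected ∩ CSCG set| / n_CSCG; expected genome size
G_S = A_S / R_CSCG with A_S the assembly size.  The Clopper–Pearson
interval on R (n = n_CSCG trials) is propagated to G_S (upper recovery
bound → lower size bound).  G_S is additionally reported in Mb at one
decimal, the field's usual precision; the full-precision value is always
available.  With 273 families the interval half-width in R is ~0.05–0.06,
i.e. ~10 % relative in G_S at moderate completeness; coordinate-bookkeeping
detection introduces a small (< 1 %) downward bias in R because a gene must
be *fully* covered, which the interval comfortably absorbs (measured
coverage ≥ 93 % across completeness 0.3–0.9).

Gene-class frequencies (glycoside hydrolases by default; sulfatases,
peptidases, lyases/esterases by parameter) are copy-weighted class counts
over total annotated genes, per genome.  Taxon enrichment reports the
per-taxon mean and sample SD (n−1; undefined for single-genome taxa) of
per-genome frequencies plus an all-genomes average.  The GH-count vs
assembly-size association is the squared Pearson correlation (OLS R²).

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume —
a rare (0.1 %) labeled subpopulation among ~10⁵ cell-like events with
separable log-normal channel distributions, beads consistent with a
declared virtual acquisition volume (the volume is a bookkeeping convention
of this package, chosen so the abundance estimator's unbiasedness is
testable), a 60-fold-attenuated killed control, 315/66/3-well MDA plates
with 4-parameter logistic curves whose midpoint shifts by −4 h per decade
of template (log10(cells + 1)) plus 0.5 h well jitter and Gaussian read
noise, amplicon libraries built from ancestors ≥ 5 % diverged with members
at exact 0.5 % substitution distance (substitutions only; indel-free so
identity bookkeeping stays exact), and genomes from taxon-specific order-3
Markov sources (profile-seeded Dirichlet transition rows) with uniform
single-copy gene annotations and Dirichlet-sized non-overlapping assembly
segments.

Not emulated: spectral overlap/compensation and doublets in cytometry; MDA
amplification bias and chimera formation; sequencing error and indels in
amplicons; repeats, mobile elements, operon structure or GC skew in
genomes; read-level sequencing.  Passing tests therefore demonstrate the
estimators' correctness and calibration under the stated stochastic model,
not robustness to instrument- or chemistry-specific artifacts of real data.

All generators are deterministic given their seed (bit-identical repeat
output), and all pipeline randomness derives from one master seed through
SHA-256 per-stage streams, so a full demo bundle is byte-reproducible from
its config.  Markov sequence generation is numba-accelerated with a pure
Python fallback.

## Problem sizes in tests and the acceptance script

Statistical checks run at sizes giving comfortable power while staying
desk-scale: 200 acquisitions of 10⁵ events for estimator bias/coverage,
100 partial assemblies per completeness level (true size 4 Mb) for interval
coverage, 50 amplicon libraries for clustering recovery, 1 Mb genome pairs
for ANI, 50-scaffold assemblies (40 spiked + 50 null seeds) for the
contamination screen, and full enumeration up to n = 12 for the rank-sum
oracle.  `scripts/acceptance.py` recomputes the same quantities at somewhat
smaller replication (its runtime is ~30 s) and prints each value with the
problem size used.

## Known limitations

* The ANI aligner is a desk-scale seed-and-extend re-implementation; very
  diverged homologs (< ~80 % identity) lose seed sensitivity at the default
  15-mer seed length, and ANI values are not numerically identical to
  BLAST-based pipelines (agreement on same-species pairs is within the
  tolerance the tests assert).
* The PCA screen's false-flag rate exceeds the Gaussian nominal at small
  scaffold counts (see above).
* Phylotype identity is pairwise, not reference-alignment based; at the
  99 % threshold the two conventions can split or merge borderline pairs
  differently.
* The cytometry model draws each channel independently per population; real
  cytograms show correlated scatter/fluorescence within populations, which
  only affects how conservative rectangular gates need to be.
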