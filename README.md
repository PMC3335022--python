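# sagkit

Quantitative analysis pipeline for fluorescent-substrate single-cell
genomics studies of polysaccharide-degrading bacterioplankton.

In these studies, cells from a natural aquatic community are probed with a
fluorescently labeled polysaccharide (e.g. laminarin or xylan); cells that
bind and hydrolyze the substrate acquire green fluorescence, are counted and
sorted one per well by flow cytometry, whole-genome amplified (MDA), 16S
rRNA-typed, and a few are shotgun sequenced into partial single amplified
genomes (SAGs).  `sagkit` implements the downstream quantitative steps of
that workflow as a tested, reusable library with a command-line interface:

* **cytometry** — polygon gating on (log10 side scatter, log10 green
  fluorescence) event tables and bead-calibrated absolute abundance:
  `abundance = (cells_gated / beads_gated) · C_beads · dilution`, with an
  exact (Clopper–Pearson) interval from the conditional-binomial treatment
  of the two Poisson counts.
* **mda_qc** — critical point of each MDA reaction, Cp = time to half of the
  maximal fluorescence (first crossing on the running maximum, linearly
  interpolated), and a Wilcoxon rank-sum test that 1-cell wells amplified
  earlier than 0-cell controls.
* **phylotyping** — pairwise SSU rRNA identity (global alignment, free end
  gaps, terminal-gap columns excluded) and deterministic greedy centroid
  clustering at ≥99 % identity into phylotypes, with per-probe-library
  composition tables.
* **diversity** — Jukes–Cantor distances d = −(3/4)·ln(1 − 4p/3),
  Saitou–Nei neighbor joining, normalized abundance-weighted UniFrac
  u = Σᵢ bᵢ·|pᵢ − qᵢ| / Σⱼ dⱼ·(pⱼ + qⱼ), and classical PCoA.
* **genome_compare** — tetranucleotide z-score signatures under the
  maximal-order Markov model (E = N(n₁n₂n₃)·N(n₂n₃n₄)/N(n₂n₃)) with Pearson
  correlation between genomes; fragment-based ANI (1020 bp fragments, 30 %
  identity / 70 % coverage filters); and a per-scaffold tetramer-PCA
  contamination screen over the first eight components.
* **genome_stats** — conserved single-copy gene (CSCG) completeness:
  recovery R_CSCG of a reference-derived CSCG set and expected genome size
  G_S = A_S / R_CSCG with a propagated binomial interval; glycoside
  hydrolase (and sulfatase/peptidase/lyase-esterase) gene frequencies and
  per-taxon enrichment.
* **synthdata** — generators for every input the pipeline consumes (event
  tables with a ~0.1 % labeled subpopulation and ~10⁵ beads/mL, 315/66/3
  MDA plates, phylotype-structured amplicon libraries, Markov-biased genomes
  with partial SAG assemblies of known completeness), each emitting truth
  labels for validation.

## Worked example

Estimate the completeness and expected size of a partial SAG assembly from
CSCG recovery — a 2.1 Mb assembly containing 151 of 273 reference CSCGs:

```
$ sagkit completeness --assembly-bp 2100000 --n-found 151 --n-cscg 273
recovery=55.3% G_S=3.8 Mb [3.4, 4.3] Mb
```

55.3 % of the conserved single-copy gene set was recovered, so the assembly
is an estimated 55.3 % of a genome whose full size extrapolates to 3.8 Mb;
the bracket propagates the binomial uncertainty of 151/273 to the size.

Run the full pipeline end to end on generated data:

```
$ sagkit demo --seed 5 --out demo_run
ani_sibling_sags: 99.5022574804985
fold_infinite: False
killed_abundance_per_ml: 31.860345485621362
labeled_event_percent: 0.10045
live_abundance_per_ml: 2014.755484835012
live_killed_fold: 63.23708842844392
max_unifrac: 0.6592313108304115
mda_p_value: 1.2202106597905268e-33
mda_pass: True
mda_suspect_wells: 3
mean_size_error_percent: 13.2061705232437
n_libraries: 2
n_phylotypes: 5
pca_flagged: 7
pca_flagged_contaminant: 4
tetra_r_same_taxon: 0.9906378534652751
```

Reading the summary: pooled over 60 replicate acquisitions, 0.10 % of
cell-like events were substrate-labeled (~2015 cells/mL), a 63-fold excess
over the heat-killed control; the MDA plate passed QC (1-cell wells
amplified significantly earlier than no-template controls, with 3 slow
1-cell wells listed as contamination suspects); the amplicons clustered
into 5 phylotypes whose two probe libraries sit 0.66 apart in weighted
UniFrac; two sibling assemblies of one genome (0.5 % sequencing divergence)
show 99.5 % ANI while two independent genomes of the same taxon correlate
at r = 0.99 in tetranucleotide signature; and the contamination screen
flags all 4 contigs spiked in from a different taxon (plus 3 compositional
outliers of the host genome).

`demo_run/` then holds the event tables, abundance estimates, per-well MDA
QC, phylotype assignments and composition, the NJ tree (newick), UniFrac
distances, PCoA coordinates, ANI/tetranucleotide comparisons, the PCA
contamination screen, completeness estimates and GH enrichment, plus a
manifest (version, config hash, seeds).  The same seed reproduces the
bundle byte-identically.

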