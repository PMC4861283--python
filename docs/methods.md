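# Methods

This note documents the models, defaults and numerical choices behind
`oleofinder`, and what the synthetic-data experiments do and do not
establish about real data.

## Study design being emulated

The package targets a comparative design with seven plant species —
four high-oil dicots (soybean as the focal species, cotton, castor
bean, Arabidopsis) and three low-oil grasses (sorghum, foxtail millet,
rice) — plus a soybean seed-development transcriptome (seven stages,
two biological replicates) and read counts for one high-oil and two
low-oil accessions at four stages (15/25/35/55 days after flowering).
All inputs can be supplied as files (OrthoMCL-style `groups.txt`,
expression/count TSVs with a sample-metadata sidecar, minimal OBO +
gene→GO TSV, promoter/alignment FASTA, newick) or generated by
`oleofinder.simulate` with planted truth.

## Markov clustering

`mcl(graph)` iterates: column-normalise → expand (matrix power,
default 2) → inflate (entrywise power, renormalise) → prune, until the
maximum entrywise change falls below `tol = 1e-6` or 200 iterations.
Details that matter:

* **Self-loops** are added per node with weight equal to the node's
  maximum incident weight, damping even/odd oscillations.
* **Pruning** zeroes entries below `1e-5` but never a column's maximum,
  so no column can empty out mid-iteration.
* **Cluster readout**: attractors are nodes with positive diagonal
  mass; attractor systems linked by flow form cluster cores; every
  other node joins the system of the lexicographically smallest
  attractor it flows to.  This makes the partition deterministic and
  invariant to node relabeling.
* **Isolated nodes** are reported as `unclustered`, never as
  singleton clusters.
* **Inflation** defaults to 2.0 at the graph level.  The
  expression-clustering wrapper passes 1.5 instead: correlation graphs
  built from 7-point profiles carry stray between-cluster edges
  (sampling noise pushes some pair correlations past the 0.7
  threshold), and at inflation 2.0 those bridges splinter the dense
  clusters they touch, while 1.5 absorbs them.  Both values are
  long-standing defaults of MCL-based tools; either can be overridden.

The implementation is sparse (scipy CSR); a dense naive implementation
lives in the test suite as an independent oracle and agrees exactly on
hundreds of random graphs.

## Lineage classification

Classification is a pure function of the species-presence set:
`dicot_specific` = all dicots present, no grass; `grass_specific`
symmetric; `shared` = both lineages present; `dicot_partial` /
`grass_partial` = one lineage only, at least two species but not all;
`other` = a single species.  The partial/other labels are an extension
so the map is total; outputs flag them as such.  The longest-isoform
rule keeps, per gene, the longest protein, breaking ties toward the
lexicographically smaller transcript id.

## Expression analysis

* **RPKM** = `1e9 * count / (length_bp * library_size)`.
* **Expressed filter**: abundance ≥ 1 RPKM in at least one stage, in
  both replicates of that stage (both thresholds configurable; the
  replicate requirement can be relaxed).
* **Profiles** are per-stage replicate means; clustering and
  correlation work on `log2(abundance + 1)` (configurable), which tames
  RPKM's dynamic range without discarding zeros.
* **Up-regulation**: a gene is up-regulated at fold `f` when its
  maximum over the stage window (stages 4–6 of 7: 5–6 mg through
  400–500 mg) is ≥ `f` times its mean over *all* seven stage means.
  `f = 1` is the "above average" rule, `f = 2` the "twice average"
  rule; the selected set shrinks monotonically in `f`.
* **Correlation graph**: edge iff `|r| > 0.7` (strict), weight `|r|`;
  constant profiles are skipped with a warning.
* **Sample clustering**: average linkage on `1 − r` between
  `log2(x+1)` sample vectors, serialised as newick with merge-height
  increments as branch lengths.

## Co-expression significance and PLC

For profiles of `n` stage means, `p = 2·P(T_{n−2} > |r|·sqrt((n−2)/(1−r²)))`.
For `n = 8` this has the closed form
`1 − (15/8)|r| + (5/4)|r|³ − (3/8)|r|⁵`, which the test suite re-derives
by numerical integration of the t density and uses to pin the
implementation to 1e-10.  PLC flags a query gene when ≥ 2 pathway
partners (inclusive, configurable) reach `p < 1e-4`; partners of either
sign count.  The TF screens reuse the machinery with presets
(1e-4, ≥2) and (0.05, ≥11).  No multiple-testing correction is applied
to PLC p-values; the stringent threshold *is* the screen, and the audit
edge list is emitted so any correction can be applied post hoc.

## Differential expression

Per stage, a gene's counts in two accessions are tested with Fisher's
exact test on `[[c_a, N_a − c_a], [c_b, N_b − c_b]]`; the two-sided p
sums hypergeometric point probabilities ≤ that of the observed table
(relative tie slack 1 + 1e-7).  The implementation enumerates the
hypergeometric support directly and batches genes sharing table margins,
which makes genome-scale scans fast; it is checked against exact
integer-arithmetic enumeration and against `scipy.stats.fisher_exact`.
A gene is a DEG when `p < 0.01` in at least one stage (an "all stages"
rule is available); replicates within an accession are pooled by
summation.  Fisher is conservative under the Poisson null — measured
type-I error at 0.01 is well below nominal.

## GO enrichment

Classic (unconditional) hypergeometric upper tail computed on the
annotation closure (every gene counts toward all is_a ancestors).  The
universe defaults to all genes with ≥ 1 annotation.  Raw p-values are
reported at `P < 0.01`.  GO-slim summarisation maps each term to its
*minimal* slim ancestors (slim hits with no other slim hit below them);
terms with no slim ancestor bucket under their namespace root.

## Motif scanning

The AW-box consensus `CNTNG(N)7CG` has five fixed positions, so uniform
background sequence matches at `4⁻⁵ ≈ 9.77e-4` per position per strand.
Scanning reports all, possibly overlapping, matches with 0-based
offsets; `N` in a sequence satisfies only degenerate pattern positions.
The default policy scans the forward strand only (the element is
orientation-specific in the WRI1 literature); both-strand mode is
available, as is any IUPAC consensus override.

## Phylogenetics

Protein distances use pairwise gap deletion and either the raw
p-distance or the Poisson correction `−ln(1−p)` (default).  Neighbor
joining follows Saitou–Nei with ties on the Q criterion broken toward
the lexicographically smallest taxon pair; negative branch lengths are
kept so additivity checks remain exact (clamping is display-side
only).  On additive inputs the reconstruction is exact to 1e-9.
Bootstrap resamples alignment columns; support is the percentage of
replicate trees containing each bipartition.  For event labeling the
tree is rooted (midpoint by default; on a given split when the true or
outgroup split is known) and an internal node is a *duplication* iff
its children's species sets intersect.  Species tags are parsed from
leaf names (prefix before the first `_` or `|`, configurable).  The
species-overlap rule is stated, not claimed identical to
reconciliation-based labeling.

## Synthetic data: what it emulates, and what it does not

* **OG tables**: per-OG composition class drawn from configurable
  probabilities (default: 55% shared, 5% dicot-specific, 5%
  grass-specific, 12% dicot-partial, 8% grass-partial, 15%
  single-species); 1 + Geometric members per present species.
* **Expression**: eight cluster archetypes over seven stages in log2
  space — three monotone declines (steps after stages 1, 3, 5), an
  early peak, single-stage peaks at stages 4, 5, 6 and at dry seed.
  These are qualitative reconstructions of canonical seed-development
  shapes, chosen with pairwise `|r| < 0.7` so the planted clusters are
  identifiable at the clustering threshold; they are illustrative, not
  calibrated to any measured dataset.  Gene log2 abundance =
  archetype + N(0, 0.5²) gene offset + N(0, 0.2²) per stage, and each
  replicate adds N(0, 0.1²).
* **Counts**: Poisson with log-normal gene proportions shared across
  accessions; planted DE genes (default 100 of 2,000) have their
  expected count multiplied by 4 in the high-oil accession.  Recorded
  library sizes are the *nominal* depth (default 2e5, mean count 100):
  a spike-in-like convention under which non-planted genes are exact
  Fisher nulls, while realised totals exceed nominal depth in the
  high-oil accession by the planted mass (~5–20%).  Without this
  convention the planted mass induces composition bias and null genes
  appear down-regulated — a real RNA-seq phenomenon, but one that
  would confound planted-truth evaluation.  Counts are Poisson, the
  sampling model under which Fisher's test is exact; overdispersed
  real data will show more false positives than these simulations.
* **Promoters**: uniform ACGT with AW-boxes planted at recorded
  positions spaced ≥ 27 bp; chance forward-strand background matches
  are scrubbed by mutating a fixed-position base outside planted
  sites, so forward scans recover planted counts exactly.  The spacing
  guarantees a stray match can overlap at most one planted site and is
  always scrubbable.
* **Families**: gene families evolve along a fixed bifurcating species
  tree (dicot clade vs grass clade); duplications are a Poisson
  process on branch length (default 0.5/unit), lineage loss
  probability `1 − exp(−0.2·branch)`; leaf distances are exact path
  lengths (additive) unless noise is requested; alignments evolve by
  per-branch Poisson substitution over 20 amino acids.
* Everything is a deterministic function of the seed, via independent
  named substreams, so regenerating one input never perturbs another.

Passing tests on these simulations demonstrates correctness of the
algorithms and recoverability of planted structure under the stated
noise model.  They do not demonstrate robustness to overdispersion,
batch effects, isoform ambiguity, annotation bias, or alignment error
in real data.

## Pipeline and problem sizes

The default end-to-end run uses 5,000 OGs, 3,000 expression genes,
2,000 count genes (100 planted DEGs), 200 promoters and 20 families;
it completes in well under five minutes on one CPU and is byte-identical
across reruns with the same seed.  The acceptance script scales the
Fisher null check to 5e4 genes and the motif background to 5e5
positions, sizes at which the Monte-Carlo error bars are far tighter
than the margins being checked.

## Known limitations

* The PLC p-value model assumes independent bivariate-normal samples
  per stage; stage means of two replicates are neither independent
  across stages nor normal, so printed p-values are approximate for
  real data (as in the tools this mirrors).
* `n` for the correlation test defaults to the number of stage means
  and is configurable; published analyses of this design differ in the
  `n` they used, and reported p-values elsewhere may not match any
  standard t-test exactly.
* Classification of OGs ignores gene counts (presence only), so a
  single stray cross-lineage member removes specificity — intended,
  but sensitive to contamination in real orthology tables.
* MCL here is dense-ish sparse linear algebra: fine to ~10⁴ nodes,
  not engineered for the 2.5e5-gene proteome-scale graphs that
  dedicated implementations handle out-of-core.
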