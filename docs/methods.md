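# Methods

## Problem setting

Comparative functional metagenomics summarizes a microbiome sample as a
vector of gene-family (KO) abundances and then as pathway abundances.  Three
routine processing steps can *mask* genuine between-sample variation:

1. **Relative normalization.** Dividing each gene's count by the sample total
   makes values depth-independent but couples every gene to the community's
   average genome size: `rel(g, s) = copy(g, s) / size(s)`, where
   `copy(g, s)` is the average per-genome copy number of `g` in sample `s`
   and `size(s)` the average annotated genome size.  Variation in `size(s)`
   both fabricates variation for genes that are constant (e.g. universal
   single-copy genes) and suppresses variation for genes whose abundance
   co-varies with community gene content.
2. **Inclusion of genome-prevalent genes.** Families carried at near-constant
   copy number by essentially every genome contribute a large, flat baseline
   to every pathway sum, diluting the informative signal.
3. **Uniform mapping and pathway-level pooling.** A shared gene family
   (annotated to several pathways) is conventionally split uniformly
   (fractional) or duplicated (complete) across its pathways, and pathway
   pooling itself can average away anti-correlated member genes
   (alternative strategies used by different communities).

The package implements the counter-measures and the statistics to quantify
their effect, plus a simulator that generates all inputs with known ground
truth.

## Single-copy marker normalization

Universal single-copy marker families occur exactly once per genome, so
their abundance measures "sequencing signal per genome".  Dividing every
gene by the per-sample **median** of marker abundances rescales values to
average copies per genome.  The median (rather than the robust mean used by
the original marker-based tool) is outlier-resistant and parameter-free; a
trimmed-mean option exists (`center="trimmed_mean"`).  We do not claim
numerical identity with the released MUSiCC tool, whose learned intra-sample
correction (a lasso over marker variability) is out of scope here.  Markers
absent from a profile are treated as annotation gaps and excluded from the
median — counting them as zeros would bias the yardstick downward.  On
noise-free simulated communities the normalized values equal the
taxa-weighted community copy numbers to machine precision (the acceptance
suite asserts 1e-9).

## Prevalence filtering

A gene's copy-number CoV (sd/mean, n−1 denominator by default, `ddof`
switchable) is computed across a genome set **with zeros included**: a low
CoV then implies the gene is both widespread and copy-stable.  Genes with
CoV < 1.5 (default) are flagged prevalent; applying the same operation to a
gut-dwelling genome subset gives the gut-prevalent list.  A zero mean yields
a +inf sentinel (never prevalent).  The statistics module uses a NaN
sentinel for zero-mean CoV instead, because there "undefined" (not
"maximal") is the right reading; the difference is intentional.

## Co-occurrence aggregation

Presence/absence profiles of genes across genomes are compared by Jaccard
distance, `1 − |G_a ∩ G_b| / |G_a ∪ G_b|` over carrier-genome sets.  (The
underlying similarity fraction is sometimes described as a distance in the
literature; complete-linkage clustering requires the distance form, so that
is what we compute.)  Complete linkage is cut with `cut_tree` into exactly
`n` clusters — by default the number of distinct pathways in the annotation,
making the two aggregation bases comparable.  Gene IDs are sorted
lexicographically before clustering so merge-tie resolution is deterministic
across platforms.  Profiles are summed over aggregates; on a partition this
conserves total abundance.

## Evidence-based (support-weighted) pathway mapping

For each sample, a pathway's **support** is the mean abundance of its
non-shared genes present in the profile — unambiguous evidence for the
pathway's presence.  Each shared gene's abundance is then partitioned across
its pathways proportionally to their support in that sample; non-shared
genes contribute in full.  Only *eligible* pathways are scored: at least 10
non-shared families in the annotation (a database property, counted from the
map) and mean fractional-mapped relative abundance above 0.05% of the raw
profile.  Two deliberate choices where the procedure is under-specified:

* Eligibility is applied **before** mapping and shared-gene degrees count
  only eligible pathways, so abundance mass is conserved over the eligible
  set (a testable invariant).  `keep_ineligible_in_degree=True` restores
  full-annotation degrees.
* A shared gene whose eligible pathways all have zero support in a sample
  falls back to a uniform fractional split for that gene/sample; discarding
  the abundance would break conservation.

Limit behaviors: equal supports reduce the scheme to uniform fractional;
complete ≥ fractional elementwise with equality at degree 1.

## Statistics

* **CoV** (n−1 sd / mean) measures per-feature variation across samples;
  scheme comparisons report per-feature CoV ratios with a paired t test
  (or a rank-sum variant).
* **Bray–Curtis** distances (`1 − 2Σmin/(Σ+Σ)`) quantify between-sample
  functional dissimilarity.
* **Mantel test**: one-sided permutation test of the Pearson correlation
  between upper triangles, p = (1 + #{r* ≥ r}) / (1 + n_perm) — the +1
  correction keeps p > 0 and makes the test exact under exchangeability.
* **Negative-pair screening** counts same-pathway gene pairs with Pearson
  r < −0.3; zero-variance genes are excluded rather than scored r = 0.
* **Association**: per-pathway two-sided Wilcoxon rank-sum with
  Benjamini–Hochberg FDR.  The "disease-association score" is defined as the
  signed tie-corrected standardized rank-sum z (positive = enriched in
  cases); p-values use the exact null distribution when both groups have
  ≤ 12 untied samples, the normal approximation otherwise.

## Fingerprinting

An individual's code is the k = 20 genes for which they hold the strict
community-wide maximum relative abundance at visit 1, ranked by the ratio to
the runner-up (a zero runner-up ranks as an infinite ratio, above all finite
ones, ordered by own abundance then gene ID).  Ties for a maximum disqualify
the gene; codes are therefore disjoint across individuals.  Visit-2 samples
earn one agreement point per code gene for which they hold the strict
maximum; assignment is by strict best score (ties → unassigned, counted
incorrect — a conservative accuracy).  Profiles are relative-normalized
inside the fingerprint operations; a single-copy mode applies marker
normalization first.

## The simulator and what it does (not) emulate

`simulate_world` builds a genome × gene copy matrix with: markers (copy 1
everywhere), a shared core (copy 1 everywhere, hence prevalent with CoV 0),
and accessory genes organized in equally sized blocks, each genome carrying
a fixed number of blocks.  Equal genome sizes by construction give a clean
no-confound baseline.  Default world: 40 genomes, 570 genes (10 markers,
200 core, 8 blocks × 45 accessory genes, 2 blocks per genome), 8 pathways.
The marker share of genome content (~3%) is chosen to match the realistic
order of magnitude of universal single-copy genes in bacterial genomes.
Pathway annotation is partially aligned with blocks (`pathway_fidelity`
0.7): each block has a home pathway receiving 70% of its genes — real
annotations correlate with genome content, and without this alignment
pathway sums would be artificially constant across communities.  30% of
mapped genes receive a second pathway (shared genes).

`simulate_profiles` draws Dirichlet(0.5) taxa weights per sample and sets
abundance = depth · copy(g, s) / size(s), with multiplicative lognormal
noise of a given CV (default 0.1).  `genome_size_spread` (default 0.5,
log-sd) scales each genome's accessory content, creating between-sample
variation in average genome size — the confound relative normalization
cannot remove; the scaled content matrix is the ground truth shipped in the
sidecar.  Two-visit cohorts regenerate the background community each visit
and persist only the planted per-individual signature genes (25 disjoint
accessory genes boosted by 10× the individual's mean gene abundance), so
zero signature strength is an exact identification null.  Case/control
cohorts multiply the affected pathway's genes by the effect (default 2) in
cases; the optional genome-size confound multiplies the cases' remaining
non-marker content by the same factor, so totals scale together and relative
normalization cancels the planted shift while the unscaled markers preserve
it — the construction behind the hidden-association analysis.

Not emulated: read-level sequencing error, phylogenetic structure among
genomes, compositional count noise (a lognormal abundance model is used
rather than Poisson counts), annotation errors, and strain-level variation.
Passing tests therefore demonstrate correctness of the processing machinery
and the qualitative masking/unmasking phenomena, not performance on real
cohorts.

## Numerical and testing choices

Problem sizes in the test and acceptance runs are deliberately modest
(worlds of 40 genomes × 570 genes, 30–50 samples, 50–100 seeds per
property, 500 replicates for calibration checks); all planted-truth
recoveries are exact to 1e-9 or better at these sizes.  Oracles are naive
per-element loops written independently of the vectorized implementations.
Text round-trips write full float precision (`repr`) and are asserted to
1e-12 relative.  All generators and permutation tests are driven by
explicit seeds; reruns are bit-identical.

## Known limitations

* The marker normalization implements only the yardstick rescaling, not the
  learned intra-sample correction of the original tool.
* Eligibility's "mean relative abundance" is computed on the raw profile;
  whether the original procedure computed it before or after marker
  normalization is unspecified, so the simpler reading was chosen.
* The Jaccard/complete-linkage aggregate count is a free parameter
  ("similar to the number of pathways"); the auto default equates it to the
  pathway count.
* Headline figures from real cohort studies depend on database snapshots and
  cohorts that are not inputs here; the package reproduces the phenomena on
  synthetic planted-truth data only.
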