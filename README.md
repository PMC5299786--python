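# funcvar

Uncovering masked functional variation in metagenomic profiles.

Comparative studies of the human gut microbiome famously report striking
*taxonomic* variation between people alongside puzzling *functional*
uniformity — pathway abundance profiles that look almost identical across
individuals.  Part of that uniformity is an artifact of routine
computational processing: relative normalization couples every gene family
to the community's average genome size, genome-prevalent gene families add
a flat baseline to every pathway, and uniform splitting of multi-pathway
("shared") gene families plus pathway-level pooling average real signal
away.  `funcvar` is a library + CLI for processing sample × gene-family
(KO) abundance tables with the revised procedures that expose this hidden
variation, and for quantifying the difference.

It is aimed at microbiome researchers working downstream of functional
annotation: the pipeline starts from a KO abundance table, a gene→pathway
association map, a genome × gene copy-number matrix and a universal
single-copy marker gene list (all plain delimited text).

## What it computes

* **Single-copy marker normalization** — rescale each sample by the median
  abundance of universal single-copy marker families, so values read as
  average copy number per genome: `a(g,s) ∝ depth·copy(g,s)/size(s)` becomes
  `copy(g,s)` exactly, removing the genome-size confound that relative
  normalization (`copy(g,s)/size(s)`) retains.
* **Prevalence filtering** — flag gene families whose copy-number CoV
  (sd/mean, zeros included) across a reference genome set is < 1.5 and
  remove them before computing pathway profiles or distances.
* **Genome co-occurrence aggregation** — Jaccard distance between gene
  presence/absence patterns across genomes, complete-linkage clustering, cut
  to a chosen number of aggregates (default: the number of pathways).
* **Evidence-based pathway mapping** — per sample, each pathway's *support*
  is the mean abundance of its non-shared gene families; shared families are
  partitioned across their pathways in proportion to support (uniform
  fractional and complete mapping are available as baselines).
* **Variation & association statistics** — CoV reports and scheme
  comparisons, Bray–Curtis distance matrices, one-sided Mantel permutation
  tests, negative-correlation screening of same-pathway gene pairs, and
  per-pathway case/control Wilcoxon rank-sum scores with BH FDR, including
  the standard-vs-revised pipeline comparison.
* **Functional fingerprinting** — per-individual metagenomic codes (the
  k = 20 gene families most specific to an individual at a baseline visit)
  and agreement-score identification of the same individuals at a later
  visit.
* **Synthetic data** — a seed-deterministic simulator of genomes, pathway
  annotations, communities, two-visit cohorts and case/control cohorts with
  full ground truth, so every stage is testable offline.

## Worked example

Simulate a community with a genome-size confound, then process it with the
*standard* preset (relative normalization, all genes, uniform fractional
mapping) and the *revised* preset (single-copy normalization, prevalence
filtering, evidence-based mapping):

```python
import funcvar as fv

world = fv.simulate_world(seed=0)
profile, truth = fv.simulate_profiles(world, n_samples=50, seed=0)

std = fv.run_pipeline(fv.PipelineConfig.standard(), profile, world.pathway_map)
rev = fv.run_pipeline(fv.PipelineConfig.revised(), profile, world.pathway_map,
                      world.markers, world.content)

report = fv.compare_scheme_variation(std.pathway_profile, rev.pathway_profile)
print(report.table[["cov_a", "cov_b", "cov_ratio"]].round(3))
print(f"median CoV ratio (revised / standard): "
      f"{report.table['cov_ratio'].median():.2f}")
print(f"paired t = {report.statistic:.2f}, p = {report.pvalue:.2e}")
```

```
     cov_a  cov_b  cov_ratio
P01  0.053  0.289      5.506
P02  0.056  0.323      5.750
P03  0.066  0.129      1.961
P04  0.049  0.277      5.618
P05  0.047  0.261      5.521
P06  0.072  0.287      3.957
P07  0.061  0.300      4.885
P08  0.069  0.148      2.156
median CoV ratio (revised / standard): 5.20
paired t = 7.10, p = 1.94e-04
```

`cov_a`/`cov_b` are each pathway's coefficient of variation across the 50
samples under the standard and revised pipelines.  The planted community
variation is real (the simulator's ground truth varies), yet the standard
pipeline sees CoVs of only 0.05–0.07; the revised pipeline recovers 2–6×
more variation per pathway — the masking effect, reproduced end to end.

The same stages are available from the shell:

```bash
funcvar simulate profiles --n-samples 50 --seed 0 -o demo/
funcvar pipeline --preset revised -i demo/profile.tsv -m demo/pathway_map.tsv \
    --markers demo/markers.txt -g demo/genomes.tsv -o demo/pathways.tsv
funcvar stats cov -i demo/pathways.tsv -o demo/cov.tsv
```

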