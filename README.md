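# haploclust

Cluster-based genome-wide association testing: group genotyped variants into
mosaic linkage-disequilibrium (LD) clusters with density-based clustering,
infer haplotypes within each cluster, and test haplotype frequency
distributions between cases and controls.

## Who this is for

Statistical geneticists analyzing unphased case-control genotype data
(PLINK bed/bim/fam or VCF) who want a multi-locus alternative to
single-variant GWAS.  Single-variant tests ignore LD between markers;
haplotype tests over *contiguous* blocks miss long-range correlation.  This
package partitions the genome into clusters of mutually correlated variants
that need not be adjacent — "mosaic" LD-blocks — and tests them jointly.

## The method

1. **LD clustering.** For each chromosome (arm), compute the pairwise r²
   matrix (two-locus EM haplotype-frequency estimate by default, the same
   quantity `plink --r2 square` reports) and transform it to distances
   d = 1 − r².  Cluster with DBSCAN or HDBSCAN on the precomputed distances;
   variants not assigned to any cluster are noise.  A clustering radius
   eps = 0.41 admits pairs with r² ≥ 0.59.  Parameters are tuned per
   partition by a two-stage grid search maximizing the silhouette
   coefficient (Calinski–Harabasz as tie-break).

2. **Haplotype association.** Within a cluster of n variants (coordinate
   sorted), the prefix LD-blocks of sizes 2..n are enumerated.  For each
   block, haplotype frequencies f_h are estimated by EM over the haplotype
   pairs (h, k) compatible with each unphased genotype, weighting pairs by
   f_h·f_k·(2 − [h = k]).  Case and control haplotype counts are fractional,
   posterior-weighted under the jointly estimated frequencies.  Haplotypes
   below frequency 0.01 are dropped; the remaining H×2 count table is tested
   with the Pearson chi-square omnibus test, df = H − 1.  One block per
   cluster is selected (minimal p; ties to the largest block) and the
   selected p-values are Bonferroni-adjusted with m = number of clusters.

3. **Classic GWAS battery.** Allelic, genotypic (df 2), dominant, recessive
   and Cochran–Armitage trend tests plus additive logistic regression, with
   Bonferroni adjustment (or a fixed 5×10⁻⁸ threshold for simulations).

4. **Simulation.** A self-contained Hapgen-style generator: a synthetic
   phased reference panel with block LD, Li–Stephens mosaic resampling with
   template switches at recombination intervals, and a multiplicative
   disease model (heterozygote OR 1.5, homozygote OR 2.25 by default) with
   the intercept solved for a target prevalence.

## Worked example

```python
from haploclust import (DiseaseModel, HaplotypeClusterGWAS,
                        generate_reference_panel, sample_case_control,
                        select_disease_variants)
from haploclust.validation import risk_allele_odds_ratios

panel = generate_reference_panel(n_variants=600, seed=3)
disease = select_disease_variants(panel, k=3, min_separation=50_000, seed=3)
study = sample_case_control(panel, DiseaseModel(disease),
                            n_cases=4000, n_controls=650, seed=3)

model = HaplotypeClusterGWAS(algorithm="dbscan", eps=0.35, min_samples=2,
                             mode="fixed").fit(study.dataset)
print(model.summary_["n_clusters"], "clusters,",
      model.summary_["n_significant"], "significant")
print(model.results_[model.results_["significant"]]
      [["cluster_id", "block_size", "chi2", "df", "p_unadjusted"]])
print("risk-allele ORs:", risk_allele_odds_ratios(study).round(3))
```

Output from this exact run:

```
72 clusters, 2 significant
    cluster_id  block_size       chi2  df  p_unadjusted
25          25           3  35.739433   1  2.255521e-09
36          36           2  55.112399   1  1.138306e-13
risk-allele ORs: [1.479 1.467 1.662]
```

Two clusters pass the genome-wide 5×10⁻⁸ threshold, each containing one of
the three implanted disease variants; the omnibus chi-square (df =
haplotypes − 1) concentrates the case/control frequency shift carried by
the risk haplotype.  The third variant illustrates the power margin at this
threshold: its single-variant allelic p is 1.5×10⁻⁸ but its cluster's best
block falls just short.  The estimated risk-allele odds ratios recover the
simulated per-allele OR of 1.5.

A command-line interface drives the same stages on files:

```bash
haploclust simulate --out run/ --seed 1
haploclust qc --workdir run/
haploclust ld --workdir run/
haploclust cluster --workdir run/ --eps 0.35 --min-samples 2
haploclust hap-assoc --workdir run/
haploclust report --workdir run/
```

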