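# metaphylo

Metaphylogeography from COI metabarcoding data: simultaneous analysis of
community β-diversity and intraspecific genetic variation across geographic
region groups, starting from a denoised exact-sequence-variant (ESV) table.

## Who this is for

Metabarcoding of bulk benthic samples yields thousands of denoised amplicon
sequences (ESVs) with read counts per sample and field replicate. Treating
ESVs as haplotype proxies and clusters of ESVs as species proxies lets a
single survey answer two questions at once: do *communities* differ between
geographic regions (classic β-diversity), and do *populations within
species* differ between regions (phylogeographic structure, e.g. across
mountain ranges that act as dispersal barriers)? This package implements
that analysis as a tested, reusable pipeline, together with a synthetic-data
generator that plants known species/haplotype/region structure so every
stage can be validated without any sequencing data.

## What it computes

Given an ESV table (counts per sample × replicate), per-ESV taxonomy with
species-level bootstrap proportions (sBP), and sample coordinates:

1. **Quality filters** — end-gap-only alignment filtering removes putative
   frameshifted sequences (COI is protein coding, so genuine amplicons of
   one primer set share one length); ESVs with < 100 total reads are
   dropped; sample-replicate cells with < 5 reads are zeroed; replicates are
   pooled to presence/absence.
2. **Clustering** — single-linkage "no breaking" clustering joins ESVs
   within *d* differences (Levenshtein). OTUs use the *d* closest to 3 % of
   the amplicon length (*d* = 7 for 229 nt, *d* = 9 for 313 nt). Raising
   *d* from 0 until one cluster remains yields a nested hierarchy, in which
   **species-bound clusters (SBCs)** are found: for each species (ESVs with
   sBP ≥ 0.8), a cluster containing *all* of its assigned ESVs and *none*
   assigned to any other species (unassigned ESVs may ride along).
3. **Dissimilarity** — Sørensen dissimilarity
   β<sub>sor</sub> = (b + c) / (2a + b + c)
   on presence/absence, at community level (ESV / OTU / SBC columns) and at
   intraspecific level: one matrix per qualifying cluster (≥ 2 haplotypes,
   present in ≥ 3 samples in each of ≥ 2 region groups), averaged pairwise
   into a mean matrix, then greedily completed by removing the sample with
   the most missing pairs.
4. **Null model** — ESVs are shuffled among clusters, preserving the number
   and sizes of clusters ("scrambled clusters"), and the mean-matrix
   construction is repeated to obtain a null distribution of any statistic.
5. **Statistics** — PERMANOVA (pseudo-F = among-group over within-group
   mean squared dissimilarity; permutation p with the add-one rule, exact
   enumeration when feasible), pairwise PERMANOVA with Benjamini–Hochberg
   FDR, a betadisper-style dispersion homogeneity test, the Mantel test
   with Spearman rank correlation against WGS84 geodesic distances, and
   k-means region grouping on coordinates with an adjusted-Rand stability
   scan.

## Worked example

Run the bundled synthetic demo — 2 regions × 8 samples, 10 species with
region-private haplotypes:

```yaml
# demo.yaml
seed: 11
synthdata:
  n_regions: 2
  samples_per_region: 8
  n_species: 10
  structure_strength: 1.0
  detection_prob: 0.9
regions: {k: 2}
stats: {permutations: 999}
"null": {scrambles: 100}
```

```
metaphylo run --config demo.yaml --out demo_out/
```

From `demo_out/manifest.json`: 43 ESVs are loaded, 15 (all planted noise
variants) are removed by the filters, the 28 survivors cluster into 10 OTUs
at *d* = 7, and all 10 planted species are recovered as SBCs. Seven clusters
qualify for intraspecific analysis. `demo_out/stats.json` then reports:

```
community_esv        pseudo_F = 480.5   p = 0.001
intraspecific_otu    pseudo_F = 863.6   p = 0.001
null_otu             observed_pseudo_F = 863.6   percentile = 84.0
mantel_otu region_0  rho = 0.070   p = 0.361
```

Read: the two regions are strongly separated at both community and
intraspecific level (planted structure recovered; p is the permutation
floor at 999 permutations). The observed intraspecific pseudo-F sits at the
84th percentile of its 100-scramble null — inside the null, as expected
when region structure is carried by haplotype occupancy that scrambling
preserves in aggregate. Within-region Mantel correlations are near zero
because the generator plants no within-region spatial gradient.

Every stage is also exposed as a subcommand (`metaphylo simulate | filter |
cluster | sbc`) and as plain library functions (`metaphylo.workflows`).

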