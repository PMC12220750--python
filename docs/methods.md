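# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of the package. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Data model

The pipeline's input currency is the **ESV table**: denoised amplicon
sequences (exact sequence variants) with non-negative read counts per
sample × field replicate, an optional species assignment with a
species-level bootstrap proportion (sBP ∈ [0, 1]), and sample metadata with
WGS84 coordinates, collection year, and a wetland flag. Counts are stored
long-format (one TSV row per ESV × sample × replicate with reads > 0;
absent rows mean zero), sequences in FASTA, matrices as TSV with an
id header row/column and `NA` for missing pairs. Replicate ids are strings;
the default design is three field replicates per sample, but nothing
assumes exactly three.

Raw-read processing (merging, primer trimming, denoising, chimera removal,
taxonomic classification, pseudogene screening) is upstream and out of
scope; the package consumes its outputs.

## Quality filters

Applied in a fixed order; the chain is idempotent.

1. **Frameshift/length filter.** COI is protein coding, so genuine
   amplicons of one primer set should align end-to-end without internal
   gaps. With internal gaps forbidden (the effect of a prohibitively high
   gap-opening penalty), a multiple alignment of same-primer amplicons
   degenerates to block placement, and a sequence fits the block iff it has
   the modal length of the input. Sequences of any other length —
   putative indel artifacts or pseudogenes — are removed. The modal length
   is computed on the raw input (before removal); an exact tie between two
   lengths breaks toward the longer, on the view that degradation artifacts
   are more often truncated.
2. **Total-abundance filter.** ESVs with fewer than 100 reads summed over
   all sample × replicate cells are removed (strict `< 100`).
3. **Replicate filter.** Any sample-replicate cell with fewer than 5 reads
   is zeroed (guards against tag switching between samples).
4. **Pooling.** Replicates are pooled per sample; an ESV is present in a
   sample iff any replicate retains reads. Feature columns that are absent
   everywhere are dropped; empty *samples* are kept so the matrix stays
   aligned with metadata (their Sørensen pairs are undefined and handled as
   missing downstream).

## Clustering and species proxies

**Distance.** The number of differences between two ESVs is the Levenshtein
edit distance (substitutions and indels each cost 1), computed with edlib's
banded algorithm and early abandon above the working threshold. Within one
amplicon the length filter makes sequences equal length, where Levenshtein
and Hamming coincide; Levenshtein is used anyway for fidelity to
single-linkage "no breaking" clustering semantics of swarm-type tools.

**Clustering at d.** Clusters are the connected components of the graph
with an edge between ESVs at distance ≤ d (plain transitive closure; no
abundance-based breaking). Cluster ids are the lexicographically smallest
member ESV id — deterministic and stable across runs. Components are
verified against brute-force union-find in the tests. All-pairs computation
is O(n²), acceptable at desk scale (tens of thousands of ESVs per
amplicon).

**OTU threshold.** `select_otu_d` returns the integer d ≥ 1 whose ratio to
the amplicon length is closest to the 3 % species-proxy convention: d = 7
for 229 nt (3.06 %), d = 9 for 313 nt (2.88 %). Exact ties break toward
the smaller d (more conservative clustering).

**Hierarchy.** Partitions are built for every d from 0 upward until all
ESVs form one cluster, growing components incrementally so the nesting
invariant (each cluster at d is contained in one cluster at d + 1) holds by
construction and is validated on construction.

**Species-bound clusters.** ESVs are assigned to a species iff
sBP ≥ 0.8. For each species, every partition is scanned for the cluster
containing all of its assigned ESVs; the cluster qualifies when it contains
no ESV assigned to another species (unassigned ESVs allowed). Because
partitions are nested, qualifying member-sets for one species form
contiguous d-runs. When several distinct member-sets qualify (the cluster
absorbs more unassigned ESVs as d grows), the reported SBC is the set
persisting over the widest d range — the most stable choice — with ties
broken by larger membership, then smallest member id; a lowest-d selection
rule is available by option. A species with a single assigned ESV is always
an SBC (its d = 0 singleton qualifies). The search is verified against
exhaustive enumeration over all partitions in the tests.

## Dissimilarity construction

**Sørensen.** For samples i, j with a shared present features and b, c
unique to each: β_sor = (b + c)/(2a + b + c), computed by boolean matrix
products. A pair where both samples have zero present features is
undefined (missing). Only the incidence-based form is implemented; on
presence/absence data the abundance-capable variant reduces to it.

**Community matrices** use all feature columns of a representation
(ESVs, OTU-merged, or SBC-merged presence, merged by logical OR).

**Intraspecific matrices.** A cluster qualifies for intraspecific analysis
iff it has ≥ 2 member ESVs and is present in ≥ 3 samples in each of ≥ 2
region groups (hence ≥ 6 samples). Each qualifying cluster's Sørensen
matrix is computed, by default, only over samples containing ≥ 1 member
ESV: dissimilarity against a cluster-free sample would be identically 1 and
would conflate *occupancy* (a community signal) with *intraspecific*
variation. This restriction is exactly what creates missing sample pairs in
the mean matrix. The unrestricted variant (all samples, cluster-free ones
contributing occupancy signal) is available via
`per_cluster_matrices(..., restrict_to_occupied=False)`.

**Mean matrix and completion.** The intraspecific mean matrix averages each
sample pair over the cluster matrices in which the pair is defined; a pair
defined nowhere stays missing. Completion then repeatedly removes the
sample with the greatest number of missing pairs until none remain, with
ties broken toward the lexicographically smallest sample id (determinism;
the greedy rule never removes a sample that has no missing pairs).

## Scrambled-cluster null model

The intraspecific mean matrix averages many low-dimensional comparisons,
which changes its scale relative to the high-dimensional community matrix
(distance concentration). To ask whether an observed region separation
exceeds what this construction alone produces, ESVs belonging to the
selected clusters are shuffled uniformly among those clusters, preserving
the number of clusters and each cluster's size. The selection criterion is
*not* re-applied to scrambled clusters — re-filtering would change cluster
counts and sizes, defeating the size-preservation that defines the null.
Per scramble, the full mean-matrix construction is repeated (per-cluster
matrices → pairwise mean → completion → restriction to the observed
intraspecific sample set) and the statistic recorded: PERMANOVA pseudo-F
against region groups, or Spearman correlation with geodesic distance
within a region. Scrambles whose completed matrix no longer supports the
statistic are excluded and counted. A master seed spawns independent
per-rep substreams, so the distribution is reproducible and any single rep
can be replayed.

## Permutation statistics

**PERMANOVA.** With n samples and g groups,
SS_total = Σ_{i<j} d²_ij / n, SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g,
pseudo-F = (SS_among/(g−1)) / (SS_within/(n−g)) where
SS_among = SS_total − SS_within. Note SS_among is not sign-guaranteed for
semimetric dissimilarities such as Sørensen, so pseudo-F may be negative
under null groupings; no non-negativity is enforced. The permutation test
shuffles group labels; when the number of distinct label arrangements is no
larger than the requested permutation count, all arrangements are
enumerated and p is exact (it includes the identity, so p > 0). Otherwise
p = (1 + hits)/(1 + n_perm). Default 9999 permutations, α = 0.05. Pairwise
tests run per unordered group pair with Benjamini–Hochberg adjustment
across pairs; per-cluster tests complete each cluster matrix individually,
exclude clusters left without ≥ 2 groups of ≥ 2 samples (reported as
untestable, outside the FDR family), and adjust across clusters.

**Dispersion homogeneity.** The matrix is embedded by principal
coordinates (Gower double-centering of −d²/2); axes with negative
eigenvalues are kept as imaginary axes, so squared distances are the real
part minus the imaginary part, clipped at zero. Each sample's dispersion is
its distance to the group's spatial median (geometric/L1 median by
Weiszfeld iteration, computed separately in the real and imaginary
subspaces); the group-equality F statistic on those distances is tested by
permuting their group labels. The spatial median matches the common default
of the reference dispersion test; a centroid variant was considered and not
needed. Single-sample groups contribute a zero distance and are excluded
from the F test.

**Mantel–Spearman.** ρ is the Spearman rank correlation over the
n(n−1)/2 off-diagonal pairs; the null permutes rows and columns of one
matrix simultaneously. Exact enumeration engages when n! fits in the
permutation budget. The default alternative is one-sided (greater),
matching common Mantel usage; two-sided is available.

**Region groups.** k-means on raw (lat, lon) degrees — coordinates are
used directly, without projection, consistent with treating the region
grouping as a label-generating device rather than a metric analysis.
Wetland-flagged samples are excluded before clustering output is used.
Stability per k is the adjusted Rand index (Hubert–Arabie; label-invariant,
chance-corrected) between pairs of independently initialized single-start
runs — initialization variance is the signal, so `n_init = 1` inside the
stability scan — plus the total within-cluster sum of squares per k.
k-means and the adjusted Rand index are delegated to scikit-learn.

**Geodesic distances** are computed on the WGS84 ellipsoid with Vincenty's
inverse algorithm (iterative; raises rather than degrade on
near-antipodal pairs, which cannot occur in a regional design). A spherical
(haversine) approximation is deliberately not used. Agreement with an
independent ellipsoidal implementation is pinned to < 1 mm in the tests.

## Synthetic data generator

The generator emulates the statistical shape of a regional COI survey:

- **Species**: `n_species` base sequences, pairwise ≥ `interspecies_min_subs`
  apart (default 14 = 2 × the d = 7 OTU threshold, so species proxies are
  unambiguous), each with 1–5 haplotypes at 1–3 substitutions from the base.
- **Geography**: `n_regions` centroids spaced along a line through a
  Rocky-Mountain-like bounding box (lon −118…−113, lat 49…52), samples
  Gaussian-scattered (σ = 0.08°) around them — spacing ≫ σ makes region
  recovery by k-means testable.
- **Occupancy**: with probability `community_structure` a species is
  restricted to a contiguous block of ≥ 2 regions. Within the species'
  region set, each haplotype is region-private with probability
  `structure_strength`; private homes are assigned round-robin within the
  species (`haplotype_home="spread"`, species-coherent intraspecific
  structure) or independently of species membership (`"iid"`,
  community-level structure with no species-attributable component — under
  this mode cluster scrambling is a symmetry of the generative model).
  Detection per occupied sample is Bernoulli(`detection_prob`).
- **Depths**: negative binomial per sample × replicate with mean
  `mean_depth` (default 300) and dispersion 5 — overdispersed counts
  typical of amplicon data.
- **Noise**: spurious single-substitution shadows of true haplotypes with
  1 + Poisson(5) reads in one random sample replicate (capped below 100),
  exercising both abundance filters.
- **Determinism**: the seed feeds two separate streams (structure vs
  nucleotide draws), so two configs differing only in amplicon name/length
  share identical planted occupancy — the device used for cross-amplicon
  consistency experiments.

What the generator does **not** emulate: PCR/sequencing error processes,
chimeras, phylogenetically realistic sequence evolution, abundance
correlations between species, spatial gradients *within* regions, or
taxonomic misassignment. Passing tests therefore demonstrate correctness of
the analysis machinery on data with the assumed structure, not robustness
to upstream artifacts beyond the planted noise model.

## Problem sizes used in the checks

The simulation-based checks run at deliberately modest sizes chosen to
exercise the full pipeline: parameter recovery uses 2 regions × 10 samples
and 15 species over 100 datasets (and 200 datasets for the type-I rate) at
999 permutations; null-model coverage uses 4 regions × 8 samples over 20
datasets at 200 scrambles; the stability scan uses 200 run pairs per k.
Dataset seeds are consecutive integers fixed in advance.

## Known limitations

- The SBC definition leaves "the" member-set ambiguous when composition
  changes with d; the widest-persistence rule is a documented choice, not
  the only defensible one.
- Greedy completion minimizes removals only heuristically; an optimal
  minimum vertex cover of the missing-pair graph is NP-hard in general.
- PERMANOVA here is one-way only; no multi-factor designs, strata, or
  distance-based RDA.
- k-means on raw degrees treats 1° latitude and longitude as equal, which
  is adequate for compact mid-latitude designs but distorts at scale.
- The Monte-Carlo permutation p-values have resolution 1/(n_perm + 1);
  exact mode engages only for small groups.
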