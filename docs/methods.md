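# Methods

This note documents the models, algorithms and defaults behind `cytofuse`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Intensity transform

All analysis operates on arcsinh-transformed intensities, `y = asinh(x / c)`
with cofactor `c = 5` (the CyTOF convention; `c` is configurable and must be
positive). The transform is applied once — profiles carry an explicit
`transformed` flag and a second application is an error — and it precedes
everything downstream, including the merge distances. Whether merging should
run on transformed or raw intensities is not uniquely determined by the
multi-tube literature; `cytofuse` declares transformed-space matching, since
raw ion counts span several decades and would let bright markers dominate the
Euclidean backbone distance.

## Backbone merging

Panels are merged pairwise. For profiles A and B sharing backbone markers
`B`, matching repeats rounds of the *acceptable, non-ambiguous nearest
neighbour* rule until stable: among unmatched cells, `(a, b)` is paired when
each is the other's nearest unmatched neighbour (Euclidean distance over `B`)
and their distance is at most the threshold (default 3, in arcsinh units).
Matched cells leave the pool; iterating on the residue strictly increases
yield while keeping the mutual-NN stringency. Nearest neighbours are exact:
a dense distance matrix is used below ~2·10⁶ candidate pairs (where exact
ties deterministically break toward the lowest row index) and a k-d tree
above it. For continuous cytometry intensities exact ties have measure zero,
so the two paths agree in practice; the brute-force oracle tests cover the
dense path exhaustively.

A merged cell averages the backbone values of its two contributors and copies
each panel-specific marker from the panel that measured it. Three or more
panels are merged sequentially in the given order (default #A, #B, #C); the
intermediate profile's backbone is already the average of its contributors
and enters the next round as-is. Whether the original multi-tube algorithm
averages the intermediate backbone or keeps both copies is not restated in
the sources available to us; averaging is the only representation consistent
with the two-profile merge contract, and is the declared choice.

Accounting counts *original input cells* absent from the final profile:
`excluded = Σ n_input − k · n_merged` for a k-panel merge. A cell pair merged
in round one but unmatched in round two therefore contributes two excluded
cells. The bundled six-donor reference count table reproduces this identity
exactly for every donor.

## Density-dependent downsampling and clustering

The clustering stage is a parameter-matched stand-in for the density-
normalised clustering tools conventional in cytometry, not a bit-level
reproduction of any of them; its claims are at the level of its user-facing
parameters. Defaults: random pre-downsampling to 67,000 events per sample
(the conventional "size of the smallest sample" cap), 5% density-dependent
downsampling, `k = 500` clusters for a full-scale 72-marker run (`k = 100`
is typical for smaller validation panels), full upsampling.

Internals, all config-exposed: local density of a cell is the number of
events within radius `r`, where `r` is 5× the median nearest-neighbour
distance of a seeded 2,000-event subsample. Cells below the 1st density
percentile are discarded as outliers; cells below the target density TD (the
5th percentile of the remaining densities) are kept outright; denser cells
are kept with probability `TD/density`; a final uniform thinning enforces the
5% expected budget. This equalises the kept density landscape, which is what
protects rare populations — the property tests verify that a 1%-abundance
population survives at well above its input share.

Clustering is Ward agglomeration (Euclidean) on the pooled downsampled cells
of all individuals, cut at `k`; pooling (rather than per-sample clustering
plus meta-clustering) is the declared choice, since it makes cluster ids
directly comparable across individuals. Centroids are per-cluster medians;
upsampling assigns every original cell to the nearest centroid, ties to the
lowest cluster id. Cluster expression summaries use the unweighted mean of
per-individual medians so that a large sample cannot dominate a cluster's
phenotype.

## Categorical phenotyping

Per marker, the 5th–95th percentile range over the pooled cells of all
individuals (pooled rather than per-individual, so categories are comparable
across clusters) is divided into five uniform bins labelled negative, low,
medium, high, bright. Values clamp at the range ends; interior bin edges
belong to the upper bin. Clusters with fewer than 50 cells in the whole
dataset are unassigned — too few cells to define a stable median. Row and
column dendrograms (complete linkage, Euclidean) are computed on the
categorical values — not the raw mean-of-medians, a deliberate choice since
the figure being emulated displays categories — with backbone and
panel-specific marker blocks ordered separately and unassigned rows appended
last. Population labels come from an editable rule table over categories of
lineage markers (e.g. CD66 ≥ high → PMN; CD14 and HLADR ≥ high → monocyte;
CD123 and HLADR ≥ high with CD11c low → pDC); the defaults are declared
heuristics standing in for manual annotation, evaluated in priority order.

## Differential statistics

A cluster's normalised abundance in a condition is the sum over that
condition's individuals of `count / individual total` (proportions guard
against unequal sample sizes; the raw-sum alternative is not robust to them,
so the proportion form is the declared rule). The fold change is
`(a_HIV + ε)/(a_HEA + ε)` with `ε` = one cell at the smallest individual
total; clusters exceeding four-fold in either direction are enrichment trend
clusters, and sub-50-cell clusters are unassigned.

The permutation test compares per-individual values (e.g. a population's
mean marker intensity, MSI) across conditions with the statistic
`|mean₁ − mean₂|` (two-sided; the direction is reported alongside). All
`C(n₁+n₂, n₁)` relabelings are enumerated when that count is within
`max_permutations` (default 10,000, so 3v3 = 20 and 6v6 = 924 are always
exhaustive, with `p = #{stat ≥ observed}/total`); otherwise seeded
Monte-Carlo draws are used with the add-one convention
`p = (1 + exceedances)/(1 + draws)`. No multiple-testing correction is
applied; p-values are reported raw.

## Synthetic cohorts

Each population is a diagonal Gaussian in arcsinh space over the 72-marker
universe; an individual draws population labels from its condition's
abundance weights and marker values independently per marker. Panels see
only their own markers, add i.i.d. `N(0, sd)` noise to their backbone copy
(default sd 0.05, a minimal model of panel-to-panel staining variation) and
shuffle rows. Event ids carry the ground truth; the merge never reads them.

The preset cohort mirrors the emulated study design: 3 healthy + 3 HIV
individuals, three panels of 35/32/33 markers sharing the canonical 14-marker
backbone (CD1c, CD3, CD11c, CD14, CD16, CD19, CD32, CD64, CD66, CD86, CD123,
CD141, Granzyme B, HLA-DR), eight leukocyte populations with lineage-marker
means of 4.0 vs a 0.3 baseline (sd 0.25), and HIV-condition upregulation of
CD11a, CD11b, CD32, CD38, CD64, CD83, CD86 and TLR2 on monocytes and PMNs
(+2.2 arcsinh units over a 0.8 resting level). The shift is deliberately
clean — large relative to both the within-population spread and the backbone
noise — so that enrichment direction and category margins are recoverable by
construction. Events per individual default to 5,000, a desk-scale size at
which matching, clustering and the statistics all behave as at full scale;
tests and the acceptance script run the preset at 2,000–5,000 events and
`k = 20` clusters.

What passing on this generator shows: the matcher implements the exact
iterated mutual-NN rule (oracle-verified), recovers planted pairings through
realistic backbone noise, and the downstream stages propagate a planted
condition effect to the correct clusters, categories, enrichment labels and
p-values. What it does not show: robustness to features real CyTOF data have
and the generator omits — marker correlations within populations, spillover,
doublets, acquisition drift, heavy-tailed noise, and panel effects beyond
additive Gaussian backbone noise. Published per-donor merged counts depend on
the deposited accession data and are exercised here only through their
accounting identities.

## Numerical notes and limitations

* Determinism: every stochastic step takes a seed; identical spec + seed
  give bit-identical outputs (per-individual streams are derived from the
  cohort seed and the individual id).
* Degenerate inputs: empty profiles round-trip through I/O and produce empty
  assignments; a constant marker yields a degenerate range (category 1 at or
  below it, 5 above); density is undefined for fewer than two events; the
  percentile conventions are numpy's linear interpolation.
* FCS support is a minimal list-mode reader/writer (FCS 3.0/3.1, float,
  double or uniform-width integer data, single data set); TSV is the
  reference fixture format and round-trips to full precision.
* The sequential three-panel merge is order-dependent in principle; the
  default order merges the two largest panels first only insofar as the
  panel list is given in that order. At the preset's noise levels the final
  pair set is insensitive to order, but this is not guaranteed in general.
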