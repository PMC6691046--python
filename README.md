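# cytofuse

Multi-tube mass-cytometry profile merging and downstream immunophenotyping.

Mass cytometry (CyTOF) measures ~40 metal-tagged antibodies per cell, which is
not enough to phenotype the full leukocyte compartment of a complex disease at
once. A standard workaround is *multi-tube* staining: aliquots of the same
blood sample are stained with several antibody panels that share a common
**backbone** of markers, and the per-panel event tables are then merged
computationally into one wide profile — here three panels of 35/32/33 markers
sharing 14 backbone markers combine into a 72-marker profile per donor.

`cytofuse` implements that merge and the analysis that follows it:

* **Backbone merging.** Cells of two profiles are paired when they are
  *acceptable* and *non-ambiguous* nearest neighbours: writing
  `d(a, b) = ‖x_a − x_b‖₂` over the backbone markers (arcsinh-transformed,
  `asinh(x/5)`), the pair `(a, b)` is matched iff `b = argmin_b' d(a, b')`,
  `a = argmin_a' d(a', b)` over the still-unmatched cells, and `d(a, b) ≤ 3`.
  Matched cells are removed and matching repeats until a round adds no pair.
  A merged cell takes the mean of its contributors on the backbone and their
  own values on panel-specific markers; unmatched cells are excluded and
  accounted for (`excluded = Σ inputs − k·merged` for a k-panel merge).
* **Density-dependent downsampling and clustering.** Local density is the
  neighbour count within a data-derived radius; dense regions are thinned
  toward a target density so rare populations survive, the pooled downsampled
  cells are cut into *k* clusters by Ward agglomeration, and every original
  cell is then assigned to its nearest cluster centroid (full upsampling).
* **Categorical phenotyping.** Each marker's 5th–95th percentile range is cut
  into five uniform categories (negative … bright); clusters are summarised by
  the category of their mean-of-individual-medians, clusters with <50 cells
  are left unassigned, and lineage rules over categories label the clusters
  (T cell, B cell, PMN, NK cell, monocyte, mDC, pDC, basophil).
* **Group comparison.** Enrichment-trend clusters (abundance fold-change > 4
  between conditions, on per-individual proportions with a pseudocount) and
  non-parametric permutation tests on per-individual summary statistics
  (exhaustive whenever `C(n₁+n₂, n₁)` is small, Monte-Carlo otherwise).
* **Synthetic cohorts.** A generator of multi-panel, two-condition cohorts
  (Gaussian leukocyte populations in arcsinh space with condition-dependent
  marker shifts, per-panel backbone noise and shuffled rows) with ground-truth
  cell identities, so every stage is testable without any download.

## Worked example

Split one synthetic 2,000-cell donor into three noisy panels, merge them back,
and check against the ground truth:

```python
import cytofuse as cf

spec = cf.make_hiv_cohort_preset(seed=1, n_events=2000)
full, truth = cf.generate_individual(spec, "HEA-1")
panels = cf.split_panels(full, truth, spec.panels, backbone_noise_sd=0.05, seed=42)
result = cf.merge_panelset(panels)
print(cf.merge_report(result, sample_id="HEA-1").to_string(index=False))
```

```
sample  profile n_cells n_merged n_excluded
 HEA-1       #A    2000     <NA>       <NA>
 HEA-1       #B    2000     <NA>       <NA>
 HEA-1       #C    2000     <NA>       <NA>
 HEA-1 #A+#B+#C    <NA>     2000          0
```

All 2,000 cells found their partners across the three panels (pairing accuracy
against the ground truth: 100.00%), and the merged profile carries all
72 markers. A 3-vs-3 permutation test with complete separation reaches the
smallest attainable two-sided p-value:

```python
res = cf.permutation_test([10, 11, 12], [0, 1, 2])
# p = 0.1 over 20 relabelings  (2/20: the observed split and its mirror)
```

The full pipeline is also scriptable from the shell:

```sh
cytofuse run-all --seed 1 --out out/ --n-events 2000 --k 20
```

which writes the per-panel profiles, merged profiles, the merge report, the
categorical heatmap CSV, dendrogram orders, population labels and
enrichment-trend tables, plus a manifest sufficient to reproduce the run.

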