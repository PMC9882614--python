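# nichemap

Spatial macrophage-niche analysis for multiplexed tissue imaging.

Multiplexed imaging (immunofluorescence panels, CODEX) of tumor tissue
shows that macrophage subtypes are not interchangeable: populations marked
by IL4I1, SPP1 or NLRP3 concentrate immediately around tumor nests, while
FOLR2⁺ tissue-resident macrophages sit in benign stroma far from the
tumor. `nichemap` is a reusable, tested implementation of the analysis
chain behind that kind of finding, for imaging scientists and
computational pathologists who start from a nucleus segmentation mask and
want defensible spatial statistics at the end:

1. **Quantification** (`nichemap.quantify`) — a cell is a nucleus plus the
   3-pixel rim around it; per-cell marker intensity is the mean over that
   area. Label expansion assigns each rim pixel to its nearest nucleus
   (Euclidean, ties to the lower label).
2. **Typing** (`nichemap.celltyping`) — marker intensities are z-scored,
   cells are clustered with Leiden on a k-NN graph in marker space, and
   clusters are mapped to named types by an explicit gating table
   (first-match rules on mean z), replacing manual visual annotation.
3. **Distances** (`nichemap.spatial`) — for every macrophage the distance
   to the closest tumor cell, strictly within its tissue region. One
   region: two-sided Wilcoxon rank-sum. Many regions: linear mixed model
   `distance ~ group + (1 | region)` fit by REML, all pairwise contrasts,
   Holm–Bonferroni adjusted.
4. **Cellular neighborhoods** (`nichemap.neighborhoods`) — each cell's
   window is itself plus its k = 10 nearest neighbors; windows become
   cell-type composition vectors, k-means groups them into cellular
   neighborhoods (CNs), CNs are grouped into named niches and summarized
   by type enrichment (column z-scores), frequency per anatomic location,
   tumor-cell fraction and distance-to-tumor.
5. **Cohorts** (`nichemap.cohort`) — per-sample cluster frequencies with a
   strict > 35-cell filter, between-group log2 mean-frequency ratios,
   chi-squared with margin-corrected standardized-residual post-hocs
   (r = (O−E)/√(E(1−row/N)(1−col/N))), gene-signature scoring (mean
   per-gene z), univariable Cox z per dataset, and the sample-size
   weighted Stouffer/Liptak meta-z: `z_meta = Σ√n_d·z_d / √Σn_d`, reported
   as signed −log10 p.
6. **Simulation** (`nichemap.simulate`) — synthetic tissue with tumor
   nests, macrophage rings planted at controlled distances from the
   nearest tumor cell, type-dependent log-normal marker signal over
   Gaussian background, plus Dirichlet-multinomial cohort tables and
   multi-dataset survival cohorts with a planted log-hazard. Every
   generator carries its ground truth, so the whole pipeline is testable
   end to end.

## Worked example

Simulate three tissue regions (~1,000 cells each; SPP1/IL4I1 macrophages
planted near the tumor boundary, FOLR2 macrophages distal), then test
macrophage–tumor distances across regions:

```python
from nichemap import simulate, spatial

cfg = simulate.default_tissue_config(seed=1)
mask, stack, cells, truth = simulate.simulate_tissue(cfg)

res = spatial.nearest_target_distance(
    cells, ["IL4I1 TAM", "SPP1 TAM", "FOLR2 TRM"], "Tumor")
print(res.groupby("group")["distance_um"].mean().round(1).to_string())
print(spatial.compare_distances_lmm(res).round(4).to_string(index=False))
```

prints

```
group
FOLR2 TRM    97.1
IL4I1 TAM    36.7
SPP1 TAM     34.3
  group_a   group_b  estimate    stat  p_raw  p_holm
FOLR2 TRM IL4I1 TAM   60.3662 64.7755 0.0000  0.0000
FOLR2 TRM  SPP1 TAM   62.8147 67.4028 0.0000  0.0000
IL4I1 TAM  SPP1 TAM    2.4485  2.6273 0.0086  0.0086
```

The fitted mean distances recover the planted geometry (IL4I1/SPP1 near
~37 µm, FOLR2 distal ~100 µm), and the mixed-model contrasts — with the
tissue region as a random intercept, so cells from the same core are not
treated as independent — declare all three pairwise differences
significant after Holm adjustment.

The same steps are available from the shell:

```sh
nichemap simulate --seed 1 --outdir out/
nichemap quantify --mask out/mask.tif --stack out/stack.tif --out out/cells.csv
nichemap type --cells out/cells.csv --scheme scheme.yaml --out out/typed.csv
nichemap distances --cells out/typed.csv --targets Tumor \
    --queries "IL4I1 TAM,SPP1 TAM,FOLR2 TRM" --test lmm --out out/dist.csv
nichemap neighborhoods --cells out/typed.csv --k 10 --n-clusters 30 --out out/cn.csv
```

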