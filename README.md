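# landgen

Landscape genomics of domestic/wild insect vector populations: who moves
where, which loci track the domestic habitat, and which landscape features
resist gene flow.

`landgen` is built for the analysis pattern of reduced-representation SNP
surveys of triatomine (Chagas-disease vector) populations collected from
houses ("domestic" ecotope) and surrounding forest ("wild" ecotope) at
collection sites scattered across a heterogeneous landscape. It provides,
as a tested Python library plus a `landgen` command-line tool:

* **Population-genetic statistics** — observed/expected heterozygosity,
  F_IS, rarefaction allelic richness A_r with permutation contrasts,
  composite LD r², pairwise Nei F_ST (permutation + FDR), Hedrick/Meirmans
  G″_ST and maximum-standardised F′_ST, and hierarchical F-statistics from
  nested allele-level variance components (sites / ecotopes-within-sites /
  years-within-sites), exactly Weir–Cockerham θ in the two-level case.
* **Outlier-locus scans** — random-forest importance ranking with
  backwards purging to the subset minimising out-of-bag error; partial RDA
  loadings at ±2/±3 SD conditioned on spatial principal coordinates; an
  OutFlank-style trimmed chi-square F_ST–heterozygosity null; an
  fsthet-style empirical quantile envelope; and their consensus.
* **Isolation by distance** — Mantel tests and a GLS regression with the
  MLPE correlation structure
  `Y_ij = α + β(X_ij − x̄) + H_i [+ H_i(X_ij − x̄)] + τ_ij + e_ij`,
  where pairs sharing a population are correlated (ρ ∈ [0, 0.5)); the
  domestic-vs-wild slope contrast is a Wald/LRT test on the interaction.
* **Isolation by resistance** — monomolecular resistance transforms of
  landscape rasters, commute-time effective distances from the graph
  Laplacian (circuit theory), genetic-algorithm optimisation of surface
  parameters against the MLPE log-likelihood, AICc/Akaike-weight model
  selection with site-bootstrap rank stability, and current-density
  connectivity maps.
* **A synthetic-data generator** — spatially autocorrelated elevation
  fields, site layouts, and genotype matrices whose allele-frequency
  covariance decays with true resistance distance and which carry known
  outlier loci, so every stage has a ground-truth harness.

## Worked example

Simulate a full survey and run every stage:

```bash
landgen run-all --seed 3 --out demo_out
```

or from Python:

```python
from landgen.pipeline import validate_config, run_pipeline

cfg = validate_config(data={
    "seed": 3, "out_dir": "demo_out",
    "simulate": {"n_sites": 15, "n_dual_sites": 6, "samples_per_site": 8,
                 "n_loci": 500, "n_outlier_loci": 5, "grid_shape": [40, 40]},
    "optimize": {"generations": 6, "bootstrap_iterations": 50},
})
run_pipeline(cfg)
```

This writes genotypes (VCF + CSV), site metadata, rasters (ESRI ASCII),
distance matrices and stage summaries into `demo_out/`. From one such run:

`demo_out/ibd_summary.json` (isolation by distance):

```
"mantel_domestic": {"r_m": 0.516, "p": 0.0003}
"mantel_wild":     {"r_m": 0.688, "p": 0.0001}
"slope_contrast":  {"delta_beta": 0.000197, "p_wald": 0.602}
```

Genetic distance rises significantly with geographic distance in both
ecotopes (Mantel r_m with one-sided permutation p), and the wild-vs-domestic
difference in distance slopes (Δβ per km of F_ST) is not significant in
this small simulation — the generator applied no slope difference.

`demo_out/model_selection.csv` (resistance-surface selection, AICc with
n = sites):

```
model,k,AICc,delta_AICc,weight
elevation,4,-675.47,0.00,0.842
distance,2,-672.11,3.35,0.158
null,1,-595.56,79.90,3.8e-18
```

The optimised elevation surface (intercept + slope + shape + maximum, k=4)
beats the uniform-resistance distance model by ΔAICc 3.4 and carries 84% of
the Akaike weight; the data were simulated from an elevation-derived
resistance truth, so this is the correct recovery. `current_map.asc` maps
per-cell current density between all site pairs under the optimised
surface: high-current corridors predict where gene flow concentrates.

The outlier stage (`outliers.tsv`, `outliers_summary.json`) reports
per-locus RF importance, RDA z-loadings, F_ST/heterozygosity with
OutFlank-style p/q values, per-method flags, and consensus counts; on
synthetic data with five injected domestically-shifted loci the ≥2-method
consensus typically recovers 4–5 of them.

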