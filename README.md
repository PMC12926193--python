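# scaqtl

Single-cell chromatin-accessibility QTL (caQTL) mapping for sparse scATAC-seq
count data, built for studies that genotype tens of donors and profile
thousands to hundreds of thousands of cells across multiple libraries and
cohorts.

Clustering-based scATAC analyses aggregate cells into discrete types and lose
continuous cell-state variation; pseudobulk QTL models lose per-cell
covariates and sparsity structure. `scaqtl` implements a per-cell pipeline:

- **sc-PME mapping** — the single-cell Poisson mixed-effects model. Fragment
  counts *y<sub>ic</sub>* of cell *i* in peak *c* follow

  ```
  y_ic ~ Poisson(mu_ic)
  log mu_ic = log s_i + beta_c g_d(i) + x_i' gamma + a_d(i) + b_l(i)
  ```

  with the cell's log library size *s<sub>i</sub>* as offset, donor dosage
  *g*, z-scaled QC/latent covariates *x*, and donor (*a*) and library (*b*)
  random intercepts. Estimation is penalized IRLS with a Laplace-approximate
  marginal likelihood (a fast PQL mode mirrors the zero-quadrature setting of
  lme4's `glmer`). Scans test all SNPs within ±125 kb of a peak center
  (minor-allele count ≥ 4), Bonferroni-correct within peak, extract the lead
  SNP, and call significance by Storey q < 0.1 across lead SNPs.
- **Topic model cell states** — Poisson NMF (grade of membership) with the
  incremental-K fitting ladder (EM main iterations + coordinate-descent
  refinement, uniform-column expansion so topic *i* keeps its identity as K
  grows), multinomial conversion to per-cell loadings Q and per-topic peak
  scores Phi, projection of held-out cells, and exponential distance-decay
  propagation of peak scores to gene scores.
- **Trajectories** — rank-percentile trajectories from (reversed) topic
  loadings on [0, 100], composition and feature summaries along the
  trajectory, quintile differential activity, and a mixed-effects logistic
  LRT of topic loadings against donor-level phenotype.
- **Dynamic caQTLs** — genotype-by-loading interaction LRTs per cell type and
  topic, per-topic Storey q-values Bonferroni-multiplied by the number of
  topics tested per SNP (significant at adjusted q < 0.01).
- **Meta-analysis** — allele harmonization, inverse-variance fixed effects,
  and the Han–Eskin RE2 random-effects statistic (joint test of mean effect
  and heterogeneity, p from the ½χ²₁ + ½χ²₂ mixture).
- **Integration** — greedy 1 Mb GWAS locus definition (lead p < 1e-7),
  Wakefield-ABF colocalization (PP0–PP4) with the >150-shared-SNP eligibility
  rule, cross-cell-type sharing (secondary threshold 0.1/(5−1) = 0.025),
  pairwise pi1, co-accessible-peak distal caQTL tests, and Fisher enrichment.
- **Synthetic data** — a generator that emulates the full study design
  (multi-donor, multi-library sparse Poisson counts with planted genotype,
  interaction, and topic effects; AR(1) Gaussian-copula LD) so every stage
  has calibration and ground-truth recovery tests.

## Worked example

```python
import numpy as np
from scaqtl import SimConfig, simulate_dataset, caqtl

cfg = SimConfig(n_peaks=80, n_donors=30, cells_per_donor=(60, 80), seed=11)
ds = simulate_dataset(cfg)
print(f"{ds.adata.shape[0]} cells x {ds.adata.shape[1]} peaks, "
      f"{len(ds.caqtl_peaks)} peaks carry a planted caQTL")

design = caqtl.make_cell_design(ds.adata.obs)
records, leads, _ = caqtl.scan_dataset(
    ds.adata.X, ds.peaks, ds.snps, ds.dosages, design, method="pql")
called = caqtl.call_caqtls(leads, fdr=0.10)

n_sig = int(called["significant"].sum())
true_pos = called.set_index("peak_id").loc[
    [f"peak{c}" for c in ds.caqtl_peaks], "significant"].sum()
print(f"{n_sig} significant lead caQTLs at q < 0.1 "
      f"({int(true_pos)} at peaks with a planted effect)")

hit = called[called["significant"]].nsmallest(1, "q").iloc[0]
c = int(hit["peak_id"].removeprefix("peak"))
print(f"top peak {hit['peak_id']}: lead {hit['snp_id']}, "
      f"beta={hit['beta']:+.2f} (truth {ds.truth.beta_true[c]:+.2f}), "
      f"p_bonf={hit['p_bonf']:.2e}, q={hit['q']:.2e}")
```

Output:

```
2086 cells x 80 peaks, 40 peaks carry a planted caQTL
16 significant lead caQTLs at q < 0.1 (16 at peaks with a planted effect)
top peak peak24: lead rs000241, beta=+1.02 (truth +0.95), p_bonf=4.83e-06, q=3.87e-04
```

Reading: of 80 peaks, the 16 called at q < 0.1 are all peaks with a planted
effect (no false positives among the 40 null peaks), and the strongest call
recovers its planted log-rate effect (+1.02 vs +0.95) with the causal SNP's
LD block as lead.

A thin CLI mirrors the library:
`scaqtl simulate | scan | calibrate | topics-fit | meta | coloc | loci | sharing`
(see `scaqtl --help`).

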