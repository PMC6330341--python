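# immunoarch

Quantify the spatial organization of CD8+ T cells in whole-slide pathology
data — from cell coordinates and tissue annotations to local point-process
statistics, cluster morphometrics, heterogeneity indices, and
treatment-outcome associations.

Digital pathology pipelines readily produce per-cell coordinates for
tumor-infiltrating lymphocytes (TILs), but a density number alone discards
the *architecture* of the infiltrate: whether cells scatter diffusely,
pack into lymphoid-follicle-like aggregates, or line up along the invasive
front. `immunoarch` turns coordinate lists into interpretable metrics of
that architecture and of its intra- and inter-tumoral heterogeneity, for
researchers studying the tumor microenvironment and immune-checkpoint
therapy response, and for modelers calibrating spatial agent-based models
against histology.

## What it computes

**Segmentation evaluation.** Detected vs. manually annotated cells are
paired by mutually-greedy nearest-neighbor matching (default radius 10 µm);
pooled counts give recall R = TP/(TP+FN) and precision P = TP/(TP+FP) with
binomial standard errors √(p(1−p)/n), plus Spearman's ρ between per-sample
counts.

**Local point-process analysis.** A moving window (0.5 mm edge, 0.25 mm
step) slides over the slide. Each window is tested for complete spatial
randomness with the one-tailed Clark–Evans test (H_A: clustered, α = 0.05,
Donnelly boundary correction). Aggregated windows are fitted with a Thomas
cluster process — Poisson parents of intensity κ, Poisson(µ) offspring per
parent, isotropic Gaussian dispersion σ — whose Ripley K function is

    K(r) = πr² + (1/κ)(1 − exp(−r²/4σ²))

Offspring distance to the cluster center is Rayleigh(σ), so the mean
distance is σ√(π/2) and the 95% cluster radius is σ√(2 ln 20).

**Cluster morphometrics.** HDBSCAN (minPts = 30, core neighborhood K = 4)
detects clusters slide-wide; each cluster's outline is the alpha-shape
escalated from α = 10 µm until a single connected region contains every
member. Shape descriptors: convexity f_conv = A_α/A_conv, circularity
f_circ = 4πA_α/P_α², and eccentricity e = √(1 − λ₂/λ₁) from the 95%
covariance ellipse. Phenotype rules: *circular* if e < 0.8 ∧ f_conv > 0.8 ∧
f_circ > 0.5; *elongated/irregular* if e > 0.9 ∨ f_conv < 0.3 ∨ f_circ < 0.3.

**Heterogeneity.** Every metric's spread is summarized by the quartile
coefficient of dispersion QCoD = (Q3−Q1)/(Q3+Q1), within slides
(intra-tumoral) and across per-patient medians (inter-tumoral).

**Tissue context and outcomes.** Tumor/normal GeoJSON annotations yield an
invasive-front band (±250 µm around the tumor edge), cell labels
(intratumoral / peritumoral / stromal), cluster tissue associations, and
per-region metrics compared between responders and non-responders
(Wilcoxon rank-sum) or across ordered RECIST groups (Jonckheere–Terpstra).

**Virtual slides.** A synthetic-data module generates fully specified
slides — region geometry, Thomas or Poisson infiltrates, follicle and
strip archetypes, detection noise (miss rate, false detections) — so every
stage can be validated against known ground truth.

## Worked example

```python
import immunoarch as ia
from immunoarch.synthetic_data import SlideScenario, simulate_slide

sim = simulate_slide(SlideScenario(seed=1))        # 8x8 mm virtual slide
res = ia.run_slide(sim.observed_pattern, sim.regions, patient_id="demo")

wt = res.window_table
agg = wt[wt.csr == "aggregated"]
print(f"windows: {len(wt)}, aggregated: {len(agg)}")
print(f"median cells/cluster (mu): {agg.mu.median():.1f}")
print(f"median mean distance to cluster center: {agg.mean_dist.median():.1f} um")
print(f"clusters detected: {len(res.cluster_table)}")
```

Output:

```
windows: 961, aggregated: 246
median cells/cluster (mu): 10.5
median mean distance to cluster center: 33.9 um
clusters detected: 88
```

The slide plants a Thomas infiltrate with µ = 15 cells per cluster and
σ = 25 µm inside the central tumor, and the analysis sees the *observed*
pattern after detection noise (25% of cells missed). The aggregated
windows are the tumor windows; the recovered median µ of 10.5 matches the
noise-thinned expectation 0.75 × 15 ≈ 11, and the median distance
33.9 µm sits near the Rayleigh expectation σ√(π/2) ≈ 31 µm. The cluster
count is dominated by merged Thomas clumps inside the tumor, alongside
the three planted follicles and two strips.

The same stages are exposed as a CLI:

```bash
immunoarch simulate --seed 1 --out slide/
immunoarch windows  --cells slide/cells_observed.csv --out windows.csv
immunoarch clusters --cells slide/cells_observed.csv --out clusters.csv
immunoarch eval-seg --detected slide/cells_observed.csv --reference slide/cells_true.csv
```

## Layout

- `src/immunoarch/core_io.py` — data model, CSV/GeoJSON readers, units
- `src/immunoarch/segmentation_eval.py` — point matching, recall/precision
- `src/immunoarch/spatial_pointprocess.py` — windows, CSR test, Ripley K, Thomas fits, envelopes
- `src/immunoarch/cluster_morphometrics.py` — HDBSCAN, alpha-shapes, shape descriptors
- `src/immunoarch/heterogeneity.py` — QCoD, intra/inter summaries
- `src/immunoarch/regions_outcomes.py` — invasive front, tissue labels, outcome tests
- `src/immunoarch/synthetic_data.py` — virtual-slide generator
- `src/immunoarch/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modeling assumptions, numerical choices, limitations
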