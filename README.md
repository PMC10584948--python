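# npcstorm

Quantification of nuclear pore complexes (NPCs) from single-molecule
localization microscopy (STORM/SMLM), for cell biologists asking whether
pore numbers or per-pore protein incorporation change between cell states
(e.g. progenitor vs differentiated keratinocytes). The package starts from
the localization table a PSF-fitting tool exports — one row per blink:
frame, x, y, sigma — and provides:

- **Preprocessing** — rejection of out-of-focus localizations
  (sigma > 200 nm) and cross-correlation drift correction from temporally
  binned renderings;
- **Pore extraction** — HDBSCAN clustering of localizations into
  individual NPCs, with the minimum-points-per-cluster parameter tuned by
  Monte-Carlo simulation against known ground truth, plus sub-pore
  fragment merging;
- **Per-nucleus statistics** — pore density, SML density (all
  localization events divided by nuclear area), SML per pore, and cluster
  diameter (2 × mean radial distance from the centroid);
- **Group comparison** — pooled-variance Student's t (or Welch) per
  metric, mean ± s.d. summaries, one-way ANOVA + Tukey for ≥3 groups;
- **FRAP kinetics** — exponential-association fits
  I(t) = f0 + (plateau − f0)(1 − e^(−kt)), half-time t½ = ln2/k, and
  diffusion coefficients D = γ·w²/(4·t½) for a uniform circular beam
  (γ = 0.88; a square bleach side L maps to w = L/√π);
- **N:C ratios** — nuclear / (whole-cell − nuclear) integrated signal per
  cell from an image plus two masks;
- **Synthetic data** — a generator of blinking-emitter fields (8-fold
  rings on a nuclear cap, Gaussian localization noise, uniform background,
  optional drift), FRAP traces and N:C images with full ground truth, so
  every stage is testable without any microscope data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import npcstorm as ns

# one synthetic nucleus at the default imaging statistics:
# 4 pores/um^2 on a 5 um-radius cap, ~19 localizations per pore,
# 40/um^2 background, 20,000 frames
params = ns.NPCFieldParams(seed=1)
table, truth = ns.simulate_npc_field(params)
print(len(table), truth.n_npc)        # 9068 localizations, 314 true pores

# drift-correct, sigma-filter, cluster, summarize
stats, clusters = ns.analyze_nucleus(table, ns.PipelineConfig())
print(stats.n_npc)                    # 324
print(round(stats.npc_density, 2))    # 4.23  pores/um^2
print(round(stats.sml_density, 1))    # 98.2  localizations/um^2
print(round(stats.mean_sml_per_cluster, 1))  # 20.4
print(round(stats.mean_diameter, 1))  # 128.0 nm

# FRAP: fit a noisy recovery trace sampled every 10 s to 500 s
trace = ns.simulate_frap_trace(0.2, 1.0, k=0.01, noise_sd=0.016, seed=2)
fit = ns.fit_recovery(trace)
D = ns.diffusion_coefficient(fit, ns.BleachGeometry("square", 5.0))
print(round(fit.half_time, 1), round(D, 4))  # 69.1 s, 0.0253 um^2/s
```

The recovered pore count (324 vs 314 true, +3%) reflects the tuned
clustering defaults; the mean cluster diameter (128 nm) exceeds the 107 nm
ring truth because the radial-moment diameter includes localization noise
and residual background admixture (quantified in `docs/methods.md`). The
FRAP fit recovers the simulated rate k = 0.01/s within noise, and the
diffusion coefficient matches γw²/(4t½) for the 5 µm square bleach region.

For two-condition studies, `run_npc_pipeline` applies one shared
configuration to every nucleus and `build_report` produces the per-metric
t-test table. A thin CLI mirrors the library
(`npcstorm simulate|preprocess|cluster|optimize-m|pipeline|frap|nc|compare`).

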