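# leafspec

Estimating citrus-leaf **relative water content (RWC)** from 401–2400 nm
reflectance spectra with a CWT–SPA–PLSR pipeline, including the fusion of
chlorophyll-sensitive bands into the water model.

Leaf water status drives irrigation decisions in citrus orchards, and
hyperspectral reflectance offers a non-destructive way to monitor it:
water absorption shapes the NIR/SWIR region, pigments shape the visible.
The practical obstacles are noise and band collinearity.  This package
implements the standard chemometric answer as a tested, reusable library:

1. **CWT** — continuous wavelet transform of each spectrum,
   `W(a,b) = ∫ f(λ) a^{-1/2} ψ((λ−b)/a) dλ`, with the gaus1 (first
   derivative of Gaussian) mother wavelet on dyadic scales a = 2¹…2¹⁰,
   separating absorption-feature structure from noise by scale;
2. **SPA** — successive projections algorithm: a greedy chain that picks,
   at each step, the band whose column has the largest norm orthogonal to
   the already-selected span, minimizing collinearity; candidate subsets
   are scored by validation RMSE;
3. **PLSR** — NIPALS partial least squares on the selected wavelet
   coefficients, evaluated by R², RMSE = √(Σ(ŷ−y)²/n), RSS, and
   RPD = 1/√(1−R²);
4. **Fusion** — augmenting the RWC band set with chlorophyll (LCC,
   SPAD)-sensitive bands, exploiting the negative, slightly curved
   RWC–LCC relationship and the shared SWIR features near 2224/2308 nm.

Since no public dataset matches these calibrated conditions, the package
ships a calibrated synthetic generator (`leafspec.synthetic`): RWC
uniform on 56–66 %, LCC tied to RWC so the population linear/quadratic
fit R² are 0.3648/0.3864, Gaussian absorption troughs on a leaf-like
continuum, and 10-scan replicate averaging.  See `docs/methods.md` for
the model and every default.

## Worked example

```python
import leafspec as ls

cfg = ls.default_config(n_samples=232, seed=1)      # calibrated defaults
traits, spectra = ls.make_dataset(cfg)              # 232 x 2000 bands
pc = ls.PipelineConfig(split_seed=1)                # 4:1 split -> 185/47
exp = ls.Experiment(spectra, traits, pc)

sel = exp.spa_for_scale("rwc", 16)                  # SPA at scale a=16
rwc_only = ls.fuse_features(exp, sel, [])
fused = ls.fuse_features(exp, sel, [(32, 2224.0), (32, 2308.0)])
print(fused[fused.split == "test"][["r2", "rmse", "rss", "rpd"]])
```

Running the bundled analysis (`python analysis/01_simulate_dataset.py`
… `05_fusion_models.py`) on seed 1 prints:

```
rwc: raw test R2=0.621 | best CWT scale 32 R2=0.852 | best CWT+SPA scale 32 R2=0.837 (13 bands)
lcc: raw test R2=0.842 | best CWT scale 32 R2=0.922 | best CWT+SPA scale 32 R2=0.921 (6 bands)
best RWC scale by validation RMSE: 16
RWC-only   test: R2=0.734 RMSE=0.01497 RSS=0.01053 RPD=1.94
fused      test: R2=0.768 RMSE=0.01399 RSS=0.00920 RPD=2.08
```

Read: wavelet preprocessing lifts the water model well above the raw-
spectrum baseline; SPA reaches comparable accuracy with a handful of
bands instead of 2000; and adding the two shared SWIR chlorophyll bands
to the water band set improves held-out accuracy (here +0.034 R², RPD
1.94 → 2.08).  RMSE/RSS are in RWC fraction units (multiply by 100 for
percent).  Tables land under `results/`, bulky intermediates under
`scratch/`.

A `leafspec` command-line tool exposes the same stages
(`simulate`, `decompose`, `screen`, `fit`, `fuse`, `report`).

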