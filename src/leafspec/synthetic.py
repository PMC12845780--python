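"""Synthetic citrus-leaf trait tables and reflectance spectra.

No public spectral library matches the conditions this package is
calibrated to, so every downstream stage is exercised against a generator
that reproduces that statistical structure:

* RWC ~ Uniform(0.56, 0.66) — the observed range of leaf relative water
  content (fraction of fresh mass).
* LCC (SPAD units) depends on RWC through a slightly curved, negative
  relationship plus Gaussian noise.  With Z = RWC − midpoint,

      LCC = c0 + c1·Z + c2·Z² + N(0, σ²).

  Because Z is symmetric, Z and Z² are uncorrelated, so the population R²
  of a straight-line fit of LCC on RWC has the closed form

      R²_lin  = c1²·v / (c1²·v + c2²·w + σ²),
      R²_quad = (c1²·v + c2²·w) / (c1²·v + c2²·w + σ²),

  with v = Var(Z) = range²/12 and w = Var(Z²) = h⁴·4/45 (h the half-range).
  The defaults c1 = −200, c2 = +1884.8, σ = 7.488 were derived from this
  closed form so that R²_lin = 0.3648 and R²_quad = 0.3864, matching the
  observed RWC–LCC correlation strength.  See :func:`population_r2`.
* Reflectance on the 401–2400 nm 1 nm grid: a piecewise-linear continuum
  minus Gaussian absorption troughs whose depths are driven by RWC (water
  features in the NIR/SWIR) or by LCC (pigment features in the visible,
  plus two weak SWIR features near 2224/2308 nm that overlap the water
  troughs — the hook that makes chlorophyll-band fusion informative).
* Replicate-scan averaging: each sample's spectrum is the mean of
  ``scans_per_sample`` noisy copies, emulating the acquisition protocol of
  averaging every 10 scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import SpectrumSet, TraitTable

__all__ = [
    "AbsorptionFeature",
    "SyntheticConfig",
    "default_config",
    "population_r2",
    "sample_traits",
    "generate_spectra",
    "replicate_and_average",
    "make_dataset",
]

WAVELENGTH_LOW = 401.0
WAVELENGTH_HIGH = 2400.0


@dataclass(frozen=True)
class AbsorptionFeature:
    """Gaussian absorption trough subtracted from the continuum.

    depth = depth0 + depth_slope * driver_value, clamped at >= 0, where the
    driver value is the sample's RWC (fraction), LCC (SPAD) or nothing.
    """

    center: float  # nm
    width: float  # Gaussian sigma, nm
    driver: str  # "RWC" | "LCC" | "none"
    depth0: float  # reflectance units
    depth_slope: float  # reflectance units per driver unit

    def __post_init__(self) -> None:
        if not (WAVELENGTH_LOW <= self.center <= WAVELENGTH_HIGH):
            raise ValueError(f"feature center {self.center} nm outside grid")
        if self.width <= 0:
            raise ValueError("feature width must be positive")
        if self.driver not in ("RWC", "LCC", "none"):
            raise ValueError(f"unknown driver {self.driver!r}")


# Water absorption troughs sit at the classical NIR/SWIR bands; pigment
# troughs in the blue and red.  The deep 1450/1940 nm cores are mostly
# saturated (large static depth, small RWC response), so the usable water
# signal concentrates in the weaker 970/1200/2250/2310 nm bands — as in
# real leaves, where strong absorption flattens sensitivity.  The
# chlorophyll features at 2224/2308 nm are threshold-linear (zero depth
# below ~63.5 SPAD, the clamp doing the rectification) and overlap the
# 2250/2310 nm water troughs: that nonlinear aliasing is what makes
# chlorophyll-band fusion carry information a linear RWC-band model
# cannot recover on its own.
_DEFAULT_FEATURES = (
    AbsorptionFeature(970.0, 25.0, "RWC", -0.010, 0.08),
    AbsorptionFeature(1200.0, 35.0, "RWC", -0.015, 0.10),
    AbsorptionFeature(1450.0, 40.0, "RWC", 0.160, 0.08),
    AbsorptionFeature(1940.0, 45.0, "RWC", 0.200, 0.08),
    AbsorptionFeature(2250.0, 30.0, "RWC", -0.100, 0.30),
    AbsorptionFeature(2310.0, 25.0, "RWC", -0.080, 0.25),
    AbsorptionFeature(430.0, 15.0, "LCC", 0.010, 0.0012),
    AbsorptionFeature(460.0, 15.0, "LCC", 0.010, 0.0011),
    AbsorptionFeature(640.0, 12.0, "LCC", 0.005, 0.0010),
    AbsorptionFeature(660.0, 12.0, "LCC", 0.005, 0.0011),
    AbsorptionFeature(2224.0, 15.0, "LCC", -0.2540, 0.0040),
    AbsorptionFeature(2308.0, 12.0, "LCC", -0.2159, 0.0034),
)

# (wavelength nm, reflectance) knots of the leaf-like continuum
_DEFAULT_CONTINUUM = (
    (401.0, 0.18),
    (550.0, 0.24),
    (700.0, 0.46),
    (1100.0, 0.50),
    (1350.0, 0.44),
    (1650.0, 0.42),
    (1900.0, 0.36),
    (2100.0, 0.32),
    (2400.0, 0.22),
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 232
    seed: int = 0
    rwc_low: float = 0.56
    rwc_high: float = 0.66
    lcc_intercept: float = 63.5
    lcc_linear: float = -200.0
    lcc_quadratic: float = 1884.8
    lcc_noise_sd: float = 7.488
    continuum: tuple = _DEFAULT_CONTINUUM
    features: tuple = _DEFAULT_FEATURES
    scan_noise_sd: float = 0.08
    scans_per_sample: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.rwc_low < self.rwc_high < 1.0):
            raise ValueError("require 0 < rwc_low < rwc_high < 1")
        if self.lcc_noise_sd < 0:
            raise ValueError("lcc_noise_sd must be non-negative")
        if self.scans_per_sample < 1:
            raise ValueError("scans_per_sample must be at least 1")
        if self.scan_noise_sd < 0:
            raise ValueError("scan_noise_sd must be non-negative")


def default_config(**overrides) -> SyntheticConfig:
    """The calibrated default conditions; keyword overrides for experiments."""
    return replace(SyntheticConfig(), **overrides)


def population_r2(config: SyntheticConfig = SyntheticConfig()) -> tuple[float, float]:
    """Closed-form population R² of the linear and quadratic LCC-on-RWC fits.

    Uses the uncorrelatedness of Z and Z² under the symmetric uniform RWC law.
    """
    h = (config.rwc_high - config.rwc_low) / 2.0
    v = (2 * h) ** 2 / 12.0
    w = h**4 * 4.0 / 45.0
    lin = config.lcc_linear**2 * v
    quad = config.lcc_quadratic**2 * w
    total = lin + quad + config.lcc_noise_sd**2
    return lin / total, (lin + quad) / total


def sample_traits(config: SyntheticConfig) -> TraitTable:
    """Draw a trait table under the calibrated RWC–LCC model.

    Fresh weight is fixed at 1.0 g so dry weight is 1 − RWC, keeping the
    FW/DW columns exactly consistent with RWC = (FW − DW)/FW.
    """
    if config.n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(config.seed)
    rwc = rng.uniform(config.rwc_low, config.rwc_high, size=config.n_samples)
    z = rwc - (config.rwc_low + config.rwc_high) / 2.0
    lcc = (
        config.lcc_intercept
        + config.lcc_linear * z
        + config.lcc_quadratic * z**2
        + rng.normal(0.0, config.lcc_noise_sd, size=config.n_samples)
    )
    fw = np.ones(config.n_samples)
    dw = fw * (1.0 - rwc)
    ids = [f"S{i:04d}" for i in range(config.n_samples)]
    return TraitTable(ids, fw, dw, rwc, lcc)


def _continuum_curve(config: SyntheticConfig, wavelengths: np.ndarray) -> np.ndarray:
    knots = np.asarray(config.continuum, dtype=float)
    return np.interp(wavelengths, knots[:, 0], knots[:, 1])


def generate_spectra(traits: TraitTable, config: SyntheticConfig) -> SpectrumSet:
    """Deterministic forward model: continuum minus trait-driven troughs.

    reflectance(λ) = continuum(λ) − Σ_f depth_f · exp(−(λ−c_f)²/(2 σ_f²)),
    clamped to [0, 1].  Noise enters only via :func:`replicate_and_average`.
    """
    if traits.n_samples == 0:
        raise ValueError("traits table is empty")
    wavelengths = np.arange(WAVELENGTH_LOW, WAVELENGTH_HIGH + 1.0)
    refl = np.tile(_continuum_curve(config, wavelengths), (traits.n_samples, 1))
    driver_values = {"RWC": traits.rwc, "LCC": traits.lcc, "none": np.ones(traits.n_samples)}
    for feat in config.features:
        depth = feat.depth0 + feat.depth_slope * driver_values[feat.driver]
        depth = np.clip(depth, 0.0, None)
        shape = np.exp(-((wavelengths - feat.center) ** 2) / (2.0 * feat.width**2))
        refl -= depth[:, None] * shape[None, :]
    np.clip(refl, 0.0, 1.0, out=refl)
    return SpectrumSet(list(traits.sample_ids), wavelengths, refl)


def replicate_and_average(spectra: SpectrumSet, config: SyntheticConfig) -> SpectrumSet:
    """Mean of ``scans_per_sample`` independent noisy scans per sample.

    Each scan adds i.i.d. Gaussian noise per band (sd = scan_noise_sd); the
    average therefore has per-band noise variance scan_noise_sd²/scans.
    """
    if config.scan_noise_sd == 0.0:
        return SpectrumSet(
            list(spectra.sample_ids), spectra.wavelengths.copy(), spectra.reflectance.copy()
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    noise = rng.normal(
        0.0,
        config.scan_noise_sd,
        size=(config.scans_per_sample,) + spectra.reflectance.shape,
    )
    averaged = spectra.reflectance + noise.mean(axis=0)
    return SpectrumSet(list(spectra.sample_ids), spectra.wavelengths.copy(), averaged)


def make_dataset(config: SyntheticConfig) -> tuple[TraitTable, SpectrumSet]:
    """Traits plus replicate-averaged spectra in one call (the usual entry)."""
    traits = sample_traits(config)
    clean = generate_spectra(traits, config)
    return traits, replicate_and_average(clean, config)
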