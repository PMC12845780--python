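"""Spectral library and trait table I/O, band trimming, RWC arithmetic, splits.

Spectra travel as wide CSV (first column ``sample_id``, remaining headers the
wavelengths in nm on a uniform 1 nm grid); traits as long CSV with columns
``sample_id, fw_g, dw_g, rwc, lcc``.  Relative water content (RWC) is stored
as a fraction throughout; the conventional "%" is applied only when a report
is formatted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "TraitTable",
    "SplitIndex",
    "read_spectra",
    "write_spectra",
    "read_traits",
    "write_traits",
    "trim_bands",
    "compute_rwc",
    "split_train_test",
]


@dataclass
class SpectrumSet:
    """Reflectance matrix on a uniform 1 nm wavelength grid.

    Attributes
    ----------
    sample_ids : list of str
    wavelengths : ndarray, shape (n_bands,), strictly increasing, 1 nm step
    reflectance : ndarray, shape (n_samples, n_bands), values in [0, 1]
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D (samples x bands)")
        if len(self.sample_ids) != self.reflectance.shape[0]:
            raise ValueError("sample_ids length does not match reflectance rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.wavelengths.shape[0] != self.reflectance.shape[1]:
            raise ValueError("wavelength count does not match reflectance columns")
        steps = np.diff(self.wavelengths)
        if self.wavelengths.size > 1 and not np.allclose(steps, 1.0, atol=1e-9):
            raise ValueError("non-uniform grid: wavelengths must increase in 1 nm steps")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]


@dataclass
class TraitTable:
    """Per-sample fresh weight (g), dry weight (g), RWC (fraction), LCC (SPAD)."""

    sample_ids: list[str]
    fw: np.ndarray
    dw: np.ndarray
    rwc: np.ndarray
    lcc: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("fw", "dw", "rwc", "lcc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per sample")
        if np.any(self.dw <= 0) or np.any(self.dw > self.fw):
            raise ValueError("require 0 < dw <= fw for every sample")
        if np.any(self.rwc < 0) or np.any(self.rwc >= 1):
            raise ValueError("rwc must lie in [0, 1)")
        implied = (self.fw - self.dw) / self.fw
        if not np.allclose(self.rwc, implied, atol=1e-8):
            raise ValueError("rwc inconsistent with (fw - dw)/fw")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class SplitIndex:
    """Disjoint train/test partition of sample ids with its provenance."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    method: str = "random"

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "train_ids": list(self.train_ids),
                    "test_ids": list(self.test_ids),
                    "seed": self.seed,
                    "method": self.method,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SplitIndex":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["train_ids"], d["test_ids"], d["seed"], d["method"])


def write_spectra(spectra: SpectrumSet, path) -> None:
    """Write a SpectrumSet as wide CSV; wavelengths become column headers."""
    df = pd.DataFrame(
        spectra.reflectance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[f"{w:g}" for w in spectra.wavelengths],
    )
    df.to_csv(path, float_format="%.12g")


def read_spectra(path) -> SpectrumSet:
    """Read a wide spectral CSV; grid uniformity and finiteness are enforced."""
    df = pd.read_csv(path, index_col=0)
    try:
        wavelengths = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError("spectral CSV headers must be numeric wavelengths") from exc
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("non-numeric or missing reflectance cells")
    return SpectrumSet(df.index.astype(str).tolist(), wavelengths, values)


def write_traits(traits: TraitTable, path) -> None:
    pd.DataFrame(
        {
            "sample_id": traits.sample_ids,
            "fw_g": traits.fw,
            "dw_g": traits.dw,
            "rwc": traits.rwc,
            "lcc": traits.lcc,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path)
    return TraitTable(
        df["sample_id"].astype(str).tolist(),
        df["fw_g"].to_numpy(float),
        df["dw_g"].to_numpy(float),
        df["rwc"].to_numpy(float),
        df["lcc"].to_numpy(float),
    )


def trim_bands(spectra: SpectrumSet, low: float, high: float) -> SpectrumSet:
    """Keep only bands with low <= wavelength <= high (inclusive endpoints).

    The requested range must lie inside the data grid, e.g. a 350–2500 nm
    acquisition trimmed to 401–2400 nm yields exactly 2000 bands.
    """
    w = spectra.wavelengths
    if low < w[0] or high > w[-1]:
        raise ValueError(
            f"trim range [{low}, {high}] outside data grid [{w[0]:g}, {w[-1]:g}]"
        )
    if low > high:
        raise ValueError("low must not exceed high")
    mask = (w >= low) & (w <= high)
    return SpectrumSet(list(spectra.sample_ids), w[mask], spectra.reflectance[:, mask])


def compute_rwc(fw, dw):
    """Relative water content (FW − DW)/FW as a fraction.

    Scale-invariant: compute_rwc(c*fw, c*dw) == compute_rwc(fw, dw) for c > 0.
    """
    fw = np.asarray(fw, dtype=float)
    dw = np.asarray(dw, dtype=float)
    if np.any(fw <= 0):
        raise ValueError("fresh weight must be positive")
    if np.any(dw <= 0) or np.any(dw > fw):
        raise ValueError("dry exceeds fresh (require 0 < dw <= fw)")
    out = (fw - dw) / fw
    return float(out) if out.ndim == 0 else out


def _kennard_stone_order(X: np.ndarray, n_select: int) -> list[int]:
    """Kennard–Stone design-point ordering: maximin Euclidean coverage."""
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    chosen = [int(i), int(j)]
    mind = np.minimum(d2[i], d2[j])
    while len(chosen) < n_select:
        mind[chosen] = -np.inf
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, d2[nxt])
    return chosen[:n_select]


def split_train_test(
    ids,
    ratio: tuple[int, int] = (4, 1),
    seed: int = 0,
    method: str = "random",
    X: np.ndarray | None = None,
) -> SplitIndex:
    """Partition sample ids into train/test at an integer train:test ratio.

    Train size is floor(n * train/(train+test)), remainder to test — 232
    samples at 4:1 give 185/47.  ``method`` is "random" (seeded uniform) or
    "kennard_stone" (requires the spectral matrix ``X``; deterministic, the
    most mutually distant samples go to the training set).
    """
    ids = [str(s) for s in ids]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    tr, te = ratio
    if tr <= 0 or te <= 0:
        raise ValueError("ratio parts must be positive integers")
    n_train = int(np.floor(n * tr / (tr + te)))
    n_train = min(max(n_train, 1), n - 1)
    if method == "random":
        order = np.random.default_rng(seed).permutation(n)
        train_idx = sorted(order[:n_train].tolist())
    elif method == "kennard_stone":
        if X is None:
            raise ValueError("kennard_stone split requires the spectral matrix X")
        train_idx = sorted(_kennard_stone_order(np.asarray(X, float), n_train))
    else:
        raise ValueError(f"unknown split method: {method}")
    train_set = set(train_idx)
    return SplitIndex(
        [ids[i] for i in train_idx],
        [ids[i] for i in range(n) if i not in train_set],
        seed=seed,
        method=method,
    )
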