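"""Correlation scalograms and Successive Projections Algorithm selection.

The SPA chain is the classical greedy construction: starting from one
column, repeatedly pick the unselected column with the largest norm after
projection onto the orthogonal complement of the already-selected span.
Chains built this way are nested, so candidate subset sizes m = 1..m_max
are scored by walking prefixes of a single chain per start column.
Scoring fits an ordinary multiple linear regression (the canonical SPA
inner model; PLSR scoring is available) on an internal validation split of
the training data — the held-out test set is never consulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cwt import WaveletCoefficients
from .plsr import fit_plsr

__all__ = [
    "CorrelationMap",
    "BandSelection",
    "pearson_map",
    "spa_chain",
    "spa_select",
    "top_correlated_bands",
]

_PROJ_TOL = 1e-10  # relative residual-norm floor treated as numerically zero


@dataclass
class CorrelationMap:
    """Per-band Pearson r against a trait at one wavelet scale."""

    scale: int
    wavelengths: np.ndarray
    r: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("|r| must not exceed 1")
        if np.any(self.r[~self.valid_mask] != 0.0):
            raise ValueError("masked bands must carry r = 0")


@dataclass
class BandSelection:
    """Ordered SPA pick with its validation diagnostics."""

    trait: str
    scale: int | str
    selected: list[float]  # wavelengths, nm, in selection order
    start_band: float
    chain_rmse: dict[int, float]  # candidate size -> validation RMSE
    k_selected: int
    condition_number: float = np.nan
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected wavelengths must be distinct")
        if self.k_selected != len(self.selected):
            raise ValueError("k_selected must equal len(selected)")

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "scale": self.scale,
            "selected": list(self.selected),
            "start_band": self.start_band,
            "chain_rmse": {str(k): v for k, v in self.chain_rmse.items()},
            "k_selected": self.k_selected,
            "condition_number": self.condition_number,
            "truncated": self.truncated,
        }


def pearson_map(coeffs: WaveletCoefficients, trait_values, scale: int) -> CorrelationMap:
    """Pearson r between each coefficient column at ``scale`` and the trait.

    Zero-variance columns are masked and reported as r = 0 rather than NaN.
    """
    y = np.asarray(trait_values, dtype=float)
    X = coeffs.at_scale(scale)
    if X.shape[0] != y.size:
        raise ValueError("sample counts of coefficients and trait differ")
    if y.size < 3:
        raise ValueError("need at least 3 samples for a correlation map")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    sy = np.sqrt(np.sum(yc**2))
    valid = (sx > 0) & (sy > 0)
    r = np.zeros(X.shape[1])
    np.divide(Xc.T @ yc, sx * sy, out=r, where=valid)
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationMap(scale, coeffs.wavelengths.copy(), r, valid)


def spa_chain(X: np.ndarray, start: int, m: int) -> list[int]:
    """Greedy successive-projections chain of ``m`` column indices.

    At each step every unselected column is projected onto the orthogonal
    complement of the selected span and the maximum-norm survivor is taken;
    exact ties resolve to the lowest column index (lowest wavelength for
    wavelength-ordered matrices).  If all remaining projections vanish
    numerically the chain is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, J = X.shape
    if not (0 <= start < J):
        raise ValueError("start column out of range")
    if m > min(n, J):
        raise ValueError(f"m={m} exceeds min(n, J)={min(n, J)}")
    R = X.copy()  # residuals after deflation against selected directions
    norms0 = np.linalg.norm(X, axis=0)
    floor = _PROJ_TOL * max(norms0.max(), 1.0)
    chain = [start]
    for _ in range(m - 1):
        q = R[:, chain[-1]]
        qn = np.linalg.norm(q)
        if qn <= floor:
            break
        q = q / qn
        R = R - np.outer(q, q @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        best = int(np.argmax(norms))
        if norms[best] <= floor:
            warnings.warn(
                f"SPA chain truncated at {len(chain)} of {m}: remaining "
                "projections are numerically zero",
                stacklevel=2,
            )
            break
        chain.append(best)
    return chain


def _val_rmse_mlr(Xtr, ytr, Xval, yval) -> float:
    A = np.column_stack([np.ones(Xtr.shape[0]), Xtr])
    beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    pred = np.column_stack([np.ones(Xval.shape[0]), Xval]) @ beta
    return float(np.sqrt(np.mean((pred - yval) ** 2)))


def _val_rmse_plsr(Xtr, ytr, Xval, yval) -> float:
    ncomp = min(Xtr.shape[1], max(1, min(Xtr.shape[0] - 1, 10)))
    model = fit_plsr(Xtr, ytr, ncomp)
    pred = model.predict(Xval)
    return float(np.sqrt(np.mean((pred - yval) ** 2)))


def spa_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    m_range=range(1, 31),
    start_pool=None,
    wavelengths: np.ndarray | None = None,
    trait: str = "",
    scale: int | str = 0,
    score: str = "mlr",
) -> BandSelection:
    """Best SPA subset over every (start column, subset size) candidate.

    Columns are mean-centred (no variance scaling) before projection.  For
    each start the chain is grown once to max(m_range); each prefix is
    fitted by the scoring model on the training block and scored by RMSE on
    the validation block.  The global minimum wins; ties prefer fewer bands,
    then the lower start wavelength.
    """
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, float)
    m_range = sorted(set(int(m) for m in m_range))
    J = X_train.shape[1]
    m_cap = min(X_train.shape[0] - 1, J)
    if m_range[-1] > m_cap or m_range[0] < 1:
        raise ValueError(f"m_range must lie within [1, {m_cap}]")
    if start_pool is None:
        start_pool = range(J)
    start_pool = list(start_pool)
    if not start_pool:
        raise ValueError("start_pool is empty")
    if wavelengths is None:
        wavelengths = np.arange(J, dtype=float)
    scorer = {"mlr": _val_rmse_mlr, "plsr": _val_rmse_plsr}[score]

    mu = X_train.mean(axis=0)
    Xc = X_train - mu
    best = None  # (rmse, k, start_wavelength, chain_prefix, path)
    for start in start_pool:
        chain = spa_chain(Xc, start, m_range[-1])
        truncated = len(chain) < m_range[-1]
        path: dict[int, float] = {}
        for m in m_range:
            if m > len(chain):
                break
            cols = chain[:m]
            try:
                rmse = scorer(X_train[:, cols], y_train, X_val[:, cols], y_val)
            except np.linalg.LinAlgError:  # pragma: no cover - full-rank invariant
                continue
            path[m] = rmse
            key = (rmse, m, wavelengths[start])
            if best is None or key < best[0]:
                best = (key, cols, path, truncated)
    if best is None:
        raise RuntimeError("no SPA candidate could be scored")
    (rmse, k, start_w), cols, path, truncated = best
    sub = X_train[:, cols] - X_train[:, cols].mean(axis=0)
    cond = float(np.linalg.cond(sub)) if k > 1 else 1.0
    return BandSelection(
        trait=trait,
        scale=scale,
        selected=[float(wavelengths[j]) for j in cols],
        start_band=float(start_w),
        chain_rmse=path,
        k_selected=k,
        condition_number=cond,
        truncated=truncated,
    )


def top_correlated_bands(cmap: CorrelationMap, k: int = 50) -> list[int]:
    """Indices of the k bands with largest |r| — the default SPA start pool."""
    order = np.argsort(-np.abs(cmap.r), kind="stable")
    return [int(i) for i in order[:k]]
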