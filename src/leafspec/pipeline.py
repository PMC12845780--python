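"""Experiment orchestration: per-scale models, SPA screening, band fusion.

The workflow mirrors a three-stage comparison commonly used in leaf-trait
spectroscopy:

1. baseline PLSR on raw reflectance vs PLSR on wavelet coefficients at
   each dyadic scale (does multi-scale decomposition help?);
2. the same with SPA-screened sensitive bands (does collinearity reduction
   help further?);
3. fusion — augmenting the water-sensitive band set with bands selected
   for chlorophyll, exploiting the RWC–LCC correlation.

One train/test split is fixed per experiment and reused everywhere.  All
selection (SPA starts and sizes, PLS component counts, fusion ranking)
consumes only the training block, via an internal train/validation split;
the test block is touched exclusively by final evaluation calls.  A
``rank_on_test`` switch reproduces the alternative of ranking fusion
candidates directly on test metrics, for comparison only.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cwt import WaveletSpec, cwt_transform, scale_grid
from .io import SpectrumSet, TraitTable, split_train_test, write_spectra, write_traits
from .plsr import choose_components, evaluate_model, fit_plsr
from .screening import BandSelection, spa_select
from .synthetic import SyntheticConfig, make_dataset

__all__ = [
    "PipelineConfig",
    "Experiment",
    "run_per_scale",
    "fuse_features",
    "search_fusion_extras",
    "run_full",
]


@dataclass
class PipelineConfig:
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    n_scales: int = 10
    split_ratio: tuple[int, int] = (4, 1)
    split_seed: int = 0
    split_method: str = "random"
    val_fraction_ratio: tuple[int, int] = (3, 1)  # train-internal 75/25
    spa_m_max: int = 30
    spa_start_pool: int = 50
    spa_score: str = "mlr"
    plsr_a_max: int = 12
    plsr_folds: int = 5
    model_seed: int = 0
    l1_norm: bool = False
    rank_on_test: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class Experiment:
    """A spectral dataset with its fixed split and cached scalograms."""

    def __init__(self, spectra: SpectrumSet, traits: TraitTable, config: PipelineConfig):
        if spectra.sample_ids != traits.sample_ids:
            raise ValueError("spectra and traits sample ids are not aligned")
        self.spectra = spectra
        self.traits = traits
        self.config = config
        self.scales = scale_grid(config.n_scales)
        self.split = split_train_test(
            spectra.sample_ids,
            ratio=config.split_ratio,
            seed=config.split_seed,
            method=config.split_method,
            X=spectra.reflectance,
        )
        idx = {s: i for i, s in enumerate(spectra.sample_ids)}
        self.train_idx = np.array([idx[s] for s in self.split.train_ids])
        self.test_idx = np.array([idx[s] for s in self.split.test_ids])
        # train-internal fit/validation split used by every selection step
        inner = split_train_test(
            self.split.train_ids,
            ratio=config.val_fraction_ratio,
            seed=config.split_seed + 1,
            method="random",
        )
        self.fit_idx = np.array([idx[s] for s in inner.train_ids])
        self.val_idx = np.array([idx[s] for s in inner.test_ids])
        self._coeff_cache: dict[int, np.ndarray] = {}

    # -- feature access -------------------------------------------------
    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra.wavelengths

    def coeff_matrix(self, scale: int) -> np.ndarray:
        """Samples x bands wavelet coefficients at one scale (cached)."""
        if scale not in self._coeff_cache:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coeffs = cwt_transform(
                    self.spectra, self.config.wavelet, [scale], l1_norm=self.config.l1_norm
                )
            self._coeff_cache[scale] = coeffs.coeff[0]
        return self._coeff_cache[scale]

    def trait_values(self, trait: str) -> np.ndarray:
        return getattr(self.traits, trait.lower())

    def band_index(self, wavelength: float) -> int:
        j = int(np.searchsorted(self.wavelengths, wavelength))
        if j >= self.wavelengths.size or self.wavelengths[j] != wavelength:
            raise ValueError(f"wavelength {wavelength} nm is not on the grid")
        return j

    def design_matrix(self, features: list[tuple[int | str, float]]) -> np.ndarray:
        """Column-stack coefficient (scale, wavelength nm) features.

        A scale of "raw" takes the reflectance band itself.
        """
        cols = []
        for scale, wl in features:
            j = self.band_index(wl)
            if scale == "raw":
                cols.append(self.spectra.reflectance[:, j])
            else:
                cols.append(self.coeff_matrix(int(scale))[:, j])
        return np.column_stack(cols)

    # -- model fitting helpers ------------------------------------------
    def _fit_and_report(self, X: np.ndarray, y: np.ndarray, label: dict) -> list[dict]:
        cfg = self.config
        a_max = min(cfg.plsr_a_max, len(self.train_idx) - 1, X.shape[1])
        ncomp = choose_components(
            X[self.train_idx], y[self.train_idx], folds=cfg.plsr_folds,
            a_max=a_max, seed=cfg.model_seed,
        )
        model = fit_plsr(X[self.train_idx], y[self.train_idx], ncomp)
        rows = []
        for split_name, sel in (("train", self.train_idx), ("test", self.test_idx)):
            rep = evaluate_model(model, X[sel], y[sel], split=split_name)
            rows.append({**label, "n_components": ncomp, "n_features": X.shape[1], **rep.as_row()})
        return rows

    def validation_r2(self, X: np.ndarray, y: np.ndarray) -> float:
        """Train-internal validation R²: pooled out-of-fold CV predictions.

        K-fold over the training block only; kept separate from the SPA
        fit/validation split so feature sets tuned by SPA enjoy no home
        advantage when competing against fused alternatives.
        """
        from sklearn.model_selection import KFold

        cfg = self.config
        Xtr, ytr = X[self.train_idx], y[self.train_idx]
        a_max = min(cfg.plsr_a_max, len(self.train_idx) - 1, X.shape[1])
        ncomp = choose_components(
            Xtr, ytr, folds=cfg.plsr_folds, a_max=a_max, seed=cfg.model_seed
        )
        kf = KFold(n_splits=cfg.plsr_folds, shuffle=True, random_state=cfg.model_seed + 1)
        oof = np.empty_like(ytr)
        for fit_i, val_i in kf.split(Xtr):
            a = min(ncomp, len(fit_i) - 1, X.shape[1])
            model = fit_plsr(Xtr[fit_i], ytr[fit_i], a)
            oof[val_i] = model.predict(Xtr[val_i])
        return 1.0 - float(np.sum((oof - ytr) ** 2) / np.sum((ytr - ytr.mean()) ** 2))

    def spa_for_scale(self, trait: str, scale: int | str) -> BandSelection:
        """SPA band selection at one scale, scored on the internal split."""
        cfg = self.config
        y = self.trait_values(trait)
        X = (
            self.spectra.reflectance
            if scale == "raw"
            else self.coeff_matrix(int(scale))
        )
        # correlation ranking uses the training block only
        r = _pearson_vector(X[self.train_idx], y[self.train_idx])
        order = np.argsort(-np.abs(r), kind="stable")
        pool = [int(i) for i in order[: cfg.spa_start_pool]]
        m_cap = min(cfg.spa_m_max, len(self.fit_idx) - 1, X.shape[1])
        return spa_select(
            X[self.fit_idx],
            y[self.fit_idx],
            X[self.val_idx],
            y[self.val_idx],
            m_range=range(1, m_cap + 1),
            start_pool=pool,
            wavelengths=self.wavelengths,
            trait=trait,
            scale=scale,
            score=cfg.spa_score,
        )


def _pearson_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    sy = np.sqrt(np.sum(yc**2))
    r = np.zeros(X.shape[1])
    valid = (sx > 0) & (sy > 0)
    np.divide(Xc.T @ yc, sx * sy, out=r, where=valid)
    return r


def run_per_scale(
    experiment: Experiment, trait: str, use_spa: bool = False
) -> pd.DataFrame:
    """Raw-spectrum baseline plus one PLSR per wavelet scale for a trait.

    Returns a tidy frame with train and test rows for each of the
    1 + n_scales feature sets; with ``use_spa`` each feature set is first
    reduced to its SPA selection.
    """
    y = experiment.trait_values(trait)
    rows: list[dict] = []
    feature_sets: list[tuple[str, int | str]] = [("raw", "raw")] + [
        ("cwt", a) for a in experiment.scales
    ]
    for kind, scale in feature_sets:
        label = {
            "trait": trait,
            "feature_set": f"{kind}_spa" if use_spa else kind,
            "scale": scale,
        }
        if use_spa:
            selection = experiment.spa_for_scale(trait, scale)
            feats = [(scale, wl) for wl in selection.selected]
            X = experiment.design_matrix(feats)
            label["selected_bands"] = ";".join(f"{w:g}" for w in selection.selected)
        else:
            X = (
                experiment.spectra.reflectance
                if scale == "raw"
                else experiment.coeff_matrix(int(scale))
            )
        rows.extend(experiment._fit_and_report(X, y, label))
    return pd.DataFrame(rows)


def fuse_features(
    experiment: Experiment,
    rwc_selection: BandSelection,
    extras: list[tuple[int | str, float]],
    trait: str = "rwc",
) -> pd.DataFrame:
    """PLSR on RWC-selected wavelet features augmented with extra bands.

    ``extras`` are (scale, wavelength nm) pairs, typically chlorophyll-
    sensitive bands; duplicates of already-selected features are dropped.
    Returns train/test/validation rows for the fused model.
    """
    base = [(rwc_selection.scale, wl) for wl in rwc_selection.selected]
    feats = list(base)
    for extra in extras:
        key = (extra[0], float(extra[1]))
        if key not in feats:
            feats.append(key)
    X = experiment.design_matrix(feats)
    y = experiment.trait_values(trait)
    label = {
        "trait": trait,
        "feature_set": "fusion",
        "scale": rwc_selection.scale,
        "extras": ";".join(f"{s}-{w:g}" for s, w in feats[len(base):]) or "none",
    }
    rows = experiment._fit_and_report(X, y, label)
    val_r2 = experiment.validation_r2(X, y)
    for row in rows:
        row["validation_r2"] = val_r2
    return pd.DataFrame(rows)


def search_fusion_extras(
    experiment: Experiment,
    lcc_selection: BandSelection,
    rwc_selections: dict[int | str, BandSelection],
    max_extras: int = 2,
    trait: str = "rwc",
) -> pd.DataFrame:
    """Rank fusions of each RWC scale selection with LCC band subsets.

    Candidates are every non-empty subset (size <= max_extras) of the LCC
    best-scale bands crossed with every RWC per-scale selection.  Ranking
    uses the internal validation R²; test metrics are attached only for
    the winner.  With ``rank_on_test`` the ranking key is the test R²
    itself (reported for comparison with protocols that tune on test).
    """
    if max_extras < 1:
        raise ValueError("max_extras must be at least 1")
    if not lcc_selection.selected:
        raise ValueError("empty LCC selection")
    y = experiment.trait_values(trait)
    lcc_feats = [(lcc_selection.scale, wl) for wl in lcc_selection.selected]
    subsets: list[tuple] = []
    for k in range(1, max_extras + 1):
        subsets.extend(itertools.combinations(lcc_feats, k))
    records = []
    for scale, rsel in sorted(rwc_selections.items(), key=lambda kv: str(kv[0])):
        base = [(rsel.scale, wl) for wl in rsel.selected]
        for subset in subsets:
            feats = list(base) + [f for f in subset if f not in base]
            X = experiment.design_matrix(feats)
            if experiment.config.rank_on_test:
                rep_rows = experiment._fit_and_report(X, y, {"trait": trait})
                key_r2 = next(r["r2"] for r in rep_rows if r["split"] == "test")
            else:
                key_r2 = experiment.validation_r2(X, y)
            records.append(
                {
                    "rwc_scale": scale,
                    "extras": ";".join(f"{s}-{w:g}" for s, w in subset),
                    "n_features": X.shape[1],
                    "rank_r2": key_r2,
                    "_feats": feats,
                }
            )
    ranked = sorted(records, key=lambda r: (-r["rank_r2"], r["extras"], str(r["rwc_scale"])))
    for rank, rec in enumerate(ranked, start=1):
        rec["rank"] = rank
    winner = ranked[0]
    X = experiment.design_matrix(winner["_feats"])
    for row in experiment._fit_and_report(X, y, {"trait": trait}):
        winner[f"{row['split']}_r2"] = row["r2"]
        winner[f"{row['split']}_rmse"] = row["rmse"]
        winner[f"{row['split']}_rss"] = row["rss"]
        winner[f"{row['split']}_rpd"] = row["rpd"]
    for rec in ranked:
        rec.pop("_feats")
    return pd.DataFrame(ranked)


def run_full(
    synth_config: SyntheticConfig,
    pipe_config: PipelineConfig,
    workdir,
    traits_list: tuple[str, ...] = ("rwc", "lcc"),
    fusion_extras: tuple[tuple[int, float], ...] = ((32, 2224.0), (32, 2308.0)),
) -> Path:
    """End-to-end synthetic run; writes CSV/JSON artifacts, returns workdir.

    Stages: simulate -> split -> per-scale PLSR (raw + CWT) -> SPA per
    scale -> fusion of the RWC best-scale selection with the extra bands.
    Deterministic per seed: identical configs yield byte-identical reports.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    traits, spectra = make_dataset(synth_config)
    write_traits(traits, workdir / "traits.csv")
    write_spectra(spectra, workdir / "spectra.csv")
    exp = Experiment(spectra, traits, pipe_config)
    exp.split.to_json(workdir / "split.json")

    reports = []
    selections: dict[str, dict] = {}
    for trait in traits_list:
        reports.append(run_per_scale(exp, trait, use_spa=False))
        spa_report = run_per_scale(exp, trait, use_spa=True)
        reports.append(spa_report)
    report = pd.concat(reports, ignore_index=True)

    # fusion: best RWC scale selection (validation RMSE) + fixed LCC extras
    best = None
    for scale in exp.scales:
        sel = exp.spa_for_scale("rwc", scale)
        key = min(sel.chain_rmse.values())
        if best is None or key < best[0]:
            best = (key, sel)
        selections[f"rwc_scale_{scale}"] = sel.to_dict()
    fusion = fuse_features(exp, best[1], list(fusion_extras))
    fusion["feature_set"] = "fusion"
    report = pd.concat([report, fusion], ignore_index=True)
    report.insert(0, "config_hash", pipe_config.config_hash())
    report.to_csv(workdir / "report.csv", index=False, float_format="%.10g")
    with open(workdir / "selections.json", "w") as fh:
        json.dump(selections, fh, indent=1)
    return workdir
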