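#!/usr/bin/env python
"""Fuse chlorophyll-sensitive bands into the water-content model.

Takes the SPA band set of the best RWC scale, augments it with subsets of
the LCC best-scale selection (notably the shared SWIR bands near 2224 and
2308 nm), ranks every combination by train-internal validation R2, and
reports held-out test metrics for the winner plus the fixed
Scale5-2224/2308 fusion highlighted by the screening stage.
"""

from pathlib import Path

import pandas as pd

import leafspec as ls

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main(seed: int = 1) -> None:
    spectra = ls.read_spectra(SCRATCH / "spectra.csv")
    traits = ls.read_traits(SCRATCH / "traits.csv")
    exp = ls.Experiment(spectra, traits, ls.PipelineConfig(split_seed=seed))

    rwc_sels = {a: exp.spa_for_scale("rwc", a) for a in exp.scales}
    best_scale = min(
        rwc_sels, key=lambda a: min(rwc_sels[a].chain_rmse.values())
    )
    base = ls.fuse_features(exp, rwc_sels[best_scale], [])
    fixed = ls.fuse_features(exp, rwc_sels[best_scale], [(32, 2224.0), (32, 2308.0)])
    fixed_out = pd.concat(
        [base.assign(variant="rwc_only"), fixed.assign(variant="plus_2224_2308")],
        ignore_index=True,
    )
    fixed_out.to_csv(RESULTS / "05_fusion_fixed.csv", index=False, float_format="%.5g")

    lcc_sel = exp.spa_for_scale("lcc", 32)
    ranked = ls.search_fusion_extras(
        exp, lcc_sel, rwc_sels, max_extras=2
    )
    ranked.head(50).to_csv(RESULTS / "05_fusion_search.csv", index=False, float_format="%.5g")

    b = base[base.split == "test"].iloc[0]
    f = fixed[fixed.split == "test"].iloc[0]
    print(f"best RWC scale by validation RMSE: {best_scale}")
    print(f"RWC-only   test: R2={b.r2:.3f} RMSE={b.rmse:.5f} RSS={b.rss:.5f} RPD={b.rpd:.2f}")
    print(f"fused      test: R2={f.r2:.3f} RMSE={f.rmse:.5f} RSS={f.rss:.5f} RPD={f.rpd:.2f}")
    w = ranked.iloc[0]
    print(
        f"search winner: RWC scale {w.rwc_scale} + [{w.extras}] "
        f"validation R2={w.rank_r2:.3f} test R2={w.test_r2:.3f}"
    )


if __name__ == "__main__":
    main()
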