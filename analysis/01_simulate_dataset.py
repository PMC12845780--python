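#!/usr/bin/env python
"""Generate the synthetic citrus-leaf dataset used by the downstream stages.

Draws 232 leaves under the calibrated default conditions (RWC uniform on
56-66%, LCC tied to RWC through the curved negative relationship, 10
averaged scans per sample), writes the bulky spectra to scratch/ and a
small trait summary to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import leafspec as ls

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main(seed: int = 1) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = ls.default_config(n_samples=232, seed=seed)
    traits, spectra = ls.make_dataset(cfg)
    ls.write_traits(traits, SCRATCH / "traits.csv")
    ls.write_spectra(spectra, SCRATCH / "spectra.csv")

    lin_pred = np.polyval(np.polyfit(traits.rwc, traits.lcc, 1), traits.rwc)
    quad_pred = np.polyval(np.polyfit(traits.rwc, traits.lcc, 2), traits.rwc)
    tss = np.sum((traits.lcc - traits.lcc.mean()) ** 2)
    summary = pd.DataFrame(
        {
            "quantity": [
                "n_samples", "rwc_min", "rwc_max", "lcc_min", "lcc_max",
                "rwc_lcc_linear_r2", "rwc_lcc_quadratic_r2",
                "population_linear_r2", "population_quadratic_r2",
            ],
            "value": [
                traits.n_samples, traits.rwc.min(), traits.rwc.max(),
                traits.lcc.min(), traits.lcc.max(),
                1 - np.sum((traits.lcc - lin_pred) ** 2) / tss,
                1 - np.sum((traits.lcc - quad_pred) ** 2) / tss,
                *ls.population_r2(cfg),
            ],
        }
    )
    summary.to_csv(RESULTS / "01_trait_summary.csv", index=False, float_format="%.4f")
    print(summary.to_string(index=False))
    print(f"\nspectra: {spectra.n_samples} x {spectra.n_bands} bands -> {SCRATCH}")


if __name__ == "__main__":
    main()
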