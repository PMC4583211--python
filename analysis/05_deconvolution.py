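#!/usr/bin/env python
"""Gaussian deconvolution of the composite dimer ABS/MCD spectrum.

Builds the ten-band synthetic ABS/MCD pair (band energies 7280-25380
cm^-1, FWHM 2500 cm^-1), perturbs the initial centers by up to
+-300 cm^-1, runs the simultaneous deconvolution with the 3% shared-center
constraint, and classifies every recovered band by its C0/D0 ratio
(|C0/D0| > 0.17 marks a metal-centered d-d transition).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from vtvhmcd import NoiseModel, synth_spectra
from vtvhmcd.bands import simultaneous_deconvolve
from vtvhmcd.io import write_spectrum

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    abs_spec, mcd_spec, truth = synth_spectra(noise=NoiseModel(sigma=0.0, seed=SEED))
    write_spectrum(abs_spec, OUT / "dimer_abs_synthetic.csv")
    write_spectrum(mcd_spec, OUT / "dimer_mcd_synthetic.csv")

    true_centers = np.array([b["center"] for b in truth["bands"]])
    rng = np.random.default_rng(SEED)
    init = true_centers + rng.uniform(-300.0, 300.0, size=10)
    result = simultaneous_deconvolve(abs_spec, mcd_spec, 10, init, shift_bound=0.03)

    rows = []
    for k, (b, cls) in enumerate(zip(result.bands, result.classifications), start=1):
        rows.append(
            {
                "band": k,
                "center_true_cm1": true_centers[k - 1],
                "center_fit_cm1": b.center,
                "fwhm_cm1": b.fwhm,
                "mcd_amplitude": b.mcd_amplitude,
                "c0_over_d0": b.c0_over_d0,
                "class": cls,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "deconvolution_table.csv", index=False, float_format="%.6g")
    print(df.round(3).to_string(index=False))
    print(f"\nband 1 recovered at {result.bands[0].center:.1f} cm^-1 "
          f"(true 7280; residual norms {result.abs_residual_norm:.2e} / "
          f"{result.mcd_residual_norm:.2e})")
    (OUT / "deconvolution_summary.json").write_text(
        json.dumps({"band1_center_fit": result.bands[0].center,
                    "max_center_error": float(np.max(np.abs(df.center_fit_cm1 - df.center_true_cm1)))},
                   indent=1)
    )
    print(f"wrote {OUT / 'deconvolution_table.csv'}")


if __name__ == "__main__":
    main()
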