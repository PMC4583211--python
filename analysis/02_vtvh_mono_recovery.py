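#!/usr/bin/env python
"""Variable-temperature MCD of the mononuclear complex: simulate and refit.

Generates synthetic VT MCD intensities at 10 T for four bands with
distinct polarizations (1% noise), then refits the axial ZFS parameter D
and the per-band effective transition dipole moment products.  The
recovered D and fractional polarizations document that the saturation
behavior pins the ZFS even from fixed-field, variable-temperature data.
"""

import json
from pathlib import Path

import pandas as pd

from vtvhmcd import (
    FitSpec,
    NoiseModel,
    OrientationGrid,
    fit_spin_hamiltonian,
    fractional_polarizations,
    preset_bands,
    preset_system,
    synth_mono_vtvh,
)
from vtvhmcd.io import write_vtvh

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    data = synth_mono_vtvh(NoiseModel(sigma=0.01, seed=SEED))
    write_vtvh(data, OUT / "mono_vtvh_synthetic.csv")

    fit_grid = OrientationGrid.gauss_legendre(12, 24)
    result = fit_spin_hamiltonian(
        data,
        preset_system("complex1_mono"),
        FitSpec(free={"D_A": (5.0, 60.0)}, n_restarts=4, seed=SEED),
        grid=fit_grid,
    )
    d_fit = result.parameters["D_A"]
    print(f"generating D = 28.0 cm^-1; recovered D = {d_fit:.2f} cm^-1 "
          f"(error {d_fit - 28.0:+.2f})")

    report = {"D_A_true": 28.0, "D_A_fit": d_fit, "sse": result.sse, "bands": []}
    truth_bands = preset_bands("complex1_mono")
    for ds, mom, tb in zip(data, result.moments, truth_bands):
        pol = fractional_polarizations(mom)
        true_pol = fractional_polarizations(tb["moments"])
        report["bands"].append(
            {
                "wavelength_nm": ds.wavelength_nm,
                "polarization_fit": [round(pol.pct_x, 1), round(pol.pct_y, 1), round(pol.pct_z, 1)],
                "polarization_true": [round(true_pol.pct_x, 1), round(true_pol.pct_y, 1),
                                      round(true_pol.pct_z, 1)],
            }
        )
        print(f"  {ds.wavelength_nm:6.0f} nm: fit %(x,y,z) = "
              f"({pol.pct_x:5.1f}, {pol.pct_y:5.1f}, {pol.pct_z:5.1f})  "
              f"true ({true_pol.pct_x:5.1f}, {true_pol.pct_y:5.1f}, {true_pol.pct_z:5.1f})")
    (OUT / "mono_fit_report.json").write_text(json.dumps(report, indent=1))
    print("\nnote: for an axial system (E/D = 0) the x and y directions are")
    print("equivalent, so the fit can only determine the combined x,y fraction;")
    print("the oppositely polarized pseudo-A partners refit to ~equal x/y mixes")
    print("while the z fractions and D are well determined.")
    print(f"wrote {OUT / 'mono_fit_report.json'}")


if __name__ == "__main__":
    main()
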