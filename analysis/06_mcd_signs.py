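#!/usr/bin/env python
"""MCD C-term and pseudo-A-term signs for the ligand-field transitions.

Applies the one-electron sign rule (spin-orbit coupling between excited
states, transition dipole handedness, energy ordering) to the two
pseudo-A pairs of the mononuclear complex: E(d_xz,yz -> d_x2-y2), whose
lower member absorbs right circularly polarized light (negative C-term)
giving a positive pseudo-A feature, and E(d_xz,yz -> d_z2), whose
pseudo-A feature is negative.
"""

import json
from pathlib import Path

from vtvhmcd import (
    ExcitedStatePair,
    OneElectronTransition,
    cterm_sign_handedness,
    cterm_sign_saturation,
    d_orbital_angmom,
    pseudo_a_sign,
)

OUT = Path(__file__).resolve().parents[1] / "results"

PAIRS = {
    "E(2e->2b1) d_xz,yz -> d_x2-y2": (
        ("d_xz", "d_x2-y2", "-x", 13700.0),
        ("d_yz", "d_x2-y2", "-y", 15220.0),
    ),
    "E(2e->2a1) d_xz,yz -> d_z2": (
        ("d_xz", "d_z2", "+x", 17960.0),
        ("d_yz", "d_z2", "-y", 18050.0),
    ),
}


def main() -> None:
    print("one-electron angular momentum couplings (units hbar):")
    print(f"  Im<d_yz|l_z|d_xz>    = {d_orbital_angmom('d_yz', 'd_xz', 'z'):+.0f}")
    print(f"  Im<d_x2-y2|l_z|d_xy> = {d_orbital_angmom('d_x2-y2', 'd_xy', 'z'):+.0f}\n")

    report = {}
    for name, (t1, t2) in PAIRS.items():
        pair = ExcitedStatePair(
            OneElectronTransition.make(*t1), OneElectronTransition.make(*t2)
        )
        lower = cterm_sign_saturation(pair, "lower")
        upper = cterm_sign_saturation(pair, "upper")
        geo = cterm_sign_handedness(pair, "lower")
        pa = pseudo_a_sign(pair)
        print(f"{name}:")
        print(f"  lower C-term {lower:+d} (handedness rule {geo:+d}), "
              f"upper C-term {upper:+d}, pseudo-A {pa:+d}")
        report[name] = {"lower": lower, "upper": upper, "pseudo_A": pa}
    (OUT / "sign_predictions.json").write_text(json.dumps(report, indent=1))
    print(f"\nwrote {OUT / 'sign_predictions.json'}")


if __name__ == "__main__":
    main()
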