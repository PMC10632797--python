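"""Osmotic power output of the potassium-permselective membrane.

Fits the I–V line of a synthetic 1 M KCl | 1 M NaCl measurement (reversal
potential 73.1 mV), evaluates the dual-ion Coulomb repulsion at the
3.9 Å ion–ion distance, and scales the ~0.13 pW single-pore power to an
areal power density at one pore per 10 nm × 10 nm patch (10¹⁶ pores/m²,
porosity < 1%).  Writes results/power.json.
"""

import json
from pathlib import Path

from twistpore import power as pw, synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 11


def main() -> None:
    iv = syn.gen_iv(u_diff=73.1, conductance=0.097, noise_sd=0.2, seed=SEED)
    fit = pw.fit_iv(iv)
    out = pw.osmotic_output(fit, patch_edge_nm=10.0)
    print(f"I-V fit: G = {fit.conductance:.4f} nS, I_diff = {fit.i_diff:.2f} pA, "
          f"U_diff = {fit.u_diff:.1f} mV")
    print(f"single-pore power (max transfer |IU|/4): "
          f"{out.single_pore_power * 1e12:.3f} pW")
    print(f"pore density {out.pore_density:.3g} /m^2 -> "
          f"power density {out.power_density:.0f} W/m^2")

    phi = pw.porosity(32.0, out.pore_density)
    print(f"porosity at 32 A^2/pore: {phi:.4f} (<1%)")

    e_coul = pw.coulomb_energy(1, 1, 3.9)
    print(f"dual-ion Coulomb energy at 3.9 A in vacuum: {e_coul:.1f} kcal/mol")

    nernst = pw.ghk_reversal({"K": 1.0}, {"K": 1.0}, {"K": 0.1})
    print(f"GHK single-cation Nernst check, 10:1 ratio: {nernst:.1f} mV")

    (OUT / "power.json").write_text(json.dumps({
        "conductance_nS": fit.conductance,
        "I_diff_pA": fit.i_diff,
        "U_diff_mV": fit.u_diff,
        "single_pore_power_W": out.single_pore_power,
        "pore_density_per_m2": out.pore_density,
        "power_density_W_m2": out.power_density,
        "porosity_at_32A2": phi,
        "coulomb_3p9A_kcal_mol": e_coul,
        "nernst_10to1_mV": nernst,
    }, indent=1))


if __name__ == "__main__":
    main()
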