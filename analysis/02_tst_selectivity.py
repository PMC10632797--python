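"""Transition-state-theory selectivity kinetics.

Generates K⁺- and Na⁺-like PMF profiles with the reported barrier
structure (interlayer hop 3.5 vs 8.9 kcal/mol), estimates the attempt
period from a damped-oscillator velocity autocorrelation, and evaluates
TST permeation rates and the K⁺/Na⁺ selectivity ratio implied by the
barrier difference.  Writes results/tst_kinetics.json and the PMF
tables under results/pmf/.
"""

import json
from pathlib import Path

from twistpore import synthetic as syn, tst_kinetics as tk

OUT = Path(__file__).resolve().parent.parent / "results"
(OUT / "pmf").mkdir(parents=True, exist_ok=True)

SEED = 20230
TEMPERATURE = 300.0
VIBRATION_PERIOD_PS = 0.4


def main() -> None:
    pmf_k = syn.potassium_pmf(seed=SEED)
    pmf_na = syn.sodium_pmf(seed=SEED + 1)
    tk.write_pmf(pmf_k, OUT / "pmf" / "pmf_K.tsv")
    tk.write_pmf(pmf_na, OUT / "pmf" / "pmf_Na.tsv")

    velocities = syn.gen_oscillator_velocities(
        VIBRATION_PERIOD_PS, damping_ratio=0.02, seed=SEED
    )
    tau = tk.attempt_period_from_vacf(velocities)
    print(f"attempt period from VACF second zero: {tau:.4f} ps "
          f"(3/4 of the {VIBRATION_PERIOD_PS} ps vibration period)")

    result = {"attempt_period_ps": tau, "temperature_K": TEMPERATURE}
    for ion, pmf in (("K", pmf_k), ("Na", pmf_na)):
        barrier = tk.rate_determining_barrier(pmf)
        rate = tk.permeation_rate(barrier, tau, TEMPERATURE)
        result[ion] = {"barrier_kcal_mol": barrier, "rate_per_s": rate}
        print(f"{ion:2s}: hop barrier {barrier:.2f} kcal/mol -> {rate:.3e} ions/s")

    sr = tk.selectivity_ratio(result["K"]["rate_per_s"], result["Na"]["rate_per_s"])
    result["selectivity_ratio"] = sr
    print(f"selectivity ratio from the 5.4 kcal/mol barrier difference "
          f"(equal attempt periods): {sr:.0f}")
    print("note: the MD-derived headline SR additionally folds in the "
          "ion-specific attempt periods, which are not desk-reproducible.")

    (OUT / "tst_kinetics.json").write_text(json.dumps(result, indent=1))


if __name__ == "__main__":
    main()
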