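"""Voltage-clamp fluorometry gating analysis on a synthetic control cohort.

Simulates 12 control cells under the standard step protocol (-100 mV holding,
250-ms pulses from -140 to +40 mV in 10 mV steps, 5 kHz sampling), runs the
full processing chain (filtering, leak and bleach corrections, per-sweep
summaries) and the per-cell fits, and prints the recovered steady-state
activation parameters next to the generator's ground truth.
"""

from tevcf import analyze_cohort
from tevcf.reference import GATING_CONDITIONS, cohort_config
from tevcf.synthetic import simulate_cohort

cells = simulate_cohort(cohort_config("control", seed=1))
table = analyze_cohort(cells, normalize_amplitudes=False)

truth = GATING_CONDITIONS["control"]
print(table[["cell_id", "v_half_f", "k_f", "v_half_g", "k_g"]].round(2).to_string(index=False))
print()
print(f"F-V midpoint: recovered {table['v_half_f'].mean():.1f} mV "
      f"(generator truth {truth.v_half_f} mV) — voltage-sensor half-activation")
print(f"G-V midpoint: recovered {table['v_half_g'].mean():.1f} mV "
      f"(generator truth {truth.v_half_g} mV) — pore half-activation")
print("The F-V curve sits ~17 mV negative to the G-V curve: the voltage sensor")
print("moves before the pore opens, as expected for a K_V channel.")
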