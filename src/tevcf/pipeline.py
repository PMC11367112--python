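"""End-to-end per-cell and per-cohort analysis.

Glues the processing and fitting stages together: a sweep set goes through
leak and bleach corrections, summary-point extraction, the GHK x Boltzmann
I-V fit, the Boltzmann F-V fit and (optionally) the exponential kinetics
fits, producing one row of the cohort table per cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gating
from .traces import ProcessingConfig, SweepSet, process_sweepset

__all__ = ["analyze_cell", "analyze_cohort", "DEFAULT_KINETICS_RANGE"]

#: voltage range over which activation kinetics are fitted (mV); at these
#: depolarized potentials the rises are large and well approximated by the
#: exponential models.
DEFAULT_KINETICS_RANGE = (-10.0, 40.0)


def analyze_cell(
    sweepset: SweepSet,
    config: ProcessingConfig | None = None,
    fit_kinetics: bool = False,
    kinetics_range: tuple = DEFAULT_KINETICS_RANGE,
) -> dict:
    """Process one cell and fit the gating models; returns a cohort-table row."""
    processed = process_sweepset(sweepset, config)
    v = processed.test_potentials
    gv = gating.fit_iv_ghk_boltzmann(v, processed.peak_current)

    ss_dff = processed.steady_state_dff
    fmax = np.max(np.abs(ss_dff))
    if fmax <= 0:
        raise ValueError(f"cell {sweepset.cell_id}: no fluorescence signal to normalize")
    sign = np.sign(ss_dff[np.argmax(np.abs(ss_dff))])
    fnorm = sign * ss_dff / fmax  # normalized to max obtained intensity, rising
    fv = gating.fit_boltzmann_fv(v, fnorm)

    i40 = float(processed.peak_current[np.argmin(np.abs(v - 40.0))])
    row = {
        "cell_id": sweepset.cell_id,
        "day_id": sweepset.day_id,
        "treatment": sweepset.treatment_label,
        "v_half_g": gv.v_half,
        "k_g": gv.k,
        "gmax": gv.gmax,
        "erev": gv.erev,
        "gv_converged": gv.converged,
        "v_half_f": fv.v_half,
        "k_f": fv.k,
        "fv_converged": fv.converged,
        "peak_I_at_40": i40,
    }
    if fit_kinetics:
        row.update(_fit_kinetics(sweepset, processed, kinetics_range))
    return row


def _fit_kinetics(sweepset, processed, kinetics_range):
    protocol = sweepset.protocol
    pulse = protocol.pulse_slice()
    margin = int(round(processed.config.exclusion_margin_ms / protocol.dt_ms))
    lo, hi = sorted(kinetics_range)
    out = {"tau_act_by_v": {}, "tau_fast_by_v": {}, "tau_slow_by_v": {}, "fast_fraction_by_v": {}}
    for idx, s in enumerate(sweepset.sweeps):
        v = s.test_potential
        if not lo - 1e-9 <= v <= hi + 1e-9:
            continue
        # current: skip the capacitive-transient margin after pulse onset;
        # fluorescence: no capacitive artifact, fit from onset so the fitted
        # amplitudes reflect the true fast/slow split (a delayed window
        # attenuates the fast amplitude by e^{-margin/tau_f})
        seg = slice(pulse.start + margin, pulse.stop)
        t = s.time_ms[seg] - s.time_ms[seg.start]
        single = gating.fit_single_exp_activation(t, processed.corrected_current[idx][seg])
        fseg = pulse
        tf = s.time_ms[fseg] - s.time_ms[fseg.start]
        double = gating.fit_double_exp_activation(tf, processed.dff[idx][fseg])
        out["tau_act_by_v"][v] = single.tau_act
        out["tau_fast_by_v"][v] = double.tau_fast
        out["tau_slow_by_v"][v] = double.tau_slow
        out["fast_fraction_by_v"][v] = double.fast_amplitude_fraction
    return out


def analyze_cohort(
    sweepsets,
    config: ProcessingConfig | None = None,
    fit_kinetics: bool = False,
    control_label: str = "control",
    normalize_amplitudes: bool = True,
) -> pd.DataFrame:
    """Analyze a list of sweep sets into a one-row-per-cell cohort table.

    When ``normalize_amplitudes`` is set, relative current amplitudes are
    computed against the daily control mean (requires control cells on every
    recording day).
    """
    rows = [analyze_cell(ss, config, fit_kinetics) for ss in sweepsets]
    table = pd.DataFrame(rows)
    if normalize_amplitudes:
        table = gating.relative_amplitudes(table, control_label=control_label)
    return table
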