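"""Gating-model equations and per-cell fits for voltage-clamp fluorometry.

The module implements the five model equations used to quantify K_V channel
activation from two-electrode voltage-clamp fluorometry data:

* a Goldman-Hodgkin-Katz (GHK) rectification term multiplied by a Boltzmann
  open-probability term, fitted to leak-corrected current-voltage (I-V)
  points to obtain the conductance-voltage (G-V) parameters
  ``(Gmax, Erev, V_half, k)``;
* the normalized Boltzmann conductance curve ``G(V) = 1/(1+exp(-(V-V_half)/k))``;
* a single-exponential rise for current activation kinetics;
* a double-exponential rise for fluorescence (voltage-sensor) activation
  kinetics, with a fast component carrying most of the amplitude;
* a Boltzmann function fitted to normalized fluorescence-voltage (F-V) points.

All voltages are in mV, currents in uA, conductances in uS and time constants
in ms.  The 25 mV constant in the rectification quotient is the thermal
voltage scale printed in the model equation and is fixed, never fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GVFitResult",
    "FVFitResult",
    "KineticsFit",
    "boltzmann",
    "eval_ghk_boltzmann",
    "gnorm_curve",
    "fit_iv_ghk_boltzmann",
    "fit_boltzmann_fv",
    "fit_single_exp_activation",
    "fit_double_exp_activation",
    "relative_amplitudes",
]

#: thermal voltage scale (mV) of the GHK rectification quotient; a literal of
#: the model equation, not a free parameter.
RECTIFICATION_SLOPE_MV = 25.0

# Default optimizer bounds.  They bracket every physiologically plausible
# K_V fit and keep the 4-parameter I-V fit out of its flat-valley minima.
_GV_BOUNDS = {
    "gmax": (0.0, np.inf),
    "erev": (-120.0, -40.0),
    "v_half": (-100.0, 50.0),
    "k": (1.0, 60.0),
}


@dataclass
class GVFitResult:
    """GHK x Boltzmann fit of an I-V relationship (one cell)."""

    gmax: float
    erev: float
    v_half: float
    k: float
    residual_norm: float
    converged: bool
    rectification_slope: float = RECTIFICATION_SLOPE_MV


@dataclass
class FVFitResult:
    """Boltzmann fit of a normalized F-V relationship (one cell)."""

    v_half: float
    k: float
    residual_norm: float
    converged: bool


@dataclass
class KineticsFit:
    """Exponential activation fit of a current or fluorescence rise.

    ``kind`` is ``"single"`` (current) or ``"double"`` (fluorescence).  For
    double fits the components are ordered so ``tau_fast < tau_slow`` and
    ``fast_amplitude_fraction = A_fast / (A_fast + A_slow)``.
    """

    kind: str
    amplitudes: tuple
    taus: tuple
    offset: float
    residual_norm: float
    converged: bool
    flags: list = field(default_factory=list)

    @property
    def tau_act(self) -> float:
        return self.taus[0]

    @property
    def tau_fast(self) -> float:
        return self.taus[0]

    @property
    def tau_slow(self) -> float:
        return self.taus[-1]

    @property
    def fast_amplitude_fraction(self) -> float:
        if self.kind != "double":
            raise AttributeError("fast_amplitude_fraction is defined for double fits")
        a_f, a_s = self.amplitudes
        return a_f / (a_f + a_s)


def boltzmann(v, v_half: float, k: float):
    """Boltzmann activation curve ``1 / (1 + exp(-(V - V_half)/k))``."""
    if k <= 0:
        raise ValueError(f"slope factor k must be positive, got {k}")
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v - v_half) / k))


def _ghk_quotient(v):
    """``V / (1 - exp(-V/25))`` with the removable singularity at V = 0.

    For |V| < 0.5 mV the denominator is expanded as
    ``1 - e^{-x} = x (1 - x/2 + x^2/6 - x^3/24 + x^4/120)`` with ``x = V/25``,
    so the quotient becomes ``25 / series``; this agrees with the direct
    evaluation to better than 1e-10 at the switchover.
    """
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    small = np.abs(v) < 0.5
    x = v[small] / RECTIFICATION_SLOPE_MV
    series = 1.0 - x / 2.0 + x**2 / 6.0 - x**3 / 24.0 + x**4 / 120.0
    out[small] = RECTIFICATION_SLOPE_MV / series
    vb = v[~small]
    out[~small] = vb / -np.expm1(-vb / RECTIFICATION_SLOPE_MV)
    return out


def eval_ghk_boltzmann(v, gmax: float, erev: float, v_half: float, k: float):
    """Steady-state current of the GHK-rectification x Boltzmann model.

    I(V) = V * Gmax * (1 - e^{-(V-Erev)/25}) / (1 - e^{-V/25})
             * 1 / (1 + e^{-(V-V_half)/k})

    Zero at ``V = Erev`` for any gating parameters; continuous at ``V = 0``.
    """
    if k <= 0:
        raise ValueError(f"slope factor k must be positive, got {k}")
    v = np.asarray(v, dtype=float)
    rect = -np.expm1(-(v - erev) / RECTIFICATION_SLOPE_MV)
    return _ghk_quotient(v) * gmax * rect * boltzmann(v, v_half, k)


def gnorm_curve(fit: GVFitResult, v_grid):
    """Normalized conductance ``G(V) = 1/(1+exp(-(V-V_half)/k))`` of a G-V fit."""
    return boltzmann(v_grid, fit.v_half, fit.k)


def fit_iv_ghk_boltzmann(
    voltages,
    currents,
    init: dict | None = None,
    n_grid_starts: int = 1,
) -> GVFitResult:
    """Fit the GHK x Boltzmann equation to leak-corrected I-V points.

    Parameters
    ----------
    voltages, currents : array-like
        Test potentials (mV) and leak-corrected steady-state/peak currents
        (uA).  At least 6 points spanning sub- and supra-threshold voltages
        are required.
    init : dict, optional
        Initial values for any of ``gmax, erev, v_half, k``; parameters not
        given are initialized from a coarse grid scan.
    n_grid_starts : int
        Number of best grid candidates refined by the optimizer (multi-start
        when > 1); the lowest-cost solution is returned.

    Non-convergence is reported through ``converged=False``, not raised.
    Degenerate data (all currents zero) raises ``ValueError``.
    """
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    if v.size < 6:
        raise ValueError("need at least 6 I-V points for a 4-parameter fit")
    if np.allclose(i, 0.0):
        raise ValueError("all currents are zero; G-V parameters are not identifiable")

    def residuals(p):
        gmax, erev, v_half, k = p
        return eval_ghk_boltzmann(v, gmax, erev, v_half, k) - i

    starts = _gv_grid_starts(v, i, init, n_grid_starts)
    lo = [_GV_BOUNDS[n][0] for n in ("gmax", "erev", "v_half", "k")]
    hi = [_GV_BOUNDS[n][1] for n in ("gmax", "erev", "v_half", "k")]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
        sol = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    gmax, erev, v_half, k = best.x
    return GVFitResult(
        gmax=gmax,
        erev=erev,
        v_half=v_half,
        k=k,
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
    )


def _gv_grid_starts(v, i, init, n_starts):
    """Coarse grid scan over (Erev, V_half, k); Gmax by linear least squares."""
    init = dict(init or {})
    erevs = [init.get("erev")] if "erev" in init else [-110.0, -90.0, -70.0, -50.0]
    v_halves = (
        [init.get("v_half")] if "v_half" in init else list(np.arange(-80.0, 40.1, 10.0))
    )
    ks = [init.get("k")] if "k" in init else [5.0, 10.0, 20.0, 40.0]
    cands = []
    for erev in erevs:
        for v_half in v_halves:
            for k in ks:
                shape = eval_ghk_boltzmann(v, 1.0, erev, v_half, k)
                denom = float(shape @ shape)
                gmax = float(shape @ i) / denom if denom > 0 else 0.0
                gmax = init.get("gmax", max(gmax, 1e-9))
                cost = float(np.sum((gmax * shape - i) ** 2))
                cands.append((cost, [gmax, erev, v_half, k]))
    cands.sort(key=lambda c: c[0])
    return [p for _, p in cands[: max(1, n_starts)]]


def fit_boltzmann_fv(voltages, fnorm, init: dict | None = None) -> FVFitResult:
    """Fit a Boltzmann function to normalized F-V points.

    ``fnorm`` must be normalized to a maximum of 1 (the convention of
    normalizing steady-state fluorescence to the largest obtained value).
    Fewer than 4 points raises; degenerate (constant) data is returned with
    ``converged=False``.
    """
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(fnorm, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 F-V points for a Boltzmann fit")
    if np.ptp(y) < 1e-12:
        return FVFitResult(
            v_half=float(np.mean(v)), k=np.nan, residual_norm=np.nan, converged=False
        )

    def residuals(p):
        return boltzmann(v, p[0], p[1]) - y

    init = dict(init or {})
    # midpoint guess: voltage where the curve crosses 0.5
    order = np.argsort(v)
    v_half0 = init.get("v_half", float(np.interp(0.5, y[order], v[order])))
    k0 = init.get("k", 10.0)
    sol = least_squares(
        residuals, [v_half0, k0], bounds=([-100.0, 1.0], [50.0, 60.0]), method="trf"
    )
    return FVFitResult(
        v_half=float(sol.x[0]),
        k=float(sol.x[1]),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
    )


def fit_single_exp_activation(t_ms, y, offset_init: float | None = None) -> KineticsFit:
    """Fit ``y = I0 (1 - e^{-t/tau}) + C`` to a rising activation segment.

    ``t_ms`` is time from the start of the fitted segment.  A non-rising
    segment is fitted anyway but flagged ``"non_rising"`` with
    ``converged=False`` semantics left to the caller.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(y, dtype=float)
    flags = []
    span = y[-1] - y[0]
    sd = float(np.std(np.diff(y))) / np.sqrt(2.0) if y.size > 2 else 0.0
    if abs(span) <= 3.0 * sd or abs(span) < 1e-15:
        flags.append("non_rising")
    i0_0 = span if span != 0 else 1e-12
    c0 = offset_init if offset_init is not None else float(y[0])
    # time to reach 63% of the span as a tau guess
    frac = (y - y[0]) / i0_0
    above = np.nonzero(frac >= 0.632)[0]
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 3.0

    def residuals(p):
        i0, tau, c = p
        return i0 * -np.expm1(-t / tau) + c - y

    sol = least_squares(
        residuals,
        [i0_0, max(tau0, 1e-3), c0],
        bounds=([-np.inf, 1e-4, -np.inf], [np.inf, 1e5, np.inf]),
        method="trf",
    )
    i0, tau, c = sol.x
    return KineticsFit(
        kind="single",
        amplitudes=(float(i0),),
        taus=(float(tau),),
        offset=float(c),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success) and "non_rising" not in flags,
        flags=flags,
    )


def fit_double_exp_activation(t_ms, y, separation_guard: float = 2.0) -> KineticsFit:
    """Fit ``y = A_f (1-e^{-t/tau_f}) + A_s (1-e^{-t/tau_s}) + C``.

    Initialization: a single-exponential fit supplies ``tau_f``; ``tau_s``
    starts at 5x ``tau_f``; the amplitudes are solved by linear least squares
    given the taus.  After convergence the components are relabeled so
    ``tau_f < tau_s``.  Fits with ``tau_s / tau_f < separation_guard`` are
    flagged ``"poorly_separated"``; a vanishing amplitude is flagged
    ``"degenerate_component"`` (the data are effectively single-exponential).
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(y, dtype=float)
    single = fit_single_exp_activation(t, y)
    tau_f0 = single.tau_act
    tau_s0 = 5.0 * tau_f0
    a_f0, a_s0 = _linear_amplitudes(t, y, tau_f0, tau_s0)

    def residuals(p):
        a_f, tau_f, a_s, tau_s, c = p
        return (
            a_f * -np.expm1(-t / tau_f) + a_s * -np.expm1(-t / tau_s) + c - y
        )

    sol = least_squares(
        residuals,
        [a_f0, tau_f0, a_s0, tau_s0, float(y[0])],
        bounds=(
            [-np.inf, 1e-4, -np.inf, 1e-4, -np.inf],
            [np.inf, 1e5, np.inf, 1e5, np.inf],
        ),
        method="trf",
    )
    a_f, tau_f, a_s, tau_s, c = sol.x
    if tau_f > tau_s:  # relabel so the fast component comes first
        a_f, a_s, tau_f, tau_s = a_s, a_f, tau_s, tau_f
    flags = list(single.flags)
    total = abs(a_f) + abs(a_s)
    if tau_f > 0 and tau_s / tau_f < separation_guard:
        flags.append("poorly_separated")
    if total > 0 and min(abs(a_f), abs(a_s)) / total < 1e-3:
        flags.append("degenerate_component")
    return KineticsFit(
        kind="double",
        amplitudes=(float(a_f), float(a_s)),
        taus=(float(tau_f), float(tau_s)),
        offset=float(c),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        flags=flags,
    )


def _linear_amplitudes(t, y, tau_f, tau_s):
    basis = np.column_stack(
        [-np.expm1(-t / tau_f), -np.expm1(-t / tau_s), np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return float(coef[0]), float(coef[1])


def relative_amplitudes(
    cohort: pd.DataFrame,
    peak_column: str = "peak_I_at_40",
    control_label: str = "control",
) -> pd.DataFrame:
    """Normalize +40 mV peak currents to the daily mean of control cells.

    Each cell's leak-corrected peak at +40 mV is divided by the mean peak of
    the control cells recorded on the same day, removing day-to-day
    variability of expression.  Requires at least one control cell per day;
    a day without controls raises ``ValueError`` naming the day.
    """
    required = {"cell_id", "day_id", "treatment", peak_column}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    out = cohort.copy()
    daily_control = (
        out[out["treatment"] == control_label].groupby("day_id")[peak_column].mean()
    )
    for day in out["day_id"].unique():
        if day not in daily_control.index:
            raise ValueError(f"day {day!r} has no {control_label!r} cells to normalize to")
    out["relative_amplitude"] = out[peak_column] / out["day_id"].map(daily_control)
    return out
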