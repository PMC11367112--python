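"""Synthetic-data generators for every stage of the analysis pipeline.

Because the recordings this package analyzes (two-electrode voltage-clamp
fluorometry sweeps from *Xenopus* oocytes, spectrofluorometry intensity sets
and confocal two-channel cell images) are not publicly deposited, the
generators here produce all of them from known ground-truth parameters.  Every
downstream stage — trace processing, gating fits, probe quantification,
ratiometric imaging, group statistics — is then verifiable by closed-loop
parameter recovery.

The electrophysiology generator is phenomenological, not mechanistic: pulse
currents follow the GHK x Boltzmann steady state with a single-exponential
rise, fluorescence follows a Boltzmann steady state with a double-exponential
rise dominated by a fast component, on top of an ohmic leak, a mono-exponential
photobleaching envelope and Gaussian noise.  No Markov-state or
Hodgkin-Huxley kinetics, and no inactivation, are simulated — the analysis
equations require none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import gating
from .traces import Sweep, SweepSet, VoltageProtocol

__all__ = [
    "VoltageProtocol",
    "GatingGroundTruth",
    "SyntheticCohortConfig",
    "make_default_protocol",
    "default_tau_map",
    "simulate_current_sweep",
    "simulate_fluorescence_sweep",
    "simulate_sweepset",
    "simulate_cohort",
    "simulate_polarized_intensities",
    "simulate_gp_intensities",
    "simulate_ratio_images",
    "RatioImageTruth",
    "RatioImageSet",
]


def make_default_protocol() -> VoltageProtocol:
    """The standard activation protocol: -100 mV holding, 250-ms test pulses
    from -140 to +40 mV in 10 mV steps every 30 s, sampled at 5 kHz."""
    return VoltageProtocol(
        holding_potential=-100.0,
        test_start=-140.0,
        test_end=40.0,
        test_step=10.0,
        pulse_duration=250.0,
        inter_sweep_interval=30.0,
        sample_rate=5000.0,
        pre_pulse_duration=100.0,
        post_pulse_duration=50.0,
    )


def default_tau_map(
    voltages, tau_at_minus10: float, tau_floor: float, v_scale: float = 40.0
) -> dict:
    """Mono-exponentially decreasing tau(V) map (synthetic convention).

    tau(V) = tau_floor + (tau_at_minus10 - tau_floor) * exp(-(V + 10)/v_scale).
    Activation speeds up with depolarization, as observed for K_V channels;
    the exact voltage dependence is a convention of the generator.
    """
    return {
        float(v): tau_floor + (tau_at_minus10 - tau_floor) * math.exp(-(v + 10.0) / v_scale)
        for v in voltages
    }


def _default_voltages():
    return [float(v) for v in range(-140, 41, 10)]


def _default_tau_act():
    return default_tau_map(_default_voltages(), tau_at_minus10=20.0, tau_floor=2.0)


def _default_tau_fast():
    return default_tau_map(_default_voltages(), tau_at_minus10=7.5, tau_floor=1.5, v_scale=50.0)


def _default_tau_slow():
    return {v: 5.0 * tau for v, tau in _default_tau_fast().items()}


@dataclass
class GatingGroundTruth:
    """Ground-truth gating and signal parameters of one simulated cell.

    Defaults describe a healthy control oocyte expressing a K_V1.3-like
    channel: ~5 uA maximal current (Gmax 0.1 uS, Erev -90 mV), G-V midpoint
    -25.4 mV (k 9.6 mV), F-V midpoint -42.5 mV (k 16.8 mV), 2% maximal
    dF/F, and a fast fluorescence component carrying 90% of the amplitude.
    """

    gmax: float = 0.1                 # uS
    erev: float = -90.0               # mV
    v_half_g: float = -25.4           # mV
    k_g: float = 9.6                  # mV
    v_half_f: float = -42.5           # mV
    k_f: float = 16.8                 # mV
    tau_act_by_v: dict = field(default_factory=_default_tau_act)     # ms
    tau_fast_by_v: dict = field(default_factory=_default_tau_fast)   # ms
    tau_slow_by_v: dict = field(default_factory=_default_tau_slow)   # ms
    fast_fraction: float = 0.9        # dimensionless, in (0, 1]
    dff_max: float = 2.0              # maximal steady-state dF/F (%)
    dff_sign: float = 1.0             # +1: fluorescence increases on depolarization
    baseline_fluorescence: float = 1000.0  # a.u.
    leak_conductance: float = 0.002   # uS
    leak_offset: float = 0.0          # uA
    bleach_rate: float = 0.02         # 1/s
    noise_sd_current: float = 0.05    # uA
    noise_sd_fluor: float = 1e-3      # fraction of baseline
    capacitive_amplitude: float = 0.0 # uA; 1-ms edge transient, off by default

    def __post_init__(self):
        if self.k_g <= 0 or self.k_f <= 0:
            raise ValueError("slope factors k_G and k_F must be positive")
        if not 0.0 < self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must lie in (0, 1]")
        if self.gmax < 0:
            raise ValueError("Gmax must be non-negative")
        for name in ("tau_act_by_v", "tau_fast_by_v", "tau_slow_by_v"):
            if any(tau <= 0 for tau in getattr(self, name).values()):
                raise ValueError(f"all time constants in {name} must be positive")
        for v, tau_f in self.tau_fast_by_v.items():
            tau_s = self.tau_slow_by_v.get(v)
            if tau_s is not None and tau_f >= tau_s:
                raise ValueError(f"tau_fast must be < tau_slow at every voltage (V={v})")

    def steady_state_current(self, v):
        """Channel steady-state current (uA) of the GHK x Boltzmann model."""
        return gating.eval_ghk_boltzmann(v, self.gmax, self.erev, self.v_half_g, self.k_g)

    def steady_state_dff(self, v):
        """Steady-state dF/F (%) at test potential ``v``."""
        return self.dff_sign * self.dff_max * gating.boltzmann(v, self.v_half_f, self.k_f)


def _tau_lookup(tau_map: dict, v: float) -> float:
    for key, tau in tau_map.items():
        if abs(key - v) < 1e-6:
            return tau
    raise KeyError(f"no time constant tabulated for test potential {v} mV")


@dataclass
class SyntheticCohortConfig:
    """One simulated treatment group: shared ground truth plus between-cell
    Gaussian variability (``cell_to_cell_sd`` maps parameter name -> SD)."""

    treatment_label: str
    n_cells: int
    ground_truth: GatingGroundTruth
    protocol: VoltageProtocol
    cell_to_cell_sd: dict = field(default_factory=dict)
    seed: int = 0
    day_id: str = "day1"

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _check_sweep_args(gt: GatingGroundTruth, protocol: VoltageProtocol, v: float):
    if protocol.sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    lo, hi = sorted((protocol.test_start, protocol.test_end))
    if not lo - 1e-9 <= v <= hi + 1e-9:
        raise ValueError(f"test potential {v} mV outside protocol range [{lo}, {hi}]")


def simulate_current_sweep(
    gt: GatingGroundTruth,
    protocol: VoltageProtocol,
    v: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate one current sweep (uA) at test potential ``v``.

    The trace is the ohmic leak through the commanded voltage, plus the
    channel current rising single-exponentially to its GHK x Boltzmann steady
    state during the pulse, plus white Gaussian noise.
    """
    _check_sweep_args(gt, protocol, v)
    rng = np.random.default_rng(rng)
    t = protocol.time_ms()
    v_cmd = protocol.voltage_trace(v)
    trace = gt.leak_offset + gt.leak_conductance * v_cmd
    sl = protocol.pulse_slice()
    t_pulse = t[sl] - protocol.pre_pulse_duration
    tau = _tau_lookup(gt.tau_act_by_v, v)
    i_ss = float(gt.steady_state_current(v))
    trace[sl] += i_ss * -np.expm1(-t_pulse / tau)
    if gt.capacitive_amplitude:
        trace += _capacitive_transients(gt, protocol, t)
    if gt.noise_sd_current > 0:
        trace = trace + rng.normal(0.0, gt.noise_sd_current, size=trace.shape)
    return trace


def _capacitive_transients(gt, protocol, t):
    """Optional 1-ms decaying spikes at the pulse edges (off by default)."""
    spike = np.zeros_like(t)
    for edge, sign in (
        (protocol.pre_pulse_duration, 1.0),
        (protocol.pre_pulse_duration + protocol.pulse_duration, -1.0),
    ):
        dt = t - edge
        m = (dt >= 0) & (dt < 5.0)
        spike[m] += sign * gt.capacitive_amplitude * np.exp(-dt[m] / 0.25)
    return spike


def simulate_fluorescence_sweep(
    gt: GatingGroundTruth,
    protocol: VoltageProtocol,
    v: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate one fluorescence sweep (a.u.) at test potential ``v``.

    F(t) = F0 e^{-bleach t} [1 + (dff_ss(V)/100) g(t')] with
    g(t') = f (1 - e^{-t'/tau_f}) + (1 - f)(1 - e^{-t'/tau_s}) during the
    pulse and 0 elsewhere; multiplicative Gaussian noise is applied last.
    """
    _check_sweep_args(gt, protocol, v)
    rng = np.random.default_rng(rng)
    t = protocol.time_ms()
    envelope = gt.baseline_fluorescence * np.exp(-gt.bleach_rate * t / 1000.0)
    g = np.zeros_like(t)
    sl = protocol.pulse_slice()
    t_pulse = t[sl] - protocol.pre_pulse_duration
    tau_f = _tau_lookup(gt.tau_fast_by_v, v)
    tau_s = _tau_lookup(gt.tau_slow_by_v, v)
    f = gt.fast_fraction
    g[sl] = f * -np.expm1(-t_pulse / tau_f) + (1.0 - f) * -np.expm1(-t_pulse / tau_s)
    trace = envelope * (1.0 + gt.steady_state_dff(v) / 100.0 * g)
    if gt.noise_sd_fluor > 0:
        trace = trace * (1.0 + rng.normal(0.0, gt.noise_sd_fluor, size=trace.shape))
    return trace


def simulate_sweepset(
    gt: GatingGroundTruth,
    protocol: VoltageProtocol,
    cell_id: str = "cell",
    treatment_label: str = "control",
    day_id: str = "day1",
    rng: np.random.Generator | int | None = None,
) -> SweepSet:
    """Simulate the full two-channel sweep set of one cell."""
    rng = np.random.default_rng(rng)
    t = protocol.time_ms()
    sweeps = []
    for v in protocol.test_potentials():
        current = simulate_current_sweep(gt, protocol, v, rng)
        fluor = simulate_fluorescence_sweep(gt, protocol, v, rng)
        sweeps.append(Sweep(test_potential=v, time_ms=t, current_ua=current,
                            fluorescence_au=fluor))
    return SweepSet(
        cell_id=cell_id,
        treatment_label=treatment_label,
        day_id=day_id,
        protocol=protocol,
        sweeps=sweeps,
        metadata={"ground_truth": _gt_metadata(gt)},
    )


_PERTURBABLE_BOUNDS = {
    # truncation ranges keeping each perturbed parameter physically valid
    "gmax": (1e-4, np.inf),
    "erev": (-120.0, -40.0),
    "v_half_g": (-100.0, 50.0),
    "k_g": (1.0, 60.0),
    "v_half_f": (-100.0, 50.0),
    "k_f": (1.0, 60.0),
    "fast_fraction": (0.5, 1.0),
    "dff_max": (0.1, np.inf),
    "leak_conductance": (0.0, np.inf),
    "bleach_rate": (0.0, np.inf),
}


def perturb_ground_truth(
    gt: GatingGroundTruth, cell_to_cell_sd: dict, rng: np.random.Generator
) -> GatingGroundTruth:
    """Draw one cell's parameters: independent Gaussian perturbations,
    truncated (by redrawing) to each parameter's valid range."""
    updates = {}
    for name, sd in cell_to_cell_sd.items():
        if name not in _PERTURBABLE_BOUNDS:
            raise KeyError(f"unknown perturbable parameter {name!r}")
        lo, hi = _PERTURBABLE_BOUNDS[name]
        mean = getattr(gt, name)
        for _ in range(100):
            value = rng.normal(mean, sd)
            if lo <= value <= hi:
                break
        else:
            value = float(np.clip(mean, lo, hi))
        updates[name] = float(value)
    return replace(gt, **updates)


def simulate_cohort(config: SyntheticCohortConfig) -> list[SweepSet]:
    """Simulate ``n_cells`` sweep sets for one treatment group.

    Per-cell parameters are drawn around the group ground truth with the
    configured between-cell SDs.  The true per-cell parameters and the seed
    are stored in each sweep set's metadata; identical configs (same seed)
    produce bit-identical output.
    """
    root = np.random.SeedSequence(config.seed)
    cells = []
    for idx, child in enumerate(root.spawn(config.n_cells)):
        rng = np.random.default_rng(child)
        cell_gt = perturb_ground_truth(config.ground_truth, config.cell_to_cell_sd, rng)
        ss = simulate_sweepset(
            cell_gt,
            config.protocol,
            cell_id=f"{config.treatment_label}_{idx:03d}",
            treatment_label=config.treatment_label,
            day_id=config.day_id,
            rng=rng,
        )
        ss.metadata["cohort_seed"] = config.seed
        cells.append(ss)
    return cells


def _gt_metadata(gt: GatingGroundTruth) -> dict:
    d = asdict(gt)
    for name in ("tau_act_by_v", "tau_fast_by_v", "tau_slow_by_v"):
        d[name] = {str(k): v for k, v in d[name].items()}
    return d


# ---------------------------------------------------------------------------
# spectrofluorometry generators (analytic inversions of the probe formulas)
# ---------------------------------------------------------------------------

def simulate_polarized_intensities(
    r_true: float,
    g_true: float,
    total_intensity: float = 4e5,
    noise_sd: float = 0.005,
    n: int = 9,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Generate L-format polarized-intensity quadruples with known anisotropy.

    Inverts the anisotropy formula r = (Ivv - G Ivh)/(Ivv + 2 G Ivh): with
    u = Ivv/(G Ivh) = (1 + 2r)/(1 - r), the quadruple (Ivv, Ivh, Ihv, Ihh)
    reproduces ``r_true`` and the instrument factor ``g_true = Ihv/Ihh``
    exactly at zero noise.  Noise is multiplicative Gaussian per intensity.
    """
    if not -0.5 < r_true < 1.0:
        raise ValueError("r_true must lie in (-0.5, 1)")
    if g_true <= 0:
        raise ValueError("G factor must be positive")
    rng = np.random.default_rng(rng)
    u = (1.0 + 2.0 * r_true) / (1.0 - r_true)
    ihh = total_intensity / 4.0
    ihv = g_true * ihh
    ivh = total_intensity / 4.0
    ivv = u * g_true * ivh
    base = np.tile([ivv, ivh, ihv, ihh], (n, 1))
    if noise_sd > 0:
        base = base * (1.0 + rng.normal(0.0, noise_sd, size=base.shape))
    base = np.abs(base)  # intensities stay positive
    return pd.DataFrame(base, columns=["Ivv", "Ivh", "Ihv", "Ihh"]).assign(
        sample_id=[f"s{i:02d}" for i in range(n)]
    )


def simulate_gp_intensities(
    gp_true: float,
    total_intensity: float = 2e5,
    noise_sd: float = 0.01,
    n: int = 9,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Generate (I_blue, I_red) emission pairs with known generalized
    polarization: I_blue/I_red = (1 + GP)/(1 - GP), multiplicative noise."""
    if not -1.0 < gp_true < 1.0:
        raise ValueError("gp_true must lie in (-1, 1)")
    rng = np.random.default_rng(rng)
    i_blue = total_intensity * (1.0 + gp_true) / 2.0
    i_red = total_intensity * (1.0 - gp_true) / 2.0
    base = np.tile([i_blue, i_red], (n, 1))
    if noise_sd > 0:
        base = base * (1.0 + rng.normal(0.0, noise_sd, size=base.shape))
    base = np.abs(base)
    return pd.DataFrame(base, columns=["I_blue", "I_red"]).assign(
        sample_id=[f"s{i:02d}" for i in range(n)]
    )


# ---------------------------------------------------------------------------
# ratiometric two-channel image generator
# ---------------------------------------------------------------------------

@dataclass
class RatioImageTruth:
    """Ground truth of one synthetic image pair."""

    ratio_true: float
    background_level: float
    label_mask: np.ndarray
    membrane_mask: np.ndarray
    centers: list
    radii: list


@dataclass
class RatioImageSet:
    """Two-excitation-channel image pair with seed points.

    ``channel_blue`` is the 458-nm-excitation image and ``channel_red`` the
    514-nm one; the dipole-sensitive excitation ratio is blue/red.  ``seeds``
    is a list of ``(row, col, kind)`` with kind ``"cell"`` or ``"background"``
    (0-based pixel coordinates).  ``truth`` is populated by the generator.
    """

    channel_blue: np.ndarray
    channel_red: np.ndarray
    seeds: list
    truth: RatioImageTruth | None = None


def simulate_ratio_images(
    ratio_true: float,
    n_cells: int = 35,
    image_size: tuple = (512, 512),
    membrane_width_px: float = 3.0,
    background_level: float = 50.0,
    noise_sd: float = 3.0,
    rng: np.random.Generator | int | None = None,
    membrane_amplitude: float = 600.0,
    interior_fraction: float = 0.1,
    radius_range: tuple = (15.0, 30.0),
) -> RatioImageSet:
    """Simulate a midplane two-channel image of ring-stained cells.

    Cells are non-overlapping circles; the membrane ring has a radial Gaussian
    intensity profile (sigma = membrane_width_px / 2) peaking at
    ``membrane_amplitude`` counts in the red channel, and the blue channel is
    ``ratio_true`` times the red everywhere above background, so the pixelwise
    background-subtracted blue/red ratio is ``ratio_true`` on the membrane.
    Interiors carry a faint haze (``interior_fraction`` of the membrane
    amplitude) with the same channel ratio.  One interior seed per cell plus
    background seeds are emitted; ground-truth label and membrane masks are
    attached as ``truth``.
    """
    if ratio_true <= 0:
        raise ValueError("ratio_true must be positive")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(rng)
    h, w = image_size
    centers, radii = _place_cells(rng, n_cells, h, w, radius_range)

    red = np.full((h, w), float(background_level))
    labels = np.zeros((h, w), dtype=int)
    membrane = np.zeros((h, w), dtype=bool)
    sigma = membrane_width_px / 2.0
    for idx, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        pad = int(math.ceil(r + 4 * sigma))
        y0, y1 = max(0, cy - pad), min(h, cy + pad + 1)
        x0, x1 = max(0, cx - pad), min(w, cx + pad + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(yy - cy, xx - cx)
        ring = membrane_amplitude * np.exp(-((d - r) ** 2) / (2.0 * sigma**2))
        interior = (d < r) * interior_fraction * membrane_amplitude
        red[y0:y1, x0:x1] += ring + interior
        labels[y0:y1, x0:x1][d <= r] = idx  # label disk extends to the ring crest
        membrane[y0:y1, x0:x1] |= np.abs(d - r) <= membrane_width_px / 2.0
    blue = background_level + ratio_true * (red - background_level)
    if noise_sd > 0:
        blue = blue + rng.normal(0.0, noise_sd, size=blue.shape)
        red = red + rng.normal(0.0, noise_sd, size=red.shape)

    seeds = [(cy, cx, "cell") for cy, cx in centers]
    seeds += _background_seeds(labels, h, w, max(radius_range))
    truth = RatioImageTruth(
        ratio_true=ratio_true,
        background_level=background_level,
        label_mask=labels,
        membrane_mask=membrane,
        centers=centers,
        radii=radii,
    )
    return RatioImageSet(channel_blue=blue, channel_red=red, seeds=seeds, truth=truth)


def _place_cells(rng, n_cells, h, w, radius_range, max_tries=20000):
    """Rejection-sample non-overlapping circle centers; raise if impossible."""
    centers, radii = [], []
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise ValueError(
                f"could only place {len(centers)} of {n_cells} cells in a "
                f"{h}x{w} image without overlap"
            )
        tries += 1
        r = rng.uniform(*radius_range)
        margin = r + 4.0
        cy = rng.integers(int(margin), int(h - margin))
        cx = rng.integers(int(margin), int(w - margin))
        if all(np.hypot(cy - y, cx - x) > r + rr + 4.0 for (y, x), rr in zip(centers, radii)):
            centers.append((int(cy), int(cx)))
            radii.append(float(r))
    return centers, radii


def _background_seeds(labels, h, w, max_radius):
    """Background seed points away from every cell (corners, then fallback)."""
    guard = int(max_radius + 8)
    candidates = [
        (8, 8), (8, w - 9), (h - 9, 8), (h - 9, w - 9), (h // 2, 8), (8, w // 2),
    ]
    seeds = [(r, c, "background") for r, c in candidates if labels[r, c] == 0]
    if not seeds:  # dense image: scan for any free pixel
        free = np.argwhere(labels == 0)
        if free.size:
            r, c = free[0]
            seeds = [(int(r), int(c), "background")]
    return seeds
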