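"""Raw two-channel sweep processing: filtering, leak and bleach corrections,
dF/F computation and per-sweep summary points.

A :class:`SweepSet` holds the time-aligned current and fluorescence traces of
one cell across the voltage protocol.  :func:`process_sweepset` turns it into
a :class:`ProcessedSweepSet` carrying leak-corrected currents, bleach-corrected
dF/F traces (in percent), and the per-sweep summary points used by the gating
fits: the leak-corrected peak current and the steady-state dF/F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "VoltageProtocol",
    "Sweep",
    "SweepSet",
    "ProcessingConfig",
    "ProcessedSweepSet",
    "gaussian_filter_trace",
    "estimate_leak",
    "subtract_leak",
    "correct_photobleach",
    "compute_dff",
    "extract_peak_current",
    "extract_steady_state_dff",
    "process_sweepset",
]


@dataclass(frozen=True)
class VoltageProtocol:
    """Step-depolarization protocol of a voltage-clamp experiment.

    All voltages in mV, durations in ms, the inter-sweep interval in s and
    the sample rate in Hz.
    """

    holding_potential: float
    test_start: float
    test_end: float
    test_step: float
    pulse_duration: float
    inter_sweep_interval: float
    sample_rate: float
    pre_pulse_duration: float = 100.0
    post_pulse_duration: float = 50.0

    def __post_init__(self):
        if self.test_step <= 0:
            raise ValueError("test_step must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        span = self.test_end - self.test_start
        n = span / self.test_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(test_end - test_start) must be divisible by test_step")

    @property
    def n_sweeps(self) -> int:
        return int(round((self.test_end - self.test_start) / self.test_step)) + 1

    def test_potentials(self) -> list[float]:
        return [self.test_start + i * self.test_step for i in range(self.n_sweeps)]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    @property
    def pulse_samples(self) -> int:
        return int(round(self.pulse_duration / self.dt_ms))

    @property
    def n_samples(self) -> int:
        total = self.pre_pulse_duration + self.pulse_duration + self.post_pulse_duration
        return int(round(total / self.dt_ms))

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def pulse_slice(self) -> slice:
        start = int(round(self.pre_pulse_duration / self.dt_ms))
        return slice(start, start + self.pulse_samples)

    def voltage_trace(self, test_potential: float) -> np.ndarray:
        v = np.full(self.n_samples, self.holding_potential)
        v[self.pulse_slice()] = test_potential
        return v


@dataclass
class Sweep:
    """One test-potential sweep: time base plus the two recorded channels."""

    test_potential: float
    time_ms: np.ndarray
    current_ua: np.ndarray
    fluorescence_au: np.ndarray


@dataclass
class SweepSet:
    """All sweeps of one cell, ordered by increasing test potential."""

    cell_id: str
    treatment_label: str
    day_id: str
    protocol: VoltageProtocol
    sweeps: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        pots = [s.test_potential for s in self.sweeps]
        if any(b <= a for a, b in zip(pots, pots[1:])):
            raise ValueError("sweeps must be ordered by strictly increasing test potential")
        lengths = {len(s.current_ua) for s in self.sweeps} | {
            len(s.fluorescence_au) for s in self.sweeps
        }
        if len(lengths) > 1:
            raise ValueError("all sweeps must share the same sample count")

    def sweep_at(self, test_potential: float) -> Sweep:
        for s in self.sweeps:
            if abs(s.test_potential - test_potential) < 1e-6:
                return s
        raise KeyError(f"no sweep at {test_potential} mV")


def gaussian_filter_trace(trace, cutoff_hz: float, sample_rate_hz: float) -> np.ndarray:
    """Zero-phase Gaussian low-pass filter with its -3 dB point at ``cutoff_hz``.

    The kernel SD is chosen from the Gaussian's continuous frequency response
    ``H(f) = exp(-2 pi^2 f^2 sigma_t^2)``: setting ``H(f_c) = 10^{-3/20}``
    gives ``sigma_t = sqrt((3/20) ln 10 / 2) / (pi f_c)``.  DC gain is 1 and
    the output length equals the input length (edge handling by nearest-value
    extension).
    """
    if not 0 < cutoff_hz < sample_rate_hz / 2.0:
        raise ValueError("cutoff must lie strictly between 0 and the Nyquist frequency")
    sigma_t = math.sqrt(0.15 * math.log(10.0) / 2.0) / (math.pi * cutoff_hz)
    sigma_samples = sigma_t * sample_rate_hz
    return gaussian_filter1d(np.asarray(trace, dtype=float), sigma_samples, mode="nearest")


class InsufficientLeakDataError(ValueError):
    """Fewer than two sweeps fall inside the leak-fit voltage range."""


def estimate_leak(
    sweepset: SweepSet,
    fit_voltage_range: tuple = (-140.0, -80.0),
    exclusion_margin_ms: float = 2.0,
) -> tuple:
    """Estimate the ohmic leak from subthreshold sweeps.

    Fits an ordinary least-squares line through (test potential, mean pulse
    current) over the sweeps whose test potential lies in
    ``fit_voltage_range`` — voltages at which the channel's open probability
    is negligible, so the pulse current is leak only.  Returns
    ``(offset_uA, conductance_uS)``.
    """
    lo, hi = sorted(fit_voltage_range)
    sl = sweepset.protocol.pulse_slice()
    skip = int(round(exclusion_margin_ms / sweepset.protocol.dt_ms))
    points = [
        (s.test_potential, float(np.mean(s.current_ua[sl][skip:])))
        for s in sweepset.sweeps
        if lo - 1e-9 <= s.test_potential <= hi + 1e-9
    ]
    if len(points) < 2:
        raise InsufficientLeakDataError(
            f"need >=2 sweeps in [{lo}, {hi}] mV for the leak fit, found {len(points)}"
        )
    v = np.array([p[0] for p in points])
    i = np.array([p[1] for p in points])
    conductance, offset = np.polyfit(v, i, 1)
    return float(offset), float(conductance)


def subtract_leak(sweepset: SweepSet, leak_params: tuple) -> list[np.ndarray]:
    """Subtract the ohmic leak sample-by-sample using the commanded voltage.

    corrected(t) = raw(t) - (offset + conductance * V_cmd(t)).
    """
    offset, conductance = leak_params
    if not (np.isfinite(offset) and np.isfinite(conductance)):
        raise ValueError("leak parameters must be finite")
    out = []
    for s in sweepset.sweeps:
        v_cmd = sweepset.protocol.voltage_trace(s.test_potential)
        out.append(s.current_ua - (offset + conductance * v_cmd))
    return out


def correct_photobleach(
    fluor_trace, baseline_trace, prepulse_window: slice
) -> np.ndarray:
    """Remove the photobleaching envelope using a no-signal baseline sweep.

    The baseline trace (recorded at a test potential evoking no
    voltage-dependent fluorescence change, by default the most hyperpolarized
    sweep) is subtracted and its pre-pulse mean added back, so the corrected
    trace keeps an absolute baseline level and dF/F denominators remain
    meaningful.
    """
    trace = np.asarray(fluor_trace, dtype=float)
    baseline = np.asarray(baseline_trace, dtype=float)
    if trace.shape != baseline.shape:
        raise ValueError("fluorescence and baseline traces must have the same length")
    return trace - baseline + float(np.mean(baseline[prepulse_window]))


def compute_dff(corrected_trace, baseline_window: slice) -> np.ndarray:
    """dF/F in percent: ``100 (F(t) - F) / F`` with F the pre-pulse baseline mean."""
    trace = np.asarray(corrected_trace, dtype=float)
    f0 = float(np.mean(trace[baseline_window]))
    if f0 <= 0:
        raise ValueError(f"baseline fluorescence must be positive, got {f0}")
    return 100.0 * (trace - f0) / f0


def extract_peak_current(
    corrected_current,
    pulse_window: slice,
    exclusion_margin_samples: int = 0,
) -> float:
    """Signed extremum of the (filtered, leak-corrected) current within the
    pulse window, excluding the capacitive-transient margin at pulse onset."""
    trace = np.asarray(corrected_current, dtype=float)
    seg = trace[pulse_window][exclusion_margin_samples:]
    return float(seg[np.argmax(np.abs(seg))])


def extract_steady_state_dff(
    dff_trace, pulse_window: slice, steady_fraction: float = 0.1
) -> float:
    """Mean dF/F over the final ``steady_fraction`` of the pulse window."""
    seg = np.asarray(dff_trace, dtype=float)[pulse_window]
    n_tail = max(1, int(round(steady_fraction * seg.size)))
    return float(np.mean(seg[-n_tail:]))


@dataclass
class ProcessingConfig:
    """Windows and options of the trace-processing stage.

    Defaults: 1 kHz Gaussian filtering of the current channel, leak fitted
    over -140..-80 mV, the first 2 ms of each pulse excluded from peaks and
    fits, a 50-ms pre-pulse baseline window for F, the most hyperpolarized
    sweep as the bleach-correction baseline, and the final 10% of the pulse
    as the steady-state window.

    ``peak_measurement_hz`` is an additional narrow-band Gaussian smoothing
    applied only when picking the per-sweep peak: for a non-inactivating
    current the peak sits on the steady plateau, which a 100 Hz measurement
    bandwidth preserves while suppressing the upward bias an extremum search
    would otherwise take from wide-band noise.  Kinetics fits always use the
    full ``filter_cutoff_hz`` traces.
    """

    filter_cutoff_hz: float | None = 1000.0
    peak_measurement_hz: float | None = 100.0
    leak_fit_range: tuple = (-140.0, -80.0)
    exclusion_margin_ms: float = 2.0
    baseline_window_ms: float = 50.0
    steady_fraction: float = 0.1
    bleach_baseline_potential: float | None = None  # None: most hyperpolarized sweep
    known_leak: tuple | None = None  # (offset, conductance): skip estimation


@dataclass
class ProcessedSweepSet:
    """Leak- and bleach-corrected traces plus per-sweep summary points."""

    parent: SweepSet
    leak_params: tuple
    corrected_current: list
    dff: list
    peak_current: np.ndarray
    steady_state_dff: np.ndarray
    config: ProcessingConfig

    @property
    def test_potentials(self) -> np.ndarray:
        return np.array([s.test_potential for s in self.parent.sweeps])

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test_potential_mV": self.test_potentials,
                "peak_current_uA": self.peak_current,
                "steady_state_dff_pct": self.steady_state_dff,
            }
        )


def process_sweepset(
    sweepset: SweepSet, config: ProcessingConfig | None = None
) -> ProcessedSweepSet:
    """Run the full per-cell processing chain.

    Current channel: optional Gaussian filtering, ohmic leak estimation over
    the subthreshold range and sample-wise subtraction, then per-sweep peak
    extraction.  Fluorescence channel: photobleach correction against the
    baseline sweep, dF/F conversion against the pre-pulse window, then
    steady-state extraction over the final window.
    """
    cfg = config or ProcessingConfig()
    protocol = sweepset.protocol
    pulse = protocol.pulse_slice()
    margin = int(round(cfg.exclusion_margin_ms / protocol.dt_ms))
    n_base = int(round(cfg.baseline_window_ms / protocol.dt_ms))
    baseline_window = slice(max(0, pulse.start - n_base), pulse.start)

    filtered = sweepset
    if cfg.filter_cutoff_hz is not None:
        filtered = SweepSet(
            cell_id=sweepset.cell_id,
            treatment_label=sweepset.treatment_label,
            day_id=sweepset.day_id,
            protocol=protocol,
            sweeps=[
                Sweep(
                    test_potential=s.test_potential,
                    time_ms=s.time_ms,
                    current_ua=gaussian_filter_trace(
                        s.current_ua, cfg.filter_cutoff_hz, protocol.sample_rate
                    ),
                    fluorescence_au=s.fluorescence_au,
                )
                for s in sweepset.sweeps
            ],
            metadata=sweepset.metadata,
        )

    leak = cfg.known_leak
    if leak is None:
        leak = estimate_leak(filtered, cfg.leak_fit_range, cfg.exclusion_margin_ms)
    corrected = subtract_leak(filtered, leak)

    base_v = cfg.bleach_baseline_potential
    if base_v is None:
        base_v = min(s.test_potential for s in sweepset.sweeps)
    baseline_trace = sweepset.sweep_at(base_v).fluorescence_au

    dff_traces, peaks, ss_dff = [], [], []
    for s, cur in zip(sweepset.sweeps, corrected):
        debleached = correct_photobleach(s.fluorescence_au, baseline_trace, baseline_window)
        dff = compute_dff(debleached, baseline_window)
        dff_traces.append(dff)
        peak_trace = cur
        if cfg.peak_measurement_hz is not None:
            peak_trace = gaussian_filter_trace(
                cur, cfg.peak_measurement_hz, protocol.sample_rate
            )
        peaks.append(extract_peak_current(peak_trace, pulse, margin))
        ss_dff.append(extract_steady_state_dff(dff, pulse, cfg.steady_fraction))
    return ProcessedSweepSet(
        parent=sweepset,
        leak_params=leak,
        corrected_current=corrected,
        dff=dff_traces,
        peak_current=np.array(peaks),
        steady_state_dff=np.array(ss_dff),
        config=cfg,
    )
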