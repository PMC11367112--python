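"""Reference study conditions for a ceramide / glucosylceramide modulation study.

This module encodes, as generator ground truths, the group-level parameters of
a three-arm lipid-loading study on a K_V1.3-like channel: untreated control
cells, C16-ceramide (Cer) loaded cells, and C16-glucosylceramide (GlcCer)
loaded cells.  Ceramide shifts both the conductance-voltage (G-V) and the
fluorescence-voltage (F-V) activation midpoints rightward and lowers current
amplitudes; glucosylceramide shifts only the G-V midpoint; both lipids raise
membrane anisotropy and generalized polarization, and they move the
dipole-potential excitation ratio in opposite directions.

Each closed-loop ``recover_*`` function simulates cohorts at these ground
truths (between-cell SDs chosen so the simulated cohort SEM matches the
stated group SEM, i.e. SD = SEM * sqrt(n)), runs the full analysis pipeline,
and returns the recovered group statistic — the package's primary
self-validation: the pipeline must give back what the generator put in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import gating, imaging, probes
from .pipeline import analyze_cohort
from .synthetic import (
    GatingGroundTruth,
    SyntheticCohortConfig,
    make_default_protocol,
    simulate_cohort,
    simulate_gp_intensities,
    simulate_polarized_intensities,
    simulate_ratio_images,
)

__all__ = [
    "GroupGatingParams",
    "GATING_CONDITIONS",
    "AMPLITUDE_CONDITIONS",
    "ANISOTROPY_CONDITIONS",
    "GP_CONDITIONS",
    "IMAGING_CONDITIONS",
    "cohort_config",
    "recover_gating_midpoints",
    "recover_relative_amplitude",
    "recover_anisotropy_mean",
    "recover_gp_mean",
    "recover_imaging_ratio_mean",
]


@dataclass(frozen=True)
class GroupGatingParams:
    """Group mean +/- SEM of the Boltzmann midpoints and slopes, with group size."""

    n: int
    v_half_f: float
    sem_v_half_f: float
    k_f: float
    sem_k_f: float
    v_half_g: float
    sem_v_half_g: float
    k_g: float
    sem_k_g: float


#: steady-state activation parameters per condition (mV; mean +/- SEM over cells)
GATING_CONDITIONS = {
    "control": GroupGatingParams(12, -42.5, 1.0, 16.8, 0.4, -25.4, 1.2, 9.6, 0.5),
    "cer": GroupGatingParams(10, -35.7, 0.9, 17.7, 0.4, -17.1, 1.3, 11.5, 0.9),
    "glccer": GroupGatingParams(11, -42.7, 0.7, 17.4, 0.4, -18.2, 1.9, 9.8, 0.5),
}

#: relative +40 mV current amplitude (vs daily control mean): (mean, sem, n)
AMPLITUDE_CONDITIONS = {
    "control": (1.000, 0.041, 14),
    "cer": (0.637, 0.036, 12),
    "glccer": (0.707, 0.044, 12),
}

#: TMA-DPH-type fluorescence anisotropy ground truths: (mean, sem, n)
ANISOTROPY_CONDITIONS = {
    "control": (0.283, 0.002, 9),
    "cer": (0.300, 0.002, 9),
    "glccer": (0.295, 0.002, 9),
}

#: Laurdan-type generalized polarization ground truths: (mean, sem, n)
GP_CONDITIONS = {
    "control": (0.182, 0.002, 9),
    "cer": (0.202, 0.003, 9),
    "glccer": (0.192, 0.003, 9),
}

#: membrane dipole-potential excitation ratio ground truths: (mean, sem, n images)
IMAGING_CONDITIONS = {
    "control": (0.620, 0.003, 20),
    "cer": (0.598, 0.003, 20),
    "glccer": (0.647, 0.003, 20),
}


def cohort_config(condition: str, seed: int, n_cells: int | None = None) -> SyntheticCohortConfig:
    """Cohort configuration for one condition's voltage-clamp fluorometry arm.

    Between-cell SDs of the four Boltzmann parameters are set to
    ``SEM * sqrt(n)`` so the simulated cohort reproduces the stated SEMs;
    maximal conductance varies with the CV implied by the relative-amplitude
    spread, scaled by the condition's mean relative amplitude.
    """
    g = GATING_CONDITIONS[condition]
    amp_mean, amp_sem, amp_n = AMPLITUDE_CONDITIONS[condition]
    n = n_cells if n_cells is not None else g.n
    base = GatingGroundTruth()
    gt = replace(
        base,
        v_half_f=g.v_half_f,
        k_f=g.k_f,
        v_half_g=g.v_half_g,
        k_g=g.k_g,
        gmax=base.gmax * amp_mean,
    )
    sd = {
        "v_half_f": g.sem_v_half_f * np.sqrt(g.n),
        "k_f": g.sem_k_f * np.sqrt(g.n),
        "v_half_g": g.sem_v_half_g * np.sqrt(g.n),
        "k_g": g.sem_k_g * np.sqrt(g.n),
        "gmax": base.gmax * amp_sem * np.sqrt(amp_n),
    }
    return SyntheticCohortConfig(
        treatment_label=condition,
        n_cells=n,
        ground_truth=gt,
        protocol=make_default_protocol(),
        cell_to_cell_sd=sd,
        seed=seed,
    )


def recover_gating_midpoints(condition: str, seed: int) -> dict:
    """Simulate one cohort and recover the mean F-V and G-V midpoints (mV).

    Full pipeline: sweep simulation, filtering, leak and bleach corrections,
    per-sweep summary extraction, per-cell GHK x Boltzmann I-V and Boltzmann
    F-V fits, then the cohort means.
    """
    cells = simulate_cohort(cohort_config(condition, seed))
    table = analyze_cohort(cells, normalize_amplitudes=False)
    return {
        "v_half_f": float(table["v_half_f"].mean()),
        "v_half_g": float(table["v_half_g"].mean()),
        "k_f": float(table["k_f"].mean()),
        "k_g": float(table["k_g"].mean()),
        "n": len(table),
    }


def recover_relative_amplitude(seed: int, treated: str = "cer") -> dict:
    """Day-structured amplitude experiment: controls plus one treated group.

    Simulates one recording day with the stated group sizes, the treated
    group's Gmax scaled by its mean relative amplitude; runs leak correction,
    +40 mV peak extraction and daily-control normalization, and returns the
    treated group's mean relative amplitude.
    """
    _, _, n_control = AMPLITUDE_CONDITIONS["control"]
    _, _, n_treated = AMPLITUDE_CONDITIONS[treated]
    root = np.random.SeedSequence(seed)
    s_ctrl, s_trt = (int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(2))
    cells = simulate_cohort(cohort_config("control", s_ctrl, n_cells=n_control))
    cells += simulate_cohort(cohort_config(treated, s_trt, n_cells=n_treated))
    table = analyze_cohort(cells, normalize_amplitudes=True)
    treated_mean = float(
        table.loc[table["treatment"] == treated, "relative_amplitude"].mean()
    )
    control_mean = float(
        table.loc[table["treatment"] == "control", "relative_amplitude"].mean()
    )
    return {"treated_mean": treated_mean, "control_mean": control_mean,
            "n": n_treated}


def recover_anisotropy_mean(
    condition: str, seed: int, g_factor_true: float = 1.1, noise_sd: float = 0.005
) -> dict:
    """Generate polarized quadruples at the condition's anisotropy and recover
    the group mean through the G-factor and L-format anisotropy formulas."""
    r_true, _, n = ANISOTROPY_CONDITIONS[condition]
    quads = simulate_polarized_intensities(
        r_true, g_factor_true, noise_sd=noise_sd, n=n, rng=np.random.default_rng(seed)
    )
    values = probes.anisotropy_from_quadruples(quads)
    return {"mean": float(values.mean()), "n": n}


def recover_gp_mean(condition: str, seed: int, noise_sd: float = 0.01) -> dict:
    """Generate emission pairs at the condition's GP and recover the group mean."""
    gp_true, _, n = GP_CONDITIONS[condition]
    pairs = simulate_gp_intensities(
        gp_true, noise_sd=noise_sd, n=n, rng=np.random.default_rng(seed)
    )
    values = probes.gp_from_pairs(pairs)
    return {"mean": float(values.mean()), "n": n}


def recover_imaging_ratio_mean(
    condition: str,
    seed: int,
    n_images: int | None = None,
    rng_cells=(30, 41),
    background_level: float = 50.0,
    noise_sd: float = 3.0,
) -> dict:
    """Simulate image pairs at the condition's excitation ratio and recover the
    mean of per-image mean membrane ratios through the full imaging pipeline
    (seeded watershed, membrane band, background subtraction, pixel ratios)."""
    ratio_true, _, n_default = IMAGING_CONDITIONS[condition]
    n_images = n_images if n_images is not None else n_default
    root = np.random.SeedSequence(seed)
    means = []
    for child in root.spawn(n_images):
        rng = np.random.default_rng(child)
        n_cells = int(rng.integers(*rng_cells))
        image = simulate_ratio_images(
            ratio_true,
            n_cells=n_cells,
            background_level=background_level,
            noise_sd=noise_sd,
            rng=rng,
        )
        _, result = imaging.analyze_ratio_image(image)
        means.append(result.mean_ratio)
    return {"mean": float(np.mean(means)), "n": n_images}
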