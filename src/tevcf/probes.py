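"""Membrane-probe spectroscopy: fluorescence anisotropy and generalized
polarization.

Fluorescence anisotropy of a membrane-partitioning rod-like probe (e.g.
TMA-DPH) reports rotational freedom and hence membrane fluidity; it is
measured in the L-format from polarized intensity components with an
instrument G factor.  Generalized polarization (GP) of a solvatochromic probe
(e.g. Laurdan) reports water penetration into the bilayer from the normalized
two-band emission ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "g_factor",
    "anisotropy",
    "generalized_polarization",
    "anisotropy_from_quadruples",
    "gp_from_pairs",
    "batch_probe_summary",
]


def g_factor(i_hv, i_hh):
    """Instrument correction factor ``G = I_hv / I_hh`` (horizontal excitation)."""
    i_hv = np.asarray(i_hv, dtype=float)
    i_hh = np.asarray(i_hh, dtype=float)
    if np.any(i_hh <= 0):
        raise ValueError("I_hh must be positive")
    return i_hv / i_hh


def anisotropy(i_vv, i_vh, g):
    """Steady-state fluorescence anisotropy ``r = (Ivv - G Ivh)/(Ivv + 2 G Ivh)``.

    For positive intensities and G > 0 the value lies in (-0.5, 1]."""
    i_vv = np.asarray(i_vv, dtype=float)
    i_vh = np.asarray(i_vh, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("G factor must be positive")
    denom = i_vv + 2.0 * g * i_vh
    if np.any(denom <= 0):
        raise ValueError("anisotropy denominator Ivv + 2 G Ivh must be positive")
    return (i_vv - g * i_vh) / denom


def generalized_polarization(i_blue, i_red):
    """``GP = (I_blue - I_red)/(I_blue + I_red)``, in [-1, 1] for non-negative
    intensities."""
    i_blue = np.asarray(i_blue, dtype=float)
    i_red = np.asarray(i_red, dtype=float)
    total = i_blue + i_red
    if np.any(total <= 0):
        raise ValueError("total emission intensity must be positive")
    return (i_blue - i_red) / total


def anisotropy_from_quadruples(quadruples: pd.DataFrame) -> pd.Series:
    """Per-sample anisotropy from a table with columns Ivv, Ivh, Ihv, Ihh.

    The G factor is computed per measurement session as the mean Ihv/Ihh over
    the table's samples (the factor characterizes the instrument, not the
    sample) and applied to every row.
    """
    g = float(np.mean(g_factor(quadruples["Ihv"], quadruples["Ihh"])))
    return pd.Series(
        anisotropy(quadruples["Ivv"], quadruples["Ivh"], g),
        index=quadruples.index,
        name="anisotropy",
    )


def gp_from_pairs(pairs: pd.DataFrame) -> pd.Series:
    """Per-sample GP from a table with columns I_blue, I_red."""
    return pd.Series(
        generalized_polarization(pairs["I_blue"], pairs["I_red"]),
        index=pairs.index,
        name="gp",
    )


def batch_probe_summary(values, group_labels) -> pd.DataFrame:
    """Per-group mean and SEM (SD/sqrt(n)) of a derived probe parameter."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(group_labels)})
    counts = df.groupby("group")["value"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"groups need >=2 samples for a SEM: {bad}")
    out = df.groupby("group")["value"].agg(
        n="count", mean="mean", sem=lambda x: np.std(x, ddof=1) / np.sqrt(len(x))
    )
    return out.reset_index()
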