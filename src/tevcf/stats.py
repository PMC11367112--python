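"""Group-level statistics: one-way ANOVA, Tukey HSD post-hoc comparisons and
report assembly.

The sequential procedure mirrors standard practice for three-arm treatment
comparisons: a one-way fixed-effects ANOVA gates all-pairs Tukey HSD tests
(Tukey-Kramer adjusted for unequal group sizes); pairwise p-values are always
reported but flagged as not interpretable when the ANOVA is not significant
at the chosen alpha.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "anova_oneway",
    "tukey_hsd",
    "compare_groups",
    "build_report",
    "write_report",
]

#: numerical floor below which p-values are displayed as "<1e-12"
P_FLOOR = 1e-12


def anova_oneway(groups) -> tuple:
    """Classical one-way fixed-effects ANOVA over a list of value arrays.

    Returns ``(F, p)``.  Degenerate data with zero between- and within-group
    variability returns ``(0.0, 1.0)``; zero within-group variability with
    distinct means returns ``(inf, 0.0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = all_values.size - len(groups)
    if ss_within == 0.0:
        return (0.0, 1.0) if ss_between == 0.0 else (float("inf"), 0.0)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def tukey_hsd(groups, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD table (Tukey-Kramer for unequal group sizes).

    Columns: group_a, group_b, mean_diff, p, significant (p < alpha),
    interpreted (False when the gating ANOVA p >= alpha — the pairwise tests
    are still reported, mirroring the sequential ANOVA-then-post-hoc
    procedure, but should not be read as evidence).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    _, anova_p = anova_oneway(groups)
    with np.errstate(invalid="ignore", divide="ignore"):  # zero-variance groups
        res = sps.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(groups[i].mean() - groups[j].mean()),
                "p": p,
                "p_display": f"<{P_FLOOR:g}" if p < P_FLOOR else f"{p:.4g}",
                "significant": p < alpha,
                "interpreted": anova_p < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """One comparison block: group summaries plus ANOVA and Tukey results."""

    labels: list
    n: list
    means: list
    sems: list
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "groups": [
                {"label": l, "n": int(n), "mean": m, "sem": s}
                for l, n, m, s in zip(self.labels, self.n, self.means, self.sems)
            ],
            "anova_F": self.anova_f,
            "anova_p": self.anova_p,
            "alpha": self.alpha,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def compare_groups(values_by_label: dict, alpha: float = 0.05) -> GroupComparison:
    """ANOVA + Tukey HSD over a ``{label: values}`` mapping."""
    labels = list(values_by_label)
    groups = [np.asarray(values_by_label[l], dtype=float) for l in labels]
    f, p = anova_oneway(groups)
    pairwise = tukey_hsd(groups, labels, alpha)
    return GroupComparison(
        labels=labels,
        n=[g.size for g in groups],
        means=[float(g.mean()) for g in groups],
        sems=[float(np.std(g, ddof=1) / np.sqrt(g.size)) for g in groups],
        anova_f=f,
        anova_p=p,
        pairwise=pairwise,
        alpha=alpha,
    )


def build_report(
    cohort: pd.DataFrame | None = None,
    probe_values: dict | None = None,
    imaging_values: dict | None = None,
    alpha: float = 0.05,
    config: dict | None = None,
) -> dict:
    """Assemble the study-level report.

    ``cohort`` is the per-cell gating table (columns treatment, v_half_f,
    k_f, v_half_g, k_g, relative_amplitude as available); ``probe_values``
    and ``imaging_values`` map parameter name -> {group label: values}.
    Each available parameter gets a :class:`GroupComparison`; parameters whose
    groups collapse to a single label are summarized without tests.
    Deterministic: regenerating from the same inputs gives identical output.
    """
    report = {"alpha": alpha, "config": config or {}, "comparisons": {}}
    sections = {}
    if cohort is not None:
        for col in ("v_half_f", "k_f", "v_half_g", "k_g", "relative_amplitude"):
            if col in cohort.columns:
                sections[col] = {
                    label: sub[col].dropna().to_numpy()
                    for label, sub in cohort.groupby("treatment", sort=False)
                }
    for source in (probe_values or {}), (imaging_values or {}):
        sections.update(source)
    for name, by_label in sections.items():
        by_label = {l: np.asarray(v, dtype=float) for l, v in by_label.items() if len(v)}
        if not by_label:
            raise ValueError(f"parameter {name!r} has no groups with data")
        if len(by_label) < 2 or any(v.size < 2 for v in by_label.values()):
            report["comparisons"][name] = {
                "groups": [
                    {
                        "label": l,
                        "n": int(v.size),
                        "mean": float(v.mean()),
                        "sem": float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else None,
                    }
                    for l, v in by_label.items()
                ],
                "anova_F": None,
                "anova_p": None,
                "pairwise": [],
                "alpha": alpha,
            }
        else:
            report["comparisons"][name] = compare_groups(by_label, alpha).to_dict()
    return report


def write_report(report: dict, path) -> None:
    """Write the report bundle as deterministic, sorted-key JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
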