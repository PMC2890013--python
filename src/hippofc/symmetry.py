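"""Suprathreshold voxel counts and histograms across group contrasts.

For each seed (left/right hippocampus) and each intergroup contrast, the
number of voxels with t above a display threshold (t > 6 by default,
strict) summarizes how strongly that patient group's connectivity falls
short of controls. Comparing the counts across contrasts quantifies the
asymmetry of the deficit - in the modelled condition, the
control-vs-left-MTLE count exceeds the control-vs-right-MTLE count for
both seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group import GroupStatMap

__all__ = [
    "suprathreshold_count",
    "t_histogram",
    "asymmetry_summary",
    "AsymmetryReport",
]

#: Contrasts entering the asymmetry analysis, in reporting order.
COMPARISONS = ("control_vs_right_mtle", "control_vs_left_mtle", "right_vs_left_mtle")


def suprathreshold_count(stat_map: GroupStatMap, t_threshold: float = 6.0) -> int:
    """Number of defined voxels with t strictly above the threshold."""
    t = stat_map.t
    with np.errstate(invalid="ignore"):
        return int(np.sum(t[~np.isnan(t)] > t_threshold))


def t_histogram(
    stat_map: GroupStatMap,
    t_threshold: float = 6.0,
    bin_width: float = 0.5,
) -> pd.DataFrame:
    """Right-open histogram of suprathreshold t values, bins from threshold.

    Bin edges start at ``t_threshold`` and advance by ``bin_width`` until
    the map maximum is covered; counts sum exactly to
    :func:`suprathreshold_count`.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = stat_map.t
    vals = t[~np.isnan(t)]
    vals = vals[vals > t_threshold]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return pd.DataFrame(
            dict(bin_lo=[t_threshold], bin_hi=[t_threshold + bin_width], count=[0])
        )
    n_bins = int(np.ceil((vals.max() - t_threshold) / bin_width)) + 1
    edges = t_threshold + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(dict(bin_lo=edges[:-1], bin_hi=edges[1:], count=counts))


@dataclass
class AsymmetryReport:
    """Counts per (seed, comparison), their ratios, and the group ordering."""

    counts: pd.DataFrame
    histograms: dict
    ratios: pd.DataFrame
    ordering: dict
    t_threshold: float

    def to_text(self) -> str:
        lines = [
            f"Suprathreshold voxel counts (t > {self.t_threshold:g}):",
            self.counts.to_string(index=False),
            "",
            "Left/right-seed deficit ratios (control-vs-left over control-vs-right):",
            self.ratios.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
        ]
        for seed, order in self.ordering.items():
            lines.append(f"{seed} seed implied connectivity ordering: {' > '.join(order)}")
        return "\n".join(lines)


def asymmetry_summary(
    maps: dict[tuple[str, str], GroupStatMap],
    t_threshold: float = 6.0,
    bin_width: float = 0.5,
) -> AsymmetryReport:
    """Tabulate suprathreshold counts for both seeds and all contrasts.

    ``maps`` is keyed by (seed side, comparison name) with the comparison
    direction control-minus-patient (and right-minus-left-MTLE). The
    implied ordering per seed ranks groups by deficit: a larger
    control-vs-X count marks group X as more impaired; the patient-patient
    contrast breaks ties.
    """
    for seed in ("left", "right"):
        for comp in COMPARISONS[:2]:
            if (seed, comp) not in maps:
                raise ValueError(f"missing map for seed={seed!r}, comparison={comp!r}")

    rows, histograms = [], {}
    for (seed, comp), stat_map in sorted(maps.items()):
        count = suprathreshold_count(stat_map, t_threshold)
        histograms[(seed, comp)] = t_histogram(stat_map, t_threshold, bin_width)
        rows.append(dict(seed=seed, comparison=comp, count=count))
    counts = pd.DataFrame(rows)

    ratio_rows, ordering = [], {}
    for seed in ("left", "right"):
        c_right = int(counts.query("seed == @seed and comparison == 'control_vs_right_mtle'")["count"].iloc[0])
        c_left = int(counts.query("seed == @seed and comparison == 'control_vs_left_mtle'")["count"].iloc[0])
        ratio = c_left / c_right if c_right > 0 else np.inf if c_left > 0 else 1.0
        ratio_rows.append(dict(seed=seed, control_vs_right=c_right,
                               control_vs_left=c_left, left_over_right_ratio=ratio))
        if c_left > c_right:
            order = ["control", "right_mtle", "left_mtle"]
        elif c_right > c_left:
            order = ["control", "left_mtle", "right_mtle"]
        else:
            order = ["control", "right_mtle=left_mtle"]
        ordering[seed] = order
    ratios = pd.DataFrame(ratio_rows)

    return AsymmetryReport(counts=counts, histograms=histograms, ratios=ratios,
                           ordering=ordering, t_threshold=t_threshold)
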