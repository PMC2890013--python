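"""Hippocampal volumetry and neuropsychology statistics.

The quantitative asymmetry index (QAI) of a subject's hippocampi is

    QAI = 1 - VSH / VBH

where VSH and VBH are the volumes of the smaller and bigger hippocampus;
QAI = 0 means perfect symmetry, values near 1 extreme atrophy of one side.

Group comparisons use the pooled-variance (equal-variance) two-sample
t-test, which exactly reproduces the published group statistics from the
bundled per-subject tables; Welch's unequal-variance variant is available.
Neuropsychological measures may be missing for individual patients and are
excluded per-measure (listwise within each measure only).

Two fixtures ship with the package: ``table1_volumes.tsv`` (27 subjects'
left/right hippocampal volumes in mm^3 across control, right-MTLE and
left-MTLE groups) and ``table2_neuropsych.tsv`` (the two patient groups'
neuropsychological scores, NA where a test was not administered).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_qai",
    "pooled_two_sample_t",
    "TwoSampleResult",
    "load_table1",
    "load_table2",
    "volumetry_report",
    "neuropsych_report",
    "VolumetryReport",
]

GROUPS = ("control", "right_mtle", "left_mtle")

#: Sentinel t magnitude for zero pooled variance with unequal means.
T_INFINITE = math.inf

NEUROPSYCH_MEASURES = [
    "estimated_iq",
    "boston_naming_z",
    "verbal_fluency_z",
    "vigilance_errors",
    "wmsr_general_memory_z",
    "wmsr_verbal_memory_z",
    "wmsr_visual_memory_z",
    "wmsr_delayed_recall_z",
]


def compute_qai(vlh: float, vrh: float) -> float:
    """Quantitative asymmetry index: 1 - (smaller volume / bigger volume).

    Symmetric in its arguments, invariant under common rescaling, and in
    [0, 1) for positive volumes.
    """
    if not (vlh > 0 and vrh > 0):
        raise ValueError(f"hippocampal volumes must be positive, got ({vlh}, {vrh})")
    return 1.0 - min(vlh, vrh) / max(vlh, vrh)


@dataclass
class TwoSampleResult:
    """Two-sample t-test outcome with the sample sizes actually used."""

    t: float
    df: int
    p: float
    n1: int
    n2: int
    mean1: float
    mean2: float


def pooled_two_sample_t(xs, ys, equal_var: bool = True) -> TwoSampleResult:
    """Two-sided two-sample t-test, pooled variance by default.

    Missing values (NaN) are dropped per sample. Degenerate zero-variance
    cases: equal means give t = 0, p = 1; unequal means give an infinite-t
    sentinel with p = 0.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    xs = xs[~np.isnan(xs)]
    ys = ys[~np.isnan(ys)]
    n1, n2 = len(xs), len(ys)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each sample needs >= 2 non-missing values, got {n1} and {n2}"
        )
    df = n1 + n2 - 2 if equal_var else None
    m1, m2 = float(xs.mean()), float(ys.mean())
    if xs.var(ddof=1) == 0 and ys.var(ddof=1) == 0:
        if np.isclose(m1, m2):
            return TwoSampleResult(0.0, n1 + n2 - 2, 1.0, n1, n2, m1, m2)
        t = math.copysign(T_INFINITE, m1 - m2)
        return TwoSampleResult(t, n1 + n2 - 2, 0.0, n1, n2, m1, m2)
    res = stats.ttest_ind(xs, ys, equal_var=equal_var)
    return TwoSampleResult(
        float(res.statistic), int(round(float(res.df))), float(res.pvalue),
        n1, n2, m1, m2,
    )


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("hippofc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    """Bundled per-subject hippocampal volumes with the QAI recomputed.

    Columns: subject_id, group, vlh_mm3, vrh_mm3, qai. The asymmetry index
    is recomputed from the volumes at full precision rather than read from
    a rounded column.
    """
    df = _fixture("table1_volumes.tsv")
    df["qai"] = [compute_qai(l, r) for l, r in zip(df.vlh_mm3, df.vrh_mm3)]
    return df


def load_table2() -> pd.DataFrame:
    """Bundled patient neuropsychology scores; NA marks missing values."""
    return _fixture("table2_neuropsych.tsv")


@dataclass
class VolumetryReport:
    """Group summaries plus ipsilateral and contralateral t-tests."""

    summary: pd.DataFrame
    ipsilateral: pd.DataFrame
    contralateral: pd.DataFrame

    def to_text(self) -> str:
        parts = [
            "Group summaries (mean / sd):",
            self.summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "Ipsilateral comparisons (pooled two-sample t):",
            self.ipsilateral.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "Contralateral comparisons:",
            self.contralateral.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(parts)


def volumetry_report(table: pd.DataFrame | None = None, equal_var: bool = True) -> VolumetryReport:
    """Full volumetry statistics in the published layout.

    ``summary`` holds per-group mean/sd of left volume, right volume and
    QAI; ``ipsilateral`` the nine group-pair t-scores (three measures by
    three pairs); ``contralateral`` the two cross-hemisphere patient
    comparisons (left volume of right-MTLE vs right volume of left-MTLE,
    and vice versa).
    """
    if table is None:
        table = load_table1()
    missing = set(GROUPS) - set(table.group.unique())
    if missing:
        raise ValueError(f"volumetry table is missing groups: {sorted(missing)}")
    if "qai" not in table.columns:
        table = table.assign(
            qai=[compute_qai(l, r) for l, r in zip(table.vlh_mm3, table.vrh_mm3)]
        )

    by = {g: table[table.group == g] for g in GROUPS}
    summary = pd.DataFrame(
        [
            dict(
                group=g,
                n=len(by[g]),
                vlh_mean=by[g].vlh_mm3.mean(), vlh_sd=by[g].vlh_mm3.std(ddof=1),
                vrh_mean=by[g].vrh_mm3.mean(), vrh_sd=by[g].vrh_mm3.std(ddof=1),
                qai_mean=by[g].qai.mean(), qai_sd=by[g].qai.std(ddof=1),
            )
            for g in GROUPS
        ]
    )

    pairs = [
        ("control", "right_mtle"),
        ("control", "left_mtle"),
        ("right_mtle", "left_mtle"),
    ]
    rows = []
    for g1, g2 in pairs:
        for measure, col in (("vlh", "vlh_mm3"), ("vrh", "vrh_mm3"), ("qai", "qai")):
            res = pooled_two_sample_t(by[g1][col], by[g2][col], equal_var=equal_var)
            rows.append(
                dict(comparison=f"{g1}_vs_{g2}", measure=measure,
                     t=res.t, df=res.df, p=res.p)
            )
    ipsi = pd.DataFrame(rows)

    contra_rows = []
    for label, a, b in (
        ("vlh_right_mtle_vs_vrh_left_mtle", by["right_mtle"].vlh_mm3, by["left_mtle"].vrh_mm3),
        ("vrh_right_mtle_vs_vlh_left_mtle", by["right_mtle"].vrh_mm3, by["left_mtle"].vlh_mm3),
    ):
        res = pooled_two_sample_t(a, b, equal_var=equal_var)
        contra_rows.append(dict(comparison=label, t=res.t, df=res.df, p=res.p))
    contra = pd.DataFrame(contra_rows)

    return VolumetryReport(summary=summary, ipsilateral=ipsi, contralateral=contra)


def neuropsych_report(
    table: pd.DataFrame | None = None,
    measures: list[str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-measure right-MTLE vs left-MTLE t-tests with NA exclusion.

    The sign convention is right-MTLE minus left-MTLE, so a positive t
    means higher scores in the right-MTLE group. A measure with fewer than
    two non-missing values in either group is reported as not computable
    (NaN statistics) rather than raising.
    """
    if table is None:
        table = load_table2()
    measures = measures or [m for m in NEUROPSYCH_MEASURES if m in table.columns]
    for g in ("right_mtle", "left_mtle"):
        if g not in set(table.group.unique()):
            raise ValueError(f"neuropsychology table is missing group {g!r}")
    right = table[table.group == "right_mtle"]
    left = table[table.group == "left_mtle"]
    rows = []
    for m in measures:
        xs = right[m].astype(float)
        ys = left[m].astype(float)
        try:
            res = pooled_two_sample_t(xs, ys, equal_var=equal_var)
            rows.append(
                dict(measure=m, t=res.t, df=res.df, p=res.p, n_right=res.n1,
                     n_left=res.n2, significant=bool(res.p < alpha))
            )
        except ValueError:
            rows.append(
                dict(measure=m, t=np.nan, df=np.nan, p=np.nan,
                     n_right=int(xs.notna().sum()), n_left=int(ys.notna().sum()),
                     significant=False)
            )
    return pd.DataFrame(rows)
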