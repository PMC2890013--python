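"""Per-subject seed-based connectivity mapping.

The seed is the unweighted mean time series over a hippocampus mask. Each
brain voxel's Pearson correlation r with the seed is converted to a t value
via the standard transformation

    t = r * sqrt(n - 2) / sqrt(1 - r**2),   n = number of time points,

negative correlations are removed, and the map is carried into group
statistics on a z scale. Two z definitions are provided: the Fisher
transform z = arctanh(r) (default - the usual variance-stabilizer for
correlations), and a Gaussianization of the t values through their CDF,
z = Phi^{-1}(F_t(t; n-2)). Both are strictly increasing in r, so they rank
voxels identically.

Voxels whose series has zero variance (e.g. outside the head) are marked
undefined (NaN) and excluded from all statistics rather than set to r = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .images import ROIMask, VolumeSeries, check_same_grid

__all__ = [
    "SeedSeries",
    "CorrelationMap",
    "SubjectConnectivityMap",
    "extract_seed",
    "correlation_map",
    "r_to_t",
    "r_cutoff_for_p",
    "apply_positive_threshold",
    "to_z",
    "subject_map",
]

#: |t| reported where |r| = 1 exactly (the formula diverges).
T_SENTINEL = 1e10


@dataclass
class SeedSeries:
    """Mask-averaged reference time series for one hippocampus."""

    side: str
    values: np.ndarray
    n_timepoints: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("seed series must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("seed series contains non-finite values")
        self.n_timepoints = int(self.values.size)


@dataclass
class CorrelationMap:
    """Voxelwise seed-correlation map and its derived fields.

    ``r`` is NaN where undefined (outside the brain mask or zero-variance
    voxels); ``t`` and ``z`` are filled by :func:`r_to_t` / :func:`to_z`.
    ``r_threshold`` records the correlation cutoff equivalent to the
    subject-level one-sided p threshold once thresholding is applied.
    """

    r: np.ndarray
    n: int
    affine: np.ndarray
    t: np.ndarray | None = None
    z: np.ndarray | None = None
    threshold_p: float = 1e-4
    r_threshold: float | None = None
    z_method: str | None = None


@dataclass
class SubjectConnectivityMap:
    """Per-subject z map plus provenance of how it was aggregated."""

    z: np.ndarray
    affine: np.ndarray
    seed_side: str
    n_timepoints: int
    n_runs: int
    z_method: str
    aggregation: str


def extract_seed(series: VolumeSeries, mask: ROIMask, side: str | None = None) -> SeedSeries:
    """Average the preprocessed series over the mask voxels."""
    check_same_grid(series, mask, "series and seed mask")
    if mask.n_voxels == 0:
        raise ValueError("seed mask is empty")
    values = series.data[mask.data].mean(axis=0)
    return SeedSeries(side=side or mask.name, values=values)


def correlation_map(
    series: VolumeSeries,
    seed: SeedSeries,
    brain_mask: ROIMask | None = None,
    threshold_p: float = 1e-4,
) -> CorrelationMap:
    """Pearson correlation of every brain voxel's series with the seed."""
    if series.n_timepoints != seed.n_timepoints:
        raise ValueError(
            f"length mismatch: series has {series.n_timepoints} time points, "
            f"seed has {seed.n_timepoints}"
        )
    data = series.data
    mask = np.ones(data.shape[:3], dtype=bool) if brain_mask is None else brain_mask.data
    if brain_mask is not None:
        check_same_grid(series, brain_mask, "series and brain mask")

    vox = data[mask].astype(np.float64)
    s = seed.values - seed.values.mean()
    s_norm = np.sqrt((s**2).sum())
    vc = vox - vox.mean(axis=1, keepdims=True)
    v_norm = np.sqrt((vc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_vals = (vc @ s) / (v_norm * s_norm)
    r_vals[(v_norm == 0) | (s_norm == 0)] = np.nan
    r_vals = np.clip(r_vals, -1.0, 1.0)

    r = np.full(data.shape[:3], np.nan)
    r[mask] = r_vals
    return CorrelationMap(r=r, n=seed.n_timepoints, affine=series.affine,
                          threshold_p=threshold_p)


def r_to_t(r, n: int):
    """Standard r-to-t transformation, t = r sqrt(n-2) / sqrt(1-r^2).

    Strictly increasing in r at fixed n. |r| = 1 maps to a +/-1e10 sentinel
    with a warning. Accepts scalars or arrays; NaN propagates.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 time points, got {n}")
    r_arr = np.asarray(r, dtype=float)
    if np.nanmax(np.abs(r_arr), initial=0.0) > 1:
        raise ValueError("|r| must not exceed 1")
    saturated = np.abs(r_arr) == 1
    if np.any(saturated):
        warnings.warn("|r| = 1 encountered; reporting sentinel t = +/-1e10",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt(n - 2) / np.sqrt(1.0 - r_arr**2)
    t = np.where(saturated, np.sign(r_arr) * T_SENTINEL, t)
    return float(t) if np.isscalar(r) else t


def r_cutoff_for_p(p: float, n: int) -> float:
    """Correlation cutoff whose one-sided p-value (df = n-2) equals ``p``."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    df = n - 2
    t_c = stats.t.isf(p, df)
    return float(t_c / np.sqrt(df + t_c**2))


def apply_positive_threshold(cmap: CorrelationMap, hard: bool = False) -> CorrelationMap:
    """Zero negative correlations; optionally zero sub-threshold positives.

    With ``hard=True`` voxels whose one-sided p (from t with df = n-2) is
    not below ``threshold_p`` are also zeroed - the literal subject-level
    display threshold. Idempotent in either mode; the equivalent r cutoff
    is recorded on the returned map.
    """
    r = cmap.r.copy()
    defined = ~np.isnan(r)
    r[defined & (r < 0)] = 0.0
    r_cut = r_cutoff_for_p(cmap.threshold_p, cmap.n)
    if hard:
        r[defined & (r < r_cut) & (r > 0)] = 0.0
    return CorrelationMap(r=r, n=cmap.n, affine=cmap.affine, t=None, z=None,
                          threshold_p=cmap.threshold_p, r_threshold=r_cut,
                          z_method=cmap.z_method)


def to_z(cmap: CorrelationMap, method: str = "fisher_r") -> CorrelationMap:
    """Fill the z field from r (``fisher_r``) or from t (``t_to_normal``).

    ``fisher_r``: z = arctanh(r). ``t_to_normal``: z is the standard-normal
    quantile of the t CDF at df = n-2, clipped to +/-8 in the extreme tails.
    """
    if method not in ("fisher_r", "t_to_normal"):
        raise ValueError(f"unknown z method {method!r}")
    t = r_to_t(cmap.r, cmap.n)
    if method == "fisher_r":
        with np.errstate(divide="ignore"):
            z = np.arctanh(np.clip(cmap.r, -1.0, 1.0))
        z = np.clip(z, -T_SENTINEL, T_SENTINEL)
    else:
        z = stats.norm.ppf(stats.t.cdf(t, cmap.n - 2))
        z = np.clip(z, -8.0, 8.0)
        z = np.where(np.isnan(cmap.r), np.nan, z)
    return CorrelationMap(r=cmap.r, n=cmap.n, affine=cmap.affine, t=t, z=z,
                          threshold_p=cmap.threshold_p,
                          r_threshold=cmap.r_threshold, z_method=method)


def subject_map(
    runs: list[VolumeSeries],
    seed_mask: ROIMask,
    brain_mask: ROIMask | None = None,
    z_method: str = "fisher_r",
    aggregation: str = "mean_z",
    hard_threshold: bool = False,
    threshold_p: float = 1e-4,
    seed_side: str | None = None,
) -> SubjectConnectivityMap:
    """One subject's aggregated seed-connectivity z map from >= 1 runs.

    ``mean_z`` (default) computes a z map per run and averages voxelwise;
    ``concatenate`` joins the runs in time and correlates once. Runs are
    assumed preprocessed already.
    """
    if not runs:
        raise ValueError("need at least one run")
    if aggregation not in ("mean_z", "concatenate"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    side = seed_side or seed_mask.name

    if aggregation == "concatenate":
        data = np.concatenate([r.data for r in runs], axis=-1)
        runs = [VolumeSeries(data, runs[0].affine, runs[0].tr_s)]

    z_maps = []
    n_t = runs[0].n_timepoints
    for run in runs:
        seed = extract_seed(run, seed_mask, side=side)
        cmap = correlation_map(run, seed, brain_mask=brain_mask, threshold_p=threshold_p)
        cmap = apply_positive_threshold(cmap, hard=hard_threshold)
        cmap = to_z(cmap, method=z_method)
        z_maps.append(cmap.z)
    z = np.mean(z_maps, axis=0)
    return SubjectConnectivityMap(
        z=z, affine=runs[0].affine, seed_side=side, n_timepoints=n_t,
        n_runs=len(z_maps), z_method=z_method, aggregation=aggregation,
    )
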