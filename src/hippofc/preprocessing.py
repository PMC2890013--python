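"""Temporal/spatial conditioning of 4D BOLD series.

Three deterministic stages, applied in acquisition order: discard of the
initial non-steady-state volumes, spatial Gaussian smoothing (FWHM in mm),
and temporal band-pass filtering to the low-frequency band where resting
state coherence lives (0.01-0.08 Hz by default).

The band-pass is realized as a zero-phase rectangular mask in the discrete
Fourier domain combined with exact removal of low-order polynomial trends:
the per-voxel mean (DC), all components outside the open interval
(f_lo, f_hi), and the in-band span of constant and linear trends are
annihilated. The polynomial term matters because a finite drift ramp is not
periodic and its DFT leaks into every frequency bin; projecting its in-band
span out restores exact drift suppression while keeping the whole operator
an orthogonal projection - linear and idempotent - which the synthetic-data
generator reuses so that planted signals survive preprocessing unchanged.
A Butterworth forward-backward variant is available for real-data use.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage, signal

from .images import VolumeSeries

__all__ = [
    "PreprocessConfig",
    "discard_initial",
    "smooth_gaussian",
    "bandpass",
    "bandpass_array",
    "preprocess",
]

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    n_discard : initial volumes dropped to guarantee a stable baseline.
    fwhm_mm : spatial Gaussian kernel full width at half maximum (0 = off).
    f_lo_hz, f_hi_hz : temporal pass-band edges (None disables the filter).
    """

    n_discard: int = 5
    fwhm_mm: float = 6.0
    f_lo_hz: float | None = 0.01
    f_hi_hz: float | None = 0.08
    filter_method: str = "rectangular"  # or "butterworth"

    def validate(self, tr_s: float | None = None) -> list[str]:
        errors = []
        if self.n_discard < 0:
            errors.append("preprocessing: n_discard must be nonnegative")
        if self.fwhm_mm < 0:
            errors.append("preprocessing: fwhm_mm must be nonnegative")
        if (self.f_lo_hz is None) != (self.f_hi_hz is None):
            errors.append("preprocessing: f_lo_hz and f_hi_hz must be set together")
        if self.f_lo_hz is not None and self.f_hi_hz is not None:
            if not 0 <= self.f_lo_hz < self.f_hi_hz:
                errors.append("preprocessing: need 0 <= f_lo_hz < f_hi_hz")
            if tr_s is not None and self.f_hi_hz >= 0.5 / tr_s:
                errors.append(
                    f"preprocessing: f_hi_hz={self.f_hi_hz} must be below the "
                    f"Nyquist frequency {0.5 / tr_s:g} Hz at TR={tr_s} s"
                )
        if self.filter_method not in ("rectangular", "butterworth"):
            errors.append(f"preprocessing: unknown filter_method {self.filter_method!r}")
        return errors


def discard_initial(series: VolumeSeries, n_discard: int = 5) -> VolumeSeries:
    """Drop the first ``n_discard`` volumes (non-steady-state baseline)."""
    if not 0 <= n_discard < series.n_timepoints:
        raise ValueError(
            f"n_discard={n_discard} must be in [0, {series.n_timepoints})"
        )
    return VolumeSeries(series.data[..., n_discard:], series.affine, series.tr_s)


def smooth_gaussian(series: VolumeSeries, fwhm_mm: float = 6.0) -> VolumeSeries:
    """Spatially smooth every frame with an isotropic Gaussian of given FWHM.

    Per-axis sigma in voxels is fwhm / voxel_size / (2*sqrt(2*ln 2)); the
    temporal axis is untouched. Edges are handled by reflection so constant
    images stay constant.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return series
    sigmas = fwhm_mm * FWHM_TO_SIGMA / series.voxel_size_mm
    out = ndimage.gaussian_filter(
        series.data.astype(np.float64, copy=False),
        sigma=(*sigmas, 0.0),
        mode="reflect",
    )
    return VolumeSeries(out.astype(series.data.dtype, copy=False), series.affine, series.tr_s)


#: Polynomial order (inclusive) whose trends the rectangular band-pass
#: removes exactly, on top of the frequency mask. A finite ramp is not
#: periodic, so its DFT leaks power into every bin; projecting out the
#: in-band span of constant+linear trends (the usual detrending order for
#: resting-state band-pass filters) removes ramps exactly while keeping the
#: operator an orthogonal projection (linear and idempotent). Higher orders
#: would bite visibly into genuine pass-band signal.
DETREND_ORDER = 1


def _band_mask(n_timepoints: int, tr_s: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Boolean mask over rfft bins kept by the rectangular band-pass.

    The band is open, following the stated high-pass f > f_lo and low-pass
    f < f_hi; DC is always removed, so the per-voxel mean is subtracted
    implicitly.
    """
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_s)
    return (freqs > f_lo) & (freqs < f_hi)


def _raw_band_dims(n_timepoints: int, tr_s: float, f_lo: float, f_hi: float) -> int:
    keep = _band_mask(n_timepoints, tr_s, f_lo, f_hi)
    n = n_timepoints
    dof = 0
    for k in np.nonzero(keep)[0]:
        # DC (k=0) and, for even n, the Nyquist bin contribute one real dof;
        # every other bin two. DC is never kept by construction.
        dof += 1 if (k == 0 or (n % 2 == 0 and k == n // 2)) else 2
    return dof


@lru_cache(maxsize=32)
def _inband_poly_basis(n_timepoints: int, tr_s: float, f_lo: float, f_hi: float):
    """Orthonormal basis of the band-projected polynomial span.

    The band-pass projector is P = P_band - G G^T where G spans
    {P_band p : p polynomial of degree <= DETREND_ORDER}; subtracting that
    span makes every such polynomial map exactly to zero.
    """
    tau = np.linspace(-1.0, 1.0, n_timepoints)
    polys = np.stack([tau**k for k in range(DETREND_ORDER + 1)], axis=1)
    projected = _fft_bandpass(polys.T, n_timepoints, tr_s, f_lo, f_hi).T
    q, s, _ = np.linalg.svd(projected, full_matrices=False)
    rank = int((s > s.max() * 1e-12).sum()) if s.size and s.max() > 0 else 0
    return np.ascontiguousarray(q[:, :rank])


def _fft_bandpass(arr, n, tr_s, f_lo, f_hi, axis=-1):
    spec = np.fft.rfft(arr, axis=axis)
    keep = _band_mask(n, tr_s, f_lo, f_hi)
    shape = [1] * arr.ndim
    shape[axis] = keep.size
    return np.fft.irfft(spec * keep.reshape(shape), n=n, axis=axis)


def band_dof(n_timepoints: int, tr_s: float, f_lo: float = 0.01, f_hi: float = 0.08) -> int:
    """Real dimension of the rectangular band-pass projection.

    Two per retained rfft bin, minus the rank of the in-band polynomial
    span that the filter also removes. White noise of variance s**2
    retains variance s**2 * band_dof / n_timepoints after filtering.
    """
    raw = _raw_band_dims(n_timepoints, tr_s, f_lo, f_hi)
    g = _inband_poly_basis(n_timepoints, float(tr_s), float(f_lo), float(f_hi))
    return raw - g.shape[1]


def bandpass_array(
    arr: np.ndarray,
    tr_s: float,
    f_lo: float = 0.01,
    f_hi: float = 0.08,
    axis: int = -1,
    method: str = "rectangular",
) -> np.ndarray:
    """Band-pass an array of time series along ``axis``.

    ``rectangular`` zeroes out-of-band DFT components (exact projection,
    idempotent); ``butterworth`` applies a 4th-order zero-phase filter after
    mean removal.
    """
    n = arr.shape[axis]
    if n < 8:
        raise ValueError(f"series too short to filter (T={n} < 8)")
    nyquist = 0.5 / tr_s
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi >= nyquist:
        raise ValueError(f"f_hi={f_hi} must be below Nyquist ({nyquist:g} Hz)")
    arr = np.asarray(arr, dtype=np.float64)
    if method == "rectangular":
        out = _fft_bandpass(arr, n, tr_s, f_lo, f_hi, axis=axis)
        g = _inband_poly_basis(n, float(tr_s), float(f_lo), float(f_hi))
        if g.shape[1]:
            moved = np.moveaxis(out, axis, -1)
            moved -= (moved @ g) @ g.T
            out = np.moveaxis(moved, -1, axis)
        return out
    if method == "butterworth":
        sos = signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=1.0 / tr_s, output="sos")
        demeaned = arr - arr.mean(axis=axis, keepdims=True)
        return signal.sosfiltfilt(sos, demeaned, axis=axis)
    raise ValueError(f"unknown band-pass method {method!r}")


def bandpass(
    series: VolumeSeries,
    f_lo: float = 0.01,
    f_hi: float = 0.08,
    method: str = "rectangular",
) -> VolumeSeries:
    """Zero-phase temporal band-pass of every voxel series; removes the mean."""
    out = bandpass_array(series.data, series.tr_s, f_lo, f_hi, axis=-1, method=method)
    return VolumeSeries(out, series.affine, series.tr_s)


def preprocess(series: VolumeSeries, config: PreprocessConfig | None = None) -> VolumeSeries:
    """Full chain: discard initial volumes, smooth, band-pass."""
    config = config or PreprocessConfig()
    errors = config.validate(tr_s=series.tr_s)
    if errors:
        raise ValueError("; ".join(errors))
    out = discard_initial(series, config.n_discard)
    if config.fwhm_mm > 0:
        out = smooth_gaussian(out, config.fwhm_mm)
    if config.f_lo_hz is not None and config.f_hi_hz is not None:
        out = bandpass(out, config.f_lo_hz, config.f_hi_hz, method=config.filter_method)
    return out
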