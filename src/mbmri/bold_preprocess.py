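"""Per-subject BOLD preprocessing: masking, band-pass filtering,
global-signal regression, spatial smoothing.

The voxel-mode pipeline order is fixed: mask -> band-pass -> global-signal
regression -> smooth.  Region-series mode uses band-pass and regression
only.  Motion correction and registration are out of scope; inputs are
assumed pre-aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import DegenerateDataError, DimensionError, ParameterError
from .io_formats import BoldImage, VolumeImage

log = logging.getLogger("mbmri")

#: FWHM -> sigma conversion factor, 2 * sqrt(2 ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PreprocessParams:
    """Band-pass and smoothing parameters (study defaults: 0.008-0.2 Hz,
    order-2 Butterworth applied forward-backward, 0.3 mm FWHM)."""

    passband_low: float = 0.008
    passband_high: float = 0.2
    filter_order: int = 2
    fwhm: float = 0.3
    detrend: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.passband_low < self.passband_high:
            raise ParameterError(
                f"need 0 < low < high, got ({self.passband_low}, "
                f"{self.passband_high})"
            )
        if self.filter_order < 1:
            raise ParameterError("filter_order must be >= 1")
        if self.fwhm < 0:
            raise ParameterError("fwhm must be >= 0")


def apply_brain_mask(bold: BoldImage, mask: VolumeImage) -> BoldImage:
    """Zero all voxels outside the binary brain mask."""
    if mask.data.shape != bold.spatial_shape:
        raise DimensionError(
            f"mask grid {mask.data.shape} does not match BOLD spatial grid "
            f"{bold.spatial_shape}"
        )
    m = np.asarray(mask.data)
    if not np.isin(m, (0, 1)).all():
        raise ParameterError("mask must be binary (0/1)")
    if not m.any():
        raise DegenerateDataError("empty brain mask")
    return BoldImage(
        data=bold.data * m[..., None], voxel_dims=bold.voxel_dims, tr=bold.tr
    )


def bandpass_filter(
    series: np.ndarray, tr: float, params: PreprocessParams
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the first (time) axis.

    The filter of the configured order is applied forward-backward
    (``sosfiltfilt``), giving zero phase and an effective order of twice the
    design order.  The series mean is removed first, so DC is exactly zero
    in the output.  Output length equals input length.
    """
    x = np.asarray(series, dtype=np.float64)
    nyquist = 1.0 / (2.0 * tr)
    if params.passband_high >= nyquist:
        raise ParameterError(
            f"passband high {params.passband_high} Hz >= Nyquist "
            f"{nyquist:.4g} Hz at TR {tr} s"
        )
    n = x.shape[0]
    if n <= 3 * params.filter_order:
        raise ParameterError(
            f"series length {n} too short for order {params.filter_order}"
        )
    if not np.all(np.isfinite(x)):
        raise ParameterError("series contains non-finite values")
    sos = signal.butter(
        params.filter_order,
        (params.passband_low, params.passband_high),
        btype="bandpass",
        fs=1.0 / tr,
        output="sos",
    )
    x = x - x.mean(axis=0, keepdims=True)
    return signal.sosfiltfilt(sos, x, axis=0)


def global_signal_regress(
    series_matrix: np.ndarray, global_signal: np.ndarray | None = None,
    detrend: bool = False,
) -> np.ndarray:
    """Regress the global mean series out of every column.

    ``series_matrix`` is frames x series (regions or in-mask voxels); the
    global signal defaults to the unweighted row mean.  Each column is
    replaced by its residual after least squares on {intercept, global
    signal} (plus a linear term when ``detrend``), so every residual is
    exactly orthogonal to the global signal.
    """
    x = np.asarray(series_matrix, dtype=np.float64)
    if x.ndim != 2:
        raise DimensionError("expected a frames x series matrix")
    if x.shape[0] < 2:
        raise DegenerateDataError("need at least 2 time points")
    g = x.mean(axis=1) if global_signal is None else np.asarray(global_signal,
                                                               dtype=np.float64)
    if g.shape != (x.shape[0],):
        raise DimensionError("global signal length must match frame count")
    if np.ptp(g) == 0:
        raise DegenerateDataError("degenerate global signal (constant)")
    cols = [np.ones_like(g), g]
    if detrend:
        cols.insert(1, np.linspace(-1.0, 1.0, len(g)))
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def gaussian_smooth(
    bold: BoldImage, fwhm: float, mask: VolumeImage | None = None
) -> BoldImage:
    """Per-frame 3D Gaussian smoothing at the stated FWHM in mm.

    sigma per axis is fwhm / (2 sqrt(2 ln 2)) / voxel_dim.  With a mask, the
    kernel is renormalised inside the mask (smoothing of data*mask divided
    by smoothing of mask) so no intensity bleeds in from the zeroed
    background and the in-mask mean is preserved.  ``fwhm == 0`` is the
    identity.
    """
    if fwhm < 0:
        raise ParameterError("fwhm must be >= 0")
    if fwhm == 0:
        return BoldImage(data=bold.data.copy(), voxel_dims=bold.voxel_dims,
                         tr=bold.tr)
    sigma_vox = [fwhm / FWHM_TO_SIGMA / v for v in bold.voxel_dims]
    out = np.empty_like(bold.data)
    if mask is not None:
        if mask.data.shape != bold.spatial_shape:
            raise DimensionError("mask grid does not match BOLD spatial grid")
        m = np.asarray(mask.data, dtype=np.float64)
        norm = ndimage.gaussian_filter(m, sigma_vox)
        inside = m > 0
        for t in range(bold.n_frames):
            sm = ndimage.gaussian_filter(bold.data[..., t] * m, sigma_vox)
            frame = np.zeros(bold.spatial_shape)
            frame[inside] = sm[inside] / norm[inside]
            out[..., t] = frame
    else:
        for t in range(bold.n_frames):
            out[..., t] = ndimage.gaussian_filter(bold.data[..., t], sigma_vox)
    return BoldImage(data=out, voxel_dims=bold.voxel_dims, tr=bold.tr)


def preprocess_voxel_pipeline(
    bold: BoldImage, mask: VolumeImage, params: PreprocessParams
) -> BoldImage:
    """Fixed-order voxel pipeline: mask -> band-pass -> GSR -> smooth."""
    log.info(
        "preprocess: mask -> bandpass (%g-%g Hz, order %d) -> GSR -> "
        "smooth (FWHM %g mm)",
        params.passband_low, params.passband_high, params.filter_order,
        params.fwhm,
    )
    masked = apply_brain_mask(bold, mask)
    inside = np.asarray(mask.data) > 0
    series = masked.data[inside].T          # frames x voxels
    series = bandpass_filter(series, bold.tr, params)
    series = global_signal_regress(series, detrend=params.detrend)
    data = np.zeros_like(masked.data)
    data[inside] = series.T
    smoothed = gaussian_smooth(
        BoldImage(data=data, voxel_dims=bold.voxel_dims, tr=bold.tr),
        params.fwhm, mask=mask,
    )
    return smoothed


def preprocess_region_series(
    series_matrix: np.ndarray, tr: float, params: PreprocessParams
) -> np.ndarray:
    """Region-series mode: band-pass then global-signal regression (no mask
    or smoothing at the region level)."""
    filtered = bandpass_filter(series_matrix, tr, params)
    return global_signal_regress(filtered, detrend=params.detrend)
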