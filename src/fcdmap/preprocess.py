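"""Computational preprocessing chain: volume dropping, motion screening,
nuisance regression, spatial smoothing and temporal band-pass filtering.

Spatial registration steps are out of scope: inputs are assumed to share a
common grid already.  The canonical stage order is drop -> motion screening
-> nuisance regression -> smoothing -> band-pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionalityError, ParameterError
from .io_formats import BrainMask, Series4D

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceModel:
    """Which nuisance regressors to project out.

    ``wm_series``/``csf_series`` are mean tissue signals (one value per
    volume); the motion model is the 24-parameter expansion of the 6
    realignment parameters (params, their lag-1 copies, and squares of both).
    """

    include_linear_trend: bool = True
    wm_series: np.ndarray | None = None
    csf_series: np.ndarray | None = None
    include_motion: bool = True


def drop_initial_volumes(series: Series4D, n: int = 10) -> Series4D:
    """Remove the first ``n`` time points."""
    if n < 0:
        raise ParameterError("n must be non-negative")
    if n >= series.n_volumes:
        raise DimensionalityError(
            f"cannot drop {n} volumes from a series of {series.n_volumes}"
        )
    return Series4D(grid=series.grid, data=series.data[..., n:], tr_seconds=series.tr_seconds)


def exceeds_motion_limit(trace: np.ndarray, trans_limit: float = 2.5,
                         rot_limit: float = 2.5) -> bool:
    """True iff any |translation| exceeds ``trans_limit`` mm or any
    |rotation| exceeds ``rot_limit`` degrees (strict inequality)."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6 or trace.shape[0] < 1:
        raise DimensionalityError("motion trace must be non-empty (n, 6)")
    return bool(
        (np.abs(trace[:, :3]) > trans_limit).any()
        or (np.abs(trace[:, 3:]) > rot_limit).any()
    )


def framewise_displacement(trace: np.ndarray, head_radius: float = 50.0) -> np.ndarray:
    """Power-style FD per volume transition: sum of |Δtranslation| plus
    head_radius times sum of |Δrotation| in radians."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6 or trace.shape[0] < 2:
        raise DimensionalityError("motion trace must be (n >= 2, 6)")
    delta = np.diff(trace, axis=0)
    trans = np.abs(delta[:, :3]).sum(axis=1)
    rot = np.abs(np.deg2rad(delta[:, 3:])).sum(axis=1)
    return trans + head_radius * rot


def mean_framewise_displacement(trace: np.ndarray, head_radius: float = 50.0) -> float:
    """Mean FD across volume transitions — the per-subject head-motion covariate."""
    return float(framewise_displacement(trace, head_radius).mean())


def friston24(trace: np.ndarray) -> np.ndarray:
    """Friston 24-parameter expansion: the 6 parameters, their one-volume-back
    lags (zero for the first volume), and the squares of both."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise DimensionalityError("motion trace must be (n, 6)")
    lagged = np.vstack([np.zeros((1, 6)), trace[:-1]])
    return np.hstack([trace, lagged, trace ** 2, lagged ** 2])


def build_nuisance_design(model: NuisanceModel, trace: np.ndarray | None,
                          n_volumes: int) -> np.ndarray:
    """Assemble the (n_volumes, p) nuisance design, intercept first."""
    cols = [np.ones(n_volumes)]
    if model.include_linear_trend:
        cols.append(np.linspace(-1.0, 1.0, n_volumes))
    for tissue in (model.wm_series, model.csf_series):
        if tissue is not None:
            tissue = np.asarray(tissue, dtype=float)
            if tissue.shape != (n_volumes,):
                raise DimensionalityError("tissue regressor length mismatch")
            cols.append(tissue)
    if model.include_motion:
        if trace is None:
            raise ParameterError("motion model requested but no trace given")
        if trace.shape[0] != n_volumes:
            raise DimensionalityError("motion trace length does not match series")
        cols.append(friston24(trace))
    return np.column_stack(cols)


def regress_nuisance(series: Series4D, model: NuisanceModel,
                     trace: np.ndarray | None = None) -> Series4D:
    """Per-voxel least-squares residuals after projecting out the nuisance
    design.  Rank-deficient designs fall back to the pseudo-inverse with a
    warning."""
    design = build_nuisance_design(model, trace, series.n_volumes)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("nuisance design is rank-deficient; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
    flat = series.data.reshape(-1, series.n_volumes)  # (V, T)
    beta = np.linalg.pinv(design) @ flat.T            # (p, V)
    resid = flat.T - design @ beta                    # (T, V)
    return Series4D(grid=series.grid,
                    data=resid.T.reshape(series.data.shape),
                    tr_seconds=series.tr_seconds)


def bandpass_array(data: np.ndarray, tr_seconds: float, low: float = 0.01,
                   high: float = 0.1, roll_off_hz: float = 0.002) -> np.ndarray:
    """Band-pass along the last axis via a frequency-domain filter with
    half-cosine roll-off of width ``roll_off_hz`` outside [low, high]."""
    if low < 0 or high <= low:
        raise ParameterError(f"invalid band [{low}, {high}]")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if high >= nyquist:
        raise ParameterError(f"high cutoff {high} Hz >= Nyquist {nyquist} Hz")
    n = data.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    weights = np.zeros_like(freqs)
    inband = (freqs >= low) & (freqs <= high)
    weights[inband] = 1.0
    if roll_off_hz > 0:
        lo_ramp = (freqs >= low - roll_off_hz) & (freqs < low)
        weights[lo_ramp] = 0.5 * (1 + np.cos(np.pi * (low - freqs[lo_ramp]) / roll_off_hz))
        hi_ramp = (freqs > high) & (freqs <= high + roll_off_hz)
        weights[hi_ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_ramp] - high) / roll_off_hz))
    spectrum = np.fft.rfft(data, axis=-1)
    return np.fft.irfft(spectrum * weights, n=n, axis=-1)


def bandpass(series: Series4D, low: float = 0.01, high: float = 0.1,
             roll_off_hz: float = 0.002) -> Series4D:
    return Series4D(grid=series.grid,
                    data=bandpass_array(series.data, series.tr_seconds, low, high,
                                        roll_off_hz),
                    tr_seconds=series.tr_seconds)


def smooth_gaussian(data: np.ndarray, fwhm_mm: float,
                    voxel_size: tuple[float, float, float],
                    mask: np.ndarray | None = None) -> np.ndarray:
    """3D Gaussian smoothing of a volume (3D array) or series (4D array,
    smoothed volume-by-volume).

    Outside-grid values are treated as zero.  When ``mask`` is given the
    result is renormalized by the smoothed mask inside it (avoiding edge
    attenuation at mask borders) and set to zero outside.
    """
    if fwhm_mm < 0:
        raise ParameterError("fwhm must be >= 0")
    data = np.asarray(data, dtype=float)
    if data.ndim not in (3, 4):
        raise DimensionalityError("expected a 3D volume or 4D series")
    if fwhm_mm == 0:
        out = data.copy()
        if mask is not None:
            out *= (np.asarray(mask, bool)[..., None] if data.ndim == 4
                    else np.asarray(mask, bool))
        return out
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in voxel_size]
    sigma = sigma_vox + [0.0] if data.ndim == 4 else sigma_vox

    if mask is None:
        return ndimage.gaussian_filter(data, sigma=sigma, mode="constant", cval=0.0)

    m = np.asarray(mask, bool).astype(float)
    sm_mask = ndimage.gaussian_filter(m, sigma=sigma_vox, mode="constant", cval=0.0)
    masked = data * (m[..., None] if data.ndim == 4 else m)
    smoothed = ndimage.gaussian_filter(masked, sigma=sigma, mode="constant", cval=0.0)
    denom = np.where(sm_mask > 0, sm_mask, 1.0)
    out = smoothed / (denom[..., None] if data.ndim == 4 else denom)
    out *= (m[..., None] if data.ndim == 4 else m)
    return out


def smooth_series(series: Series4D, fwhm_mm: float = 6.0,
                  mask: BrainMask | None = None) -> Series4D:
    inside = mask.inside if mask is not None else None
    return Series4D(grid=series.grid,
                    data=smooth_gaussian(series.data, fwhm_mm,
                                         series.grid.voxel_size, inside),
                    tr_seconds=series.tr_seconds)


def preprocess_series(series: Series4D, trace: np.ndarray | None = None,
                      model: NuisanceModel | None = None, drop: int = 10,
                      fwhm_mm: float = 6.0, band: tuple[float, float] = (0.01, 0.1),
                      mask: BrainMask | None = None,
                      smooth_before_filter: bool = True) -> Series4D:
    """Full chain with the canonical stage order (filter/smooth order is
    configurable; smoothing first is the default)."""
    out = drop_initial_volumes(series, drop) if drop else series
    if trace is not None and trace.shape[0] == series.n_volumes and drop:
        trace = trace[drop:]
    if model is not None:
        out = regress_nuisance(out, model, trace)
    stages = [lambda s: smooth_series(s, fwhm_mm, mask),
              lambda s: bandpass(s, *band)]
    if not smooth_before_filter:
        stages.reverse()
    for stage in stages:
        out = stage(out)
    return out
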