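"""Voxel-wise cerebrovascular-reactivity (CVR) mapping.

Two estimation modes:

- absolute: OLS of each voxel time course on the synchronized EtCO2 regressor
  (linear trend as covariate), scaled to %ΔBOLD per mmHg of CO2;
- relative (gas-free): OLS on the detrended, low-pass-filtered whole-brain
  mean signal, each voxel's percent coefficient normalized by the whole-brain
  mean coefficient (relative units, mask mean 1).

Negative values inside the ventricles are the quantity of interest: a
vasodilation-driven exchange of bright stroma for dark blood in choroid-plexus
voxels lowers the signal while parenchymal BOLD rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import InvalidArgumentError
from .params import AcquisitionParams
from .physio import EtCO2Series

FWHM_TO_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))
MIN_MEAN_FRACTION = 0.05  # voxels dimmer than 5% of the mask mean are excluded


@dataclass
class BoldSeries:
    """A 4D BOLD acquisition: data (x, y, z, t), acquisition parameters, brain mask."""

    data: np.ndarray
    acq: AcquisitionParams
    brain_mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.data.ndim != 4:
            raise InvalidArgumentError("data must be 4D (x, y, z, t)")
        if self.data.shape[-1] != self.acq.n_volumes:
            raise InvalidArgumentError(
                f"time dimension {self.data.shape[-1]} != acq.n_volumes {self.acq.n_volumes}"
            )
        if self.brain_mask.shape != self.data.shape[:3]:
            raise InvalidArgumentError("brain_mask shape must match the spatial grid")

    @property
    def volume_times(self) -> np.ndarray:
        return self.acq.volume_times

    def global_mean(self) -> np.ndarray:
        """Whole-brain mean time course over the brain mask."""
        return self.data[self.brain_mask].mean(axis=0)


@dataclass
class CVRMap:
    """3D CVR coefficient map.

    units is "%dBOLD/mmHg" for absolute maps or "r.u." for relative maps;
    ``mask`` is the set of voxels with a valid estimate; metadata records the
    regressor type, filter settings and normalization constant.
    """

    values: np.ndarray
    units: str
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise InvalidArgumentError("values and mask shapes differ")

    def mean_in(self, roi: np.ndarray) -> float:
        roi = np.asarray(roi, bool) & self.mask
        if not roi.any():
            raise InvalidArgumentError("ROI does not intersect the map mask")
        return float(self.values[roi].mean())


def smooth_gaussian(b: BoldSeries, fwhm: float) -> BoldSeries:
    """Spatially smooth each volume with a 3D Gaussian of the given FWHM (mm).

    FWHM is converted to sigma via FWHM = sigma * sqrt(8 ln 2) and divided by
    the voxel edge length per axis, so anisotropic voxels are honored.
    fwhm = 0 is the identity.
    """
    if fwhm < 0:
        raise InvalidArgumentError("fwhm must be >= 0")
    if fwhm == 0:
        return BoldSeries(b.data.copy(), b.acq, b.brain_mask.copy())
    sigma_mm = fwhm / FWHM_TO_SIGMA
    sigmas = tuple(sigma_mm / v for v in b.acq.voxel_size) + (0.0,)
    return BoldSeries(ndimage.gaussian_filter(b.data, sigma=sigmas), b.acq, b.brain_mask.copy())


def _voxelwise_ols(data: np.ndarray, mask: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Solve y = X b for every masked voxel; returns (n_masked, n_regressors)."""
    Y = data[mask].T  # (t, n_voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return beta.T


def _valid_voxels(data: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exclude near-zero-signal voxels (mean below 5% of the mask mean)."""
    ybar = data.mean(axis=-1)
    threshold = MIN_MEAN_FRACTION * ybar[mask].mean()
    valid = mask & (ybar > threshold)
    return valid, ybar


def fit_cvr_glm(b: BoldSeries, etco2: EtCO2Series) -> CVRMap:
    """Absolute CVR map in %ΔBOLD/mmHg from a synchronized EtCO2 regressor.

    Per voxel: OLS y(t) = b0 + b1*EtCO2(t) + b2*t, with t a linear trend
    covariate; CVR = 100 * b1 / mean(y). Voxels with mean signal below 5% of
    the mask mean are excluded (division guard).
    """
    if len(etco2.values) != b.acq.n_volumes:
        raise InvalidArgumentError("EtCO2 series length does not match the BOLD series")
    if np.std(etco2.values) == 0:
        raise InvalidArgumentError("EtCO2 regressor has zero variance for this run")
    t = np.arange(b.acq.n_volumes, dtype=float)
    X = np.column_stack([np.ones_like(t), etco2.values, t])
    valid, ybar = _valid_voxels(b.data, b.brain_mask)
    beta = _voxelwise_ols(b.data, valid, X)
    values = np.zeros(b.data.shape[:3])
    values[valid] = 100.0 * beta[:, 1] / ybar[valid]
    return CVRMap(
        values,
        units="%dBOLD/mmHg",
        mask=valid,
        metadata={
            "regressor": "etco2",
            "applied_delay_s": etco2.applied_delay,
            "covariates": ["intercept", "linear_trend"],
        },
    )


def global_regressor(b: BoldSeries, cutoff: float = 0.1164, order: int = 2) -> np.ndarray:
    """Low-frequency global-signal regressor for gas-free relative CVR.

    Whole-brain mean time course, linearly detrended, then zero-phase
    low-pass Butterworth filtered (forward-backward) at ``cutoff`` Hz.
    """
    fs = 1000.0 / b.acq.tr
    nyquist = fs / 2.0
    if not 0 < cutoff < nyquist:
        raise InvalidArgumentError(f"cutoff must lie in (0, Nyquist={nyquist:.4f} Hz)")
    g = signal.detrend(b.global_mean(), type="linear")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, g)


def fit_relative_cvr(
    b: BoldSeries,
    regressor: np.ndarray,
    motion: np.ndarray | None = None,
) -> CVRMap:
    """Relative CVR map (r.u.) from an arbitrary (typically global-signal) regressor.

    Per voxel: OLS coefficient on the regressor with intercept, linear trend
    and optional motion covariates; coefficients are expressed as percent of
    the voxel mean, then divided by their whole-brain mean so the map has mask
    mean 1. If the whole-brain mean coefficient is not positive the map cannot
    be normalized: the unnormalized percent map is returned with
    ``metadata["normalized"] = False``.
    """
    regressor = np.asarray(regressor, dtype=float)
    if regressor.shape != (b.acq.n_volumes,):
        raise InvalidArgumentError("regressor length does not match the BOLD series")
    if np.std(regressor) == 0:
        raise InvalidArgumentError("regressor has zero variance for this run")
    t = np.arange(b.acq.n_volumes, dtype=float)
    cols = [np.ones_like(t), regressor, t]
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] == b.acq.n_volumes:
            motion = motion.T
        if motion.shape[1] != b.acq.n_volumes:
            raise InvalidArgumentError("motion covariates must match the number of volumes")
        cols.extend(list(motion))
    X = np.column_stack(cols)
    valid, ybar = _valid_voxels(b.data, b.brain_mask)
    beta = _voxelwise_ols(b.data, valid, X)
    percent = 100.0 * beta[:, 1] / ybar[valid]
    norm = float(percent.mean())
    values = np.zeros(b.data.shape[:3])
    meta = {
        "regressor": "global_signal",
        "covariates": ["intercept", "linear_trend"] + (["motion"] if motion is not None else []),
        "normalization_constant": norm,
        "normalized": norm > 0,
    }
    if norm > 0:
        values[valid] = percent / norm
        units = "r.u."
    else:  # flagged: emit the unnormalized percent map
        values[valid] = percent
        units = "%dBOLD/unit"
    return CVRMap(values, units=units, mask=valid, metadata=meta)
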