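"""End-tidal CO2 extraction and BOLD/EtCO2 synchronization.

The capnograph records pCO2 breath by breath; the regressor the CVR model
needs is the end-tidal envelope sampled at the BOLD volume times, shifted by
the delay between the recording and the cerebral response. The delay is found
by brute-force search: for each candidate delay the shifted EtCO2 is regressed
against the whole-brain BOLD time course and the sum-of-square residual is
minimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import EmptyPhysioError, InvalidArgumentError
from .respiration import RespiratoryTrace

PHYSIO_RANGE = (10.0, 80.0)  # plausible EtCO2 range, mmHg


@dataclass
class EtCO2Series:
    """End-tidal CO2 resampled at BOLD volume times.

    ``applied_delay`` (s) is the shift already applied to the recording;
    ``out_of_range`` flags values outside the physiological 10-80 mmHg window.
    """

    volume_times: np.ndarray
    values: np.ndarray
    applied_delay: float = 0.0

    def __post_init__(self):
        self.volume_times = np.asarray(self.volume_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.volume_times.shape != self.values.shape:
            raise InvalidArgumentError("volume_times and values must have equal length")

    @property
    def out_of_range(self) -> bool:
        return bool(np.any((self.values < PHYSIO_RANGE[0]) | (self.values > PHYSIO_RANGE[1])))


@dataclass
class DelayFit:
    """Result of the residual-minimizing delay search.

    residual_curve is an (n_candidates, 2) array of (delay_s, rss);
    ``at_boundary`` warns that the optimum sits on the search-range edge.
    """

    best_delay: float
    residual_curve: np.ndarray
    search_range: tuple[float, float]

    @property
    def at_boundary(self) -> bool:
        lo, hi = self.search_range
        return bool(np.isclose(self.best_delay, lo) or np.isclose(self.best_delay, hi))


def extract_end_tidal(
    trace: RespiratoryTrace,
    min_breath_interval: float = 2.0,
    prominence_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect expiratory plateaus and return breath-wise (times, EtCO2) samples.

    A breath's end-tidal value is the local maximum of the pCO2 waveform;
    peaks must be separated by at least ``min_breath_interval`` seconds and
    have prominence of at least ``prominence_fraction`` of the trace's dynamic
    range (robust to plateau noise).
    """
    pco2 = np.asarray(trace.pco2, dtype=float)
    dynamic_range = float(np.ptp(pco2))
    distance = max(1, int(round(min_breath_interval * trace.sampling_rate)))
    if dynamic_range <= 1e-9:
        raise EmptyPhysioError(
            f"no breaths detected: trace is constant at {pco2[0]:.2f} mmHg "
            f"(dynamic range {dynamic_range:.3g} mmHg)"
        )
    peaks, _ = find_peaks(
        pco2, distance=distance, prominence=prominence_fraction * dynamic_range, plateau_size=1
    )
    if len(peaks) < 2:
        raise EmptyPhysioError(
            f"no breaths detected: {len(peaks)} peak(s) found with "
            f"min interval {min_breath_interval}s and prominence "
            f">= {prominence_fraction:.0%} of range {dynamic_range:.1f} mmHg"
        )
    return trace.times[peaks], pco2[peaks]


def resample_to_volumes(
    breath_times: np.ndarray,
    breath_values: np.ndarray,
    volume_times: np.ndarray,
    applied_delay: float = 0.0,
) -> EtCO2Series:
    """Linearly interpolate breath-wise EtCO2 onto BOLD volume times.

    ``applied_delay`` shifts the recording earlier: the value assigned to
    volume time t is the recorded EtCO2 at t + applied_delay (edge values are
    held beyond the recording).
    """
    values = np.interp(np.asarray(volume_times) + applied_delay, breath_times, breath_values)
    return EtCO2Series(np.asarray(volume_times, float), values, applied_delay=applied_delay)


def _ols_rss(y: np.ndarray, x: np.ndarray) -> float:
    """Residual sum of squares of y ~ intercept + x."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def find_optimal_delay(
    breath_times: np.ndarray,
    breath_values: np.ndarray,
    bold_global: np.ndarray,
    volume_times: np.ndarray,
    search_range: tuple[float, float] = (-5.0, 30.0),
    step: float = 0.5,
    min_overlap: float = 0.8,
) -> DelayFit:
    """Find the EtCO2 delay minimizing the residual against the global BOLD course.

    For each candidate delay the breath-wise EtCO2 is shifted, resampled to
    the volume times, and regressed (OLS, intercept + EtCO2) against the
    whole-brain mean BOLD time course; the delay with the lowest residual sum
    of squares wins. Every candidate must keep at least ``min_overlap`` of the
    scan inside the recorded trace.
    """
    breath_times = np.asarray(breath_times, float)
    breath_values = np.asarray(breath_values, float)
    volume_times = np.asarray(volume_times, float)
    bold_global = np.asarray(bold_global, float)
    if bold_global.shape != volume_times.shape:
        raise InvalidArgumentError("bold_global and volume_times must have equal length")
    lo, hi = search_range
    if not hi > lo or step <= 0:
        raise InvalidArgumentError("search_range must be increasing and step positive")
    delays = np.arange(lo, hi + step / 2, step)
    for d in (delays[0], delays[-1]):
        shifted = volume_times + d
        overlap = np.mean((shifted >= breath_times[0]) & (shifted <= breath_times[-1]))
        if overlap < min_overlap:
            raise InvalidArgumentError(
                f"delay {d:+.1f}s leaves only {overlap:.0%} of the scan inside the "
                f"recorded trace (need >= {min_overlap:.0%})"
            )
    rss = np.array(
        [
            _ols_rss(bold_global, np.interp(volume_times + d, breath_times, breath_values))
            for d in delays
        ]
    )
    best = delays[int(np.argmin(rss))]
    return DelayFit(float(best), np.column_stack([delays, rss]), (float(lo), float(hi)))


def synchronize(
    trace: RespiratoryTrace,
    bold_global: np.ndarray,
    volume_times: np.ndarray,
    search_range: tuple[float, float] = (-5.0, 30.0),
    step: float = 0.5,
    min_breath_interval: float = 2.0,
) -> tuple[EtCO2Series, DelayFit]:
    """Full synchronization: extract end-tidal samples, search the delay, resample."""
    bt, bv = extract_end_tidal(trace, min_breath_interval=min_breath_interval)
    fit = find_optimal_delay(bt, bv, bold_global, volume_times, search_range, step)
    series = resample_to_volumes(bt, bv, volume_times, applied_delay=fit.best_delay)
    return series, fit
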