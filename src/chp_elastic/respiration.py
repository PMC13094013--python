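"""Synthetic capnograph traces for the three vasoactive paradigms.

Each simulator produces a breath-by-breath CO2 waveform: during expiration the
measured pCO2 rises to an end-tidal plateau (tracking arterial CO2), during
inspiration it falls toward the near-zero CO2 content of inhaled air. The
slowly varying end-tidal *envelope* is the physiological quantity of interest;
downstream code recovers it by peak detection (see :mod:`chp_elastic.physio`).

Paradigms
---------
- hypercapnia: room air / CO2-enriched air alternating in fixed blocks,
  first-order wash-in, optional recording delay.
- breath modulation: brief paced-breathing epochs (3 breaths of 2 s in /
  2 s out) that transiently lower EtCO2, separated by randomized free
  breathing — a gas-free way to modulate arterial CO2.
- resting: spontaneous low-frequency EtCO2 fluctuation, band-limited noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

INSPIRED_PCO2 = 2.0  # mmHg, residual CO2 seen by the capnograph during inspiration


@dataclass
class RespiratoryTrace:
    """Raw sampled CO2 waveform.

    times in s (strictly increasing), pco2 in mmHg, sampling_rate in Hz.
    ``meta`` records the generating paradigm and its ground-truth parameters
    (e.g. the recording delay) for downstream validation.
    """

    times: np.ndarray
    pco2: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.pco2 = np.asarray(self.pco2, dtype=float)
        if self.times.shape != self.pco2.shape:
            raise InvalidArgumentError("times and pco2 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.any(self.pco2 < 0):
            raise InvalidArgumentError("pco2 must be non-negative")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def _first_order_response(times: np.ndarray, target: np.ndarray, tau: float, y0: float) -> np.ndarray:
    """Exact piecewise-exponential relaxation of y toward target(t) with time constant tau."""
    if tau <= 0:
        return target.copy()
    y = np.empty_like(target)
    y[0] = y0
    dt = np.diff(times)
    decay = np.exp(-dt / tau)
    for i in range(1, len(times)):
        y[i] = target[i] + (y[i - 1] - target[i]) * decay[i - 1]
    return y


def _breath_waveform(
    times: np.ndarray,
    envelope: np.ndarray,
    breath_period: float,
    rng: np.random.Generator,
    plateau_jitter: float = 0.3,
) -> np.ndarray:
    """Impose a breathing carrier on an end-tidal envelope.

    Within each breath cycle: inspiration (low pCO2) for the first 40%, a
    half-cosine rise for 30%, then an expiratory plateau at the envelope value
    for the final 30%. A small per-breath plateau jitter (mmHg) emulates
    breath-to-breath variability.
    """
    phase = (times / breath_period) % 1.0
    shape = np.where(
        phase < 0.4,
        0.0,
        np.where(phase < 0.7, 0.5 * (1 - np.cos(np.pi * (phase - 0.4) / 0.3)), 1.0),
    )
    breath_index = np.floor(times / breath_period).astype(int)
    n_breaths = breath_index.max() + 1
    jitter = rng.normal(0.0, plateau_jitter, size=n_breaths)[breath_index]
    plateau = np.maximum(envelope + jitter, INSPIRED_PCO2)
    return INSPIRED_PCO2 + (plateau - INSPIRED_PCO2) * shape


def simulate_etco2_hypercapnia(
    duration: float = 420.0,
    block_length: float = 60.0,
    baseline: float = 40.0,
    delta: float = 8.0,
    breath_period: float = 4.0,
    delay: float = 0.0,
    tau: float = 10.0,
    sampling_rate: float = 10.0,
    seed: int | None = 0,
    plateau_jitter: float = 0.3,
) -> RespiratoryTrace:
    """Capnograph trace for a block hypercapnia challenge.

    Room air and CO2-enriched air alternate every ``block_length`` seconds,
    starting with room air, for ``duration`` seconds total. The end-tidal
    envelope follows the block design through a first-order wash-in/wash-out
    (time constant ``tau``) and is shifted by ``delay`` seconds — the lag of
    the recorded trace behind the design (sampling-line transit plus lung-to-
    capnograph delay), which the synchronization step must recover.
    """
    if duration <= 0 or block_length <= 0 or breath_period <= 0:
        raise InvalidArgumentError("duration, block_length and breath_period must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, 1.0 / sampling_rate)
    design_times = times - delay  # recorded trace lags the design by `delay`
    block = np.floor(np.maximum(design_times, 0.0) / block_length).astype(int)
    target = baseline + delta * (block % 2 == 1)
    envelope = _first_order_response(times, target.astype(float), tau, baseline)
    pco2 = _breath_waveform(times, envelope, breath_period, rng, plateau_jitter)
    meta = dict(
        paradigm="hypercapnia",
        baseline=baseline,
        delta=delta,
        block_length=block_length,
        delay=delay,
        tau=tau,
        breath_period=breath_period,
    )
    return RespiratoryTrace(times, pco2, sampling_rate, meta)


def simulate_etco2_breathmod(
    duration: float = 420.0,
    n_paced_epochs: int = 7,
    free_min: float = 30.0,
    free_max: float = 60.0,
    baseline: float = 40.0,
    dip: float = -4.0,
    recovery_tau: float = 15.0,
    dip_tau: float = 4.0,
    breath_period: float = 4.0,
    sampling_rate: float = 10.0,
    seed: int | None = 0,
    plateau_jitter: float = 0.3,
) -> RespiratoryTrace:
    """Capnograph trace for intermittent breath modulation.

    Each paced epoch is three breaths of 2 s in / 2 s out (12 s); epochs are
    separated by free-breathing gaps drawn uniformly from
    [``free_min``, ``free_max``]. Paced breathing transiently lowers EtCO2 by
    ``dip`` mmHg (signed; negative = hypocapnic dip) with fast onset
    (``dip_tau``) and slower recovery (``recovery_tau``).
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if free_min > free_max or free_min < 0:
        raise InvalidArgumentError("need 0 <= free_min <= free_max")
    epoch_len = 12.0  # 3 breaths x (2 s in + 2 s out)
    rng = np.random.default_rng(seed)
    if n_paced_epochs > 0 and n_paced_epochs * (epoch_len + free_min) > duration:
        raise InvalidArgumentError(
            f"{n_paced_epochs} paced epochs plus free-breathing gaps exceed duration {duration} s"
        )
    # draw gap vectors until the schedule fits the run (feasibility checked above)
    gaps = rng.uniform(free_min, free_max, size=n_paced_epochs)
    while n_paced_epochs > 0 and gaps.sum() + epoch_len * n_paced_epochs > duration:
        gaps = rng.uniform(free_min, free_max, size=n_paced_epochs)
    starts = np.cumsum(gaps) + epoch_len * np.arange(n_paced_epochs)
    times = np.arange(0.0, duration, 1.0 / sampling_rate)
    in_epoch = np.zeros_like(times, dtype=bool)
    for s in starts:
        in_epoch |= (times >= s) & (times < s + epoch_len)
    target = baseline + dip * in_epoch
    # fast dip during paced epochs, slower recovery afterwards
    env = np.empty_like(times)
    env[0] = baseline
    for i in range(1, len(times)):
        tau = dip_tau if in_epoch[i] else recovery_tau
        dt = times[i] - times[i - 1]
        env[i] = target[i] + (env[i - 1] - target[i]) * np.exp(-dt / tau)
    pco2 = _breath_waveform(times, env, breath_period, rng, plateau_jitter)
    meta = dict(
        paradigm="breathmod",
        baseline=baseline,
        dip=dip,
        epoch_starts=starts.tolist(),
        epoch_length=epoch_len,
        delay=0.0,
    )
    return RespiratoryTrace(times, pco2, sampling_rate, meta)


def simulate_etco2_resting(
    duration: float = 600.0,
    baseline: float = 40.0,
    sd: float = 1.5,
    band: tuple[float, float] = (0.0, 0.05),
    breath_period: float = 4.0,
    sampling_rate: float = 10.0,
    seed: int | None = 0,
    plateau_jitter: float = 0.3,
) -> RespiratoryTrace:
    """Resting capnograph trace with band-limited spontaneous EtCO2 fluctuation.

    The end-tidal envelope is zero-mean Gaussian noise strictly band-limited
    to ``band`` (Hz, default 0-0.05), scaled to standard deviation ``sd``
    mmHg, superimposed on ``baseline``.
    """
    if sd < 0:
        raise InvalidArgumentError("sd must be non-negative")
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    lo, hi = band
    nyq = sampling_rate / 2.0
    if not (0 <= lo < hi <= nyq):
        raise InvalidArgumentError(f"band must satisfy 0 <= lo < hi <= Nyquist ({nyq} Hz)")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, 1.0 / sampling_rate)
    n = len(times)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    spectrum = np.zeros(len(freqs), dtype=complex)
    in_band = (freqs > lo) & (freqs <= hi) & (freqs > 0)
    spectrum[in_band] = rng.normal(size=in_band.sum()) + 1j * rng.normal(size=in_band.sum())
    fluct = np.fft.irfft(spectrum, n=n)
    if sd > 0 and fluct.std() > 0:
        fluct *= sd / fluct.std()
    else:
        fluct[:] = 0.0
    env = baseline + fluct
    pco2 = _breath_waveform(times, env, breath_period, rng, plateau_jitter)
    meta = dict(paradigm="resting", baseline=baseline, sd=sd, band=list(band), delay=0.0)
    return RespiratoryTrace(times, pco2, sampling_rate, meta)
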