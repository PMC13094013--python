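"""Biophysical 4D BOLD phantoms with a blood/stroma partial-volume ChP mechanism.

A choroid-plexus (ChP) voxel is modeled as a mixture of capillary blood,
stroma, ventricular CSF and static epithelium. Vasodilation (rising EtCO2)
expands the capillary space at the expense of the stroma, reciprocally, so the
total volume is conserved:

    f_blood(t) = f_blood0 + eps * (EtCO2(t) - EtCO2_baseline)
    f_stroma(t) = f_stroma0 - eps * (EtCO2(t) - EtCO2_baseline)

Because stroma is plasma-like (long T2*) and blood is not, the voxel signal

    S(t) = f_blood(t)*S_blood + f_stroma(t)*S_stroma + f_csf*S_csf + f_rest*S_epi

falls with EtCO2 whenever S_stroma > S_blood — i.e. at echo times beyond the
blood/stroma crossover — producing the negative-CVR signature in the
ventricles. Parenchymal (gray/white) voxels carry a conventional positive
multiplicative BOLD response. Compartment steady-state signals follow the
spoiled gradient-echo equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import physio
from .cvr import BoldSeries
from .errors import InvalidArgumentError, SimulationRangeError
from .params import (
    AcquisitionParams,
    CompartmentProperties,
    ElasticityParams,
    breathmod_acquisition,
    default_compartments,
    hypercapnia_acquisition,
    multiecho_acquisition,
)
from .respiration import (
    RespiratoryTrace,
    simulate_etco2_breathmod,
    simulate_etco2_hypercapnia,
    simulate_etco2_resting,
)

LABELS = {"background": 0, "gray": 1, "white": 2, "csf": 3, "chp": 4}

DEFAULT_PARENCHYMAL_CVR = {"gray": 0.20, "white": 0.10}  # %dBOLD per mmHg CO2


def spgr_signal(c: CompartmentProperties, acq: AcquisitionParams, te: float) -> float:
    """Steady-state spoiled gradient-echo signal of one compartment.

    S = m0 * sin(a) * (1 - E1) / (1 - cos(a) * E1) * exp(-TE / T2*),
    with E1 = exp(-TR / T1); ideal spoiling, inflow ignored.
    """
    if te < 0:
        raise InvalidArgumentError("te must be >= 0")
    alpha = math.radians(acq.flip_angle)
    e1 = math.exp(-acq.tr / c.t1)
    return c.m0 * math.sin(alpha) * (1 - e1) / (1 - math.cos(alpha) * e1) * math.exp(-te / c.t2star)


def blood_stroma_crossover_te(
    acq: AcquisitionParams, compartments: dict[str, CompartmentProperties] | None = None
) -> float:
    """Echo time at which blood and stroma signals are equal (ms).

    Below TE* blood is brighter (ChP response positive); above, stroma is
    brighter and vessel expansion darkens the voxel (negative response).
    """
    comp = compartments or default_compartments()
    b, s = comp["blood"], comp["stroma"]
    a0 = spgr_signal(b, acq, 0.0)
    a1 = spgr_signal(s, acq, 0.0)
    rate = 1.0 / b.t2star - 1.0 / s.t2star
    if rate <= 0 or a0 <= a1:
        return math.inf
    return math.log(a0 / a1) / rate


def chp_voxel_timecourse(
    e: ElasticityParams,
    etco2,
    acq: AcquisitionParams,
    te: float,
    compartments: dict[str, CompartmentProperties] | None = None,
    baseline: float | None = None,
) -> np.ndarray:
    """Signal time course of a ChP voxel under reciprocal blood/stroma exchange.

    ``etco2`` may be an :class:`~chp_elastic.physio.EtCO2Series` or a plain
    mmHg array; ``baseline`` defaults to its temporal mean. Raises
    :class:`SimulationRangeError` naming the first offending time point if a
    fraction leaves [0, 1].
    """
    if isinstance(etco2, physio.EtCO2Series):
        values, times = etco2.values, etco2.volume_times
    else:
        values = np.asarray(etco2, dtype=float)
        times = np.arange(len(values)) * acq.tr / 1000.0
    comp = compartments or default_compartments()
    base = float(np.mean(values)) if baseline is None else baseline
    d = values - base
    f_blood = e.f_blood0 + e.epsilon * d
    f_stroma = e.f_stroma0 - e.epsilon * d
    bad = (f_blood < 0) | (f_blood > 1) | (f_stroma < 0) | (f_stroma > 1)
    if bad.any():
        i = int(np.argmax(bad))
        raise SimulationRangeError(
            f"compartment fraction left [0, 1] at t = {times[i]:.2f} s "
            f"(f_blood = {f_blood[i]:.3f}, f_stroma = {f_stroma[i]:.3f})",
            time_s=float(times[i]),
        )
    s = {k: spgr_signal(comp[k], acq, te) for k in ("blood", "stroma", "csf", "epithelium")}
    return (
        f_blood * s["blood"]
        + f_stroma * s["stroma"]
        + e.f_csf * s["csf"]
        + e.f_rest * s["epithelium"]
    )


@dataclass
class PhantomSpec:
    """Phantom geometry plus per-class signal parameters.

    label_map is a 3D integer grid over the classes in :data:`LABELS`;
    parenchymal_cvr gives the positive BOLD response (%dBOLD/mmHg) of gray and
    white matter; elasticity parameterizes every ChP voxel; noise_sigma is the
    additive white-noise SD as a fraction of the mean parenchymal signal.
    """

    label_map: np.ndarray
    elasticity: ElasticityParams = field(default_factory=ElasticityParams)
    compartments: dict[str, CompartmentProperties] = field(default_factory=default_compartments)
    parenchymal_cvr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARENCHYMAL_CVR)
    )
    noise_sigma: float = 0.002
    seed: int = 0

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 3:
            raise InvalidArgumentError("label_map must be 3D")
        known = set(LABELS.values())
        if not set(np.unique(self.label_map)).issubset(known):
            raise InvalidArgumentError(f"label_map values must be among {sorted(known)}")
        if self.noise_sigma < 0:
            raise InvalidArgumentError("noise_sigma must be >= 0")
        chp = self.label_map == LABELS["chp"]
        if chp.any():
            # ChP sits inside the ventricle: every connected ChP component must
            # touch the ventricular CSF it borders.
            csf = self.label_map == LABELS["csf"]
            near_csf = ndimage.binary_dilation(csf, structure=np.ones((3, 3, 3), bool))
            labeled, n = ndimage.label(chp, structure=np.ones((3, 3, 3), bool))
            for lab in range(1, n + 1):
                if not np.any(near_csf & (labeled == lab)):
                    raise InvalidArgumentError(
                        "every ChP region must lie inside or adjacent to the "
                        "ventricular-CSF region"
                    )

    def mask(self, name: str) -> np.ndarray:
        return self.label_map == LABELS[name]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_map != LABELS["background"]


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return d <= 1.0


def default_phantom_spec(
    shape: tuple[int, int, int] = (32, 32, 16),
    noise_sigma: float = 0.002,
    seed: int = 0,
    elasticity: ElasticityParams | None = None,
) -> PhantomSpec:
    """Desk-scale head phantom: gray/white parenchyma, two ellipsoidal lateral
    ventricles, and 2-3-voxel-thick ChP strips on the medial ventricle walls."""
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    labels = np.zeros(shape, dtype=np.int16)
    brain = _ellipsoid(shape, (cx, cy, cz), (nx * 0.44, ny * 0.44, nz * 0.44))
    white = _ellipsoid(shape, (cx, cy, cz), (nx * 0.30, ny * 0.34, nz * 0.30))
    vent_l = _ellipsoid(shape, (cx - 5, cy, cz), (3.2, ny * 0.22, 3.2))
    vent_r = _ellipsoid(shape, (cx + 5, cy, cz), (3.2, ny * 0.22, 3.2))
    ventricles = vent_l | vent_r
    labels[brain] = LABELS["gray"]
    labels[white & ~ventricles] = LABELS["white"]
    labels[ventricles] = LABELS["csf"]
    x = np.arange(nx)[:, None, None]
    chp = (vent_l & (x >= cx - 3.5)) | (vent_r & (x <= cx + 3.5))
    labels[chp] = LABELS["chp"]
    return PhantomSpec(
        labels,
        elasticity=elasticity or ElasticityParams(),
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Sidecar truth record emitted with every phantom."""

    delay: float
    epsilon: float
    drive: np.ndarray  # EtCO2 seen by the brain, at volume times (mmHg)
    volume_times: np.ndarray
    cvr_maps: dict[float, np.ndarray]  # TE (ms) -> true CVR map (%dBOLD/mmHg)
    label_map: np.ndarray

    def mask(self, name: str) -> np.ndarray:
        return self.label_map == LABELS[name]


def build_phantom(
    spec: PhantomSpec,
    trace: RespiratoryTrace,
    acq: AcquisitionParams,
) -> tuple[list[BoldSeries], GroundTruth]:
    """Render 4D BOLD series (one per echo) driven by a capnograph trace.

    The physiological drive is the end-tidal envelope of ``trace`` advanced by
    the trace's recorded delay (the brain responds before the capnograph
    reports). Parenchymal voxels respond multiplicatively about the run-mean
    drive; ventricular CSF is static; ChP voxels follow the reciprocal
    blood/stroma exchange. White Gaussian noise (SD = noise_sigma x mean
    parenchymal signal) is added inside the head.
    """
    volume_times = acq.volume_times
    if volume_times[-1] > trace.times[-1] + 1e-9:
        raise InvalidArgumentError(
            f"scan duration {volume_times[-1]:.0f}s exceeds the trace ({trace.times[-1]:.0f}s)"
        )
    delay = float(trace.meta.get("delay", 0.0))
    bt, bv = physio.extract_end_tidal(trace)
    drive = np.interp(volume_times + delay, bt, bv)
    d = drive - drive.mean()

    comp = spec.compartments
    masks = {name: spec.mask(name) for name in ("gray", "white", "csf", "chp")}
    e = spec.elasticity
    rng = np.random.default_rng(spec.seed)
    series: list[BoldSeries] = []
    cvr_maps: dict[float, np.ndarray] = {}
    for te in acq.te_list:
        s = {k: spgr_signal(comp[k], acq, te) for k in comp}
        data = np.zeros(spec.label_map.shape + (acq.n_volumes,))
        truth = np.zeros(spec.label_map.shape)
        for tissue in ("gray", "white"):
            cvr = spec.parenchymal_cvr[tissue]
            data[masks[tissue]] = s[tissue] * (1.0 + cvr / 100.0 * d)
            truth[masks[tissue]] = cvr
        data[masks["csf"]] = s["csf"]
        if masks["chp"].any():
            course = chp_voxel_timecourse(e, drive, acq, te, comp, baseline=float(drive.mean()))
            data[masks["chp"]] = course
            s0_chp = (
                e.f_blood0 * s["blood"]
                + e.f_stroma0 * s["stroma"]
                + e.f_csf * s["csf"]
                + e.f_rest * s["epithelium"]
            )
            truth[masks["chp"]] = 100.0 * e.epsilon * (s["blood"] - s["stroma"]) / s0_chp
        if spec.noise_sigma > 0:
            tissue_mean = np.mean([s["gray"], s["white"]])
            brain = spec.brain_mask
            noise = rng.normal(0.0, spec.noise_sigma * tissue_mean, size=(brain.sum(), acq.n_volumes))
            data[brain] += noise
        series.append(BoldSeries(data, acq, spec.brain_mask))
        cvr_maps[te] = truth
    gt = GroundTruth(
        delay=delay,
        epsilon=e.epsilon,
        drive=drive,
        volume_times=volume_times,
        cvr_maps=cvr_maps,
        label_map=spec.label_map.copy(),
    )
    return series, gt


@dataclass
class SimulatedSubject:
    """One cohort member: multi-echo BOLD, capnograph trace, covariates, truth."""

    subject_id: str
    bold: list[BoldSeries]
    trace: RespiratoryTrace
    covariates: dict
    truth: GroundTruth


def _default_acq(paradigm: str) -> AcquisitionParams:
    return {
        "hypercapnia": hypercapnia_acquisition,
        "breathmod": breathmod_acquisition,
        "resting": multiecho_acquisition,
    }[paradigm]()


def iter_cohort(
    n_young: int = 17,
    n_old: int = 10,
    epsilon_young: float = 0.005,
    epsilon_old: float | None = None,
    paradigm: str = "hypercapnia",
    acq: AcquisitionParams | None = None,
    shape: tuple[int, int, int] = (32, 32, 16),
    noise_sigma: float = 0.002,
    epsilon_cv: float = 0.3,
    seed: int = 0,
):
    """Yield simulated subjects one at a time (memory-friendly form of
    :func:`simulate_cohort`; see there for semantics)."""
    if n_young < 2 or n_old < 2:
        raise InvalidArgumentError("need at least 2 subjects per group")
    if epsilon_old is None:
        epsilon_old = epsilon_young / 3.0
    if acq is None:
        acq = _default_acq(paradigm)
    rng = np.random.default_rng(seed)
    groups = ["young"] * n_young + ["old"] * n_old
    age_range = {"young": (20, 36), "old": (55, 81)}
    group_eps = {"young": epsilon_young, "old": epsilon_old}
    sex_counter = {"young": 0, "old": 0}
    for i, group in enumerate(groups):
        eps = group_eps[group] * max(0.2, 1.0 + epsilon_cv * rng.standard_normal())
        age = int(rng.integers(*age_range[group]))
        sex = "M" if sex_counter[group] % 2 == 0 else "F"
        sex_counter[group] += 1
        trace_seed = int(rng.integers(0, 2**31 - 1))
        spec_seed = int(rng.integers(0, 2**31 - 1))
        duration = acq.scan_duration + 20.0
        if paradigm == "hypercapnia":
            delay = float(rng.uniform(2.0, 10.0))
            trace = simulate_etco2_hypercapnia(duration=duration, delay=delay, seed=trace_seed)
        elif paradigm == "breathmod":
            trace = simulate_etco2_breathmod(duration=duration, seed=trace_seed)
        elif paradigm == "resting":
            trace = simulate_etco2_resting(duration=duration, seed=trace_seed)
        else:
            raise InvalidArgumentError(f"unknown paradigm {paradigm!r}")
        spec = default_phantom_spec(
            shape=shape,
            noise_sigma=noise_sigma,
            seed=spec_seed,
            elasticity=ElasticityParams(epsilon=eps),
        )
        bold, truth = build_phantom(spec, trace, acq)
        covariates = {"subject": f"sub-{i:03d}", "age": age, "sex": sex, "group": group}
        yield SimulatedSubject(f"sub-{i:03d}", bold, trace, covariates, truth)


def simulate_cohort(*args, **kwargs) -> list[SimulatedSubject]:
    """Simulate a two-group cohort with group-specific ChP elasticity.

    Each subject gets an elasticity epsilon drawn around the group value
    (lognormal-free multiplicative jitter, CV ``epsilon_cv``), an age from the
    group's range (young 20-35, old 55-80), alternating sex, an individual
    capnograph trace (with a random recording delay under hypercapnia) and an
    individually noisy phantom. Ground truth is attached per subject.
    """
    return list(iter_cohort(*args, **kwargs))
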