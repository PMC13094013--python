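"""Acquisition and tissue-compartment parameter containers.

The phantom treats every voxel as a mixture of compartments (blood, stroma,
ventricular CSF, epithelium, gray/white matter), each with its own relaxation
parameters. The asymmetry that drives the choroid-plexus (ChP) elasticity
signal is that stroma — plasma-like fluid — has a much longer T2*/T2 than
blood, so exchanging blood volume for stroma volume changes the voxel signal
in a TE-dependent way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

VALID_COMPARTMENTS = ("blood", "stroma", "csf", "gray", "white", "epithelium")


@dataclass(frozen=True)
class CompartmentProperties:
    """MR properties of one tissue compartment.

    Parameters
    ----------
    name : str
        One of ``blood | stroma | csf | gray | white | epithelium``.
    t1 : float
        Longitudinal relaxation time, ms.
    t2star : float
        Effective transverse relaxation time, ms.
    m0 : float
        Relative proton density (dimensionless, > 0). For blood this is an
        *effective* value that may exceed 1 to absorb steady-state inflow
        enhancement not otherwise modeled.
    """

    name: str
    t1: float
    t2star: float
    m0: float

    def __post_init__(self):
        if self.name not in VALID_COMPARTMENTS:
            raise InvalidArgumentError(
                f"unknown compartment {self.name!r}; expected one of {VALID_COMPARTMENTS}"
            )
        for attr in ("t1", "t2star", "m0"):
            if not getattr(self, attr) > 0:
                raise InvalidArgumentError(f"{self.name}.{attr} must be > 0")


def default_compartments() -> dict[str, CompartmentProperties]:
    """Default compartment table.

    Blood T2* is short (~50 ms) while stroma, being plasma-like fluid, is long
    (300 ms) — at 3T plasma T2 is ~410 ms versus ~100 ms for whole blood, and
    the T2* values here preserve that ordering. Blood m0 = 1.25 is an effective
    value chosen so the blood/stroma signal crossover falls between 28 and
    44 ms at TR 2470 ms (see docs/methods.md).
    """
    return {
        "blood": CompartmentProperties("blood", t1=1650.0, t2star=50.0, m0=1.25),
        "stroma": CompartmentProperties("stroma", t1=3500.0, t2star=300.0, m0=1.0),
        "csf": CompartmentProperties("csf", t1=4000.0, t2star=500.0, m0=1.0),
        "gray": CompartmentProperties("gray", t1=1300.0, t2star=45.0, m0=0.78),
        "white": CompartmentProperties("white", t1=850.0, t2star=45.0, m0=0.74),
        "epithelium": CompartmentProperties("epithelium", t1=1400.0, t2star=60.0, m0=0.80),
    }


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo EPI acquisition parameters.

    tr, te_list in ms; flip_angle in degrees; voxel_size in mm (x, y, z).
    """

    tr: float
    te_list: tuple[float, ...]
    flip_angle: float
    n_volumes: int
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self):
        te = tuple(float(t) for t in self.te_list)
        object.__setattr__(self, "te_list", te)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if len(te) < 1:
            raise InvalidArgumentError("te_list needs at least one echo")
        if any(b <= a for a, b in zip(te, te[1:])):
            raise InvalidArgumentError("te_list must be strictly increasing")
        if not self.tr > max(te):
            raise InvalidArgumentError("tr must exceed the longest echo time")
        if self.n_volumes < 2:
            raise InvalidArgumentError("need at least 2 volumes")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise InvalidArgumentError("voxel_size must be three positive lengths (mm)")

    @property
    def volume_times(self) -> np.ndarray:
        """Acquisition time of each volume in seconds (volume k at k*TR)."""
        return np.arange(self.n_volumes) * self.tr / 1000.0

    @property
    def scan_duration(self) -> float:
        return self.n_volumes * self.tr / 1000.0


@dataclass(frozen=True)
class ElasticityParams:
    """ChP voxel composition and vascular elasticity.

    f_blood0, f_stroma0, f_csf are baseline volume fractions of capillary
    blood, stroma and ventricular CSF; the remainder (epithelium/other) is
    static. epsilon is the blood-fraction change per mmHg of end-tidal CO2:
    during vasodilation the capillary space grows at the expense of stroma,
    reciprocally, so total volume is conserved.
    """

    f_blood0: float = 0.15
    f_stroma0: float = 0.35
    f_csf: float = 0.30
    epsilon: float = 0.005

    def __post_init__(self):
        for attr in ("f_blood0", "f_stroma0", "f_csf"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{attr}={v} outside [0, 1]")
        if self.f_blood0 + self.f_stroma0 + self.f_csf > 1.0 + 1e-12:
            raise InvalidArgumentError("baseline fractions sum above 1")

    @property
    def f_rest(self) -> float:
        """Static epithelium/other fraction."""
        return 1.0 - self.f_blood0 - self.f_stroma0 - self.f_csf


def hypercapnia_acquisition(n_volumes: int = 200) -> AcquisitionParams:
    """Single-echo acquisition matching the hypercapnia protocol (TR 2000 ms, TE 25 ms, 80 deg)."""
    return AcquisitionParams(tr=2000.0, te_list=(25.0,), flip_angle=80.0, n_volumes=n_volumes)


def breathmod_acquisition(n_volumes: int = 270) -> AcquisitionParams:
    """Single-echo acquisition matching the breath-modulation protocol (TR 1500 ms, TE 37 ms, 52 deg)."""
    return AcquisitionParams(tr=1500.0, te_list=(37.0,), flip_angle=52.0, n_volumes=n_volumes)


def multiecho_acquisition(n_volumes: int = 230) -> AcquisitionParams:
    """Four-echo resting-state acquisition (TR 2470 ms, TE 12/28/44/60 ms, 78 deg)."""
    return AcquisitionParams(
        tr=2470.0, te_list=(12.0, 28.0, 44.0, 60.0), flip_angle=78.0, n_volumes=n_volumes
    )
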