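"""CSF/tissue contrast ratio — the sensitivity gate for the ChP elasticity signal.

The partial-volume mechanism is only detectable when ventricular CSF (and the
plasma-like stroma) is brighter than the surrounding tissue on the mean BOLD
image; the ratio of ventricular to periventricular mean signal quantifies
that prerequisite and grows with echo time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class ContrastResult:
    """CSF/tissue contrast ratio on a temporal-mean BOLD image."""

    ratio: float
    csf_mean: float
    tissue_mean: float
    n_csf: int
    n_tissue: int
    te: float | None = None


def compute_contrast_ratio(
    mean_image: np.ndarray,
    csf_mask: np.ndarray,
    tissue_mask: np.ndarray,
    te: float | None = None,
) -> ContrastResult:
    """Ratio of ventricular-CSF to periventricular-tissue mean signal.

    ``mean_image`` is the temporal mean of the BOLD series; masks must be
    disjoint and non-empty.
    """
    csf_mask = np.asarray(csf_mask, bool)
    tissue_mask = np.asarray(tissue_mask, bool)
    if not csf_mask.any() or not tissue_mask.any():
        raise InvalidArgumentError("csf and tissue masks must be non-empty")
    if (csf_mask & tissue_mask).any():
        raise InvalidArgumentError("csf and tissue masks must be disjoint")
    img = np.asarray(mean_image, float)
    csf_mean = float(img[csf_mask].mean())
    tissue_mean = float(img[tissue_mask].mean())
    if tissue_mean == 0:
        raise InvalidArgumentError("tissue mean signal is zero; ratio undefined")
    return ContrastResult(
        ratio=csf_mean / tissue_mean,
        csf_mean=csf_mean,
        tissue_mean=tissue_mean,
        n_csf=int(csf_mask.sum()),
        n_tissue=int(tissue_mask.sum()),
        te=te,
    )


def periventricular_shell(
    ventricle_mask: np.ndarray,
    thickness: int = 2,
    brain_mask: np.ndarray | None = None,
    connectivity: int = 26,
) -> np.ndarray:
    """Tissue shell surrounding the ventricles.

    Morphological dilation of the ventricle mask by ``thickness`` voxels
    (6- or 26-neighborhood) minus the ventricles, intersected with the brain
    mask when given.
    """
    if thickness < 1:
        raise InvalidArgumentError("thickness must be >= 1")
    if connectivity not in (6, 26):
        raise InvalidArgumentError("connectivity must be 6 or 26")
    vent = np.asarray(ventricle_mask, bool)
    structure = (
        np.ones((3, 3, 3), bool)
        if connectivity == 26
        else ndimage.generate_binary_structure(3, 1)
    )
    dilated = ndimage.binary_dilation(vent, structure=structure, iterations=thickness)
    shell = dilated & ~vent
    if brain_mask is not None:
        shell &= np.asarray(brain_mask, bool)
    if not shell.any():
        raise InvalidArgumentError("periventricular shell is empty")
    return shell
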