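"""File I/O: gzipped NIfTI-1 images with JSON sidecars, TSV physio traces,
CSV covariate tables, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cvr import BoldSeries, CVRMap
from .errors import InvalidArgumentError
from .params import AcquisitionParams
from .physio import DelayFit
from .respiration import RespiratoryTrace


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_bold(series: BoldSeries, path: str | Path, te: float | None = None) -> Path:
    """Write a 4D BOLD series as gzipped NIfTI-1 plus a JSON sidecar.

    The sidecar (<stem>.json) records TR, the echo time of this file, flip
    angle and voxel size; the brain mask goes to <stem>_mask.nii.gz.
    """
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.acq.voxel_size))
    img.header.set_zooms(series.acq.voxel_size + (series.acq.tr / 1000.0,))
    nib.save(img, path)
    stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
    sidecar = {
        "tr_ms": series.acq.tr,
        "te_ms": te if te is not None else series.acq.te_list[0],
        "te_list_ms": list(series.acq.te_list),
        "flip_angle_deg": series.acq.flip_angle,
        "n_volumes": series.acq.n_volumes,
        "voxel_size_mm": list(series.acq.voxel_size),
    }
    (path.parent / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    mask_img = nib.Nifti1Image(
        series.brain_mask.astype(np.uint8), _affine(series.acq.voxel_size)
    )
    nib.save(mask_img, path.parent / f"{stem}_mask.nii.gz")
    return path


def load_bold(path: str | Path, mask_path: str | Path | None = None) -> BoldSeries:
    """Load a 4D NIfTI written by :func:`save_bold` (sidecar required)."""
    path = Path(path)
    stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
    sidecar_path = path.parent / f"{stem}.json"
    if not sidecar_path.exists():
        raise InvalidArgumentError(f"missing acquisition sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    acq = AcquisitionParams(
        tr=meta["tr_ms"],
        te_list=tuple(meta.get("te_list_ms", [meta["te_ms"]])),
        flip_angle=meta["flip_angle_deg"],
        n_volumes=data.shape[-1],
        voxel_size=tuple(meta["voxel_size_mm"]),
    )
    if mask_path is None:
        candidate = path.parent / f"{stem}_mask.nii.gz"
        mask_path = candidate if candidate.exists() else None
    if mask_path is not None:
        mask = np.asarray(nib.load(mask_path).dataobj) > 0
    else:
        mask = data.mean(axis=-1) > 0
    return BoldSeries(data, acq, mask)


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj) > 0


def save_map(cvr_map: CVRMap, path: str | Path, voxel_size=(3.0, 3.0, 3.0)) -> Path:
    """Write a CVR map as NIfTI with units/metadata in a JSON sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(cvr_map.values.astype(np.float32), _affine(voxel_size)), path)
    stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
    meta = {"units": cvr_map.units, **cvr_map.metadata}
    (path.parent / f"{stem}.json").write_text(json.dumps(meta, indent=2, default=float))
    nib.save(
        nib.Nifti1Image(cvr_map.mask.astype(np.uint8), _affine(voxel_size)),
        path.parent / f"{stem}_mask.nii.gz",
    )
    return path


def load_map(path: str | Path) -> CVRMap:
    path = Path(path)
    stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
    meta = json.loads((path.parent / f"{stem}.json").read_text())
    values = np.asarray(nib.load(path).dataobj, dtype=float)
    mask_file = path.parent / f"{stem}_mask.nii.gz"
    mask = np.asarray(nib.load(mask_file).dataobj) > 0 if mask_file.exists() else values != 0
    units = meta.pop("units", "r.u.")
    return CVRMap(values, units=units, mask=mask, metadata=meta)


def save_trace(trace: RespiratoryTrace, path: str | Path) -> Path:
    """Write a respiratory trace as 2-column TSV (time_s, pco2_mmHg) + JSON meta."""
    path = Path(path)
    arr = np.column_stack([trace.times, trace.pco2])
    np.savetxt(path, arr, fmt="%.4f", delimiter="\t", header="time_s\tpco2_mmhg", comments="")
    meta = {"sampling_rate_hz": trace.sampling_rate, **trace.meta}
    (path.parent / f"{path.stem}.json").write_text(json.dumps(meta, indent=2, default=float))
    return path


def load_trace(path: str | Path) -> RespiratoryTrace:
    path = Path(path)
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    meta_path = path.parent / f"{path.stem}.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    rate = meta.pop("sampling_rate_hz", None)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(arr[:, 0])))
    return RespiratoryTrace(arr[:, 0], arr[:, 1], float(rate), meta)


def save_delay_fit(fit: DelayFit, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "best_delay_s": fit.best_delay,
        "search_range_s": list(fit.search_range),
        "at_boundary": fit.at_boundary,
        "residual_curve": [[float(d), float(r)] for d, r in fit.residual_curve],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_covariates(path: str | Path) -> pd.DataFrame:
    """Read a covariate table (CSV with header: subject, age, sex, group)."""
    df = pd.read_csv(path)
    missing = {"subject", "age", "sex"} - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"covariate table missing columns {sorted(missing)}")
    return df
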