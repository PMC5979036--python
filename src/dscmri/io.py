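"""NIfTI readers/writers, YAML configuration and provenance sidecars."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .acquisition import AcquisitionParams
from .bolus import FitOptions
from .errors import InputError
from .metrics import PerfusionMaps

__all__ = [
    "read_4d_volume",
    "read_mask",
    "write_volume",
    "write_maps",
    "load_acquisition",
]

MAP_FILENAMES = {
    "rcbv": "rcbv.nii.gz",
    "mtt": "mtt.nii.gz",
    "rcbf": "rcbf.nii.gz",
    "ttp": "ttp.nii.gz",
    "bat": "bat.nii.gz",
}
VALID_FILENAME = "valid_mask.nii.gz"
SIDECAR_FILENAME = "provenance.json"


def read_4d_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D NIfTI time-series; returns (data, affine).

    The frame axis is the 4th dimension.  Raises InputError on any other
    dimensionality.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise InputError(f"{path}: expected a 4-D volume, got {data.ndim}-D")
    return data, img.affine


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D NIfTI mask; non-zero voxels are in-mask."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise InputError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    return data != 0, img.affine


def write_volume(data: np.ndarray, path, affine: Optional[np.ndarray] = None) -> None:
    """Write an array as NIfTI-1 (identity affine when none given)."""
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def write_maps(maps: PerfusionMaps, outdir, extra_provenance: Optional[dict] = None) -> dict:
    """Write one NIfTI per metric plus the validity mask and a JSON
    provenance sidecar recording the acquisition parameters, counts and
    package version.  Returns {name: path} of everything written.

    Invalid voxels are NaN in the metric volumes; the validity mask is a
    separate uint8 volume.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = maps.affine if maps.affine is not None else np.eye(4)
    written: dict[str, Path] = {}
    for name, vol in maps.metric_dict().items():
        path = outdir / MAP_FILENAMES[name]
        nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), str(path))
        written[name] = path
    valid_path = outdir / VALID_FILENAME
    nib.save(nib.Nifti1Image(maps.valid.astype(np.uint8), affine), str(valid_path))
    written["valid"] = valid_path

    sidecar = {
        "package": "dscmri",
        "version": __version__,
        "acquisition": asdict(maps.acq),
        "counts": maps.counts,
    }
    if extra_provenance:
        sidecar.update(extra_provenance)
    sidecar_path = outdir / SIDECAR_FILENAME
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    written["provenance"] = sidecar_path
    return written


def load_acquisition(path) -> AcquisitionParams:
    """Read acquisition parameters from a YAML file.

    Recognised keys: te_ms or te_s, tr_s (or tr_ms), n_frames,
    baseline_frames, bolus_start_frame.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: expected a mapping")
    if "te_s" in cfg:
        te = float(cfg["te_s"])
    elif "te_ms" in cfg:
        te = float(cfg["te_ms"]) / 1000.0
    else:
        raise InputError(f"{path}: missing te_ms or te_s")
    if "tr_s" in cfg:
        tr = float(cfg["tr_s"])
    elif "tr_ms" in cfg:
        tr = float(cfg["tr_ms"]) / 1000.0
    else:
        raise InputError(f"{path}: missing tr_s or tr_ms")
    try:
        kwargs = {
            "n_frames": int(cfg["n_frames"]),
        }
    except KeyError as exc:
        raise InputError(f"{path}: missing {exc}") from exc
    for key in ("baseline_frames", "bolus_start_frame"):
        if key in cfg:
            kwargs[key] = int(cfg[key])
    return AcquisitionParams(te=te, tr=tr, **kwargs)


def fit_options_from_dict(cfg: dict) -> FitOptions:
    """Build FitOptions from a (possibly partial) mapping."""
    allowed = {f for f in FitOptions.__dataclass_fields__}
    unknown = set(cfg) - allowed
    if unknown:
        raise InputError(f"unknown fit options: {sorted(unknown)}")
    return FitOptions(**cfg)
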