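"""NIfTI I/O for dynamic volumes and VOI masks.

NIfTI headers cannot carry injected dose, patient weight or the frame
schedule, so dynamic images travel with a JSON sidecar next to the image
file (``image.nii.gz`` -> ``image.json``) with the schema::

    {
      "injected_dose_MBq": 600.0,
      "patient_weight_kg": 80.0,
      "delay_s": 1.0,
      "frames": [[12, 10.0], [2, 30.0], [2, 60.0], [1, 120.0]]
    }

Extra keys are preserved on read (fixture generators use this to store
simulation ground truth).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError
from .frames import DynamicPETImage, VOIMask, make_frame_schedule

__all__ = [
    "sidecar_path",
    "read_dynamic_nifti",
    "write_dynamic_nifti",
    "read_mask_nifti",
    "write_mask_nifti",
]


def sidecar_path(image_path) -> Path:
    """JSON sidecar path for a ``.nii`` / ``.nii.gz`` file."""
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_dynamic_nifti(image: DynamicPETImage, path, extra_meta: dict | None = None) -> Path:
    """Write a 4-D image plus its JSON sidecar; returns the sidecar path."""
    path = Path(path)
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float64), _affine(image.voxel_size)), path)
    meta = {
        "injected_dose_MBq": image.injected_dose_MBq,
        "patient_weight_kg": image.patient_weight_kg,
        "delay_s": image.schedule.delay,
        "frames": [[int(c), float(d)] for c, d in image.schedule.to_spec()],
    }
    if extra_meta:
        meta.update(extra_meta)
    side = sidecar_path(path)
    side.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return side


def read_dynamic_nifti(path, sidecar: Path | None = None) -> DynamicPETImage:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{path}: dynamic image must be 4-D, got {data.ndim}-D")
    side = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    try:
        schedule = make_frame_schedule(
            [(int(c), float(d)) for c, d in meta["frames"]], delay=float(meta["delay_s"])
        )
        dose = float(meta["injected_dose_MBq"])
        weight = float(meta["patient_weight_kg"])
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed sidecar {side}: {exc}") from exc
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicPETImage(
        voxels=data,
        voxel_size=voxel_size,  # type: ignore[arg-type]
        schedule=schedule,
        injected_dose_MBq=dose,
        patient_weight_kg=weight,
    )


def read_sidecar(path) -> dict:
    """Raw sidecar dictionary (including any extra keys such as fixture truth)."""
    side = sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing metadata sidecar {side}")
    return json.loads(side.read_text())


def write_mask_nifti(mask: VOIMask, path, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(voxel_size)), Path(path))


def read_mask_nifti(path) -> VOIMask:
    path = Path(path)
    data = np.asarray(nib.load(path).dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: mask must be 3-D, got {data.ndim}-D")
    # VOIMask binarizes (with a warning) anything outside {0,1}
    return VOIMask(voxels=data)
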