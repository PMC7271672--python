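"""NIfTI round-trip helpers (nibabel-backed)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_nifti_volume", "write_nifti_volume"]


def read_nifti_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D/4D NIfTI volume; returns ``(data, affine)``."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    return np.asarray(img.dataobj), img.affine


def write_nifti_volume(data: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a volume as NIfTI-1, preserving dtype and geometry."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path
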