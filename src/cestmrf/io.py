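"""Shared I/O helpers: NIfTI maps/stacks with YAML sidecars, config hashing."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import yaml

__all__ = ["write_nifti", "read_nifti", "config_hash"]


def write_nifti(path, array: np.ndarray, sidecar: Optional[dict] = None) -> None:
    """Write an array as NIfTI (identity affine) plus optional YAML sidecar.

    Arrays keep their dtype and shape bit-exact; NaN backgrounds round-trip.
    """
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(array), affine=np.eye(4))
    nib.save(img, path)
    if sidecar is not None:
        path.with_suffix(".yaml").write_text(
            yaml.safe_dump(sidecar, sort_keys=False))


def read_nifti(path, expect_shape: Optional[tuple] = None) -> np.ndarray:
    """Read a NIfTI file back as a plain array; optionally check its shape
    against sidecar-declared geometry."""
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    if expect_shape is not None and tuple(data.shape) != tuple(expect_shape):
        raise ValueError(
            f"{path}: shape {data.shape} does not match declared {expect_shape}")
    return data


def read_sidecar(path) -> dict:
    return yaml.safe_load(Path(path).with_suffix(".yaml").read_text())


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping (embedded in all artifacts)."""
    payload = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
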