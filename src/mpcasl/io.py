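"""NIfTI volume and YAML configuration plumbing."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "read_volume",
    "write_volume",
    "load_config",
    "dump_config",
    "write_manifest",
]


def read_volume(path):
    """Load a NIfTI volume; returns ``(data, affine)`` with float64 data."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header, wrong magic, missing file
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def write_volume(data, path, affine=None, voxel_size=None):
    """Write a NIfTI-1 volume.

    Either an explicit ``affine`` or a ``voxel_size`` (mm, diagonal
    affine) can be given; data are stored as float64 so that a
    read-back round trip is bit-exact.
    """
    data = np.asarray(data, dtype=np.float64)
    if affine is None:
        vs = np.ones(3) if voxel_size is None else np.asarray(voxel_size, dtype=float)
        affine = np.diag(list(vs[:3]) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_data_dtype(np.float64)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_config(path) -> dict:
    """Read a YAML config into a plain dict (empty file -> {})."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return cfg


def dump_config(cfg: dict, path) -> Path:
    """Write the resolved config next to the outputs it produced."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path


def write_manifest(path, **entries) -> Path:
    """JSON run manifest (seed, parameters, package version)."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"mpcasl_version": __version__, **entries}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return path
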