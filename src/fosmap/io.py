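"""Readers and writers for volumes, label tables and tabular outputs.

Supported volume containers are NIfTI-1 (``.nii``/``.nii.gz``, via nibabel)
and multi-page TIFF (via tifffile). The in-memory axis order is ``(z, y, x)``;
NIfTI stores ``(x, y, z)`` and is transposed on read and write. Voxel sizes
travel in the NIfTI header zooms (with micron or mm spatial units) and, for
TIFF, in a JSON ImageDescription tag written by this package; integer
intensities round-trip bit-exactly in both formats.

Tables are TSV with a header row, UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import json
import os
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import LabelVolume, TissueMask, Volume3D
from .errors import ConfigurationError, VolumeIOError

_TIFF_SUFFIXES = (".tif", ".tiff")
_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("nifti", "tiff"):
            raise ConfigurationError(f"unknown volume format {fmt!r}")
        return fmt
    low = str(path).lower()
    if low.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if low.endswith(_TIFF_SUFFIXES):
        return "tiff"
    raise ConfigurationError(f"cannot infer volume format from path {path!r}")


def read_volume(
    path: str,
    format: str | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> Volume3D:
    """Read a 3-D volume from NIfTI or multi-page TIFF.

    The voxel size is taken from the file header when present; an explicit
    ``voxel_size`` (µm, ``(z, y, x)``) overrides it and is required when the
    file carries none.
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise VolumeIOError(f"volume file not found: {path}")
    try:
        if fmt == "nifti":
            data, header_vs = _read_nifti(path)
        else:
            data, header_vs = _read_tiff(path)
    except VolumeIOError:
        raise
    except Exception as exc:  # corrupt file, wrong format
        raise VolumeIOError(f"could not read volume {path}: {exc}") from exc
    vs = voxel_size if voxel_size is not None else header_vs
    if vs is None:
        raise ConfigurationError(
            f"no voxel size in header of {path} and none supplied; pass voxel_size explicitly"
        )
    return Volume3D(data=data, voxel_size=tuple(float(v) for v in vs))


def _read_nifti(path: str):
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3-D NIfTI, got ndim={data.ndim}")
    data = data.transpose(2, 1, 0)  # (x,y,z) -> (z,y,x)
    zooms = img.header.get_zooms()[:3]
    space_unit = img.header.get_xyzt_units()[0]
    if space_unit == "micron":
        vs = (zooms[2], zooms[1], zooms[0])
    elif space_unit in ("mm", "meter"):
        factor = 1e3 if space_unit == "mm" else 1e6
        vs = (zooms[2] * factor, zooms[1] * factor, zooms[0] * factor)
    elif any(abs(z - 1.0) > 1e-12 for z in zooms):
        # units unknown but zooms explicitly set: take them as µm
        vs = (zooms[2], zooms[1], zooms[0])
    else:
        vs = None
    return data, vs


def _read_tiff(path: str):
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a TIFF stack, got ndim={data.ndim}")
    vs = None
    try:
        meta = json.loads(desc)
        if isinstance(meta, dict) and "voxel_size_um" in meta:
            vs = tuple(float(v) for v in meta["voxel_size_um"])
    except (json.JSONDecodeError, TypeError, ValueError):
        vs = None
    return data, vs


def write_volume(volume: Volume3D, path: str, format: str | None = None) -> str:
    """Write a volume to NIfTI or multi-page TIFF, embedding the voxel size."""
    fmt = _infer_format(path, format)
    vz, vy, vx = volume.voxel_size
    try:
        if fmt == "nifti":
            affine = np.diag([vx, vy, vz, 1.0])
            img = nib.Nifti1Image(volume.data.transpose(2, 1, 0), affine)
            img.header.set_zooms((vx, vy, vz))
            img.header.set_xyzt_units("micron")
            nib.save(img, path)
        else:
            tifffile.imwrite(
                path,
                volume.data,
                description=json.dumps({"voxel_size_um": [vz, vy, vx]}),
            )
    except OSError as exc:
        raise VolumeIOError(f"could not write volume {path}: {exc}") from exc
    return path


def write_mask(mask: TissueMask, path: str, voxel_size=(25.0, 25.0, 25.0)) -> str:
    """Store a boolean mask as a uint8 volume."""
    return write_volume(Volume3D(mask.data.astype(np.uint8), voxel_size), path)


def read_mask(path: str) -> TissueMask:
    vol = read_volume(path, voxel_size=(1.0, 1.0, 1.0))
    return TissueMask(vol.data > 0)


def write_labels(labels: LabelVolume, path: str, table_path: str | None = None,
                 voxel_size=(25.0, 25.0, 25.0)) -> str:
    """Store a label volume plus an optional two-column (label, name) TSV."""
    write_volume(Volume3D(labels.data.astype(np.int32), voxel_size), path)
    if table_path is not None:
        write_label_table(labels.label_table, table_path)
    return path


def read_labels(path: str, table_path: str | None = None) -> LabelVolume:
    vol = read_volume(path, voxel_size=(1.0, 1.0, 1.0))
    data = vol.data.astype(np.int64)
    if table_path is not None:
        table = read_label_table(table_path)
    else:
        table = {int(l): f"region_{int(l)}" for l in np.unique(data) if l != 0}
    return LabelVolume(data, table)


def write_label_table(table: Mapping[int, str], path: str) -> str:
    df = pd.DataFrame(sorted(table.items()), columns=["label", "name"])
    df.to_csv(path, sep="\t", index=False)
    return path


def read_label_table(path: str) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"label", "name"} <= set(df.columns):
        raise VolumeIOError(f"{path}: label table needs 'label' and 'name' columns")
    return {int(r.label): str(r.name) for r in df.itertuples()}


def write_table(df: pd.DataFrame, path: str) -> str:
    """All tabular outputs: TSV, header row, UTF-8, '.' decimals."""
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")
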