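"""Reading, writing and inspecting 3D angiographic volumes.

Volumes are plain scalar arrays indexed ``(z, y, x)`` with per-axis voxel
spacing in millimetres.  Three on-disk dialects are supported, chosen by file
extension: NIfTI (``.nii``/``.nii.gz``, via nibabel), MetaImage
(``.mha``/``.mhd``, via SimpleITK) and multi-page TIFF stacks
(``.tif``/``.tiff``, via tifffile).  TIFF carries no spacing metadata, so
stacks are assigned unit spacing with a logged warning.

All voxel coordinates throughout the package are 0-based ``(z, y, x)``
indices.  Anisotropic spacing is accepted but logged: the filter's scale
parameter is interpreted in voxels, so strongly anisotropic inputs should be
resampled by the caller first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["Volume", "read_volume", "write_volume", "mip"]


@dataclass
class Volume:
    """A 3D scalar intensity field with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array indexed ``(z, y, x)``; each axis must have length >= 3.
    spacing:
        Physical voxel size per axis ``(z, y, x)`` in mm, all positive.
    origin:
        Physical offset of voxel (0, 0, 0); defaults to zeros.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must have exactly 3 axes, got {self.data.ndim}"
            )
        if min(self.data.shape) < 3:
            raise ValueError(f"each axis must have length >= 3, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if len(set(self.spacing)) > 1:
            logger.info("anisotropic spacing %s: scale s is in voxels; consider resampling",
                        self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """Copy of this volume carrying new voxel data, same geometry."""
        return Volume(data, self.spacing, self.origin)


_NIFTI = (".nii", ".nii.gz")
_META = (".mha", ".mhd")
_TIFF = (".tif", ".tiff")


def _dialect(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI):
        return "nifti"
    if name.endswith(_META):
        return "meta"
    if name.endswith(_TIFF):
        return "tiff"
    raise ValueError(f"unsupported volume format: {path}")


def read_volume(path: str | Path) -> Volume:
    """Read a 3D volume, choosing the dialect by file extension.

    Raises a format error for unreadable files and a dimensionality error
    for non-3D data.  TIFF stacks get spacing (1, 1, 1) and a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    kind = _dialect(path)
    try:
        if kind == "nifti":
            img = nib.load(str(path))
            data = np.asarray(img.dataobj)
            zooms = img.header.get_zooms()[:3]
            # nibabel arrays are (x, y, z); our convention is (z, y, x)
            data = np.transpose(data, (2, 1, 0))
            spacing = tuple(float(z) for z in reversed(zooms))
            origin = (0.0, 0.0, 0.0)
        elif kind == "meta":
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img)  # already (z, y, x)
            spacing = tuple(reversed(img.GetSpacing()))
            origin = tuple(reversed(img.GetOrigin()))
        else:
            data = tifffile.imread(str(path))
            spacing = (1.0, 1.0, 1.0)
            origin = (0.0, 0.0, 0.0)
            logger.warning("TIFF stack %s has no spacing metadata; assuming (1, 1, 1)", path)
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # unreadable / corrupt container
        raise ValueError(f"could not read volume file {path}: {exc}") from exc
    if np.asarray(data).ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got {np.asarray(data).ndim} axes")
    return Volume(np.asarray(data), spacing, origin)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume to disk; the dialect is chosen by extension.

    Round trips through :func:`read_volume` preserve the data bit-exactly at
    the container's native precision.
    """
    path = Path(path)
    kind = _dialect(path)
    if kind == "nifti":
        affine = np.diag(list(reversed(volume.spacing)) + [1.0])
        img = nib.Nifti1Image(np.transpose(volume.data, (2, 1, 0)), affine)
        img.header.set_zooms(tuple(reversed(volume.spacing)))
        nib.save(img, str(path))
    elif kind == "meta":
        img = sitk.GetImageFromArray(volume.data)
        img.SetSpacing(tuple(reversed(volume.spacing)))
        img.SetOrigin(tuple(reversed(volume.origin)))
        sitk.WriteImage(img, str(path))
    else:
        tifffile.imwrite(str(path), volume.data)


def mip(volume: Volume, axis: int) -> np.ndarray:
    """Maximum intensity projection along one axis.

    Each output pixel is the maximum of the volume along ``axis``
    (0 = z, 1 = y, 2 = x).
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return volume.data.max(axis=axis)
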