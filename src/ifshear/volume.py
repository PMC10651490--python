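"""3D scalar volumes with physical voxel spacing.

``Volume3D`` is the carrier for every image-like input in the pipeline:
two-photon fluorescence stacks, MRI brain masks and CT-like tracer scans.
Axes are ordered (x, y, z) = (left-right, rostral-caudal, dorsal-ventral),
and each axis carries its own physical voxel size so that anisotropic
acquisitions survive round-trips through resampling.

Physical coordinates follow the voxel-centre convention: the centre of
voxel ``i`` along an axis with spacing ``s`` lies at ``(i + 0.5) * s``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

AXIS_NAMES = ("x", "y", "z")


def axis_index(axis: int | str) -> int:
    """Resolve an axis given by index or name ('x'|'y'|'z') to 0/1/2."""
    if isinstance(axis, str):
        try:
            return AXIS_NAMES.index(axis.lower())
        except ValueError:
            raise ValueError(f"unknown axis {axis!r}; expected one of {AXIS_NAMES}") from None
    axis = int(axis)
    if axis not in (0, 1, 2):
        raise ValueError(f"axis index {axis} out of range")
    return axis


@dataclasses.dataclass
class Volume3D:
    """A 3D scalar intensity grid with per-axis physical spacing.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units), indexed ``[x, y, z]``.
    spacing
        Physical size of one voxel along each axis (μm or mm; the pipeline
        is unit-agnostic as long as usage is consistent).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int | str) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        ax = axis_index(axis)
        return (np.arange(self.shape[ax]) + 0.5) * self.spacing[ax]

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF (ImageJ-compatible) and NIfTI-1


def write_tiff(vol: Volume3D, path: str | Path) -> None:
    """Write as ImageJ-compatible multi-page TIFF (pages along z)."""
    import tifffile

    sx, sy, sz = vol.spacing
    # ImageJ layout: pages = z, rows = y, cols = x
    pages = np.transpose(vol.data, (2, 1, 0))
    tifffile.imwrite(
        str(path),
        pages.astype(np.float32),
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


def read_tiff(path: str | Path) -> Volume3D:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        meta = tif.imagej_metadata or {}
        sz = float(meta.get("spacing", 1.0))
        tags = tif.pages[0].tags
        def _res(tagname: str) -> float:
            if tagname in tags:
                num, den = tags[tagname].value
                if num:
                    return den / num
            return 1.0
        sx = _res("XResolution")
        sy = _res("YResolution")
    if pages.ndim == 2:
        pages = pages[None]
    data = np.transpose(pages, (2, 1, 0))
    return Volume3D(data, (sx, sy, sz))


def write_nifti(vol: Volume3D, path: str | Path) -> None:
    """Write as NIfTI-1 with spacing carried in the affine diagonal."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> Volume3D:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data, spacing)


def read_volume(path: str | Path) -> Volume3D:
    """Dispatch on suffix: .tif/.tiff or .nii/.nii.gz."""
    p = Path(path)
    name = p.name.lower()
    if name.endswith((".tif", ".tiff")):
        return read_tiff(p)
    if name.endswith((".nii", ".nii.gz")):
        return read_nifti(p)
    raise ValueError(f"unrecognised volume format: {p.name}")
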