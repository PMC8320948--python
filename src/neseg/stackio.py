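"""TIFF stack input/output for serial block-face SEM volumes.

Volumes are held as ``ImageStack`` objects: an 8-bit greyscale voxel array in
``(row, col, slice)`` order together with the physical voxel size.  Stacks may
live on disk either as a directory of single-channel per-slice TIFF files
(slices ordered by the numeric content of their filenames) or as one multipage
TIFF.  Segmentation masks are stored as 8-bit TIFFs with values {0, 255}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

#: Physical voxel size (d_row, d_col, d_slice) in nanometres of the source
#: acquisitions: 10 nm in plane, 50 nm section thickness.
DEFAULT_VOXEL_SIZE = (10.0, 10.0, 50.0)


class StackFormatError(ValueError):
    """Raised when slice files cannot be assembled into a consistent volume."""


@dataclass
class ImageStack:
    """A 3D greyscale volume with voxel-size metadata.

    Attributes
    ----------
    voxels : ndarray, shape (n_h, n_w, n_d), uint8
        Intensities in ``(row, col, slice)`` order, 0-based, row increasing
        downward.
    voxel_size : tuple of float
        Physical size (d_row, d_col, d_slice) of one voxel in nm.
    origin : tuple of int
        Position of voxel (0, 0, 0) inside the parent volume this stack was
        cropped from; (0, 0, 0) for a freshly loaded stack.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[:, :, None]
        if self.voxels.ndim != 3:
            raise StackFormatError(
                f"expected a 2D or 3D array, got ndim={self.voxels.ndim}"
            )
        if self.voxels.dtype != np.uint8:
            self.voxels = _to_uint8(self.voxels)

    @property
    def n_h(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_w(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_d(self) -> int:
        return self.voxels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice(self, index: int) -> np.ndarray:
        """Return the 2D image of slice ``index`` (a view, not a copy)."""
        return self.voxels[:, :, index]


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Linearly rescale higher-bit-depth data to 8 bit (min–max stretch)."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == bool:
        return arr.astype(np.uint8) * 255
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.full(arr.shape, min(max(int(lo), 0), 255), dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def _numeric_key(name: str) -> list:
    """Sort key interleaving text and integer runs so slice_2 < slice_10."""
    parts = re.split(r"(\d+)", name)
    return [int(p) if p.isdigit() else p for p in parts]


def _slice_files(directory: Path) -> list[Path]:
    exts = {".tif", ".tiff"}
    files = [p for p in directory.iterdir() if p.suffix.lower() in exts]
    return sorted(files, key=lambda p: _numeric_key(p.name))


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> ImageStack:
    """Read a volume from a directory of per-slice TIFFs or a multipage TIFF.

    Slices from a directory are ordered by the numeric content of their
    filenames; pages of a multipage file keep their page order.  Intensities
    are preserved bit-exact for 8-bit inputs; higher bit depths are min–max
    rescaled to 8 bit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if path.is_dir():
        files = _slice_files(path)
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = [np.atleast_2d(tifffile.imread(f)) for f in files]
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            slices = [data]
        elif data.ndim == 3:
            slices = [data[i] for i in range(data.shape[0])]
        else:
            raise StackFormatError(
                f"{path}: expected single-channel pages, got shape {data.shape}"
            )
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise StackFormatError(f"inconsistent slice dimensions: {sorted(shapes)}")
    if slices[0].ndim != 2:
        raise StackFormatError("slices must be single-channel 2D images")
    vol = np.stack([_to_uint8(s) for s in slices], axis=-1)
    return ImageStack(vol, voxel_size=voxel_size)


def write_stack(stack: ImageStack | np.ndarray, path: str | Path) -> None:
    """Write a stack as a multipage TIFF (``.tif`` path) or slice directory."""
    vox = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if vox.ndim == 2:
        vox = vox[:, :, None]
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, np.moveaxis(vox, -1, 0), photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(3, len(str(vox.shape[2] - 1)))
        for k in range(vox.shape[2]):
            tifffile.imwrite(path / f"slice_{k:0{width}d}.tif", vox[:, :, k])


def crop_cell(
    stack: ImageStack,
    centroid: tuple[int, int, int],
    size: tuple[int, int, int],
) -> ImageStack:
    """Extract the sub-volume of ``size`` centred on ``centroid``.

    The window is clipped to the stack bounds; the resulting offset of the
    crop inside the parent volume is reported in ``origin``.  One cell per
    cropped sub-volume is assumed downstream.
    """
    cr, cc, cs = (int(v) for v in centroid)
    if not (0 <= cr < stack.n_h and 0 <= cc < stack.n_w and 0 <= cs < stack.n_d):
        raise ValueError(f"centroid {centroid} outside stack of shape {stack.shape}")
    lo = []
    hi = []
    for centre, extent, bound in zip((cr, cc, cs), size, stack.shape):
        a = centre - extent // 2
        b = a + int(extent)
        lo.append(max(0, a))
        hi.append(min(bound, b))
    if any(h <= l for l, h in zip(lo, hi)):
        raise ValueError(f"empty crop window for size {size}")
    sub = stack.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    return ImageStack(sub, voxel_size=stack.voxel_size, origin=tuple(lo))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask (2D or 3D) as 8-bit {0, 255} TIFF(s)."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise TypeError(f"mask must be boolean, got {mask.dtype}")
    write_stack(mask.astype(np.uint8) * 255, path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a {0, 255} TIFF mask back as a boolean (n_h, n_w, n_d) array."""
    stack = read_stack(path)
    return stack.voxels > 127


def stack_slices(slices: Sequence[np.ndarray]) -> np.ndarray:
    """Stack a sequence of 2D slice arrays into (row, col, slice) order."""
    return np.stack(list(slices), axis=-1)
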