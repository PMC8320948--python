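"""Rigid inter-slice translation correction.

Serial block-face acquisitions can suffer a sudden in-plane displacement of
the field of view (for example, from a vibration reaching the microscope),
which appears as a rigid translation between two consecutive slices and then
persists for the rest of the stack.  This module detects such discontinuities
by integer-precision phase correlation of consecutive slices and corrects
them by translating every slice from the discontinuity onward back by the
detected shift.  Only pure translations are handled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .stackio import ImageStack

#: Shift magnitude (pixels) below which consecutive-slice motion is treated
#: as normal acquisition jitter rather than a discontinuity.
DEFAULT_THRESHOLD = 5.0


@dataclass(frozen=True)
class ShiftRecord:
    """A detected discontinuity.

    ``slice_index`` is the first slice *after* the jump; ``shift`` is the
    (d_rows, d_cols) translation of that slice relative to the previous one.
    """

    slice_index: int
    shift: tuple[int, int]

    @property
    def magnitude(self) -> float:
        return float(np.hypot(*self.shift))


def detect_shift(slice_a: np.ndarray, slice_b: np.ndarray) -> tuple[int, int]:
    """Integer translation of ``slice_b`` relative to ``slice_a``.

    Returns the (d_rows, d_cols) that maximises the cross-correlation, i.e.
    ``detect_shift(a, translate(a, s)) == s``.  Uses phase correlation at
    integer precision.
    """
    a = np.asarray(slice_a, dtype=np.float64)
    b = np.asarray(slice_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"slice shapes differ: {a.shape} vs {b.shape}")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant slice: translation is undefined")
    # phase_cross_correlation reports the shift that registers b onto a,
    # which is the negative of b's displacement relative to a.  Plain
    # cross-correlation (normalization=None) is more robust than whitened
    # phase correlation on weakly textured micrographs.
    reg_shift, _, _ = phase_cross_correlation(a, b, upsample_factor=1, normalization=None)
    return (int(round(-reg_shift[0])), int(round(-reg_shift[1])))


def detect_discontinuity(
    stack: ImageStack, threshold: float = DEFAULT_THRESHOLD
) -> list[ShiftRecord]:
    """Scan consecutive slice pairs and report shifts exceeding ``threshold``.

    Because a real acquisition jump displaces all subsequent slices together,
    only the pair straddling the jump shows a large relative shift; the
    returned records are therefore local and independent.

    A candidate record is only retained when undoing the shift genuinely
    improves the correlation between the two slices; on slices with little
    or no structure (bare resin at the ends of a crop) the correlation peak
    is driven by noise and the spurious shift fails this check.
    """
    if stack.n_d < 2:
        raise ValueError("need at least 2 slices to scan for discontinuities")
    records = []
    for k in range(1, stack.n_d):
        a, b = stack.slice(k - 1), stack.slice(k)
        if a.std() == 0 or b.std() == 0:
            continue
        shift = detect_shift(a, b)
        if np.hypot(*shift) < threshold:
            continue
        if _correlation_gain(a, b, shift) > 0.1:
            records.append(ShiftRecord(slice_index=k, shift=shift))
    return records


def _correlation_gain(
    slice_a: np.ndarray, slice_b: np.ndarray, shift: tuple[int, int]
) -> float:
    """Increase in Pearson correlation between two slices when the second is
    translated back by ``shift``."""
    a = np.asarray(slice_a, dtype=np.float64)
    b = np.asarray(slice_b, dtype=np.float64)
    undone = translate_slice(b, -shift[0], -shift[1])
    c0 = np.corrcoef(a.ravel(), b.ravel())[0, 1]
    c1 = np.corrcoef(a.ravel(), undone.ravel())[0, 1]
    return float(c1 - c0)


def translate_slice(
    image: np.ndarray, d_rows: int, d_cols: int, fill: float | None = None
) -> np.ndarray:
    """Translate a 2D image by integer (d_rows, d_cols), filling vacated
    pixels with ``fill``.

    The default fill is the slice's 95th-percentile intensity, an estimate
    of the bright resin background (the brightest intensity class).  A fill
    matching an interior grey class is hazardous: where the vacated band
    cuts through the nuclear envelope it would connect the nucleoplasm to
    the border with no intervening edge.
    """
    image = np.asarray(image)
    h, w = image.shape
    if abs(d_rows) >= h or abs(d_cols) >= w:
        raise ValueError(f"shift ({d_rows}, {d_cols}) exceeds slice size {image.shape}")
    if fill is None:
        fill = np.percentile(image, 95)
    out = np.full_like(image, np.asarray(fill, dtype=image.dtype))
    src_r = slice(max(0, -d_rows), h - max(0, d_rows))
    src_c = slice(max(0, -d_cols), w - max(0, d_cols))
    dst_r = slice(max(0, d_rows), h - max(0, -d_rows))
    dst_c = slice(max(0, d_cols), w - max(0, -d_cols))
    out[dst_r, dst_c] = image[src_r, src_c]
    return out


def correct_shift(stack: ImageStack, record: ShiftRecord) -> ImageStack:
    """Undo a discontinuity: translate slices from ``record.slice_index``
    onward by the negated shift.  Vacated border pixels are filled with each
    slice's estimated resin-background intensity.  Slices before the index
    are untouched."""
    if not (0 < record.slice_index < stack.n_d):
        raise ValueError(f"slice_index {record.slice_index} outside stack")
    dr, dc = record.shift
    vox = stack.voxels.copy()
    for k in range(record.slice_index, stack.n_d):
        vox[:, :, k] = translate_slice(vox[:, :, k], -dr, -dc)
    return ImageStack(vox, voxel_size=stack.voxel_size, origin=stack.origin)


def correct_all(
    stack: ImageStack, records: list[ShiftRecord] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[ImageStack, list[ShiftRecord]]:
    """Detect (unless given) and correct every discontinuity in order."""
    if records is None:
        records = detect_discontinuity(stack, threshold=threshold)
    for record in records:
        stack = correct_shift(stack, record)
    return stack, records
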