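"""Boundary-line annotations, class masks, tiling and normalization.

OCT layer annotations arrive as per-column boundary lines (one depth value per
image column for each layer interface).  Training needs dense class masks, so
the central operations here convert between the two representations:

* ``boundaries_to_mask`` — pixels between two boundary lines are assigned the
  class of the line that precedes them (top to bottom); everything above the
  first line is pre-retinal space (0) and everything at/below the last line is
  background (11).
* ``mask_to_boundaries`` — the exact inverse for masks without pathology
  classes.

``tile_crops`` cuts non-overlapping square patches from a B-scan (optionally
anchored on the fovea) and ``normalize_image`` applies per-image zero-mean /
unit-variance normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import BoundaryCrossingError, UnsupportedContentError, ValidationError
from .scheme import BACKGROUND, CLASS_NAMES, COLLAPSED, CYST, PRERETINAL

logger = logging.getLogger(__name__)

#: canonical boundary names for the ten-layer retina; the trailing line marks
#: the bottom of the RPE, below which lies background
CANONICAL_BOUNDARIES: tuple[str, ...] = (
    "ILM", "RNFL", "GCL", "IPL", "INL", "OPL", "ELM", "PR1", "PR2", "RPE",
    "RPE_lower",
)

_NAME_TO_CLASS = {n: i for i, n in enumerate(CLASS_NAMES)}


class BoundarySet:
    """Ordered, non-crossing per-column layer boundaries.

    ``depths`` has shape (n_boundaries, width); ``depths[k, c]`` is the row
    coordinate (0 = top of scan, increasing downward) at which boundary ``k``
    sits in column ``c``.  Boundaries are ordered top to bottom.
    """

    def __init__(self, names: Sequence[str], depths: np.ndarray):
        depths = np.atleast_2d(np.asarray(depths, dtype=float))
        if len(names) != depths.shape[0]:
            raise ValidationError(
                f"{len(names)} names for {depths.shape[0]} boundary rows"
            )
        self.names = list(names)
        self.depths = depths
        self.validate()

    @property
    def n_boundaries(self) -> int:
        return self.depths.shape[0]

    @property
    def width(self) -> int:
        return self.depths.shape[1]

    def validate(self) -> None:
        if np.any(self.depths < 0):
            raise ValidationError("boundary depths must be non-negative")
        d = self.depths
        for k in range(self.n_boundaries - 1):
            bad = np.where(d[k] > d[k + 1])[0]
            if bad.size:
                raise BoundaryCrossingError(
                    bad[0], self.names[k], self.names[k + 1]
                )

    def __len__(self) -> int:
        return self.n_boundaries

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BoundarySet)
            and self.names == other.names
            and self.depths.shape == other.depths.shape
            and np.array_equal(self.depths, other.depths)
        )

    # --- I/O: CSV with one row per boundary --------------------------------
    def to_csv(self, path: Union[str, Path]) -> None:
        width = self.width
        header = "boundary," + ",".join(f"c{i}" for i in range(width))
        lines = [header]
        for name, row in zip(self.names, self.depths):
            lines.append(name + "," + ",".join(repr(float(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "BoundarySet":
        text = Path(path).read_text().strip().splitlines()
        names, rows = [], []
        for line in text[1:]:
            parts = line.split(",")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        if not names:
            return cls.empty(0)
        return cls(names, np.array(rows, dtype=float))

    @classmethod
    def empty(cls, width: int) -> "BoundarySet":
        return cls([], np.zeros((0, width), dtype=float))


@dataclass
class ClassMask:
    """Integer label image over the 14-class scheme with a provenance tag."""

    labels: np.ndarray
    provenance: str = "ground_truth"  # ground_truth | predicted | postprocessed

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("mask must be a 2-D label image")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() > CYST
        ):
            raise ValidationError("mask labels must lie in 0..13")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy(self) -> "ClassMask":
        return ClassMask(self.labels.copy(), self.provenance)


def as_labels(mask: Union[ClassMask, np.ndarray]) -> np.ndarray:
    """Accept either a ClassMask or a bare 2-D label array."""
    if isinstance(mask, ClassMask):
        return mask.labels
    return np.asarray(mask)


def boundaries_to_mask(b: BoundarySet, height: int, width: Optional[int] = None) -> ClassMask:
    """Rasterize boundary lines into a dense class mask.

    Per column: rows above the first boundary are pre-retinal space (0); rows
    ``r`` with ``boundary_k <= r < boundary_{k+1}`` take the class of boundary
    ``k``; rows at/below the last boundary are background (11).  Fractional
    depths are floored, so the boundary row itself belongs to the class the
    line introduces.
    """
    if b.n_boundaries == 0:
        w = width if width is not None else b.width
        return ClassMask(np.zeros((height, w), dtype=np.uint8))
    b.validate()
    if height < np.floor(b.depths.max()):
        raise ValidationError("height smaller than the deepest boundary")
    w = b.width
    rows = np.arange(height)[:, None]
    mask = np.full((height, w), PRERETINAL, dtype=np.uint8)
    n = b.n_boundaries
    for k in range(n):
        depth = np.floor(b.depths[k])[None, :]
        if k == n - 1:
            cls = BACKGROUND
        else:
            cls = _NAME_TO_CLASS.get(b.names[k], k + 1)
        mask[rows >= depth] = cls
    return ClassMask(mask, provenance="ground_truth")


def mask_to_boundaries(m: Union[ClassMask, np.ndarray]) -> BoundarySet:
    """Recover boundary lines from a layer-ordered class mask.

    The boundary introducing class ``k`` is, per column, the first row whose
    label is >= ``k``.  Masks containing pathology classes (12/13) have no
    layer ordering and are rejected.
    """
    labels = as_labels(m)
    present = np.unique(labels)
    if COLLAPSED in present or CYST in present:
        raise UnsupportedContentError(
            "mask contains collapsed-layer or cyst pixels; boundaries undefined"
        )
    height, width = labels.shape
    if present.max(initial=0) == PRERETINAL:
        return BoundarySet.empty(width)
    names = list(CANONICAL_BOUNDARIES)
    depths = np.empty((len(names), width), dtype=float)
    for k in range(1, BACKGROUND + 1):
        ge = labels >= k
        any_col = ge.any(axis=0)
        first = np.argmax(ge, axis=0).astype(float)
        first[~any_col] = height
        depths[k - 1] = first
    return BoundarySet(names, depths)


@dataclass
class Crop:
    """A square patch cut from a B-scan, with its mask patch when available."""

    image: np.ndarray
    mask: Optional[np.ndarray]
    source_id: str
    col_offset: int
    row_offset: int = 0


def tile_crops(
    image: np.ndarray,
    mask: Optional[Union[ClassMask, np.ndarray]] = None,
    size: int = 64,
    anchor_col: Optional[int] = None,
    source_id: str = "",
) -> list[Crop]:
    """Cut non-overlapping ``size`` x ``size`` crops from a B-scan.

    Without an anchor, tiles run left to right from column 0 and trailing
    columns narrower than ``size`` are discarded.  With ``anchor_col`` (e.g.
    the fovea) the first crop is centered on that column (clipped to the image)
    and the remaining width on both sides is tiled outward without overlap.
    The vertical window is the top ``size`` rows.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < size:
        raise ValidationError(f"image height {h} smaller than crop size {size}")
    if w < size:
        logger.warning("image width %d smaller than crop size %d; no crops", w, size)
        return []
    labels = as_labels(mask) if mask is not None else None
    if labels is not None and labels.shape[:2] != image.shape[:2]:
        raise ValidationError("mask shape differs from image shape")

    if anchor_col is None:
        offsets = list(range(0, w - size + 1, size))
    else:
        start = int(np.clip(int(anchor_col) - size // 2, 0, w - size))
        offsets = [start]
        o = start - size
        while o >= 0:            # tile leftwards, adjacent to the anchor crop
            offsets.append(o)
            o -= size
        o = start + size
        while o + size <= w:     # tile rightwards
            offsets.append(o)
            o += size
        offsets.sort()

    crops = []
    for o in offsets:
        crops.append(
            Crop(
                image=image[:size, o : o + size],
                mask=None if labels is None else labels[:size, o : o + size],
                source_id=source_id,
                col_offset=o,
            )
        )
    return crops


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image normalization: subtract the mean, divide by the population
    standard deviation.  Constant images use divisor 1 and map to all zeros."""
    x = np.asarray(image, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("cannot normalize an empty image")
    mu = x.mean()
    sd = x.std()
    if sd < 1e-12:  # constant image: divisor 1, exact zeros
        return np.zeros_like(x)
    return (x - mu) / sd
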