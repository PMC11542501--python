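"""Cyst post-processing: adding the fourteenth class to predicted masks.

The networks segment 13 classes; for diseased eyes a cyst class (id 13) is
added afterwards.  Cysts are hyporeflective cavities within the retinal
layers, so candidate pixels are those lying strictly inside the retinal band
(classes 2-9 or collapsed layers) whose intensity falls well below the robust
central intensity of their predicted class in the same image:

    intensity < k * median_c

with ``median_c`` the median intensity of the pixels predicted as class c in
the same image and ``k`` a dimensionless contrast factor (default 0.5: a
candidate must be less than half as reflective as its class).  The median
stays calibrated as long as cysts cover under half of a class, and the rule
needs no spread estimate, so speckle strength and intensity clipping do not
perturb it.  Connected candidate components smaller than a minimum area are
discarded as speckle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import StateError, ValidationError
from .preprocess import ClassMask, as_labels
from .scheme import CYST

#: predicted classes inside which cysts may sit (strictly inside the retina)
DEFAULT_CYST_CLASSES: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 12)




@dataclass
class CystParams:
    """Contrast factor, minimum area, and the class set open to relabeling."""

    k: float = 0.5
    min_area: int = 10
    classes: tuple[int, ...] = field(default_factory=lambda: DEFAULT_CYST_CLASSES)

    def validate(self) -> None:
        if not 0.0 < self.k < 1.0:
            raise ValidationError("contrast factor k must lie in (0, 1)")
        if self.min_area < 1:
            raise ValidationError("min_area must be >= 1")


def add_cyst_class(
    pred: ClassMask, image: np.ndarray, params: CystParams | None = None
) -> ClassMask:
    """Relabel hyporeflective in-retina components of ``pred`` as cysts.

    Only labels in ``params.classes`` may change, and only to 13; all other
    pixels are untouched.  ``pred`` must not already contain class 13.
    """
    params = params or CystParams()
    params.validate()
    labels = as_labels(pred)
    image = np.asarray(image, dtype=np.float64)
    if image.shape != labels.shape:
        raise ValidationError("image and predicted mask shapes differ")
    if (labels == CYST).any():
        raise StateError("prediction already contains cyst pixels")

    candidates = np.zeros(labels.shape, dtype=bool)
    for c in params.classes:
        sel = labels == c
        if not sel.any():
            continue
        threshold = params.k * np.median(image[sel])
        candidates |= sel & (image < threshold)

    out = labels.copy()
    if candidates.any():
        comp, n = ndimage.label(candidates)
        if n:
            areas = ndimage.sum_labels(
                np.ones_like(comp), comp, index=np.arange(1, n + 1)
            )
            keep = np.isin(comp, np.nonzero(areas >= params.min_area)[0] + 1)
            keep &= candidates
            out[keep] = CYST
    return ClassMask(out, provenance="postprocessed")
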