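"""On-disk dataset layout: PNG images/masks, CSV boundaries, JSONL manifest.

Images are 16-bit grayscale PNG (intensities in [0, 1] scaled to 0..65535),
masks are 8-bit PNG holding raw class ids, boundaries are CSV with one row per
boundary line.  A dataset manifest is JSON lines, one record per scan, plus a
patient-level train/val/test split.  All coordinates are 0-based with row 0 at
the top of the scan.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import imageio.v3 as iio
import numpy as np

from .errors import DataError, ValidationError
from .preprocess import BoundarySet, ClassMask

SPLITS = ("train", "val", "test")


def save_image(path: Union[str, Path], image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def load_image(path: Union[str, Path]) -> np.ndarray:
    raw = np.asarray(iio.imread(Path(path)))
    if raw.ndim == 3:  # tolerate RGB(A) input; use the first channel
        raw = raw[..., 0]
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    return raw.astype(np.float64) / 65535.0


def save_mask(path: Union[str, Path], mask: Union[ClassMask, np.ndarray]) -> None:
    labels = mask.labels if isinstance(mask, ClassMask) else np.asarray(mask)
    iio.imwrite(Path(path), labels.astype(np.uint8))


def load_mask(path: Union[str, Path], provenance: str = "ground_truth") -> ClassMask:
    return ClassMask(np.asarray(iio.imread(Path(path))).astype(np.uint8), provenance)


@dataclass
class ManifestRecord:
    """One scan of one patient, with its file paths and flags."""

    scan_id: str
    patient_id: str
    split: str
    labeled: bool
    diseased: bool
    eye: str = "left"
    image_path: Optional[str] = None
    mask_path: Optional[str] = None
    boundaries_path: Optional[str] = None
    fovea_col: Optional[int] = None
    seed: Optional[int] = None


@dataclass
class DatasetManifest:
    """All records of a generated dataset plus per-split counts.

    ``access_log`` records every scan id whose pixel data was loaded through
    the manifest, which lets tests assert that training never touches the
    test split.
    """

    root: Path
    records: list[ManifestRecord] = field(default_factory=list)
    access_log: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    # --- selection ----------------------------------------------------------
    def select(
        self,
        split: Optional[str] = None,
        labeled: Optional[bool] = None,
        diseased: Optional[bool] = None,
    ) -> list[ManifestRecord]:
        out = []
        for r in self.records:
            if split is not None and r.split != split:
                continue
            if labeled is not None and r.labeled != labeled:
                continue
            if diseased is not None and r.diseased != diseased:
                continue
            out.append(r)
        return out

    def counts(self) -> dict:
        c = {s: 0 for s in SPLITS}
        for r in self.records:
            c[r.split] += 1
        return c

    def patients(self, split: Optional[str] = None) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if split is None or r.split == split:
                seen.setdefault(r.patient_id, None)
        return list(seen)

    def validate(self) -> None:
        assignment: dict[str, str] = {}
        for r in self.records:
            if r.split not in SPLITS:
                raise ValidationError(f"unknown split '{r.split}'")
            prev = assignment.setdefault(r.patient_id, r.split)
            if prev != r.split:
                raise ValidationError(
                    f"patient {r.patient_id} appears in splits {prev} and {r.split}"
                )
            if not r.labeled and (r.mask_path or r.boundaries_path):
                raise ValidationError(
                    f"unlabeled record {r.scan_id} carries annotation paths"
                )

    # --- pixel access (logged) ---------------------------------------------
    def load_image(self, record: ManifestRecord) -> np.ndarray:
        self.access_log.append(record.scan_id)
        if record.image_path is None:
            raise DataError(f"record {record.scan_id} has no image path")
        return load_image(self.root / record.image_path)

    def load_mask(self, record: ManifestRecord) -> ClassMask:
        self.access_log.append(record.scan_id)
        if record.mask_path is None:
            raise DataError(f"record {record.scan_id} has no mask")
        return load_mask(self.root / record.mask_path)

    def load_boundaries(self, record: ManifestRecord) -> BoundarySet:
        self.access_log.append(record.scan_id)
        if record.boundaries_path is None:
            raise DataError(f"record {record.scan_id} has no boundaries")
        return BoundarySet.from_csv(self.root / record.boundaries_path)

    # --- persistence --------------------------------------------------------
    def save(self, path: Optional[Union[str, Path]] = None) -> Path:
        path = Path(path) if path else self.root / "manifest.jsonl"
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(asdict(r)) + "\n")
        return path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "DatasetManifest":
        path = Path(path)
        records = []
        for line in path.read_text().strip().splitlines():
            records.append(ManifestRecord(**json.loads(line)))
        return cls(root=path.parent, records=records)


def largest_remainder_split(n: int, fractions: Iterable[float]) -> list[int]:
    """Apportion ``n`` items to groups by largest-remainder rounding."""
    fractions = list(fractions)
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: quotas[i] - counts[i], reverse=True
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts
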