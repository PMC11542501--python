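"""Per-class IOU evaluation and paired signed-rank model comparison.

IOU for class c is |pred==c AND truth==c| / |pred==c OR truth==c|; when the
union is empty the value is undefined and that image is excluded from the
class's statistics (a trivially correct absence earns no credit).  Reports
collect an image x class IOU matrix with per-class mean and standard error.

Two models are compared per class with a one-sided paired signed-rank test on
per-image IOU differences: zero differences are dropped, absolute differences
are ranked with midranks for ties, and W+ is the rank sum of positive
differences.  For n <= 20 the p-value P(W >= W+) is exact over all 2^n sign
assignments; beyond that a tie-corrected normal approximation with continuity
correction is used.  No multiple-testing correction is applied: p-values are
reported per class, as in per-class IOU tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .preprocess import ClassMask, as_labels
from .scheme import CLASS_NAMES, DEFAULT_SCHEME, ClassScheme

EXACT_LIMIT = 20


def compute_iou(
    pred: Union[ClassMask, np.ndarray],
    truth: Union[ClassMask, np.ndarray],
    class_id: int,
) -> Optional[float]:
    """Intersection over union for one class; None when the union is empty."""
    p = as_labels(pred)
    t = as_labels(truth)
    if p.shape != t.shape:
        raise ValidationError(f"mask shapes differ: {p.shape} vs {t.shape}")
    pm = p == class_id
    tm = t == class_id
    union = np.count_nonzero(pm | tm)
    if union == 0:
        return None
    return float(np.count_nonzero(pm & tm) / union)


@dataclass
class IOUReport:
    """Image x class IOU matrix with per-class mean and standard error."""

    matrix: pd.DataFrame  # rows: image ids, columns: class ids, NaN = undefined
    model_id: str = "model"

    @property
    def image_ids(self) -> list:
        return list(self.matrix.index)

    def class_mean(self) -> pd.Series:
        return self.matrix.mean(axis=0, skipna=True)

    def class_se(self) -> pd.Series:
        def se(col: pd.Series) -> float:
            vals = col.dropna()
            if len(vals) < 2:
                return 0.0
            return float(vals.std(ddof=1) / np.sqrt(len(vals)))

        return self.matrix.apply(se, axis=0)

    def mean_iou(self) -> float:
        """Grand mean over defined (image, class) entries' class means."""
        return float(self.class_mean().mean(skipna=True))

    def summary(self) -> pd.DataFrame:
        """Per-class table in the layout of a mean +/- SE results table."""
        means = self.class_mean()
        ses = self.class_se()
        return pd.DataFrame(
            {
                "class": [CLASS_NAMES[c] for c in self.matrix.columns],
                "mean_iou": means.values,
                "se": ses.values,
                "n": self.matrix.notna().sum(axis=0).values,
            },
            index=self.matrix.columns,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.summary().to_csv(path, index_label="class_id")


def iou_report(
    preds: Sequence[Union[ClassMask, np.ndarray]],
    truths: Sequence[Union[ClassMask, np.ndarray]],
    scheme: ClassScheme = DEFAULT_SCHEME,
    image_ids: Optional[Sequence] = None,
    model_id: str = "model",
) -> IOUReport:
    if len(preds) != len(truths):
        raise ValidationError("prediction and truth lists differ in length")
    if image_ids is None:
        image_ids = list(range(len(preds)))
    rows = []
    for p, t in zip(preds, truths):
        rows.append(
            [compute_iou(p, t, c) for c in range(scheme.n_classes)]
        )
    matrix = pd.DataFrame(
        np.array(rows, dtype=float),
        index=list(image_ids),
        columns=list(range(scheme.n_classes)),
    )
    return IOUReport(matrix=matrix, model_id=model_id)


# --------------------------------------------------------------------------
# signed-rank test


def _midranks(absdiffs: np.ndarray) -> np.ndarray:
    return stats.rankdata(absdiffs, method="average")


def signed_rank_test(
    diffs: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided paired signed-rank test. Returns (W+, p).

    ``alternative='greater'`` tests whether the differences are shifted
    positive.  Zero differences are dropped before ranking.
    """
    if alternative != "greater":
        raise ValidationError("only the one-sided 'greater' alternative is supported")
    d = np.asarray(list(diffs), dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_LIMIT:
        # exact null distribution by enumerating all 2^n sign assignments;
        # midranks are multiples of 1/2, so double to stay in integers
        r2 = np.round(2.0 * ranks).astype(np.int64)
        sums = np.zeros(1, dtype=np.int64)
        for r in r2:
            sums = np.concatenate([sums, sums + r])
        w2 = int(round(2.0 * w_plus))
        p = float(np.count_nonzero(sums >= w2) / sums.size)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean - 0.5) / np.sqrt(var)  # continuity correction
        p = float(stats.norm.sf(z))
    return w_plus, p


@dataclass
class ComparisonTable:
    """Per-class mean IOU difference (B - A) with one-sided p-values."""

    table: pd.DataFrame  # index: class id; columns: mean_diff, p, significant, n
    model_a: str
    model_b: str
    alpha: float = 0.05

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.table.copy()
        out.insert(0, "class", [CLASS_NAMES[c] for c in out.index])
        out["flag"] = np.where(out["significant"], "*", "")
        out.to_csv(path, index_label="class_id")


def compare_models(
    report_a: IOUReport, report_b: IOUReport, alpha: float = 0.05
) -> ComparisonTable:
    """Test, per class, whether model B outperforms model A on paired images.

    Differences are taken over images where both IOUs are defined.  Classes
    with no nonzero difference (including self-comparison) get p = 1.
    """
    ids_a, ids_b = list(report_a.matrix.index), list(report_b.matrix.index)
    if set(ids_a) != set(ids_b):
        raise ValidationError("reports cover different image sets")
    b = report_b.matrix.loc[ids_a]
    a = report_a.matrix
    rows = []
    for c in a.columns:
        both = a[c].notna() & b[c].notna()
        diffs = (b[c][both] - a[c][both]).to_numpy()
        n = diffs.size
        mean_diff = float(diffs.mean()) if n else float("nan")
        try:
            _, p = signed_rank_test(diffs, alternative="greater")
        except DegenerateInputError:
            p = 1.0
        rows.append((c, mean_diff, p, p < alpha, n))
    table = pd.DataFrame(
        rows, columns=["class_id", "mean_diff", "p", "significant", "n"]
    ).set_index("class_id")
    return ComparisonTable(
        table=table, model_a=report_a.model_id, model_b=report_b.model_id, alpha=alpha
    )


# --------------------------------------------------------------------------
# overlay rendering

#: RGB colors per class id for overlays (muted anatomical palette)
CLASS_COLORS = np.array([
    [0, 0, 0],        # preretinal: transparent-ish black
    [230, 60, 60],    # ILM
    [240, 150, 50],   # RNFL
    [230, 220, 60],   # GCL
    [140, 210, 60],   # IPL
    [60, 200, 120],   # INL
    [60, 200, 210],   # OPL
    [70, 130, 230],   # ELM
    [130, 80, 230],   # PR1
    [200, 70, 220],   # PR2
    [240, 100, 160],  # RPE
    [90, 90, 90],     # background below RPE
    [250, 250, 250],  # collapsed layers
    [0, 255, 255],    # cyst
], dtype=np.float64)


def render_overlay(image: np.ndarray, mask, alpha: float = 0.4) -> np.ndarray:
    """Blend a class mask over a grayscale B-scan; returns an RGB uint8 array."""
    labels = as_labels(mask)
    img = np.asarray(image, dtype=np.float64)
    if img.shape != labels.shape:
        raise ValidationError("image and mask shapes differ")
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    base = np.repeat(gray[..., None] * 255.0, 3, axis=-1)
    color = CLASS_COLORS[labels]
    return np.clip((1 - alpha) * base + alpha * color, 0, 255).astype(np.uint8)


def save_overlay(path, image: np.ndarray, mask, alpha: float = 0.4) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), render_overlay(image, mask, alpha))
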