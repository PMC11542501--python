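"""Desk-scale semi-supervised benchmark.

Fixed study conditions: 64x64 synthetic B-scans, 8 labeled training scans
(4 patients), 200 unlabeled scans (100 patients), 10 validation and 30 test
scans, a small U-Net, and cross pseudo supervision at unlabeled fractions
{0, 0.5, 1.0} over several seeds.  The fraction-0 arm trains on labeled data
only and therefore *is* the seed-matched supervised baseline.

The headline quantities are the median over seeds of the mean test IOU of the
CPS-100% arm versus the supervised arm, and the median Spearman correlation
between unlabeled fraction and mean test IOU — together they probe whether
leveraging more unlabeled data improves segmentation.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .segmenters import SegmenterConfig
from .synthetic import SimulationParams, make_benchmark_dataset
from .training import AblationReport, TrainConfig, run_ablation

BENCHMARK_FRACTIONS = (0.0, 0.5, 1.0)


def benchmark_train_config(seed: int = 0) -> TrainConfig:
    """The small U-Net training configuration used by the benchmark."""
    return TrainConfig(
        segmenter=SegmenterConfig(architecture="unet", width=8, depth=2),
        loss="ce",
        epochs=150,
        batch_labeled=2,
        batch_unlabeled=2,
        lr=2e-3,
        lambda_u=1.0,
        seed=seed,
        crop_size=64,
    )


@dataclass
class BenchmarkResult:
    ablation: AblationReport
    seeds: list[int]
    summary: dict = field(default_factory=dict)

    def compute_summary(self) -> dict:
        t = self.ablation.table
        sup = t[t.fraction == 0.0].set_index("seed")["mean_iou"]
        cps = t[t.fraction == 1.0].set_index("seed")["mean_iou"]
        paired = pd.DataFrame({"supervised": sup, "cps100": cps}).dropna()
        self.summary = {
            "supervised_mean_iou_median": float(paired["supervised"].median()),
            "cps100_mean_iou_median": float(paired["cps100"].median()),
            "cps_benefit_median": float(
                (paired["cps100"] - paired["supervised"]).median()
            ),
            "median_spearman_fraction_iou": self.ablation.median_spearman,
            "n_seeds": len(self.seeds),
        }
        return self.summary


def run_desk_benchmark(
    seeds: Sequence[int],
    dataset_seed: Optional[int] = None,
    out_dir: Optional[Union[str, Path]] = None,
    fractions: Sequence[float] = BENCHMARK_FRACTIONS,
    params: Optional[SimulationParams] = None,
    train_cfg: Optional[TrainConfig] = None,
) -> BenchmarkResult:
    """Generate the benchmark dataset and run the CPS unlabeled-fraction
    ablation over the given seeds."""
    seeds = [int(s) for s in seeds]
    dataset_seed = seeds[0] if dataset_seed is None else int(dataset_seed)
    params = params or SimulationParams()
    base_cfg = train_cfg or benchmark_train_config()

    if out_dir is None:
        tmp = tempfile.TemporaryDirectory(prefix="octseg-bench-")
        data_dir = Path(tmp.name)
    else:
        tmp = None
        data_dir = Path(out_dir)
        data_dir.mkdir(parents=True, exist_ok=True)
    try:
        manifest = make_benchmark_dataset(params, seed=dataset_seed, out_dir=data_dir)
        ablation = run_ablation(base_cfg, manifest, fractions=fractions, seeds=seeds)
    finally:
        if tmp is not None:
            tmp.cleanup()
    result = BenchmarkResult(ablation=ablation, seeds=seeds)
    result.compute_summary()
    return result
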