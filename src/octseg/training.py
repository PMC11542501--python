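"""Training regimes: supervised, cross pseudo supervision, Mean Teacher.

All regimes share the same ingredients: crops are cut from the training
scans, normalized per image, batched, and pushed through a segmenter; Adam
updates the weights; after every epoch the model is scored by mean IOU over
the learned classes on the validation split and the best-validation weights
are kept.

Cross pseudo supervision (CPS) trains two identically configured models with
different initialization seeds.  Each step draws one labeled and one unlabeled
batch; both models learn from the labeled batch independently while each is
additionally scored against the other's hard argmax pseudo-mask on the
unlabeled batch.  After training the first model is used for prediction.

Mean Teacher trains a student by gradient and maintains a teacher as an
exponential moving average of the student's weights; the student is pulled
toward the teacher's softmax output on labeled and unlabeled batches alike,
and the teacher is the predictor.

The unlabeled-fraction ablation driver retrains CPS at several unlabeled
fractions and seeds and tabulates test IOU against fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import losses
from .dataio import DatasetManifest, ManifestRecord
from .errors import ConfigError, DataError
from .evaluation import IOUReport, compute_iou, iou_report
from .nn import Adam
from .postprocess import CystParams, add_cyst_class
from .preprocess import ClassMask, normalize_image, tile_crops
from .scheme import DEFAULT_SCHEME, LEARNED_CLASSES
from .segmenters import (
    DoubleUNetModule,
    ScoreMap,
    Segmenter,
    SegmenterConfig,
    build_segmenter,
)

_LOSSES = ("ce", "wce", "dice", "ce_dice")


@dataclass
class TrainConfig:
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    loss: str = "wce"
    epochs: int = 10
    batch_labeled: int = 2
    batch_unlabeled: int = 2
    lr: float = 2e-3
    schedule: str = "constant"
    lambda_u: float = 1.0
    ema_decay: float = 0.99
    seed: int = 0
    unlabeled_fraction: float = 1.0
    crop_size: int = 64
    patience: Optional[int] = None
    #: CE flavour of the labeled CPS term; unweighted by default, switchable
    cps_labeled_loss: str = "ce"

    def validate(self) -> None:
        self.segmenter.validate()
        if self.loss not in _LOSSES:
            raise ConfigError(f"unknown loss '{self.loss}'; choose from {_LOSSES}")
        if self.cps_labeled_loss not in ("ce", "wce"):
            raise ConfigError("cps_labeled_loss must be 'ce' or 'wce'")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_labeled < 1 or self.batch_unlabeled < 1:
            raise ConfigError("batch sizes must be >= 1")
        if not 0.0 <= self.unlabeled_fraction <= 1.0:
            raise ConfigError("unlabeled_fraction must lie in [0, 1]")
        if not 0.0 <= self.ema_decay <= 1.0:
            raise ConfigError("ema_decay must lie in [0, 1]")


@dataclass
class TrainedModel:
    """A trained segmenter with its config, history and predictor role."""

    segmenter: Segmenter
    config: TrainConfig
    history: list[dict]
    predictor: str = "model"
    extras: dict = field(default_factory=dict)

    def predict(self, image: np.ndarray) -> ScoreMap:
        return self.segmenter.predict(normalize_image(image))

    def predict_mask(self, image: np.ndarray) -> ClassMask:
        return ClassMask(self.predict(image).argmax(), provenance="predicted")

    def save(self, directory: Union[str, Path]) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.segmenter.save(directory / "predictor", history=self.history)
        meta = {
            "config": _config_dict(self.config),
            "predictor": self.predictor,
            "history": self.history,
        }
        (directory / "train_meta.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "train_meta.json").read_text())
        cfg_d = dict(meta["config"])
        cfg_d["segmenter"] = SegmenterConfig(**cfg_d["segmenter"])
        cfg = TrainConfig(**cfg_d)
        seg = Segmenter.load(directory / "predictor")
        return cls(
            segmenter=seg,
            config=cfg,
            history=meta["history"],
            predictor=meta["predictor"],
        )


def _config_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    return d


# --------------------------------------------------------------------------
# data plumbing


@dataclass
class _Pool:
    """In-memory crops: normalized images (M,1,S,S) and optional masks (M,S,S)."""

    images: np.ndarray
    masks: Optional[np.ndarray]
    ids: list[str]

    @property
    def size(self) -> int:
        return self.images.shape[0]


def _learned_labels(manifest: DatasetManifest, record: ManifestRecord) -> np.ndarray:
    """Ground-truth mask in its 13-class view: cysts are a post-processing
    class, so for training targets cyst pixels revert to the layer class the
    boundary lines imply."""
    from .preprocess import boundaries_to_mask
    from .scheme import CYST

    labels = manifest.load_mask(record).labels.copy()
    cysts = labels == CYST
    if cysts.any():
        b = manifest.load_boundaries(record)
        base = boundaries_to_mask(b, labels.shape[0]).labels
        labels[cysts] = base[cysts]
    return labels


def _load_pool(
    manifest: DatasetManifest,
    records: Sequence[ManifestRecord],
    crop_size: int,
    with_masks: bool,
) -> _Pool:
    imgs, masks, ids = [], [], []
    for r in records:
        image = manifest.load_image(r)
        mask = _learned_labels(manifest, r) if with_masks else None
        for crop in tile_crops(image, mask, size=crop_size, source_id=r.scan_id):
            imgs.append(normalize_image(crop.image).astype(np.float32)[None])
            if with_masks:
                masks.append(crop.mask.astype(np.int64))
            ids.append(f"{r.scan_id}@{crop.col_offset}")
    if not imgs:
        raise DataError("no usable crops in the selected records")
    return _Pool(
        images=np.stack(imgs),
        masks=np.stack(masks) if with_masks else None,
        ids=ids,
    )


class _Batcher:
    """Cycling shuffled mini-batch iterator over a pool."""

    def __init__(self, pool: _Pool, batch: int, rng: np.random.Generator):
        self.pool = pool
        self.batch = min(batch, pool.size)
        self.rng = rng
        self._order = rng.permutation(pool.size)
        self._pos = 0

    def next(self) -> tuple[np.ndarray, Optional[np.ndarray]]:
        if self._pos + self.batch > self.pool.size:
            self._order = self.rng.permutation(self.pool.size)
            self._pos = 0
        idx = self._order[self._pos : self._pos + self.batch]
        self._pos += self.batch
        x = self.pool.images[idx]
        y = None if self.pool.masks is None else self.pool.masks[idx]
        return x, y


def _nchw_to_nhwc(scores: np.ndarray) -> np.ndarray:
    return np.moveaxis(scores, 1, -1)


def _nhwc_to_nchw(grad: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.moveaxis(grad, -1, 1))


def _supervised_loss_grad(name, scores_nchw, target, weights):
    s = _nchw_to_nhwc(scores_nchw)
    if name == "ce":
        loss, g = losses.weighted_cross_entropy_grad(s, target, None)
    elif name == "wce":
        loss, g = losses.weighted_cross_entropy_grad(s, target, weights)
    elif name == "dice":
        loss, g = losses.dice_loss_grad(s, target)
    else:  # ce_dice
        loss, g = losses.ce_dice_loss_grad(s, target, weights)
    return loss, _nhwc_to_nchw(g)


def _backprop(segmenter: Segmenter, scores: np.ndarray, grad: np.ndarray,
              aux_grad_fn=None) -> float:
    """Backpropagate a gradient; for Double UNet also supervise the interim map.

    Returns the extra (interim) loss value, 0 for single networks."""
    module = segmenter.module
    if isinstance(module, DoubleUNetModule) and aux_grad_fn is not None:
        aux_loss, aux_grad = aux_grad_fn(module.aux_scores)
        module.backward(grad, aux_grad)
        return aux_loss
    if isinstance(module, DoubleUNetModule):
        module.backward(grad, None)
        return 0.0
    module.backward(grad)
    return 0.0


def _mean_val_iou(segmenter: Segmenter, val: _Pool) -> float:
    """Mean over learned classes of defined IOUs, averaged over val crops."""
    vals = []
    for i in range(val.size):
        scores = segmenter.predict_batch(val.images[i : i + 1])[0]
        pred = np.argmax(scores, axis=0)
        truth = val.masks[i]
        per_class = [
            v
            for c in LEARNED_CLASSES
            if (v := compute_iou(pred, truth, c)) is not None
        ]
        if per_class:
            vals.append(float(np.mean(per_class)))
    return float(np.mean(vals)) if vals else 0.0


def _class_weights_for(cfg: TrainConfig, labeled: _Pool) -> Optional[np.ndarray]:
    if cfg.loss in ("wce", "ce_dice"):
        return losses.compute_class_weights(
            list(labeled.masks), cfg.segmenter.n_classes
        )
    return None


def _split_pools(cfg: TrainConfig, manifest: DatasetManifest):
    labeled_records = manifest.select(split="train", labeled=True)
    if not labeled_records:
        raise DataError("no labeled training records in the manifest")
    labeled = _load_pool(manifest, labeled_records, cfg.crop_size, with_masks=True)
    val_records = manifest.select(split="val")
    val = (
        _load_pool(manifest, val_records, cfg.crop_size, with_masks=True)
        if val_records
        else None
    )
    return labeled, val


# --------------------------------------------------------------------------
# supervised


def train_supervised(cfg: TrainConfig, manifest: DatasetManifest) -> TrainedModel:
    """Train one segmenter on the labeled training records only."""
    cfg.validate()
    labeled, val = _split_pools(cfg, manifest)
    weights = _class_weights_for(cfg, labeled)
    rng = np.random.default_rng(cfg.seed)
    seg = build_segmenter(replace(cfg.segmenter, seed=cfg.seed))
    opt = Adam(seg.module.params(), lr=cfg.lr)
    batcher = _Batcher(labeled, cfg.batch_labeled, rng)
    steps = max(1, math.ceil(labeled.size / cfg.batch_labeled))

    history: list[dict] = []
    best = (-np.inf, seg.module.get_weights())
    stale = 0
    for epoch in range(cfg.epochs):
        epoch_loss = 0.0
        for _ in range(steps):
            x, y = batcher.next()
            scores = seg.predict_batch(x)
            loss, grad = _supervised_loss_grad(cfg.loss, scores, y, weights)
            opt.zero_grad()
            loss += _backprop(
                seg, scores, grad,
                aux_grad_fn=lambda aux: _supervised_loss_grad(cfg.loss, aux, y, weights),
            )
            opt.step()
            epoch_loss += loss
        entry = {"epoch": epoch, "train_loss": epoch_loss / steps}
        if val is not None:
            miou = _mean_val_iou(seg, val)
            entry["val_mean_iou"] = miou
            if miou > best[0]:
                best = (miou, seg.module.get_weights())
                stale = 0
            else:
                stale += 1
        history.append(entry)
        if cfg.patience is not None and stale > cfg.patience:
            break
    if val is not None:
        seg.module.set_weights(best[1])
    return TrainedModel(seg, cfg, history, predictor="supervised")


# --------------------------------------------------------------------------
# cross pseudo supervision


def subsample_unlabeled(
    records: Sequence[ManifestRecord], fraction: float, seed: int
) -> list[ManifestRecord]:
    """Fixed scan-level subsample of the unlabeled pool, reproducible from seed."""
    n = int(round(fraction * len(records)))
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(records), size=n, replace=False)) if n else []
    return [records[i] for i in idx]


def train_cps(cfg: TrainConfig, manifest: DatasetManifest) -> TrainedModel:
    """Cross pseudo supervision over a pair of differently seeded models.

    With ``unlabeled_fraction == 0`` this degenerates to two independent
    supervised runs, and the first model is returned, matching the
    fraction-0 arm of the ablation.
    """
    cfg.validate()
    labeled, val = _split_pools(cfg, manifest)
    unlabeled_records = manifest.select(split="train", labeled=False)
    if cfg.unlabeled_fraction > 0 and not unlabeled_records:
        raise DataError("unlabeled_fraction > 0 but the manifest has no unlabeled records")
    chosen = subsample_unlabeled(unlabeled_records, cfg.unlabeled_fraction, cfg.seed)
    unlabeled = (
        _load_pool(manifest, chosen, cfg.crop_size, with_masks=False)
        if chosen
        else None
    )

    lab_weights = (
        losses.compute_class_weights(list(labeled.masks), cfg.segmenter.n_classes)
        if cfg.cps_labeled_loss == "wce"
        else None
    )
    rng = np.random.default_rng(cfg.seed)
    seg1 = build_segmenter(replace(cfg.segmenter, seed=cfg.seed))
    seg2 = build_segmenter(replace(cfg.segmenter, seed=cfg.seed + 1))
    opt1 = Adam(seg1.module.params(), lr=cfg.lr)
    opt2 = Adam(seg2.module.params(), lr=cfg.lr)
    lab_batch = _Batcher(labeled, cfg.batch_labeled, rng)
    unl_batch = _Batcher(unlabeled, cfg.batch_unlabeled, rng) if unlabeled else None
    steps = max(1, math.ceil(labeled.size / cfg.batch_labeled))

    history: list[dict] = []
    best = (-np.inf, seg1.module.get_weights())
    stale = 0
    for epoch in range(cfg.epochs):
        lab_sum = unl_sum = 0.0
        for _ in range(steps):
            x, y = lab_batch.next()
            opt1.zero_grad()
            opt2.zero_grad()
            # labeled term: CE for each model against the ground truth
            # (unweighted by default; cfg.cps_labeled_loss switches to wce)
            s1 = seg1.predict_batch(x)
            l1, g1 = _supervised_loss_grad(cfg.cps_labeled_loss, s1, y, lab_weights)
            _backprop(seg1, s1, g1)
            s2 = seg2.predict_batch(x)
            l2, g2 = _supervised_loss_grad(cfg.cps_labeled_loss, s2, y, lab_weights)
            _backprop(seg2, s2, g2)
            lab_sum += l1 + l2
            # unlabeled term: cross pseudo supervision with hard argmax masks
            if unl_batch is not None and cfg.lambda_u != 0.0:
                xu, _ = unl_batch.next()
                s1u = seg1.predict_batch(xu)
                p1 = np.argmax(s1u, axis=1)
                s2u = seg2.predict_batch(xu)
                p2 = np.argmax(s2u, axis=1)
                lu2, gu2 = _supervised_loss_grad("ce", s2u, p1, None)
                _backprop(seg2, s2u, cfg.lambda_u * gu2)
                lu1, gu1 = _supervised_loss_grad("ce", s1u, p2, None)
                _backprop(seg1, s1u, cfg.lambda_u * gu1)
                unl_sum += lu1 + lu2
            opt1.step()
            opt2.step()
        entry = {
            "epoch": epoch,
            "labeled_loss": lab_sum / steps,
            "total_loss": (lab_sum + cfg.lambda_u * unl_sum) / steps,
        }
        if unlabeled is not None:
            entry["unlabeled_loss"] = unl_sum / steps
        if val is not None:
            miou = _mean_val_iou(seg1, val)
            entry["val_mean_iou"] = miou
            if miou > best[0]:
                best = (miou, seg1.module.get_weights())
                stale = 0
            else:
                stale += 1
        history.append(entry)
        if cfg.patience is not None and stale > cfg.patience:
            break
    if val is not None:
        seg1.module.set_weights(best[1])
    return TrainedModel(
        seg1,
        cfg,
        history,
        predictor="cps_1",
        extras={"cps_2": seg2, "n_unlabeled": 0 if unlabeled is None else unlabeled.size},
    )


# --------------------------------------------------------------------------
# mean teacher


def train_mean_teacher(cfg: TrainConfig, manifest: DatasetManifest) -> TrainedModel:
    """Student/teacher consistency training; the EMA teacher is the predictor."""
    cfg.validate()
    labeled, val = _split_pools(cfg, manifest)
    unlabeled_records = manifest.select(split="train", labeled=False)
    if cfg.unlabeled_fraction > 0 and not unlabeled_records:
        raise DataError("unlabeled_fraction > 0 but the manifest has no unlabeled records")
    chosen = subsample_unlabeled(unlabeled_records, cfg.unlabeled_fraction, cfg.seed)
    unlabeled = (
        _load_pool(manifest, chosen, cfg.crop_size, with_masks=False)
        if chosen
        else None
    )
    weights = _class_weights_for(cfg, labeled)

    rng = np.random.default_rng(cfg.seed)
    student = build_segmenter(replace(cfg.segmenter, seed=cfg.seed))
    teacher = build_segmenter(replace(cfg.segmenter, seed=cfg.seed))
    teacher.module.set_weights(student.module.get_weights())
    opt = Adam(student.module.params(), lr=cfg.lr)
    lab_batch = _Batcher(labeled, cfg.batch_labeled, rng)
    unl_batch = _Batcher(unlabeled, cfg.batch_unlabeled, rng) if unlabeled else None
    steps = max(1, math.ceil(labeled.size / cfg.batch_labeled))

    history: list[dict] = []
    best = (-np.inf, teacher.module.get_weights())
    stale = 0
    for epoch in range(cfg.epochs):
        sup_sum = cons_sum = 0.0
        for _ in range(steps):
            x, y = lab_batch.next()
            opt.zero_grad()
            s = student.predict_batch(x)
            t_scores = teacher.predict_batch(x)  # constant target
            loss, grad = _supervised_loss_grad(cfg.loss, s, y, weights)
            closs, cgrad = losses.mt_consistency_loss_grad(
                _nchw_to_nhwc(s), _nchw_to_nhwc(t_scores)
            )
            _backprop(student, s, grad + _nhwc_to_nchw(cgrad))
            sup_sum += loss
            cons_sum += closs
            if unl_batch is not None:
                xu, _ = unl_batch.next()
                su = student.predict_batch(xu)
                tu = teacher.predict_batch(xu)
                closs_u, cgrad_u = losses.mt_consistency_loss_grad(
                    _nchw_to_nhwc(su), _nchw_to_nhwc(tu)
                )
                _backprop(student, su, _nhwc_to_nchw(cgrad_u))
                cons_sum += closs_u
            opt.step()
            teacher.module.set_weights(
                losses.ema_update(
                    student.module.get_weights(),
                    teacher.module.get_weights(),
                    cfg.ema_decay,
                )
            )
        entry = {
            "epoch": epoch,
            "supervised_loss": sup_sum / steps,
            "consistency_loss": cons_sum / steps,
        }
        if val is not None:
            miou = _mean_val_iou(teacher, val)
            entry["val_mean_iou"] = miou
            if miou > best[0]:
                best = (miou, teacher.module.get_weights())
                stale = 0
            else:
                stale += 1
        history.append(entry)
        if cfg.patience is not None and stale > cfg.patience:
            break
    if val is not None:
        teacher.module.set_weights(best[1])
    return TrainedModel(
        teacher, cfg, history, predictor="teacher", extras={"student": student}
    )


# --------------------------------------------------------------------------
# evaluation plumbing and the ablation driver


def predict_test_masks(
    model: TrainedModel,
    manifest: DatasetManifest,
    split: str = "test",
    cyst_params: Optional[CystParams] = None,
    postprocess: bool = True,
) -> tuple[list[ClassMask], list[ClassMask], list[str]]:
    """Predicted (optionally cyst-post-processed) and truth masks for a split."""
    preds, truths, ids = [], [], []
    for r in manifest.select(split=split):
        image = manifest.load_image(r)
        pred = model.predict_mask(image)
        if postprocess and r.diseased:
            pred = add_cyst_class(pred, image, cyst_params)
        preds.append(pred)
        truths.append(manifest.load_mask(r))
        ids.append(r.scan_id)
    return preds, truths, ids


def evaluate_model(
    model: TrainedModel,
    manifest: DatasetManifest,
    split: str = "test",
    cyst_params: Optional[CystParams] = None,
    model_id: str = "model",
) -> IOUReport:
    preds, truths, ids = predict_test_masks(model, manifest, split, cyst_params)
    return iou_report(preds, truths, DEFAULT_SCHEME, image_ids=ids, model_id=model_id)


@dataclass
class AblationReport:
    """Test IOU tabulated against the unlabeled fraction, per seed."""

    table: pd.DataFrame  # one row per (fraction, seed)
    spearman_by_seed: pd.Series  # fraction-vs-mean-IOU correlation per seed

    @property
    def median_spearman(self) -> float:
        return float(self.spearman_by_seed.median())

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "table": self.table.to_dict(orient="records"),
            "spearman_by_seed": {
                str(k): v for k, v in self.spearman_by_seed.items()
            },
            "median_spearman": self.median_spearman,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def run_ablation(
    base_cfg: TrainConfig,
    manifest: DatasetManifest,
    fractions: Sequence[float],
    seeds: Sequence[int],
    cyst_params: Optional[CystParams] = None,
) -> AblationReport:
    """Train one CPS model per (fraction, seed) and tabulate test IOU."""
    if not fractions or not seeds:
        raise ConfigError("need at least one fraction and one seed")
    rows = []
    for seed in seeds:
        for frac in fractions:
            cfg = replace(base_cfg, seed=int(seed), unlabeled_fraction=float(frac))
            model = train_cps(cfg, manifest)
            report = evaluate_model(
                model, manifest, cyst_params=cyst_params,
                model_id=f"cps_{int(frac * 100)}_s{seed}",
            )
            row = {
                "fraction": float(frac),
                "seed": int(seed),
                "mean_iou": report.mean_iou(),
            }
            for c, m in report.class_mean().items():
                row[f"iou_class_{c}"] = m
            rows.append(row)
    table = pd.DataFrame(rows)
    spearman = {}
    for seed, grp in table.groupby("seed"):
        if grp["fraction"].nunique() > 1:
            rho = stats.spearmanr(grp["fraction"], grp["mean_iou"]).statistic
        else:
            rho = np.nan
        spearman[seed] = float(rho)
    return AblationReport(table=table, spearman_by_seed=pd.Series(spearman))
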