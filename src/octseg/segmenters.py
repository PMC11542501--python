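"""Segmentation network family: image -> per-pixel class-score map.

Three interchangeable architectures over the 13 learned classes:

* ``unet`` — a small U-Net (encoder/decoder with skip connections),
* ``double_unet`` — two chained U-Nets; the first produces an interim
  prediction which, concatenated with the input image, feeds the second,
* ``dilated_encdec`` — an encoder-decoder built from dilated convolutions,
  a compact desk-scale relative of DeepLab-style context models.

All are trained from random initialization; the initialization seed is part
of the configuration so that model pairs can be "the same but randomly
initialized with different weights", as cross pseudo supervision requires.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import ConfigError
from .nn import DTYPE, DilatedEncDec, Module, UNet
from .scheme import N_LEARNED

ARCHITECTURES = ("unet", "double_unet", "dilated_encdec")


@dataclass
class SegmenterConfig:
    architecture: str = "unet"
    in_channels: int = 1
    n_classes: int = N_LEARNED
    width: int = 8
    depth: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(
                f"unknown architecture '{self.architecture}'; "
                f"choose from {ARCHITECTURES}"
            )
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.depth < 1 or self.width < 1:
            raise ConfigError("depth and width must be >= 1")


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax."""
    s = np.asarray(scores, dtype=np.float64)
    s = s - s.max(axis=axis, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=axis, keepdims=True)


class ScoreMap:
    """H x W x C unnormalized class scores with softmax/argmax views.

    Argmax ties are broken toward the lowest class id (numpy convention),
    making evaluation deterministic.
    """

    def __init__(self, scores: np.ndarray):
        scores = np.asarray(scores)
        if scores.ndim != 3:
            raise ConfigError("ScoreMap expects an (H, W, C) array")
        self.scores = scores

    @property
    def shape(self) -> tuple:
        return self.scores.shape

    @property
    def n_classes(self) -> int:
        return self.scores.shape[-1]

    def probabilities(self) -> np.ndarray:
        return softmax(self.scores, axis=-1)

    def argmax(self) -> np.ndarray:
        return np.argmax(self.scores, axis=-1).astype(np.uint8)


class DoubleUNetModule(Module):
    """Two chained U-Nets; the second sees the input image concatenated with
    the softmax of the first's interim prediction."""

    def __init__(self, in_ch: int, n_classes: int, width: int, depth: int, seed: int):
        self.unet_a = UNet(in_ch, n_classes, width, depth, seed=seed)
        self.unet_b = UNet(in_ch + n_classes, n_classes, width, depth, seed=seed + 1)
        self.n_classes = n_classes
        self.aux_scores: Optional[np.ndarray] = None

    def params(self):
        return self.unet_a.params() + self.unet_b.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        s1 = self.unet_a.forward(x)  # (N, C, H, W)
        p1 = np.asarray(softmax(s1, axis=1), dtype=DTYPE)
        xb = np.concatenate([x, p1], axis=1)
        self._x_ch = x.shape[1]
        self._p1 = p1
        self.aux_scores = s1
        return self.unet_b.forward(xb)

    def backward(self, d_final: np.ndarray, d_aux: Optional[np.ndarray] = None):
        dxb = self.unet_b.backward(np.asarray(d_final, dtype=DTYPE))
        dp1 = dxb[:, self._x_ch :]
        # softmax Jacobian along the channel axis
        p = self._p1
        ds1 = p * (dp1 - (dp1 * p).sum(axis=1, keepdims=True))
        if d_aux is not None:
            ds1 = ds1 + np.asarray(d_aux, dtype=DTYPE)
        return self.unet_a.backward(ds1)


class Segmenter:
    """A trainable function from a (normalized) image to a ScoreMap."""

    def __init__(self, cfg: SegmenterConfig, module: Module):
        self.cfg = cfg
        self.module = module

    def __call__(self, image: np.ndarray) -> ScoreMap:
        return self.predict(image)

    def predict(self, image: np.ndarray) -> ScoreMap:
        x = _to_batch(image, self.cfg.in_channels)
        scores = self.module.forward(x)  # (1, C, H, W)
        return ScoreMap(np.moveaxis(scores[0], 0, -1))

    def predict_batch(self, x: np.ndarray) -> np.ndarray:
        """NCHW batch in, NCHW scores out (training path)."""
        return self.module.forward(np.asarray(x, dtype=DTYPE))

    # --- checkpointing -------------------------------------------------------
    def save(self, path: Union[str, Path], history: Optional[list] = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        weights = self.module.get_weights()
        np.savez(path.with_suffix(".npz"), *weights)
        sidecar = {"config": asdict(self.cfg), "n_arrays": len(weights)}
        if history is not None:
            sidecar["history"] = history
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Segmenter":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = SegmenterConfig(**sidecar["config"])
        seg = build_segmenter(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            weights = [data[k] for k in data.files]
        seg.module.set_weights(weights)
        return seg


def _to_batch(image: np.ndarray, in_channels: int) -> np.ndarray:
    img = np.asarray(image, dtype=DTYPE)
    if img.ndim == 2:
        img = img[None, None]
    elif img.ndim == 3:  # (H, W, C) -> (1, C, H, W)
        img = np.moveaxis(img, -1, 0)[None]
    else:
        raise ConfigError("expected a 2-D image or (H, W, C) array")
    if img.shape[1] != in_channels:
        raise ConfigError(
            f"image has {img.shape[1]} channels, model expects {in_channels}"
        )
    return img


def build_segmenter(cfg: SegmenterConfig) -> Segmenter:
    """Construct a segmenter with weights reproducible from ``cfg.seed``."""
    cfg.validate()
    if cfg.architecture == "unet":
        module: Module = UNet(cfg.in_channels, cfg.n_classes, cfg.width, cfg.depth,
                              seed=cfg.seed)
    elif cfg.architecture == "double_unet":
        module = DoubleUNetModule(cfg.in_channels, cfg.n_classes, cfg.width,
                                  cfg.depth, cfg.seed)
    else:
        module = DilatedEncDec(cfg.in_channels, cfg.n_classes, cfg.width, cfg.depth,
                               seed=cfg.seed)
    return Segmenter(cfg, module)


def forward_double(
    unet_a: Segmenter, unet_b: Segmenter, image: np.ndarray
) -> tuple[ScoreMap, ScoreMap]:
    """Chain two independently built U-Nets on one image.

    The second network's input channels must equal the image channels plus
    the first network's class count.  Returns (interim, final) score maps so
    losses can supervise both.
    """
    expected = unet_a.cfg.in_channels + unet_a.cfg.n_classes
    if unet_b.cfg.in_channels != expected:
        raise ConfigError(
            f"second network expects {unet_b.cfg.in_channels} input channels, "
            f"chaining requires {expected}"
        )
    x = _to_batch(image, unet_a.cfg.in_channels)
    s1 = unet_a.module.forward(x)
    p1 = np.asarray(softmax(s1, axis=1), dtype=DTYPE)
    xb = np.concatenate([x, p1], axis=1)
    s2 = unet_b.module.forward(xb)
    return ScoreMap(np.moveaxis(s1[0], 0, -1)), ScoreMap(np.moveaxis(s2[0], 0, -1))
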