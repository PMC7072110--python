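"""A compact U-Net for hand-mask segmentation, trained with pixel-wise BCE.

The network is the classic encoder–decoder with skip connections: each
encoder stage is a 3x3 convolution + ReLU followed by 2x2 max pooling, the
bottleneck doubles the channel count once more, and each decoder stage
upsamples (nearest neighbor), concatenates the matching encoder activation
and convolves back down. A 1x1 convolution with a sigmoid head emits a
single-channel probability map, matching {0, 1} mask labels.

The architecture is parametric in ``depth`` (down-sampling stages) and
``base_filters`` (channels at the first stage, doubling per stage);
desk-scale experiments use depth 2 / base 4 at 64x64, realistic runs
depth 4 / base 32. Global average pooling of the bottleneck activations
yields the per-image deep feature vector (length base_filters * 2^depth)
used by the query-by-committee disagreement measure.

Training minimizes the per-image *summed* pixel-wise binary cross entropy
(mini-batches average the per-image sums) with Adam. Everything is seeded:
two models built from equal configs are bit-identical, and inference is a
deterministic forward pass.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn

_CLIP_EPS = 1e-7
_CHECKPOINT_VERSION = 1


class ContractError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class UNetConfig:
    depth: int = 2
    base_filters: int = 4
    input_size: tuple[int, int] = (64, 64)
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 4

    def __post_init__(self) -> None:
        if self.base_filters < 1 or self.depth < 1:
            raise ContractError("depth and base_filters must be >= 1")
        div = 2**self.depth
        if self.input_size[0] % div or self.input_size[1] % div:
            raise ContractError(
                f"input_size {self.input_size} not divisible by 2^depth = {div}"
            )

    @property
    def feature_length(self) -> int:
        return self.base_filters * 2**self.depth


def pixelwise_cross_entropy(truth: np.ndarray, prob: np.ndarray) -> float:
    """Summed per-pixel binary cross entropy.

    loss = sum_i [ -y_i log(p_i) - (1 - y_i) log(1 - p_i) ], probabilities
    clipped to [eps, 1 - eps] with eps = 1e-7 before the logarithms.
    """
    truth = np.asarray(truth, dtype=np.float64)
    prob = np.asarray(prob, dtype=np.float64)
    if truth.shape != prob.shape:
        raise ContractError(f"shape mismatch: {truth.shape} vs {prob.shape}")
    if not np.isin(truth, (0.0, 1.0)).all():
        raise ContractError("truth mask must be binary {0, 1}")
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ContractError("probabilities must lie in [0, 1]")
    p = np.clip(prob, _CLIP_EPS, 1.0 - _CLIP_EPS)
    return float(np.sum(-truth * np.log(p) - (1.0 - truth) * np.log1p(-p)))


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    source_model: str = ""
    source_image: str = ""


class SegmentationModel:
    """One committee member: a seeded U-Net plus its optimizer state."""

    def __init__(self, config: UNetConfig):
        self.config = config
        self.trained_epochs = 0
        rng = np.random.default_rng(config.seed)
        d, f = config.depth, config.base_filters
        self.enc = []
        c_in = 1
        for i in range(d):
            c_out = f * 2**i
            self.enc.append(nn.Conv2D(c_in, c_out, 3, rng))
            c_in = c_out
        self.bottleneck = nn.Conv2D(c_in, f * 2**d, 3, rng)
        self.dec = []
        c_up = f * 2**d
        for i in reversed(range(d)):
            c_skip = f * 2**i
            self.dec.append(nn.Conv2D(c_up + c_skip, c_skip, 3, rng))
            c_up = c_skip
        self.head = nn.Conv2D(c_up, 1, 1, rng)
        self._convs = [*self.enc, self.bottleneck, *self.dec, self.head]
        self._relus_enc = [nn.ReLU() for _ in range(d)]
        self._relu_bneck = nn.ReLU()
        self._relus_dec = [nn.ReLU() for _ in range(d)]
        self._pools = [nn.MaxPool2() for _ in range(d)]
        self.optimizer = nn.Adam(self._convs, lr=config.learning_rate)

    # ----- forward / backward -----------------------------------------

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[2:] != tuple(self.config.input_size):
            raise ContractError(
                f"expected spatial shape {self.config.input_size}, got {x.shape[2:]}"
            )
        return x

    def forward(self, x: np.ndarray, cache: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Return (probability maps (N, H, W), bottleneck tensor (N, C, h, w))."""
        x = self._check_batch(x)
        h = x
        skips = []
        for conv, relu, pool in zip(self.enc, self._relus_enc, self._pools):
            a = relu.forward(conv.forward(h, cache), cache)
            skips.append(a)
            h = pool.forward(a, cache)
        h = self._relu_bneck.forward(self.bottleneck.forward(h, cache), cache)
        bneck = h
        self._skip_channels = []
        for conv, relu, skip in zip(self.dec, self._relus_dec, reversed(skips)):
            u = nn.upsample2(h)
            self._skip_channels.append(u.shape[1])
            h = relu.forward(conv.forward(np.concatenate([u, skip], axis=1), cache), cache)
        logits = self.head.forward(h, cache)
        return nn.sigmoid(logits)[:, 0], bneck

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for conv, relu, c_up in zip(
            reversed(self.dec), reversed(self._relus_dec), reversed(self._skip_channels)
        ):
            dcat = conv.backward(relu.backward(d))
            dskips.append(dcat[:, c_up:])
            d = nn.upsample2_backward(dcat[:, :c_up])
        # dskips[i] pairs with encoder stage i (decoder runs deepest-skip last)
        d = self.bottleneck.backward(self._relu_bneck.backward(d))
        for conv, relu, pool, dskip in zip(
            reversed(self.enc), reversed(self._relus_enc), reversed(self._pools), reversed(dskips)
        ):
            da = pool.backward(d) + dskip
            d = conv.backward(relu.backward(da))

    # ----- public API --------------------------------------------------

    def predict_probability_map(self, image: np.ndarray) -> np.ndarray:
        """Deterministic inference on one image; values in [0, 1]."""
        probs, _ = self.forward(image, cache=False)
        return probs[0]

    def predict_batch(self, images: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(images, cache=False)
        return probs

    def extract_feature_vector(self, image: np.ndarray) -> FeatureVector:
        """Global-average-pooled bottleneck activations (length f * 2^depth)."""
        return FeatureVector(
            values=self.feature_matrix(np.asarray(image)[None] if np.asarray(image).ndim == 2 else image)[0],
            source_model=f"seed-{self.config.seed}",
        )

    def feature_matrix(self, images: np.ndarray) -> np.ndarray:
        """GAP bottleneck features for a batch: (N, base_filters * 2^depth)."""
        _, bneck = self.forward(images, cache=False)
        return bneck.mean(axis=(2, 3)).astype(np.float64)

    def train_epoch(
        self, items: Sequence[tuple[np.ndarray, np.ndarray]], batch_size: int | None = None
    ) -> float:
        """One seeded-shuffle pass over ``items`` = (image, mask) pairs.

        Minimizes the mean over the batch of per-image summed cross
        entropy; returns the mean per-image loss across the epoch and
        increments ``trained_epochs``.
        """
        if len(items) == 0:
            raise ContractError("labeled pool is empty")
        batch_size = batch_size or self.config.batch_size
        rng = np.random.default_rng((self.config.seed * 1_000_003 + self.trained_epochs) % 2**31)
        order = rng.permutation(len(items))
        total_loss = 0.0
        for start in range(0, len(items), batch_size):
            idx = order[start : start + batch_size]
            xb = np.stack([np.asarray(items[i][0], dtype=np.float32) for i in idx])
            yb = np.stack([np.asarray(items[i][1], dtype=np.float32) for i in idx])
            if yb.shape[1:] != tuple(self.config.input_size):
                raise ContractError(
                    f"mask shape {yb.shape[1:]} != input_size {self.config.input_size}"
                )
            probs, _ = self.forward(xb, cache=True)
            for t, p in zip(yb, probs):
                total_loss += pixelwise_cross_entropy(t, p)
            # d(sum BCE)/dlogit = p - y; batch objective averages per-image sums
            dlogits = ((probs - yb) / len(idx)).astype(np.float32)[:, None]
            self._backward(dlogits)
            self.optimizer.step()
        self.trained_epochs += 1
        return total_loss / len(items)

    # ----- serialization ----------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, conv in enumerate(self._convs):
            arrays[f"W{i}"] = conv.W
            arrays[f"b{i}"] = conv.b
        meta = dict(dataclasses.asdict(self.config))
        meta["input_size"] = list(meta["input_size"])
        np.savez(
            path,
            __version__=np.array(_CHECKPOINT_VERSION),
            __config__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            __epochs__=np.array(self.trained_epochs),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        data = np.load(path)
        if int(data["__version__"]) != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {int(data['__version__'])}")
        meta = json.loads(bytes(data["__config__"]).decode())
        meta["input_size"] = tuple(meta["input_size"])
        model = cls(UNetConfig(**meta))
        for i, conv in enumerate(model._convs):
            conv.W[...] = data[f"W{i}"]
            conv.b[...] = data[f"b{i}"]
        model.trained_epochs = int(data["__epochs__"])
        return model


def build_unet(config: UNetConfig) -> SegmentationModel:
    """Construct a seeded U-Net; equal configs give bit-identical models."""
    return SegmentationModel(config)


def extract_feature_vector(model: SegmentationModel, image: np.ndarray) -> FeatureVector:
    return model.extract_feature_vector(image)


def predict_probability_map(model: SegmentationModel, image: np.ndarray) -> np.ndarray:
    return model.predict_probability_map(image)


def train_epoch(
    model: SegmentationModel,
    items: Sequence[tuple[np.ndarray, np.ndarray]],
    batch_size: int | None = None,
) -> tuple[SegmentationModel, float]:
    loss = model.train_epoch(items, batch_size)
    return model, loss
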