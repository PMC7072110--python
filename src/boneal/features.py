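"""Deep feature extraction with global average pooling and 2-D decompositions.

A ``FeatureBackbone`` maps a preprocessed image to a 3-D activation tensor
(rows x cols x channels); global average pooling flattens it to a
per-image vector, and the stacked vectors form the feature matrix fed to
the age regressors. The default desk-scale backbone reuses the encoder of
the best active-learning committee member — a network that has already
learned hand structure — in place of the large ImageNet-pretrained
backbones used at archive scale, which plug in behind the same interface.

For inspection, feature matrices can be decomposed to two dimensions with
incremental PCA or kernel PCA (linear / RBF kernels) and exported as an
age-colored scatter plot plus a CSV of the embedding.
"""

from __future__ import annotations

import csv
import dataclasses
import warnings
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .unet import SegmentationModel


class ContractError(ValueError):
    pass


class FeatureBackbone(Protocol):
    name: str

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Deterministic map from a 2-D image to (rows, cols, channels)."""
        ...


class EncoderBackbone:
    """Backbone wrapping a trained segmentation net's encoder bottleneck."""

    def __init__(self, model: SegmentationModel, name: str | None = None):
        self.model = model
        self.name = name or f"unet-encoder-d{model.config.depth}f{model.config.base_filters}"

    def forward(self, image: np.ndarray) -> np.ndarray:
        _, bneck = self.model.forward(np.asarray(image, dtype=np.float32)[None], cache=False)
        return np.ascontiguousarray(bneck[0].transpose(1, 2, 0)).astype(np.float64)


def global_average_pool(tensor: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of a (rows, cols, channels) tensor."""
    tensor = np.asarray(tensor, dtype=np.float64)
    if tensor.ndim != 3 or tensor.shape[0] == 0 or tensor.shape[1] == 0:
        raise ContractError(f"expected a nonempty 3-D tensor, got shape {tensor.shape}")
    return tensor.mean(axis=(0, 1))


@dataclasses.dataclass(frozen=True)
class FeatureMatrix:
    rows: np.ndarray  # (n_images, n_features)
    image_ids: tuple[str, ...]
    backbone_name: str

    def __post_init__(self) -> None:
        if self.rows.ndim != 2 or len(self.image_ids) != self.rows.shape[0]:
            raise ContractError("feature matrix rows must align with image ids")
        if not np.isfinite(self.rows).all():
            raise ContractError("feature matrix contains non-finite entries")


def extract_features(
    backbone: FeatureBackbone,
    images: Sequence[np.ndarray],
    image_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Row i = GAP(backbone.forward(images[i])); input order preserved."""
    ids = tuple(image_ids) if image_ids is not None else tuple(str(i) for i in range(len(images)))
    rows = []
    for image_id, image in zip(ids, images):
        try:
            rows.append(global_average_pool(backbone.forward(image)))
        except Exception as exc:
            raise ContractError(f"backbone failed on image {image_id!r}: {exc}") from exc
    return FeatureMatrix(rows=np.stack(rows), image_ids=ids, backbone_name=backbone.name)


@dataclasses.dataclass(frozen=True)
class Embedding2D:
    points: np.ndarray  # (n, 2)
    method: str
    image_ids: tuple[str, ...]
    ages: np.ndarray | None = None


_METHODS = ("incremental-pca", "kernel-pca-linear", "kernel-pca-rbf")


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (reproducible signs)."""
    out = scores.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col.any():
            out[:, j] = col * np.sign(col[np.argmax(np.abs(col))])
    return out


def decompose_2d(
    features: FeatureMatrix,
    method: str = "incremental-pca",
    seed: int = 0,
    ages: np.ndarray | None = None,
) -> Embedding2D:
    """Center and project a feature matrix onto its top two components.

    RBF kernel PCA uses the median-pairwise-distance bandwidth heuristic.
    A rank-deficient matrix (fewer than two informative directions) emits
    a degeneracy warning and zero-fills the second column.
    """
    from sklearn.decomposition import IncrementalPCA, KernelPCA

    if method not in _METHODS:
        raise ContractError(f"method must be one of {_METHODS}, got {method!r}")
    X = np.asarray(features.rows, dtype=np.float64)
    n, d = X.shape
    if n < 3 or d < 2:
        raise ContractError(f"need n >= 3 and >= 2 features, got {X.shape}")
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < 2:
        warnings.warn("feature matrix has rank < 2: second embedding column is zero")
        if rank == 0:
            scores = np.zeros((n, 2))
        else:
            ipca = IncrementalPCA(n_components=1)
            first = ipca.fit_transform(Xc)
            scores = np.hstack([first, np.zeros((n, 1))])
    elif method == "incremental-pca":
        scores = IncrementalPCA(n_components=2).fit_transform(Xc)
    else:
        kernel = "linear" if method.endswith("linear") else "rbf"
        gamma = None
        if kernel == "rbf":
            # median pairwise squared-distance heuristic
            d2 = np.sum((Xc[:, None, :] - Xc[None, :, :]) ** 2, axis=-1)
            med = np.median(d2[np.triu_indices(n, k=1)])
            gamma = 1.0 / med if med > 0 else 1.0
        scores = KernelPCA(n_components=2, kernel=kernel, gamma=gamma, random_state=seed).fit_transform(Xc)
    return Embedding2D(
        points=_fix_signs(scores),
        method=method,
        image_ids=features.image_ids,
        ages=None if ages is None else np.asarray(ages),
    )


def export_scatter(embedding: Embedding2D, out_path: str | Path) -> tuple[Path, Path]:
    """Write an age-colored scatter PNG and a CSV (`id,x,y,age`) of the points."""
    out_path = Path(out_path)
    csv_path = out_path.with_suffix(".csv")
    ages = embedding.ages if embedding.ages is not None else np.full(len(embedding.image_ids), np.nan)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y", "age"])
        for image_id, (x, y), age in zip(embedding.image_ids, embedding.points, ages):
            writer.writerow([image_id, repr(float(x)), repr(float(y)), "" if np.isnan(age) else int(age)])

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(embedding.points[:, 0], embedding.points[:, 1], c=ages, cmap="viridis", s=12)
    fig.colorbar(sc, ax=ax, label="bone age (months)")
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.set_title(embedding.method)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path, csv_path


def read_embedding_csv(path: str | Path) -> Embedding2D:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        ids, pts, ages = [], [], []
        for row in reader:
            ids.append(row["id"])
            pts.append((float(row["x"]), float(row["y"])))
            ages.append(float(row["age"]) if row["age"] else np.nan)
    return Embedding2D(points=np.asarray(pts), method="from-csv", image_ids=tuple(ids), ages=np.asarray(ages))


def write_feature_csv(features: FeatureMatrix, path: str | Path) -> None:
    """Feature matrix as CSV with header ``id,f0,f1,...``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + [f"f{j}" for j in range(features.rows.shape[1])])
        for image_id, row in zip(features.image_ids, features.rows):
            writer.writerow([image_id] + [repr(float(v)) for v in row])


def read_feature_csv(path: str | Path, backbone_name: str = "from-csv") -> FeatureMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        ids, rows = [], []
        for line in reader:
            ids.append(line[0])
            rows.append([float(v) for v in line[1:]])
    return FeatureMatrix(rows=np.asarray(rows), image_ids=tuple(ids), backbone_name=backbone_name)
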