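"""Query-by-committee (QBC) active learning for hand-mask segmentation.

A committee of k U-Nets shares one architecture but distinct initialization
seeds, so after every training epoch each member extracts different deep
features from the same unlabeled image. Informativeness is measured by the
cosine similarity between members' feature vectors: the lower the
similarity across the committee, the more the members disagree and the more
an annotation of that image is expected to help. Each query epoch the
lowest-similarity images are sent to the oracle (ground-truth masks in the
synthetic setting), moved into the labeled pool and used from the next
epoch on; after the query phase the committee trains further without
querying. A fully supervised baseline trained on a fixed random subset of
the same annotation budget serves as the comparison arm.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Protocol, Sequence

import numpy as np

from .metrics import dice
from .preprocessing import binarize
from .unet import SegmentationModel, UNetConfig, build_unet

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


class DegenerateVectorError(ValueError):
    pass


class OracleError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# pools and configuration


@dataclasses.dataclass
class LabeledPool:
    """Annotated items (id, image, mask) plus where each label came from."""

    items: list[tuple[str, np.ndarray, np.ndarray]]
    provenance: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [i for i, _, _ in self.items]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate ids in labeled pool")
        for i in ids:
            self.provenance.setdefault(i, "initial")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def ids(self) -> set[str]:
        return {i for i, _, _ in self.items}

    def training_items(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(img, mask) for _, img, mask in self.items]


@dataclasses.dataclass
class UnlabeledPool:
    items: list[tuple[str, np.ndarray]]

    def __len__(self) -> int:
        return len(self.items)

    @property
    def ids(self) -> set[str]:
        return {i for i, _ in self.items}


@dataclasses.dataclass(frozen=True)
class ALConfig:
    """The annotation schedule.

    The reference schedule starts from 100 labeled images, queries 10 per
    epoch for 20 epochs (300 labels, 200 oracle calls) and then trains 80
    further epochs without querying.
    """

    k: int = 3
    initial_labeled: int = 100
    queries_per_epoch: int = 10
    query_epochs: int = 20
    post_epochs: int = 80
    master_seed: int = 0
    aggregate: str = "mean"  # "mean" or "min" over member pairs

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError("committee size k must be >= 2")
        if min(self.initial_labeled, self.queries_per_epoch) < 1:
            raise ConfigurationError("initial_labeled and queries_per_epoch must be >= 1")
        # query_epochs = 0 is the degenerate schedule: plain k-model supervised
        # training with no oracle calls
        if self.query_epochs < 0 or self.post_epochs < 0:
            raise ConfigurationError("query_epochs and post_epochs must be >= 0")
        if self.aggregate not in ("mean", "min"):
            raise ConfigurationError("aggregate must be 'mean' or 'min'")


@dataclasses.dataclass
class Committee:
    members: list[SegmentationModel]
    member_seeds: list[int]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ConfigurationError("committee needs k >= 2 members")
        if len(set(self.member_seeds)) != len(self.member_seeds):
            raise ConfigurationError("member seeds must be pairwise distinct")


@dataclasses.dataclass(frozen=True)
class EpochRecord:
    epoch: int
    mean_member_loss: float
    queried_ids: tuple[str, ...]
    queried_scores: tuple[float, ...]
    labeled_size: int


@dataclasses.dataclass
class ALHistory:
    epochs: list[EpochRecord] = dataclasses.field(default_factory=list)

    @property
    def oracle_calls(self) -> int:
        return sum(len(e.queried_ids) for e in self.epochs)


class Oracle(Protocol):
    def annotate(self, image_id: str) -> np.ndarray: ...


class GroundTruthOracle:
    """Synthetic oracle: serves stored ground-truth masks by image id."""

    def __init__(self, masks: dict[str, np.ndarray]):
        self._masks = masks

    def annotate(self, image_id: str) -> np.ndarray:
        if image_id not in self._masks:
            raise OracleError(f"oracle has no mask for id {image_id!r}")
        return self._masks[image_id]


# ----------------------------------------------------------------------
# disagreement


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """cos(v1, v2) = v1 . v2 / (||v1|| ||v2||), in [-1, 1]."""
    v1 = np.asarray(v1, dtype=np.float64).ravel()
    v2 = np.asarray(v2, dtype=np.float64).ravel()
    if v1.size != v2.size:
        raise ValueError(f"length mismatch: {v1.size} vs {v2.size}")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateVectorError("cosine similarity undefined for a zero vector")
    return float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))


def pairwise_similarity_score(vectors: Sequence[np.ndarray], aggregate: str = "mean") -> float:
    """Aggregate cosine similarity over all k(k-1)/2 member pairs.

    Lower = more committee disagreement = more informative sample.
    """
    if len(vectors) < 2:
        raise ConfigurationError("need at least 2 feature vectors")
    sims = [
        cosine_similarity(vectors[i], vectors[j])
        for i in range(len(vectors))
        for j in range(i + 1, len(vectors))
    ]
    return float(min(sims)) if aggregate == "min" else float(np.mean(sims))


def disagreement_score(committee: Committee, image: np.ndarray, aggregate: str = "mean") -> float:
    vectors = [m.extract_feature_vector(image).values for m in committee.members]
    return pairwise_similarity_score(vectors, aggregate)


def score_unlabeled(
    committee: Committee,
    unlabeled: UnlabeledPool,
    aggregate: str = "mean",
    chunk: int = 32,
) -> dict[str, float]:
    """Disagreement score for every unlabeled item (batched forward passes)."""
    if len(unlabeled) == 0:
        return {}
    ids = [i for i, _ in unlabeled.items]
    images = np.stack([np.asarray(img, dtype=np.float32) for _, img in unlabeled.items])
    feats = []
    for member in committee.members:
        rows = [member.feature_matrix(images[s : s + chunk]) for s in range(0, len(ids), chunk)]
        feats.append(np.concatenate(rows, axis=0))
    scores = {}
    for idx, image_id in enumerate(ids):
        scores[image_id] = pairwise_similarity_score([f[idx] for f in feats], aggregate)
    return scores


def select_queries(scores: dict[str, float], batch: int) -> list[str]:
    """The ``batch`` ids with the lowest scores, ascending; ties break lexicographically."""
    if not scores:
        raise ConfigurationError("empty unlabeled pool")
    if batch > len(scores):
        raise ConfigurationError(f"batch {batch} exceeds pool size {len(scores)}")
    return [i for i, _ in sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))[:batch]]


# ----------------------------------------------------------------------
# the AL loop


def build_committee(net_config: UNetConfig, k: int, master_seed: int) -> Committee:
    """k members sharing one architecture, seeds master_seed + 0..k-1."""
    seeds = [master_seed + i for i in range(k)]
    members = [
        build_unet(dataclasses.replace(net_config, seed=s)) for s in seeds
    ]
    return Committee(members=members, member_seeds=seeds)


def run_active_learning(
    labeled: LabeledPool,
    unlabeled: UnlabeledPool,
    oracle: Oracle,
    config: ALConfig,
    net_config: UNetConfig,
    epoch_callback: Callable[[EpochRecord], None] | None = None,
) -> tuple[Committee, ALHistory]:
    """The QBC loop: train, score, query, annotate, repeat; then post-train.

    Every query epoch each member trains one epoch on the current labeled
    pool, all unlabeled items are re-scored, the ``queries_per_epoch``
    lowest-similarity items are annotated by the oracle and join the
    labeled pool for the next epoch. If the unlabeled pool runs dry,
    querying stops early and training continues.
    """
    if len(labeled) != config.initial_labeled:
        raise ConfigurationError(
            f"labeled pool has {len(labeled)} items, config.initial_labeled = {config.initial_labeled}"
        )
    overlap = labeled.ids & unlabeled.ids
    if overlap:
        raise ConfigurationError(f"pools not disjoint: {sorted(overlap)[:5]}")

    committee = build_committee(net_config, config.k, config.master_seed)
    history = ALHistory()
    total_epochs = config.query_epochs + config.post_epochs

    for epoch in range(1, total_epochs + 1):
        losses = [m.train_epoch(labeled.training_items()) for m in committee.members]
        queried_ids: list[str] = []
        queried_scores: list[float] = []
        if epoch <= config.query_epochs and len(unlabeled) > 0:
            scores = score_unlabeled(committee, unlabeled, config.aggregate)
            batch = min(config.queries_per_epoch, len(unlabeled))
            if batch < config.queries_per_epoch:
                logger.info("epoch %d: unlabeled pool nearly exhausted, querying %d", epoch, batch)
            queried_ids = select_queries(scores, batch)
            queried_scores = [scores[i] for i in queried_ids]
            lookup = dict(unlabeled.items)
            for qid in queried_ids:
                try:
                    mask = np.asarray(oracle.annotate(qid))
                except Exception as exc:
                    raise OracleError(f"oracle failed on queried id {qid!r}: {exc}") from exc
                labeled.items.append((qid, lookup[qid], mask))
                labeled.provenance[qid] = f"queried-at-epoch-{epoch}"
            taken = set(queried_ids)
            unlabeled.items = [it for it in unlabeled.items if it[0] not in taken]
        record = EpochRecord(
            epoch=epoch,
            mean_member_loss=float(np.mean(losses)),
            queried_ids=tuple(queried_ids),
            queried_scores=tuple(queried_scores),
            labeled_size=len(labeled),
        )
        history.epochs.append(record)
        if epoch_callback is not None:
            epoch_callback(record)
    return committee, history


def run_fully_supervised_baseline(
    labeled: LabeledPool,
    net_config: UNetConfig,
    epochs: int,
    budget: int | None = None,
    seed: int = 0,
) -> SegmentationModel:
    """Single model trained on a fixed seeded subset of the annotation budget."""
    if len(labeled) == 0:
        raise ConfigurationError("labeled pool is empty")
    items = labeled.training_items()
    if budget is not None and budget < len(items):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(items), size=budget, replace=False)
        items = [items[i] for i in sorted(idx)]
    model = build_unet(net_config)
    for _ in range(epochs):
        model.train_epoch(items)
    return model


def evaluate_segmentation(
    model: SegmentationModel,
    items: Sequence[tuple[np.ndarray, np.ndarray]],
    threshold: float = 0.5,
    chunk: int = 32,
) -> float:
    """Mean Dice of thresholded predictions over (image, mask) pairs."""
    scores = []
    images = np.stack([np.asarray(i, dtype=np.float32) for i, _ in items])
    for s in range(0, len(items), chunk):
        probs = model.predict_batch(images[s : s + chunk])
        for p, (_, mask) in zip(probs, items[s : s + chunk]):
            scores.append(dice(mask, binarize(p, threshold)))
    return float(np.mean(scores))


def best_member(
    committee: Committee,
    validation_items: Sequence[tuple[np.ndarray, np.ndarray]],
    threshold: float = 0.5,
) -> tuple[int, float]:
    """Index and Dice of the member that segments the validation split best."""
    dices = [evaluate_segmentation(m, validation_items, threshold) for m in committee.members]
    idx = int(np.argmax(dices))
    return idx, float(dices[idx])


def select_queries_from_committee(
    committee: Committee, unlabeled: UnlabeledPool, batch: int, aggregate: str = "mean"
) -> list[str]:
    """Score a pool with the committee and pick the ``batch`` most informative ids."""
    return select_queries(score_unlabeled(committee, unlabeled, aggregate), batch)
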