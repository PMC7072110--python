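"""End-to-end pipeline: generate, segment (AL or FSL), extract, regress, report.

A single YAML config with per-stage blocks (plus one global seed) drives
every stage; the same seed always reproduces the same metric reports.
Stages communicate through files in a working directory:

    work/
      dataset/           phantom PNGs + manifest.csv
      models/            committee / baseline checkpoints (.npz)
      masks_pred/        predicted masks, cropped hand images
      features.csv       per-image GAP feature vectors
      embedding.csv/png  2-D decomposition colored by age
      reports/           segmentation + regression CSV reports
      runlog.jsonl       append-only structured event log
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
from PIL import Image

from . import active_learning as al
from . import features as ft
from . import metrics, phantoms, preprocessing, regression
from .unet import SegmentationModel, UNetConfig

logger = logging.getLogger(__name__)


class DependencyError(RuntimeError):
    """A stage was invoked before the stage it depends on produced its artifacts."""


class ManifestError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    work_dir: str = "work"
    # synthetic data
    n_phantoms: int = 60
    shape: tuple[int, int] = (64, 64)
    variation: phantoms.VariationConfig = dataclasses.field(default_factory=phantoms.VariationConfig)
    test_fraction: float = 0.25
    # preprocessing
    clahe_clip_limit: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_stage: str = "before_norm"  # or "after_segmentation"
    threshold: float = 0.5
    crop_margin: int = 2
    # segmentation net
    unet: UNetConfig = dataclasses.field(default_factory=UNetConfig)
    # active learning (counts are relative to the training split)
    al: al.ALConfig = dataclasses.field(
        default_factory=lambda: al.ALConfig(
            k=2, initial_labeled=10, queries_per_epoch=2, query_epochs=5, post_epochs=15
        )
    )
    fsl_epochs: int = 20
    # features / regression
    decompose_method: str = "incremental-pca"
    regressor: regression.RegressorConfig = dataclasses.field(default_factory=regression.RegressorConfig)
    ensemble: regression.EnsembleConfig = dataclasses.field(
        default_factory=lambda: regression.EnsembleConfig(n_estimators=5)
    )
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.clahe_stage not in ("before_norm", "after_segmentation"):
            raise ValueError("clahe_stage must be 'before_norm' or 'after_segmentation'")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


_NESTED = {
    "variation": phantoms.VariationConfig,
    "unet": UNetConfig,
    "al": al.ALConfig,
    "regressor": regression.RegressorConfig,
    "ensemble": regression.EnsembleConfig,
}
_TUPLE_FIELDS = {"shape", "clahe_tiles", "input_size", "brightness", "contrast", "noise_sd", "artifact_count"}


def _build_dataclass(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            raise ValueError(f"unknown configuration key {key!r} for {cls.__name__}")
        if key in _NESTED and isinstance(value, dict):
            value = _build_dataclass(_NESTED[key], value)
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file, with flag overrides on top."""
    import yaml

    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides or {})
    return _build_dataclass(PipelineConfig, data)


class RunLog:
    """Append-only JSON-lines event log; every stage writes start and end."""

    def __init__(self, path: Path):
        self.path = path

    def event(self, stage: str, event: str, **payload: Any) -> None:
        record = {
            "ts": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "stage": stage,
            "event": event,
            **payload,
        }
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record, default=str) + "\n")


# ----------------------------------------------------------------------
# manifest and image I/O


def read_manifest(path: str | Path) -> phantoms.DatasetManifest:
    """Read and validate a dataset manifest (header ``id,boneage,male,image[,mask]``)."""
    path = Path(path)
    rows: list[phantoms.ManifestRow] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "boneage", "male", "image"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ManifestError(f"manifest must have header columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                age = int(row["boneage"])
            except (TypeError, ValueError):
                raise ManifestError(f"line {lineno}: boneage {row.get('boneage')!r} is not an integer")
            if not 0 <= age <= 228:
                raise ManifestError(f"line {lineno}: boneage {age} outside [0, 228] months")
            if row["male"] not in ("True", "False"):
                raise ManifestError(f"line {lineno}: male must be True or False, got {row['male']!r}")
            if row["id"] in seen:
                raise ManifestError(f"line {lineno}: duplicate id {row['id']!r}")
            seen.add(row["id"])
            img = path.parent / row["image"]
            if not img.exists():
                raise ManifestError(f"missing image file for id {row['id']!r}: {img}")
            mask = row.get("mask") or None
            if mask and not (path.parent / mask).exists():
                raise ManifestError(f"missing mask file for id {row['id']!r}")
            rows.append(
                phantoms.ManifestRow(
                    id=row["id"], age_months=age, male=row["male"] == "True",
                    image_path=row["image"], mask_path=mask,
                )
            )
    return phantoms.DatasetManifest(records=tuple(rows), seed=-1)


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.float32)


def load_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def write_masks(ids, masks, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for image_id, mask in zip(ids, masks):
        p = out_dir / f"{image_id}_pred.png"
        Image.fromarray((np.asarray(mask) * 255).astype(np.uint8), mode="L").save(p)
        paths.append(p)
    return paths


def _resize(arr: np.ndarray, size: tuple[int, int], nearest: bool = False) -> np.ndarray:
    if arr.shape == tuple(size):
        return arr
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    resample = Image.NEAREST if nearest else Image.BILINEAR
    return np.asarray(im.resize((size[1], size[0]), resample=resample), dtype=np.float32)


def prepare_image(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Resize to the net input, optionally CLAHE, then standardize."""
    img = _resize(image, config.unet.input_size)
    if config.clahe_stage == "before_norm":
        img = preprocessing.apply_clahe(
            np.clip(img, 0, 255), config.clahe_clip_limit, config.clahe_tiles
        )
    return preprocessing.standardize(img).pixels.astype(np.float32)


# ----------------------------------------------------------------------
# stages


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.work = Path(config.work_dir)
        self.work.mkdir(parents=True, exist_ok=True)
        self.log = RunLog(self.work / "runlog.jsonl")

    # -- stage: generate -------------------------------------------------
    def generate(self) -> phantoms.DatasetManifest:
        cfg = self.config
        self.log.event("generate", "start", n=cfg.n_phantoms, seed=cfg.seed)
        manifest = phantoms.generate_dataset(
            cfg.n_phantoms, cfg.seed, self.work / "dataset", cfg.variation, cfg.shape
        )
        self.log.event("generate", "end", manifest=str(self.work / "dataset" / "manifest.csv"))
        return manifest

    def _load_dataset(self):
        manifest_path = self.work / "dataset" / "manifest.csv"
        if not manifest_path.exists():
            raise DependencyError("dataset missing: run the generate stage first")
        manifest = read_manifest(manifest_path)
        root = manifest_path.parent
        items = []
        for row in manifest.records:
            image = load_image(root / row.image_path)
            mask = load_mask(root / row.mask_path) if row.mask_path else None
            items.append((row, prepare_image(image, self.config), mask, image))
        return manifest, items

    def _split(self, items):
        # deterministic train/test split from the global seed
        rng = np.random.default_rng(self.config.seed + 777)
        n_test = max(1, int(round(self.config.test_fraction * len(items))))
        test_idx = set(rng.choice(len(items), size=n_test, replace=False).tolist())
        train = [it for i, it in enumerate(items) if i not in test_idx]
        test = [it for i, it in enumerate(items) if i in test_idx]
        return train, test

    # -- stage: al-train -------------------------------------------------
    def al_train(self) -> tuple[al.Committee, al.ALHistory]:
        cfg = self.config
        self.log.event("al-train", "start", k=cfg.al.k)
        _, items = self._load_dataset()
        train, test = self._split(items)
        n_init = cfg.al.initial_labeled
        if n_init >= len(train):
            raise al.ConfigurationError("initial_labeled must be smaller than the training split")
        labeled = al.LabeledPool(items=[(r.id, x, m) for r, x, m, _ in train[:n_init]])
        unlabeled = al.UnlabeledPool(items=[(r.id, x) for r, x, _, _ in train[n_init:]])
        oracle = al.GroundTruthOracle({r.id: m for r, _, m, _ in train if m is not None})
        net_config = dataclasses.replace(cfg.unet, seed=cfg.seed)
        committee, history = al.run_active_learning(labeled, unlabeled, oracle,
                                                    dataclasses.replace(cfg.al, master_seed=cfg.seed),
                                                    net_config)
        models_dir = self.work / "models"
        models_dir.mkdir(exist_ok=True)
        for i, member in enumerate(committee.members):
            member.save(models_dir / f"member{i}.npz")
        test_items = [(x, m) for _, x, m, _ in test if m is not None]
        best_idx, best_dice = al.best_member(committee, test_items, cfg.threshold)
        (models_dir / "best_member.json").write_text(
            json.dumps({"index": best_idx, "dice": best_dice})
        )
        self._write_history(history)
        self.log.event("al-train", "end", best_member=best_idx, test_dice=best_dice,
                       labeled_final=len(labeled), oracle_calls=history.oracle_calls)
        return committee, history

    def _write_history(self, history: al.ALHistory) -> None:
        with open(self.work / "al_history.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "mean_member_loss", "labeled_size", "queried_ids", "queried_scores"])
            for e in history.epochs:
                writer.writerow([
                    e.epoch, repr(e.mean_member_loss), e.labeled_size,
                    ";".join(e.queried_ids), ";".join(repr(s) for s in e.queried_scores),
                ])

    # -- stage: fsl-train ------------------------------------------------
    def fsl_train(self) -> SegmentationModel:
        cfg = self.config
        self.log.event("fsl-train", "start")
        _, items = self._load_dataset()
        train, _ = self._split(items)
        budget = cfg.al.initial_labeled + cfg.al.queries_per_epoch * cfg.al.query_epochs
        labeled = al.LabeledPool(items=[(r.id, x, m) for r, x, m, _ in train if m is not None])
        model = al.run_fully_supervised_baseline(
            labeled, dataclasses.replace(cfg.unet, seed=cfg.seed), cfg.fsl_epochs,
            budget=budget, seed=cfg.seed,
        )
        models_dir = self.work / "models"
        models_dir.mkdir(exist_ok=True)
        model.save(models_dir / "fsl.npz")
        self.log.event("fsl-train", "end", budget=budget)
        return model

    def _load_best_member(self) -> SegmentationModel:
        info_path = self.work / "models" / "best_member.json"
        if not info_path.exists():
            raise DependencyError("no trained committee: run the al-train stage first")
        idx = json.loads(info_path.read_text())["index"]
        return SegmentationModel.load(self.work / "models" / f"member{idx}.npz")

    # -- stage: segment --------------------------------------------------
    def segment(self) -> None:
        cfg = self.config
        self.log.event("segment", "start")
        model = self._load_best_member()
        _, items = self._load_dataset()
        out_dir = self.work / "masks_pred"
        ids = [r.id for r, _, _, _ in items]
        preds = []
        for r, x, _, raw in items:
            prob = model.predict_probability_map(x)
            pred = preprocessing.binarize(prob, cfg.threshold)
            preds.append(pred)
        write_masks(ids, preds, out_dir)
        crop_dir = self.work / "cropped"
        crop_dir.mkdir(exist_ok=True)
        for (r, x, _, raw), pred in zip(items, preds):
            raw_rs = _resize(raw, cfg.unet.input_size)
            if pred.sum() == 0:
                logger.warning("empty predicted mask for %s; skipping crop", r.id)
                continue
            cropped = preprocessing.crop_to_mask(raw_rs * pred, pred, cfg.crop_margin)
            Image.fromarray(np.clip(cropped, 0, 255).astype(np.uint8), mode="L").save(
                crop_dir / f"{r.id}_hand.png"
            )
        self.log.event("segment", "end", n=len(ids))

    # -- stage: features -------------------------------------------------
    def features(self) -> ft.FeatureMatrix:
        cfg = self.config
        self.log.event("features", "start")
        model = self._load_best_member()
        manifest, items = self._load_dataset()
        backbone = ft.EncoderBackbone(model)
        fm = ft.extract_features(backbone, [x for _, x, _, _ in items], [r.id for r, _, _, _ in items])
        ft.write_feature_csv(fm, self.work / "features.csv")
        ages = np.array([r.age_months for r, _, _, _ in items])
        emb = ft.decompose_2d(fm, cfg.decompose_method, seed=cfg.seed, ages=ages)
        ft.export_scatter(emb, self.work / "embedding.png")
        self.log.event("features", "end", n=fm.rows.shape[0], dim=fm.rows.shape[1])
        return fm

    # -- stage: regress --------------------------------------------------
    def regress(self) -> dict[str, regression.CVReport]:
        cfg = self.config
        self.log.event("regress", "start")
        feat_path = self.work / "features.csv"
        if not feat_path.exists():
            raise DependencyError("features.csv missing: run the features stage first")
        fm = ft.read_feature_csv(feat_path)
        manifest = read_manifest(self.work / "dataset" / "manifest.csv")
        by_id = {r.id: r for r in manifest.records}
        ages = np.array([by_id[i].age_months for i in fm.image_ids], dtype=float)
        male = np.array([by_id[i].male for i in fm.image_ids])
        folds = min(cfg.cv_folds, len(ages))
        strat = regression.stratified_fit(fm.rows, ages, male, cfg.regressor, folds=folds, seed=cfg.seed)
        ens_report = regression.cross_validate(
            fm.rows, ages, dataclasses.replace(cfg.ensemble, seed=cfg.seed), folds=folds, seed=cfg.seed
        )
        reports_dir = self.work / "reports"
        reports_dir.mkdir(exist_ok=True)
        with open(reports_dir / "regression.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["model", "cohort", "n", "mae_months", "rmse_months", "ccc"])
            fam = cfg.regressor.family.upper()
            for cohort, (_, rep) in strat.items():
                p = rep.pooled
                writer.writerow([f"{fam} ({cfg.regressor.kernel})", cohort, p.n,
                                 f"{p.mae:.4f}", f"{p.rmse:.4f}", f"{p.ccc:.4f}"])
            p = ens_report.pooled
            writer.writerow([f"{cfg.ensemble.method} ({cfg.ensemble.n_estimators}x KRR)", "all",
                             p.n, f"{p.mae:.4f}", f"{p.rmse:.4f}", f"{p.ccc:.4f}"])
        self.log.event("regress", "end")
        return {**{c: r for c, (_, r) in strat.items()}, "ensemble": ens_report}

    # -- stage: evaluate -------------------------------------------------
    def evaluate(self) -> dict[str, float]:
        cfg = self.config
        self.log.event("evaluate", "start")
        model = self._load_best_member()
        _, items = self._load_dataset()
        _, test = self._split(items)
        rows = []
        for r, x, mask, _ in test:
            if mask is None:
                continue
            pred = preprocessing.binarize(model.predict_probability_map(x), cfg.threshold)
            rows.append((
                metrics.dice(mask, pred),
                metrics.sensitivity(mask, pred),
                metrics.specificity(mask, pred),
            ))
        seg = {
            "dice": float(np.mean([r[0] for r in rows])),
            "sensitivity": float(np.mean([r[1] for r in rows])),
            "specificity": float(np.mean([r[2] for r in rows])),
            "n_test": len(rows),
        }
        reports_dir = self.work / "reports"
        reports_dir.mkdir(exist_ok=True)
        with open(reports_dir / "segmentation.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["strategy", "n_test", "sensitivity", "specificity", "dice"])
            writer.writerow(["AL best member", seg["n_test"],
                             f"{seg['sensitivity']:.4f}", f"{seg['specificity']:.4f}", f"{seg['dice']:.4f}"])
        self.log.event("evaluate", "end", **seg)
        return seg

    # -- everything ------------------------------------------------------
    def run_all(self) -> dict[str, Any]:
        self.generate()
        self.al_train()
        self.segment()
        self.features()
        reg = self.regress()
        seg = self.evaluate()
        return {"segmentation": seg, "regression": {c: r.pooled.mae for c, r in reg.items()}}
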