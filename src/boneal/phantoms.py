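"""Procedural hand-radiograph phantoms with ground-truth masks and a latent maturity.

A phantom is a stylized left hand — an elliptical palm plus five vertical
finger capsules — rendered onto a grayscale frame. A single latent
``maturity`` in [0, 1] drives the geometry (finger length relative to the
palm grows linearly with maturity) and maps to a bone age in months via
``age_months = round(228 * maturity)``, mirroring the 0–228 month range of
pediatric hand radiographs. Nuisance variation (brightness offset, contrast
gain, Gaussian noise, bright off-hand artifacts emulating labels and
collimator edges) emulates the wide intensity/contrast spread of clinical
X-ray archives without carrying any age signal.

Everything is reproducible: a dataset is a pure function of
``(n, seed, config)`` down to the PNG bytes.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

FULL_SCALE_MONTHS = 228

# Relative finger geometry, thumb -> pinky. Lengths are multiples of the palm
# semi-major axis; widths multiples of the semi-minor axis; columns multiples
# of the semi-minor axis offset from the palm center column.
_FINGER_LENGTH_PATTERN = np.array([0.62, 0.88, 1.00, 0.92, 0.70])
_FINGER_WIDTH_PATTERN = np.array([0.20, 0.17, 0.16, 0.15, 0.13])
_FINGER_COL_OFFSETS = np.array([-0.80, -0.40, 0.0, 0.40, 0.80])

# Finger length / palm semi-major axis = intercept + slope * maturity.
_LENGTH_INTERCEPT = 0.8
_LENGTH_SLOPE = 1.1

_BACKGROUND_INTENSITY = 30.0
_HAND_INTENSITY_BASE = 140.0
_HAND_INTENSITY_SLOPE = 50.0  # denser ossified bone renders brighter
_ARTIFACT_INTENSITY = 235.0


class ConfigurationError(ValueError):
    """A variation range or parameter value is inconsistent."""


class GeometryError(ValueError):
    """The requested hand does not fit inside the image frame."""


@dataclasses.dataclass(frozen=True)
class VariationConfig:
    """Ranges for the nuisance variation of a phantom dataset.

    Defaults emulate archives whose radiographs vary considerably in
    intensity, contrast and brightness: a +/-20 intensity-unit brightness
    offset, 0.85–1.25x contrast gain, up to 8 intensity units of Gaussian
    noise and up to 3 bright off-hand artifacts per image.
    ``geometry_jitter`` is the half-width of the multiplicative uniform
    jitter applied to finger lengths/widths and palm axes; 0 makes the
    geometry a deterministic function of maturity.
    """

    brightness: tuple[float, float] = (-20.0, 20.0)
    contrast: tuple[float, float] = (0.85, 1.25)
    noise_sd: tuple[float, float] = (0.0, 8.0)
    artifact_count: tuple[int, int] = (0, 3)
    geometry_jitter: float = 0.04
    male_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("brightness", "contrast", "noise_sd", "artifact_count"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} range has min > max: ({lo}, {hi})")
        if self.noise_sd[0] < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.artifact_count[0] < 0:
            raise ConfigurationError("artifact_count must be non-negative")
        if self.geometry_jitter < 0:
            raise ConfigurationError("geometry_jitter must be non-negative")
        if not 0.0 <= self.male_prob <= 1.0:
            raise ConfigurationError("male_prob must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class HandPhantomParams:
    """Full parameterization of one phantom; rendering is pure given these."""

    palm_center: tuple[float, float]  # (row, col) pixels
    palm_axes: tuple[float, float]  # (semi-major = vertical, semi-minor = horizontal)
    finger_count: int
    finger_lengths: tuple[float, ...]  # pixels, thumb -> pinky
    finger_widths: tuple[float, ...]  # capsule radii, pixels
    finger_cols: tuple[float, ...]  # center columns, pixels
    finger_base_row: float  # row where capsules root into the palm
    maturity: float
    brightness: float
    contrast: float
    noise_sd: float
    artifact_count: int
    male: bool
    render_seed: int  # drives noise and artifact placement only

    def __post_init__(self) -> None:
        if not 0.0 <= self.maturity <= 1.0:
            raise ConfigurationError(f"maturity must be in [0, 1], got {self.maturity}")
        if self.finger_count != 5:
            raise ConfigurationError("finger_count is fixed at 5")
        if min(self.finger_lengths) <= 0 or min(self.finger_widths) <= 0:
            raise ConfigurationError("finger lengths and widths must be strictly positive")
        if min(self.palm_axes) <= 0:
            raise ConfigurationError("palm axes must be strictly positive")
        if self.noise_sd < 0 or self.artifact_count < 0:
            raise ConfigurationError("noise_sd and artifact_count must be non-negative")

    @property
    def age_months(self) -> int:
        return int(round(FULL_SCALE_MONTHS * self.maturity))


@dataclasses.dataclass(frozen=True)
class PhantomRecord:
    """One synthetic dataset row: image, mask, age and sex."""

    id: str
    image: np.ndarray  # float32 in [0, 255]
    mask: np.ndarray  # uint8 in {0, 1}
    age_months: int
    male: bool
    params: HandPhantomParams


@dataclasses.dataclass(frozen=True)
class ManifestRow:
    id: str
    age_months: int
    male: bool
    image_path: str
    mask_path: str | None


@dataclasses.dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ManifestRow, ...]
    seed: int


def sample_phantom_params(
    rng: np.random.Generator,
    config: VariationConfig | None = None,
    shape: tuple[int, int] = (64, 64),
) -> HandPhantomParams:
    """Draw one phantom parameterization.

    Maturity is uniform on [0, 1]. Geometric fields that encode maturity
    (finger lengths relative to the palm axis) follow the deterministic
    linear map ``length_i = b * pattern_i * (0.8 + 1.1 * maturity)`` times a
    bounded multiplicative jitter, so the image geometry carries a
    recoverable age signal.
    """
    config = config or VariationConfig()
    rows, cols = shape
    maturity = float(rng.uniform(0.0, 1.0))

    jit = config.geometry_jitter

    def jitter(n: int = 1) -> np.ndarray:
        # draw even when jit == 0 so the stream layout is jitter-independent
        return 1.0 + rng.uniform(-jit, jit, size=n)

    b = 0.17 * rows * float(jitter()[0])
    a = 0.16 * cols * float(jitter()[0])
    center = (0.70 * rows, 0.50 * cols)
    lengths = b * _FINGER_LENGTH_PATTERN * (_LENGTH_INTERCEPT + _LENGTH_SLOPE * maturity)
    lengths = lengths * jitter(5)
    widths = a * _FINGER_WIDTH_PATTERN * jitter(5)
    finger_cols = center[1] + a * _FINGER_COL_OFFSETS
    base_row = center[0] - 0.55 * b

    return HandPhantomParams(
        palm_center=center,
        palm_axes=(b, a),
        finger_count=5,
        finger_lengths=tuple(float(v) for v in lengths),
        finger_widths=tuple(float(v) for v in widths),
        finger_cols=tuple(float(v) for v in finger_cols),
        finger_base_row=float(base_row),
        maturity=maturity,
        brightness=float(rng.uniform(*config.brightness)),
        contrast=float(rng.uniform(*config.contrast)),
        noise_sd=float(rng.uniform(*config.noise_sd)),
        artifact_count=int(rng.integers(config.artifact_count[0], config.artifact_count[1] + 1)),
        male=bool(rng.random() < config.male_prob),
        render_seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_params(
    maturity: float,
    shape: tuple[int, int] = (64, 64),
    male: bool = False,
    render_seed: int = 0,
    brightness: float = 0.0,
    contrast: float = 1.0,
    noise_sd: float = 0.0,
    artifact_count: int = 0,
) -> HandPhantomParams:
    """Deterministic jitter-free phantom at a chosen maturity.

    Evaluates the documented geometry map exactly: finger length =
    palm_semi_major * pattern * (0.8 + 1.1 * maturity); no nuisance
    variation unless requested.
    """
    rows, cols = shape
    b = 0.17 * rows
    a = 0.16 * cols
    center = (0.70 * rows, 0.50 * cols)
    lengths = b * _FINGER_LENGTH_PATTERN * (_LENGTH_INTERCEPT + _LENGTH_SLOPE * maturity)
    return HandPhantomParams(
        palm_center=center,
        palm_axes=(b, a),
        finger_count=5,
        finger_lengths=tuple(float(v) for v in lengths),
        finger_widths=tuple(float(v) for v in a * _FINGER_WIDTH_PATTERN),
        finger_cols=tuple(float(v) for v in center[1] + a * _FINGER_COL_OFFSETS),
        finger_base_row=float(center[0] - 0.55 * b),
        maturity=float(maturity),
        brightness=brightness,
        contrast=contrast,
        noise_sd=noise_sd,
        artifact_count=artifact_count,
        male=male,
        render_seed=render_seed,
    )


def finger_length_palm_ratio(params: HandPhantomParams) -> float:
    """Mean finger length divided by the palm semi-major axis.

    With zero jitter this equals ``mean(pattern) * (0.8 + 1.1 * maturity)``,
    an exactly linear (hence Pearson-r = 1) function of maturity.
    """
    return float(np.mean(params.finger_lengths) / params.palm_axes[0])


def geometry_features(params: HandPhantomParams) -> np.ndarray:
    """Scale-free geometric descriptors of a phantom (length 11).

    Finger lengths and capsule radii normalized by the palm axes, plus the
    summary length-to-palm ratio. Jitter-free, these are affine in maturity
    and form the noiseless regressor for age-recovery experiments.
    """
    b, a = params.palm_axes
    return np.concatenate(
        [
            np.asarray(params.finger_lengths) / b,
            np.asarray(params.finger_widths) / a,
            [finger_length_palm_ratio(params)],
        ]
    )


def measure_mask_ratio(mask: np.ndarray) -> float:
    """Finger-length-to-palm ratio measured from a rendered mask.

    Uses the mask extent: (total height - palm height) / palm height, with
    the palm height inferred from the widest-row heuristic (the palm is the
    widest structure). Quantized to the pixel grid, so only approximately
    linear in maturity.
    """
    fg = np.argwhere(mask > 0)
    if fg.size == 0:
        raise ValueError("empty mask")
    r0, r1 = fg[:, 0].min(), fg[:, 0].max()
    widths = (mask > 0).sum(axis=1)
    palm_width = widths.max()
    # palm vertical extent ~ rows at least 90% of max width
    palm_rows = np.flatnonzero(widths >= 0.9 * palm_width)
    palm_height = palm_rows.max() - palm_rows.min() + 1
    return float((r1 - r0 + 1 - palm_height) / palm_height)


def _rasterize_mask(params: HandPhantomParams, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    b, a = params.palm_axes
    cr, ccol = params.palm_center
    mask = ((rr - cr) / b) ** 2 + ((cc - ccol) / a) ** 2 <= 1.0
    for length, width, col in zip(
        params.finger_lengths, params.finger_widths, params.finger_cols
    ):
        tip = params.finger_base_row - length
        # distance from each pixel to the vertical segment [tip, base] at col
        r_clamped = np.clip(rr, tip, params.finger_base_row)
        dist2 = (rr - r_clamped) ** 2 + (cc - col) ** 2
        mask |= dist2 <= width**2
    return mask.astype(np.uint8)


def _check_fits(params: HandPhantomParams, shape: tuple[int, int]) -> None:
    rows, cols = shape
    b, a = params.palm_axes
    cr, cc = params.palm_center
    if cr + b >= rows - 0.5:
        raise GeometryError(f"palm bottom row {cr + b:.1f} exceeds frame of {rows} rows (palm_axes)")
    tips = params.finger_base_row - np.asarray(params.finger_lengths) - np.asarray(params.finger_widths)
    if tips.min() < 0.5:
        raise GeometryError(f"finger tip row {tips.min():.1f} above frame top (finger_lengths)")
    lateral = np.asarray(params.finger_cols)
    wmax = max(params.finger_widths)
    if cc - a < 0.5 or cc + a >= cols - 0.5 or lateral.min() - wmax < 0.5 or lateral.max() + wmax >= cols - 0.5:
        raise GeometryError("hand exceeds frame laterally (palm_axes/finger_cols)")


def base_intensity(mask: np.ndarray, maturity: float) -> np.ndarray:
    """Noise-free intensity: bright hand on a dark background.

    Hand intensity increases with maturity (denser ossification), adding a
    photometric age cue on top of the geometric one.
    """
    out = np.full(mask.shape, _BACKGROUND_INTENSITY, dtype=np.float64)
    out[mask > 0] = _HAND_INTENSITY_BASE + _HAND_INTENSITY_SLOPE * maturity
    return out


def render_phantom(
    params: HandPhantomParams, shape: tuple[int, int] = (64, 64)
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a phantom to ``(image, mask)``.

    image = clip(contrast * base + brightness + noise + artifacts, 0, 255);
    artifacts are bright rectangles that never touch the hand's bounding
    box, so the ground-truth mask stays unambiguous. Pure in ``params``:
    noise and artifact placement derive from ``params.render_seed``.
    """
    if shape[0] < 32 or shape[1] < 32:
        raise ConfigurationError(f"shape must be at least 32x32, got {shape}")
    _check_fits(params, shape)
    mask = _rasterize_mask(params, shape)
    img = params.contrast * base_intensity(mask, params.maturity) + params.brightness

    rng = np.random.default_rng(params.render_seed)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=shape)
    else:
        rng.normal(0.0, 1.0, size=shape)  # keep the stream aligned

    if params.artifact_count > 0:
        fg = np.argwhere(mask > 0)
        r0, c0 = fg.min(axis=0)
        r1, c1 = fg.max(axis=0)
        placed = 0
        attempts = 0
        while placed < params.artifact_count and attempts < 50 * params.artifact_count:
            attempts += 1
            h = int(rng.integers(2, 7))
            w = int(rng.integers(2, 7))
            rr = int(rng.integers(0, shape[0] - h))
            cc = int(rng.integers(0, shape[1] - w))
            # reject any overlap with the (slightly padded) hand bounding box
            if rr <= r1 + 1 and rr + h >= r0 - 1 and cc <= c1 + 1 and cc + w >= c0 - 1:
                continue
            img[rr : rr + h, cc : cc + w] = _ARTIFACT_INTENSITY
            placed += 1

    return np.clip(img, 0.0, 255.0).astype(np.float32), mask


def generate_records(
    n: int,
    seed: int,
    config: VariationConfig | None = None,
    shape: tuple[int, int] = (64, 64),
) -> list[PhantomRecord]:
    """Generate ``n`` phantoms in memory, reproducibly from ``seed``."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    config = config or VariationConfig()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        params = sample_phantom_params(rng, config, shape)
        image, mask = render_phantom(params, shape)
        records.append(
            PhantomRecord(
                id=f"ph{i:05d}",
                image=image,
                mask=mask,
                age_months=params.age_months,
                male=params.male,
                params=params,
            )
        )
    return records


def _save_png(path: Path, arr: np.ndarray) -> None:
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path, format="PNG")


def generate_dataset(
    n: int,
    seed: int,
    out_dir: str | Path,
    config: VariationConfig | None = None,
    shape: tuple[int, int] = (64, 64),
) -> DatasetManifest:
    """Write ``n`` phantom image/mask PNG pairs plus a CSV manifest.

    The manifest has header ``id,boneage,male,image,mask`` (boneage in
    months, male in {True, False}), the layout of the RSNA pediatric
    bone-age challenge CSV plus file-path columns. Byte-identical output
    for identical ``(n, seed, config)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[ManifestRow] = []
    for rec in generate_records(n, seed, config, shape):
        img_path = out_dir / f"{rec.id}.png"
        mask_path = out_dir / f"{rec.id}_mask.png"
        _save_png(img_path, np.rint(rec.image))
        _save_png(mask_path, rec.mask * 255)
        rows.append(
            ManifestRow(
                id=rec.id,
                age_months=rec.age_months,
                male=rec.male,
                image_path=img_path.name,
                mask_path=mask_path.name,
            )
        )
    manifest = DatasetManifest(records=tuple(rows), seed=seed)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "boneage", "male", "image", "mask"])
        for row in manifest.records:
            writer.writerow(
                [row.id, row.age_months, row.male, row.image_path, row.mask_path or ""]
            )
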