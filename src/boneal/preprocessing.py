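"""Image normalization, CLAHE, probability-map thresholding and ROI cropping.

The preprocessing chain mirrors a standard radiograph pipeline: per-image
standardization ``(img - mean) / std`` before the segmentation network,
contrast-limited adaptive histogram equalization (CLAHE) to flatten the wide
brightness/contrast spread across archives, binarization of the network's
probability map, and a tight mask-driven crop of the hand region of
interest.
"""

from __future__ import annotations

import dataclasses

import numpy as np


class DegenerateInputError(ValueError):
    """Input is structurally valid but statistically degenerate (e.g. constant)."""


class PreprocessConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class StandardizedImage:
    """Zero-mean, unit-variance pixel array (population moments)."""

    pixels: np.ndarray
    source_id: str = ""


def standardize(image: np.ndarray, source_id: str = "") -> StandardizedImage:
    """Per-image standardization: ``(img - mean(img)) / std(img)``.

    Population standard deviation over all pixels. Raises on a constant
    image rather than dividing by zero.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    std = image.std()
    if std == 0:
        raise DegenerateInputError(f"constant image (std = 0), source_id={source_id!r}")
    return StandardizedImage(pixels=(image - image.mean()) / std, source_id=source_id)


def _tile_mapping(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """Per-tile intensity mapping: clipped-histogram equalization, 256 bins."""
    npix = tile.size
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
    if np.isfinite(clip_limit):
        ceiling = max(clip_limit * npix / 256.0, 1.0)
        excess = np.maximum(hist - ceiling, 0.0).sum()
        hist = np.minimum(hist, ceiling) + excess / 256.0
    cdf = np.cumsum(hist)
    nonzero = np.flatnonzero(hist)
    cdf_min = cdf[nonzero[0]]
    denom = cdf[-1] - cdf_min
    if denom <= 0:  # single occupied bin: identity keeps a flat tile flat
        return np.arange(256, dtype=np.float64)
    return np.rint((cdf - cdf_min) / denom * 255.0)


def apply_clahe(
    image: np.ndarray,
    clip_limit: float = 2.0,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 255] image.

    Each tile's histogram is clipped at ``clip_limit`` times the uniform bin
    height (the excess redistributed evenly), equalized via its CDF, and the
    per-tile mappings are bilinearly interpolated at tile centers. With
    ``tiles=(1, 1)`` and an infinite clip limit this reduces exactly to
    global histogram equalization.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.min() < 0 or img.max() > 255:
        raise PreprocessConfigError("image values must lie in [0, 255]")
    if clip_limit <= 0:
        raise PreprocessConfigError("clip_limit must be > 0")
    tr, tc = tiles
    if tr < 1 or tc < 1:
        raise PreprocessConfigError("tiles must be >= (1, 1)")
    rows, cols = img.shape
    if tr > rows or tc > cols:
        raise PreprocessConfigError(f"tile grid {tiles} larger than image {img.shape}")

    q = np.clip(np.rint(img), 0, 255).astype(np.int64)
    row_edges = np.linspace(0, rows, tr + 1).astype(int)
    col_edges = np.linspace(0, cols, tc + 1).astype(int)
    mappings = np.empty((tr, tc, 256), dtype=np.float64)
    centers_r = np.empty(tr)
    centers_c = np.empty(tc)
    for i in range(tr):
        centers_r[i] = (row_edges[i] + row_edges[i + 1] - 1) / 2.0
        for j in range(tc):
            tile = q[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            mappings[i, j] = _tile_mapping(tile, clip_limit)
    for j in range(tc):
        centers_c[j] = (col_edges[j] + col_edges[j + 1] - 1) / 2.0

    rr = np.arange(rows, dtype=np.float64)[:, None]
    cc = np.arange(cols, dtype=np.float64)[None, :]
    # surrounding tile-center indices and interpolation weights, clamped at borders
    i1 = np.clip(np.searchsorted(centers_r, rr.ravel(), side="right"), 0, tr - 1)
    i0 = np.clip(i1 - 1, 0, tr - 1)
    j1 = np.clip(np.searchsorted(centers_c, cc.ravel(), side="right"), 0, tc - 1)
    j0 = np.clip(j1 - 1, 0, tc - 1)
    with np.errstate(invalid="ignore"):
        wr = np.where(
            i1 == i0, 0.0, (rr.ravel() - centers_r[i0]) / np.where(i1 == i0, 1.0, centers_r[i1] - centers_r[i0])
        )
        wc = np.where(
            j1 == j0, 0.0, (cc.ravel() - centers_c[j0]) / np.where(j1 == j0, 1.0, centers_c[j1] - centers_c[j0])
        )
    wr = np.clip(wr, 0.0, 1.0)[:, None]
    wc = np.clip(wc, 0.0, 1.0)[None, :]

    I0 = i0[:, None]
    I1 = i1[:, None]
    J0 = j0[None, :]
    J1 = j1[None, :]
    out = (
        (1 - wr) * (1 - wc) * mappings[np.broadcast_to(I0, q.shape), np.broadcast_to(J0, q.shape), q]
        + (1 - wr) * wc * mappings[np.broadcast_to(I0, q.shape), np.broadcast_to(J1, q.shape), q]
        + wr * (1 - wc) * mappings[np.broadcast_to(I1, q.shape), np.broadcast_to(J0, q.shape), q]
        + wr * wc * mappings[np.broadcast_to(I1, q.shape), np.broadcast_to(J1, q.shape), q]
    )
    return np.clip(out, 0.0, 255.0)


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a [0, 1] probability map to a {0, 1} mask (>= threshold -> 1)."""
    if not 0.0 <= threshold <= 1.0:
        raise PreprocessConfigError(f"threshold must be in [0, 1], got {threshold}")
    prob_map = np.asarray(prob_map)
    if prob_map.size and (prob_map.min() < 0 or prob_map.max() > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    return (prob_map >= threshold).astype(np.uint8)


def crop_to_mask(image: np.ndarray, mask: np.ndarray, margin: int = 0) -> np.ndarray:
    """Crop to the mask's tight bounding box, expanded by ``margin`` pixels.

    Half-open row/column intervals, clipped to the frame; the crop always
    contains every foreground pixel.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} shapes differ")
    fg = np.argwhere(mask > 0)
    if fg.size == 0:
        raise DegenerateInputError("empty mask: nothing to crop to")
    r0, c0 = fg.min(axis=0)
    r1, c1 = fg.max(axis=0) + 1
    r0 = max(int(r0) - margin, 0)
    c0 = max(int(c0) - margin, 0)
    r1 = min(int(r1) + margin, image.shape[0])
    c1 = min(int(c1) + margin, image.shape[1])
    return image[r0:r1, c0:c1]
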