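"""Grey-level co-occurrence texture analysis.

Images are quantized to a small number of grey levels (default 20), pairwise
co-occurrence is counted at 0/45/90/135 degrees for distances 1..D pixels
(default 50, ~3.3 um at 0.066 um/px) and summarised by four measures:
contrast, correlation, energy and homogeneity.  A dominant-axis correction
rotates the image so the dominant fibre orientation is vertical before
profiling, verified post hoc by requiring the 90-degree correlation to be
maximal at a reference distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ANGLES_DEG",
    "MEASURES",
    "QuantizedImage",
    "CooccurrenceMatrix",
    "HaralickSet",
    "TextureProfile",
    "DegenerateImageError",
    "quantize",
    "cooccurrence",
    "haralick",
    "texture_profile",
    "align_dominant_axis",
]

ANGLES_DEG = (0, 45, 90, 135)
MEASURES = ("contrast", "correlation", "energy", "homogeneity")

#: (row, col) offset per unit distance for each angle; rows increase downward.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class DegenerateImageError(ValueError):
    """Raised when an image has no intensity variation to analyse."""


@dataclass(frozen=True)
class QuantizedImage:
    levels: np.ndarray  # int array with values in [0, L-1]
    L: int
    pixel_size_um: float
    source_range: tuple[float, float]
    degenerate: bool


@dataclass(frozen=True)
class CooccurrenceMatrix:
    counts: np.ndarray  # (L, L) int64
    angle_deg: int
    distance_px: int
    symmetric: bool
    n_pairs: int


@dataclass(frozen=True)
class HaralickSet:
    contrast: float
    correlation: float  # NaN when undefined (zero-variance marginal)
    energy: float
    homogeneity: float
    correlation_defined: bool


@dataclass(frozen=True)
class TextureProfile:
    """Complete (measure, angle, distance) texture grid for one image.

    ``values`` has shape (4 measures, 4 angles, D distances) in the order of
    :data:`MEASURES` and :data:`ANGLES_DEG`, distances 1..D.  Flattening is
    measure-major, then angle, then distance.
    """

    values: np.ndarray
    max_distance_px: int
    pixel_size_um: float
    image_id: str = ""

    def get(self, measure: str, angle_deg: int, distance_px: int) -> float:
        return float(
            self.values[
                MEASURES.index(measure),
                ANGLES_DEG.index(angle_deg),
                distance_px - 1,
            ]
        )

    def flatten(self) -> tuple[np.ndarray, list[str]]:
        names = [
            f"{m}_a{a}_d{d}"
            for m in MEASURES
            for a in ANGLES_DEG
            for d in range(1, self.max_distance_px + 1)
        ]
        return self.values.reshape(-1).copy(), names


def quantize(
    image: np.ndarray, L: int = 20, pixel_size_um: float = 0.066
) -> QuantizedImage:
    """Linearly bin intensities into L grey levels over the per-image range."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected 2-D image, got ndim={image.ndim}")
    bad = np.count_nonzero(~np.isfinite(image))
    if bad:
        raise ValueError(f"image contains {bad} non-finite pixels")
    if L < 2:
        raise ValueError("L must be >= 2")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return QuantizedImage(
            np.zeros(image.shape, dtype=np.int64), L, pixel_size_um, (lo, hi), True
        )
    levels = np.clip(
        np.floor((image - lo) / (hi - lo) * L), 0, L - 1
    ).astype(np.int64)
    return QuantizedImage(levels, L, pixel_size_um, (lo, hi), False)


def cooccurrence(
    q: QuantizedImage, angle_deg: int, distance_px: int, symmetric: bool = True
) -> CooccurrenceMatrix:
    """Count co-occurring level pairs at one (angle, distance) offset.

    Only fully in-bounds pairs are counted; symmetric accumulation counts each
    unordered pair in both orders.
    """
    if distance_px < 1:
        raise ValueError("distance_px must be >= 1")
    if angle_deg not in _OFFSETS:
        raise ValueError(f"angle_deg must be one of {tuple(_OFFSETS)}")
    dr, dc = _OFFSETS[angle_deg]
    dr *= distance_px
    dc *= distance_px
    lv = q.levels
    nr, nc = lv.shape

    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"no in-bounds pairs for distance {distance_px} on shape {lv.shape}"
        )
    src = lv[r0:r1, c0:c1]
    dst = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    idx = src.reshape(-1) * q.L + dst.reshape(-1)
    counts = np.bincount(idx, minlength=q.L * q.L).reshape(q.L, q.L)
    if symmetric:
        counts = counts + counts.T
    counts = counts.astype(np.int64)
    return CooccurrenceMatrix(
        counts, angle_deg, distance_px, symmetric, int(counts.sum())
    )


def haralick(m: CooccurrenceMatrix) -> HaralickSet:
    """Contrast, correlation, energy and homogeneity of a normalised GLCM."""
    if m.n_pairs <= 0:
        raise ValueError("cannot normalise a GLCM with zero pairs")
    p = m.counts / m.n_pairs
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]

    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())

    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    var_i = float(((np.arange(L) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(L) - mu_j) ** 2 * pj).sum())
    denom = np.sqrt(var_i * var_j)
    if denom == 0.0:
        return HaralickSet(contrast, float("nan"), energy, homogeneity, False)
    correlation = float((((i - mu_i) * (j - mu_j) * p).sum()) / denom)
    return HaralickSet(contrast, correlation, energy, homogeneity, True)


def texture_profile(
    image: np.ndarray,
    L: int = 20,
    max_distance_px: int = 50,
    pixel_size_um: float = 0.066,
    image_id: str = "",
) -> TextureProfile:
    """Full 4-measure x 4-angle x D-distance texture grid of one image."""
    if min(image.shape) <= max_distance_px:
        raise ValueError(
            f"image dims {image.shape} must exceed max distance {max_distance_px}"
        )
    q = quantize(image, L=L, pixel_size_um=pixel_size_um)
    if q.degenerate:
        raise DegenerateImageError("constant image has no texture")
    values = np.empty((len(MEASURES), len(ANGLES_DEG), max_distance_px))
    for ai, angle in enumerate(ANGLES_DEG):
        for d in range(1, max_distance_px + 1):
            h = haralick(cooccurrence(q, angle, d))
            values[0, ai, d - 1] = h.contrast
            values[1, ai, d - 1] = h.correlation
            values[2, ai, d - 1] = h.energy
            values[3, ai, d - 1] = h.homogeneity
    return TextureProfile(values, max_distance_px, pixel_size_um, image_id)


def _central_square_crop(image: np.ndarray) -> np.ndarray:
    """Largest axis-aligned central square valid under any rotation."""
    n = min(image.shape)
    side = int(np.floor(n / np.sqrt(2.0)))
    r0 = (image.shape[0] - side) // 2
    c0 = (image.shape[1] - side) // 2
    return image[r0 : r0 + side, c0 : c0 + side]


def align_dominant_axis(
    image: np.ndarray,
    reference_distance_px: int = 4,
    L: int = 20,
    coherence_min: float = 0.2,
) -> tuple[np.ndarray, float, bool]:
    """Rotate the image so the dominant fibre orientation is vertical.

    The dominant orientation is estimated from the global structure tensor;
    the image is rotated by the negated estimate (bilinear interpolation) and
    centre-cropped to remove padding.  The stated postcondition — GLCM
    correlation at 90 degrees at the reference distance at least as large as
    at the other three angles — is verified; on failure, or when global
    coherence is below ``coherence_min``, the anisotropy flag is set and the
    (cropped) unrotated image is returned with rotation 0.

    Returns (rotated image, applied rotation in degrees, anisotropy_flag).
    """
    from .orientation import global_orientation

    theta, coherence = global_orientation(image)
    fallback = _central_square_crop(np.asarray(image, dtype=np.float64))
    if coherence < coherence_min:
        return fallback, 0.0, True

    # scipy's positive rotation angle moves a fibre at +theta to +2*theta in
    # this convention, so rotating by -theta brings the axis back to vertical
    applied = -theta
    rotated = ndimage.rotate(
        np.asarray(image, dtype=np.float64),
        angle=applied,
        reshape=True,
        order=1,
        mode="constant",
        cval=0.0,
    )
    rotated = _central_square_crop(rotated)

    q = quantize(rotated, L=L)
    if q.degenerate:
        return fallback, 0.0, True
    corr = {}
    for angle in ANGLES_DEG:
        corr[angle] = haralick(cooccurrence(q, angle, reference_distance_px))
    c90 = corr[90].correlation
    others = [corr[a].correlation for a in (0, 45, 135)]
    if not corr[90].correlation_defined or any(
        np.isnan(o) for o in others
    ) or not all(c90 >= o for o in others):
        return fallback, 0.0, True
    return rotated, applied, False
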