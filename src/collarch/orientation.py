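"""Structure-tensor fibre orientation analysis.

Angle convention: 0 degrees = vertical (the strain axis), range (-90, 90],
positive angles tilt toward increasing column with increasing row (clockwise
on screen with the origin top-left).  This matches the fibre generator in
:mod:`collarch.simgen`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "OrientationField",
    "OrientationHistogram",
    "AlignmentSummary",
    "structure_tensor_field",
    "global_orientation",
    "orientation_histogram",
    "alignment_percentage",
]


@dataclass(frozen=True)
class OrientationField:
    angle_deg: np.ndarray  # per-pixel, (-90, 90]
    energy: np.ndarray  # J_xx + J_yy >= 0
    coherence: np.ndarray  # in [0, 1], 0 where energy is 0
    sigma_grad: float
    sigma_window: float
    degenerate: bool  # True when the image is constant


@dataclass(frozen=True)
class OrientationHistogram:
    bin_centres_deg: np.ndarray
    bin_width_deg: float
    mass_pct: np.ndarray  # sums to 100
    weighting: str
    coherence_min: float
    n_included: int
    n_excluded: int


@dataclass(frozen=True)
class AlignmentSummary:
    dominant_angle_deg: float
    alignment_pct: float
    halfwidth_deg: float
    tie: bool


def _tensor_components(
    image: np.ndarray, sigma_grad: float, sigma_window: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite pixels")
    # gy: along rows (axis 0), gx: along columns (axis 1)
    gy = gaussian_filter(img, sigma_grad, order=(1, 0))
    gx = gaussian_filter(img, sigma_grad, order=(0, 1))
    jxx = gaussian_filter(gx * gx, sigma_window)
    jxy = gaussian_filter(gx * gy, sigma_window)
    jyy = gaussian_filter(gy * gy, sigma_window)
    return jxx, jxy, jyy


def _angle_from_tensor(jxx: np.ndarray, jxy: np.ndarray, jyy: np.ndarray):
    """Fibre angle from vertical, (-90, 90], given tensor components."""
    # gradient eigenvector angle from column axis; fibre is perpendicular
    alpha = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = -np.rad2deg(alpha)
    theta = ((theta + 90.0) % 180.0) - 90.0
    return np.where(theta == -90.0, 90.0, theta)


def structure_tensor_field(
    image: np.ndarray, sigma_grad: float = 1.0, sigma_window: float = 4.0
) -> OrientationField:
    """Per-pixel orientation, gradient energy and coherence."""
    jxx, jxy, jyy = _tensor_components(image, sigma_grad, sigma_window)
    energy = jxx + jyy
    degenerate = bool(np.all(energy == 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2) / energy
    coherence = np.where(energy > 0.0, coherence, 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)
    angle = _angle_from_tensor(jxx, jxy, jyy)
    return OrientationField(
        angle_deg=angle,
        energy=energy,
        coherence=coherence,
        sigma_grad=sigma_grad,
        sigma_window=sigma_window,
        degenerate=degenerate,
    )


def global_orientation(
    image: np.ndarray, sigma_grad: float = 1.0, sigma_window: float = 4.0
) -> tuple[float, float]:
    """Image-level dominant fibre angle and coherence from the summed tensor."""
    jxx, jxy, jyy = _tensor_components(image, sigma_grad, sigma_window)
    sxx, sxy, syy = jxx.sum(), jxy.sum(), jyy.sum()
    trace = sxx + syy
    if trace == 0.0:
        return 0.0, 0.0
    coherence = float(np.sqrt((sxx - syy) ** 2 + 4.0 * sxy**2) / trace)
    theta = float(_angle_from_tensor(sxx, sxy, syy))
    return theta, min(coherence, 1.0)


def orientation_histogram(
    field: OrientationField,
    bin_width_deg: float = 2.0,
    weighting: str = "energy",
    coherence_min: float = 0.1,
) -> OrientationHistogram:
    """Bin per-pixel orientations into a percentage histogram on (-90, 90]."""
    if weighting not in {"energy", "coherence_energy", "unweighted"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    n_bins = int(round(180.0 / bin_width_deg))
    if abs(n_bins * bin_width_deg - 180.0) > 1e-9 or n_bins < 1:
        raise ValueError("bin width must divide 180 degrees exactly")

    include = field.coherence >= coherence_min
    n_included = int(include.sum())
    n_excluded = int(include.size - n_included)
    if n_included == 0:
        raise ValueError(
            "all pixels excluded at coherence_min="
            f"{coherence_min}; lower the threshold"
        )

    angles = field.angle_deg[include]
    if weighting == "energy":
        w = field.energy[include]
    elif weighting == "coherence_energy":
        w = (field.energy * field.coherence)[include]
    else:
        w = np.ones(n_included)

    # bins tile (-90, 90]: bin k covers (-90 + k*w, -90 + (k+1)*w]
    idx = np.ceil((angles + 90.0) / bin_width_deg).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    mass = np.bincount(idx, weights=w, minlength=n_bins)
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero total weight after thresholding")
    mass_pct = mass / total * 100.0
    centres = -90.0 + (np.arange(n_bins) + 0.5) * bin_width_deg
    return OrientationHistogram(
        bin_centres_deg=centres,
        bin_width_deg=bin_width_deg,
        mass_pct=mass_pct,
        weighting=weighting,
        coherence_min=coherence_min,
        n_included=n_included,
        n_excluded=n_excluded,
    )


def alignment_percentage(
    hist: OrientationHistogram, halfwidth_deg: float = 10.0
) -> AlignmentSummary:
    """Percent of angular mass within +/- halfwidth of the modal bin.

    The window is circular on the 180-degree axial domain.  A multi-modal tie
    picks the first mode in angle order and flags it.
    """
    mass = hist.mass_pct
    mode_idx = int(np.argmax(mass))
    tie = int(np.count_nonzero(mass == mass[mode_idx])) > 1
    n_bins = len(mass)
    k = int(np.floor(halfwidth_deg / hist.bin_width_deg))
    window = (np.arange(-k, k + 1) + mode_idx) % n_bins
    pct = float(mass[np.unique(window)].sum())
    return AlignmentSummary(
        dominant_angle_deg=float(hist.bin_centres_deg[mode_idx]),
        alignment_pct=min(pct, 100.0),
        halfwidth_deg=halfwidth_deg,
        tie=tie,
    )
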