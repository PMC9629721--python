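"""Synthetic binary masks of non-overlapping elliptical fibril cross-sections.

Minor-axis diameters follow a lognormal law parameterised by its median;
placement is dart-throwing with a retry cap and a minimum edge-to-edge gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FibrilFieldParams", "FibrilPlacementError", "gen_fibril_mask"]


class FibrilPlacementError(RuntimeError):
    """Raised when the requested fibril density cannot be achieved."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} fibrils; "
            "reduce n_fibrils or diameters, or enlarge the field"
        )


@dataclass(frozen=True)
class FibrilFieldParams:
    image_size: int = 1024
    pixel_size_nm: float = 1.0
    n_fibrils: int = 300
    diameter_median_nm: float = 36.3
    diameter_log_sd: float = 0.25
    min_gap_px: float = 2.0
    axial_ratio_range: tuple[float, float] = (1.0, 1.6)
    seed: int = 0
    max_tries_per_fibril: int = 200

    def validate(self) -> None:
        if self.diameter_median_nm <= 0:
            raise ValueError("diameter_median_nm must be > 0")
        if self.min_gap_px < 0:
            raise ValueError("min_gap_px must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        lo, hi = self.axial_ratio_range
        if lo < 1.0 or hi < lo:
            raise ValueError("axial_ratio_range must satisfy 1 <= lo <= hi")
        if self.diameter_log_sd < 0:
            raise ValueError("diameter_log_sd must be >= 0")
        if self.n_fibrils < 1 or self.image_size < 16:
            raise ValueError("n_fibrils >= 1 and image_size >= 16 required")


def _render_ellipse(
    mask: np.ndarray, cr: float, cc: float, a_px: float, b_px: float, phi: float
) -> None:
    """Set pixels whose centres fall inside the ellipse (semi-axes a >= b)."""
    n = mask.shape[0]
    r0 = max(int(np.floor(cr - a_px - 1)), 0)
    r1 = min(int(np.ceil(cr + a_px + 1)), n - 1)
    c0 = max(int(np.floor(cc - a_px - 1)), 0)
    c1 = min(int(np.ceil(cc + a_px + 1)), n - 1)
    rr, cc_ = np.meshgrid(
        np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
    )
    dr = rr - cr
    dc = cc_ - cc
    # rotate into ellipse frame
    x = dr * np.cos(phi) + dc * np.sin(phi)
    y = -dr * np.sin(phi) + dc * np.cos(phi)
    inside = (x / a_px) ** 2 + (y / b_px) ** 2 <= 1.0
    mask[r0 : r1 + 1, c0 : c1 + 1][inside] = True


def gen_fibril_mask(
    params: FibrilFieldParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a binary fibril mask.

    Returns
    -------
    mask : (N, N) bool array
    minor_diameters_nm : (n_fibrils,) float array, one entry per rendered
        fibril in placement order.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.image_size
    mask = np.zeros((n, n), dtype=bool)

    placed: list[tuple[float, float, float]] = []  # (cr, cc, bounding radius)
    minors: list[float] = []
    lo, hi = params.axial_ratio_range

    for _ in range(params.n_fibrils):
        ok = False
        for _try in range(params.max_tries_per_fibril):
            minor_nm = params.diameter_median_nm * np.exp(
                rng.normal(0.0, params.diameter_log_sd)
            )
            ratio = rng.uniform(lo, hi)
            b_px = minor_nm / params.pixel_size_nm / 2.0  # semi-minor
            a_px = b_px * ratio  # semi-major
            phi = rng.uniform(0.0, np.pi)
            margin = a_px + 2.0  # keep clear of the border
            if 2 * margin >= n:
                continue
            cr = rng.uniform(margin, n - margin)
            cc = rng.uniform(margin, n - margin)
            radius = a_px
            conflict = any(
                np.hypot(cr - pr, cc - pc) < radius + prad + params.min_gap_px + 1.0
                for pr, pc, prad in placed
            )
            if conflict:
                continue
            _render_ellipse(mask, cr, cc, a_px, b_px, phi)
            placed.append((cr, cc, radius))
            minors.append(float(minor_nm))
            ok = True
            break
        if not ok:
            raise FibrilPlacementError(params.n_fibrils, len(placed))

    return mask, np.asarray(minors)
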