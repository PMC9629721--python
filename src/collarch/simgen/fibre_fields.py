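"""Synthetic images of wavy, preferentially oriented fibres.

Fibres are rendered as sinusoidally undulating centre-lines with a Gaussian
cross-profile on a square canvas.  Centre-line base angles are drawn from an
axial von Mises distribution on orientation space (-90, 90] degrees, where
0 degrees is the vertical (strain) axis and positive angles tilt clockwise
(toward increasing column with increasing row).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "FibreFieldParams",
    "FibreFieldTruth",
    "GroupRecipe",
    "default_group_recipes",
    "gen_fibre_image",
    "gen_group_dataset",
    "sample_axial_von_mises",
]


@dataclass(frozen=True)
class FibreFieldParams:
    """Parameters of one synthetic fibre-field image."""

    image_size: int = 512
    pixel_size_um: float = 0.066
    n_fibres: int = 120
    mean_angle_deg: float = 0.0
    kappa: float = 4.0
    undulation_amplitude_px: float = 3.0
    undulation_wavelength_px: float = 80.0
    fibre_width_px: float = 2.0
    intensity_peak: float = 20000.0
    noise_sd: float = 300.0
    blur_sigma_px: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        numeric = {
            k: v for k, v in asdict(self).items() if isinstance(v, (int, float))
        }
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite parameter {name!r}: {value}")
        if self.image_size < 64:
            raise ValueError(f"image_size must be >= 64, got {self.image_size}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if self.undulation_wavelength_px <= 0:
            raise ValueError("undulation_wavelength_px must be > 0")
        if not (-90.0 < self.mean_angle_deg <= 90.0):
            raise ValueError(
                f"mean_angle_deg must lie in (-90, 90], got {self.mean_angle_deg}"
            )
        if self.n_fibres < 1:
            raise ValueError("n_fibres must be >= 1")
        if self.fibre_width_px <= 0:
            raise ValueError("fibre_width_px must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.noise_sd < 0 or self.blur_sigma_px < 0 or self.intensity_peak <= 0:
            raise ValueError("noise_sd/blur_sigma_px must be >= 0, intensity_peak > 0")


@dataclass(frozen=True)
class FibreFieldTruth:
    """Ground truth attached to a generated fibre field."""

    angles_deg: tuple[float, ...]
    mean_angle_deg: float
    kappa: float
    seed: int


@dataclass(frozen=True)
class GroupRecipe:
    label: str
    params: FibreFieldParams
    n_images: int = 8

    def validate(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        self.params.validate()


def sample_axial_von_mises(
    rng: np.random.Generator, mean_angle_deg: float, kappa: float, n: int
) -> np.ndarray:
    """Sample axial orientations in degrees on (-90, 90].

    Standard axial construction: draw phi ~ von Mises(2*mu, kappa) on the
    circle and halve.  kappa = 0 means uniform orientations.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        angles = rng.uniform(-90.0, 90.0, size=n)
    else:
        phi = rng.vonmises(np.deg2rad(2.0 * mean_angle_deg), kappa, size=n)
        angles = np.rad2deg(phi) / 2.0
    # map to (-90, 90]
    angles = ((angles + 90.0) % 180.0) - 90.0
    angles[angles == -90.0] = 90.0
    return angles


def gen_fibre_image(
    params: FibreFieldParams,
) -> tuple[np.ndarray, FibreFieldTruth]:
    """Render one fibre field; returns (uint16 image, truth record)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.image_size

    angles = sample_axial_von_mises(
        rng, params.mean_angle_deg, params.kappa, params.n_fibres
    )

    canvas = np.zeros((n, n), dtype=np.float64)
    # long enough to cross the canvas at any angle
    half_len = n * np.sqrt(2.0)
    t = np.arange(-half_len, half_len, 0.5)

    for theta in angles:
        th = np.deg2rad(theta)
        u = np.array([np.cos(th), np.sin(th)])  # (row, col) direction
        normal = np.array([-u[1], u[0]])
        centre = rng.uniform(0.0, n, size=2)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        offset = params.undulation_amplitude_px * np.sin(
            2.0 * np.pi * t / params.undulation_wavelength_px + phase
        )
        rows = centre[0] + t * u[0] + offset * normal[0]
        cols = centre[1] + t * u[1] + offset * normal[1]
        ri = np.rint(rows).astype(np.intp)
        ci = np.rint(cols).astype(np.intp)
        keep = (ri >= 0) & (ri < n) & (ci >= 0) & (ci < n)
        np.add.at(canvas, (ri[keep], ci[keep]), 1.0)

    # Gaussian cross-profile; overlapping fibres add.
    canvas = gaussian_filter(canvas, params.fibre_width_px)
    peak = canvas.max()
    if peak > 0:
        canvas *= params.intensity_peak / peak
    if params.noise_sd > 0:
        canvas += rng.normal(0.0, params.noise_sd, size=canvas.shape)
    if params.blur_sigma_px > 0:
        canvas = gaussian_filter(canvas, params.blur_sigma_px)
    image = np.clip(canvas, 0, np.iinfo(np.uint16).max).astype(np.uint16)

    truth = FibreFieldTruth(
        angles_deg=tuple(float(a) for a in angles),
        mean_angle_deg=params.mean_angle_deg,
        kappa=params.kappa,
        seed=params.seed,
    )
    return image, truth


def gen_group_dataset(
    recipes: list[GroupRecipe], master_seed: int
) -> tuple[list[np.ndarray], list[str], list[FibreFieldTruth]]:
    """Generate a labelled multi-group image set.

    Per-image seeds are spawned deterministically from ``master_seed``; recipe
    seeds are ignored in favour of the spawned ones so the whole dataset is a
    function of (recipes, master_seed).
    """
    if len(recipes) < 2:
        raise ValueError("need at least 2 group recipes")
    labels_seen = [r.label for r in recipes]
    if len(set(labels_seen)) != len(labels_seen):
        raise ValueError(f"duplicate group labels: {labels_seen}")
    for r in recipes:
        r.validate()

    n_total = sum(r.n_images for r in recipes)
    seed_seq = np.random.SeedSequence(master_seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in seed_seq.spawn(n_total)]

    images: list[np.ndarray] = []
    labels: list[str] = []
    truths: list[FibreFieldTruth] = []
    i = 0
    for recipe in recipes:
        for _ in range(recipe.n_images):
            p = FibreFieldParams(**{**asdict(recipe.params), "seed": child_seeds[i]})
            img, truth = gen_fibre_image(p)
            images.append(img)
            labels.append(recipe.label)
            truths.append(truth)
            i += 1
    return images, labels, truths


def default_group_recipes(n_images: int = 8) -> list[GroupRecipe]:
    """Four well-separated groups: a static control plus three strained ones.

    kappa increases strictly with the nominal strain level so orientation
    analyses see a monotone alignment ordering.  The control is sparse and
    strongly undulating (disordered, wavy fibres) while the strained groups
    are denser and straighter but each extreme in a different texture knob
    (thick fibres / thin dense fibres / near-straight fibres): class centroids
    then span multiple feature directions, which a 3-component discriminant
    model can resolve, and the control separates from the rest along the
    first component.
    """

    def p(kappa, width, amp, wavelength, n_fibres):
        return FibreFieldParams(
            kappa=kappa,
            fibre_width_px=width,
            undulation_amplitude_px=amp,
            undulation_wavelength_px=wavelength,
            n_fibres=n_fibres,
        )

    return [
        GroupRecipe("control", p(0.5, 2.0, 7.0, 40.0, 50), n_images),
        GroupRecipe("3pct", p(6.0, 4.5, 1.5, 100.0, 120), n_images),
        GroupRecipe("5pct", p(10.0, 1.3, 1.5, 100.0, 150), n_images),
        GroupRecipe("10pct", p(30.0, 2.5, 0.3, 150.0, 130), n_images),
    ]
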