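"""Tensile and viscoelastic metrics from load traces.

Engineering definitions throughout: stress = F / A with the pre-load
cross-sectional area, strain = dl / l0.  The cross-section is assumed
circular (A = pi d^2 / 4); only a single projected diameter is measured.
Units: forces in N, lengths in mm, stresses in kPa (N / mm^2 * 1000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TendonGeometry",
    "StressStrainCurve",
    "MechanicalSummary",
    "area_from_diameter",
    "to_stress_strain",
    "failure_metrics",
    "youngs_modulus",
    "hysteresis_metrics",
    "stress_relaxation_rate",
    "summarise",
]


def area_from_diameter(d_mm: float) -> float:
    """Circular cross-sectional area in mm^2."""
    if not np.isfinite(d_mm) or d_mm <= 0:
        raise ValueError(f"diameter must be finite and > 0, got {d_mm}")
    return float(np.pi * d_mm**2 / 4.0)


@dataclass(frozen=True)
class TendonGeometry:
    l0_mm: float = 8.0
    diameter_mm: float = 2.43

    def __post_init__(self):
        if self.l0_mm <= 0 or self.diameter_mm <= 0:
            raise ValueError("l0_mm and diameter_mm must be > 0")

    @property
    def area_mm2(self) -> float:
        return area_from_diameter(self.diameter_mm)


@dataclass(frozen=True)
class StressStrainCurve:
    strain: np.ndarray
    stress_kpa: np.ndarray
    phase: np.ndarray
    time_s: np.ndarray | None = None

    def __post_init__(self):
        if not (len(self.strain) == len(self.stress_kpa) == len(self.phase)):
            raise ValueError("strain/stress/phase lengths differ")

    def in_phase(self, name: str) -> "StressStrainCurve":
        sel = self.phase == name
        return StressStrainCurve(
            self.strain[sel],
            self.stress_kpa[sel],
            self.phase[sel],
            None if self.time_s is None else self.time_s[sel],
        )


@dataclass(frozen=True)
class MechanicalSummary:
    sigma_max_kpa: float
    eps_max: float
    youngs_modulus_kpa: float | None
    modulus_region: tuple[int, int] | None
    modulus_r2: float | None
    hysteresis_kj_m3: float | None
    energy_loss_pct: float | None
    relaxation_rate_kpa_s: float | None
    sigma0_kpa: float | None
    sigmaT_kpa: float | None
    relax_T_s: float


def to_stress_strain(trace: pd.DataFrame, geom: TendonGeometry) -> StressStrainCurve:
    """Pointwise sigma = F/A (kPa) and eps = dl/l0 from a load trace.

    ``trace`` needs columns time_s, force_N, displacement_mm, phase.
    """
    required = {"time_s", "force_N", "displacement_mm", "phase"}
    missing = required - set(trace.columns)
    if missing:
        raise ValueError(f"trace missing columns: {sorted(missing)}")
    t = np.asarray(trace["time_s"], dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("time must be monotone non-decreasing")
    stress = np.asarray(trace["force_N"], dtype=float) / geom.area_mm2 * 1e3
    strain = np.asarray(trace["displacement_mm"], dtype=float) / geom.l0_mm
    return StressStrainCurve(
        strain, stress, np.asarray(trace["phase"], dtype=object), t
    )


def failure_metrics(
    curve: StressStrainCurve, rupture_index: int | None = None
) -> tuple[float, float]:
    """(sigma_max, eps_max); eps_max taken at the global stress peak unless a
    rupture index is supplied."""
    if len(curve.stress_kpa) < 2:
        raise ValueError("need at least 2 points")
    i = int(np.argmax(curve.stress_kpa)) if rupture_index is None else rupture_index
    return float(curve.stress_kpa.max()), float(curve.strain[i])


def youngs_modulus(
    curve: StressStrainCurve, window_fraction: float = 0.2
) -> tuple[float, tuple[int, int], float]:
    """Slope of the best (max R^2) contiguous loading-phase OLS window.

    Returns (E in kPa, (start, stop) index bounds into the loading phase,
    R^2).  Ties in R^2 prefer the steeper window, then the earlier one.
    """
    loading = curve.in_phase("loading")
    n = len(loading.strain)
    if n < 10:
        raise ValueError(f"need >= 10 loading-phase points, got {n}")
    w = max(int(round(window_fraction * n)), 3)
    eps, sig = loading.strain, loading.stress_kpa

    best = None
    for start in range(0, n - w + 1):
        x = eps[start : start + w]
        y = sig[start : start + w]
        vx = x.var()
        if vx == 0:
            continue
        slope = np.cov(x, y, bias=True)[0, 1] / vx
        resid = y - (y.mean() + slope * (x - x.mean()))
        vy = y.var()
        r2 = 1.0 - resid.var() / vy if vy > 0 else 0.0
        key = (r2, abs(slope), -start)
        if best is None or key > best[0]:
            best = (key, slope, (start, start + w), r2)
    if best is None:
        raise ValueError("no loading window with non-zero strain variance")
    _, slope, region, r2 = best
    return float(slope), region, float(r2)


def hysteresis_metrics(curve: StressStrainCurve) -> tuple[float, float]:
    """(hysteresis, % energy loss) between loading and unloading curves.

    Areas under sigma(eps) by trapezoid over each phase's own samples;
    hysteresis = loading area - unloading area (kPa * strain == kJ/m^3).
    """
    loading = curve.in_phase("loading")
    unloading = curve.in_phase("unloading")
    if len(loading.strain) < 2 or len(unloading.strain) < 2:
        raise ValueError("need loading and unloading phases with >= 2 points")
    area_load = abs(float(np.trapezoid(loading.stress_kpa, loading.strain)))
    area_unload = abs(float(np.trapezoid(unloading.stress_kpa, unloading.strain)))
    if area_load == 0:
        raise ValueError("zero area under the loading curve")
    hyst = area_load - area_unload
    return hyst, hyst / area_load * 100.0


def stress_relaxation_rate(
    curve: StressStrainCurve, T_s: float = 60.0
) -> tuple[float, float, float]:
    """((sigma_0 - sigma_T) / T, sigma_0, sigma_T) over the hold phase.

    sigma_0 is the first hold-phase sample; sigma_T is linearly interpolated
    at T seconds after hold start.
    """
    hold = curve.in_phase("hold")
    if hold.time_s is None or len(hold.time_s) < 2:
        raise ValueError("hold phase with timestamps required")
    t = hold.time_s - hold.time_s[0]
    if t[-1] < T_s:
        raise ValueError(
            f"hold phase spans only {t[-1]:.3f} s; {T_s} s required"
        )
    sigma0 = float(hold.stress_kpa[0])
    sigmaT = float(np.interp(T_s, t, hold.stress_kpa))
    return (sigma0 - sigmaT) / T_s, sigma0, sigmaT


def summarise(
    trace: pd.DataFrame,
    geom: TendonGeometry,
    relax_T_s: float = 60.0,
    window_fraction: float = 0.2,
    rupture_index: int | None = None,
) -> MechanicalSummary:
    """All metrics computable from one trace; phases absent -> None fields."""
    curve = to_stress_strain(trace, geom)
    sigma_max, eps_max = failure_metrics(curve, rupture_index)

    E = region = r2 = None
    if int(np.sum(curve.phase == "loading")) >= 10:
        E, region, r2 = youngs_modulus(curve, window_fraction)

    hyst = loss = None
    if "unloading" in curve.phase:
        hyst, loss = hysteresis_metrics(curve)

    rate = s0 = sT = None
    if "hold" in curve.phase:
        hold = curve.in_phase("hold")
        span = hold.time_s[-1] - hold.time_s[0] if hold.time_s is not None else 0
        if span >= relax_T_s:
            rate, s0, sT = stress_relaxation_rate(curve, relax_T_s)

    return MechanicalSummary(
        sigma_max_kpa=sigma_max,
        eps_max=eps_max,
        youngs_modulus_kpa=E,
        modulus_region=region,
        modulus_r2=r2,
        hysteresis_kj_m3=hyst,
        energy_loss_pct=loss,
        relaxation_rate_kpa_s=rate,
        sigma0_kpa=s0,
        sigmaT_kpa=sT,
        relax_T_s=relax_T_s,
    )
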