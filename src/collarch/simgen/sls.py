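"""Standard-linear-solid (SLS) load-trace synthesis.

The SLS is a spring (equilibrium modulus ``E_eq``) in parallel with a Maxwell
arm (spring ``E_m`` in series with a dashpot ``eta``), the minimal model
showing both stress relaxation and hysteresis.  Two protocols are generated:

``ramp_hold``
    Linear strain ramp to ``hold_strain`` followed by a constant-strain hold.
    During the hold the stress follows the step closed form
    ``sigma(t) = eps0 * (E_eq + E_m * exp(-t/tau))`` with ``t`` measured from
    the start of the hold, and the attached expected relaxation rate over a
    window ``T`` is ``eps0 * E_m * (1 - exp(-T/tau)) / T``.

``triangle``
    Symmetric load/unload strain triangle at ``ramp_rate``; the Maxwell-arm
    stress is integrated exactly for piecewise-linear strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SLSParams", "SLSTrace", "gen_sls_trace"]


@dataclass(frozen=True)
class SLSParams:
    E_eq: float = 50.0  # kPa
    E_m: float = 30.0  # kPa
    eta: float = 600.0  # kPa*s; tau = eta / E_m
    protocol: str = "ramp_hold"  # or "triangle"
    ramp_rate: float = 0.05  # strain / s
    hold_strain: float = 0.1
    hold_duration_s: float = 90.0
    sample_rate_hz: float = 100.0
    l0_mm: float = 8.0
    diameter_mm: float = 2.43

    @property
    def tau(self) -> float:
        return self.eta / self.E_m

    @property
    def area_mm2(self) -> float:
        return np.pi * self.diameter_mm**2 / 4.0

    def validate(self) -> None:
        if min(self.E_eq, self.E_m, self.eta, self.ramp_rate) <= 0:
            raise ValueError("E_eq, E_m, eta and ramp_rate must all be > 0")
        if self.protocol not in {"ramp_hold", "triangle"}:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.hold_strain <= 0 or self.hold_duration_s <= 0:
            raise ValueError("hold_strain and hold_duration_s must be > 0")
        if self.sample_rate_hz <= 0 or self.l0_mm <= 0 or self.diameter_mm <= 0:
            raise ValueError("sample_rate_hz, l0_mm, diameter_mm must be > 0")


@dataclass(frozen=True)
class SLSTrace:
    """A synthesised load trace plus its closed-form expectations."""

    time_s: np.ndarray
    stress_kpa: np.ndarray
    strain: np.ndarray
    force_n: np.ndarray
    displacement_mm: np.ndarray
    phase: np.ndarray  # 'loading' | 'unloading' | 'hold'
    params: SLSParams
    expected_relaxation_rate_kpa_s: float | None
    undersampled: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "force_N": self.force_n,
                "displacement_mm": self.displacement_mm,
                "phase": self.phase,
            }
        )


def _maxwell_stress_piecewise_linear(
    t: np.ndarray, strain: np.ndarray, E_m: float, tau: float
) -> np.ndarray:
    """Exact Maxwell-arm stress for piecewise-linear strain between samples."""
    sigma_m = np.zeros_like(t)
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        rate = (strain[i] - strain[i - 1]) / dt if dt > 0 else 0.0
        decay = np.exp(-dt / tau)
        sigma_m[i] = sigma_m[i - 1] * decay + E_m * rate * tau * (1.0 - decay)
    return sigma_m


def gen_sls_trace(params: SLSParams, relax_window_s: float = 60.0) -> SLSTrace:
    params.validate()
    tau = params.tau
    dt = 1.0 / params.sample_rate_hz
    eps0 = params.hold_strain

    if params.protocol == "ramp_hold":
        t_ramp = eps0 / params.ramp_rate
        t_end = t_ramp + params.hold_duration_s
        t = np.arange(0.0, t_end + dt / 2, dt)
        strain = np.minimum(t * params.ramp_rate, eps0)
        in_hold = t >= t_ramp
        stress = np.empty_like(t)
        # exact SLS ramp response
        tr = t[~in_hold]
        stress[~in_hold] = params.E_eq * params.ramp_rate * tr + (
            params.E_m * params.ramp_rate * tau * (1.0 - np.exp(-tr / tau))
        )
        # hold phase: step closed form, t measured from hold start
        th = t[in_hold] - t_ramp
        stress[in_hold] = eps0 * (params.E_eq + params.E_m * np.exp(-th / tau))
        phase = np.where(in_hold, "hold", "loading")
        expected_rate = (
            eps0
            * params.E_m
            * (1.0 - np.exp(-relax_window_s / tau))
            / relax_window_s
        )
    else:  # triangle
        t_peak = eps0 / params.ramp_rate
        t = np.arange(0.0, 2 * t_peak + dt / 2, dt)
        strain = np.where(
            t <= t_peak, t * params.ramp_rate, (2 * t_peak - t) * params.ramp_rate
        )
        strain = np.clip(strain, 0.0, None)
        stress = params.E_eq * strain + _maxwell_stress_piecewise_linear(
            t, strain, params.E_m, tau
        )
        phase = np.where(t <= t_peak, "loading", "unloading")
        expected_rate = None

    force_n = stress * params.area_mm2 * 1e-3  # kPa * mm^2 -> N
    displacement = strain * params.l0_mm
    undersampled = params.sample_rate_hz * tau < 10.0

    return SLSTrace(
        time_s=t,
        stress_kpa=stress,
        strain=strain,
        force_n=force_n,
        displacement_mm=displacement,
        phase=phase.astype(object),
        params=params,
        expected_relaxation_rate_kpa_s=expected_rate,
        undersampled=undersampled,
    )
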