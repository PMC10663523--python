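"""Rotational correlation times: TRACT inversion, hydrodynamics, rescaling.

TRACT measures the difference between the relaxation rates of the two
15N doublet components (TROSY-selected R_alpha, anti-TROSY R_beta); the
difference is twice the 1H-15N dipole / 15N-CSA transverse cross-correlated
rate eta_xy, which for a rigid isotropic rotor depends on tau_c through

    eta_xy = p * d * (3 cos^2 theta - 1) * (4 J(0) + 3 J(omega_N)),
    J(w) = (2/5) tau_c / (1 + w^2 tau_c^2),

with p the dipolar and d the CSA interaction constant.  eta_xy is strictly
increasing in tau_c, so Delta_R = 2 eta_xy inverts by bracketing root-find.

The Stokes-Einstein-Debye route estimates tau_c from molecular weight via
an effective hydrated radius; rescaling moves a tau_c between temperatures
with tau ~ eta(T)/T using embedded light-/heavy-water viscosity tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import constants as c

__all__ = [
    "CorrelationTime",
    "TractDecayPair",
    "SpinParams",
    "fit_tract_rates",
    "rates_to_tauc",
    "tauc_to_delta_r",
    "sed_tauc",
    "rescale_tauc",
    "viscosity_mPas",
]


class RotationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationTime:
    tau_c_ns: float
    temperature_k: float
    viscosity_mpas: float | None = None
    provenance: str = "tract"  # tract | hydrodynamic | rescaled

    def __post_init__(self) -> None:
        if self.tau_c_ns <= 0:
            raise RotationError("tau_c must be positive")


@dataclass(frozen=True)
class SpinParams:
    """Spin-interaction constants for the TRACT relation (conventional defaults)."""

    proton_frequency_mhz: float = 850.0
    r_nh_angstrom: float = 1.02
    csa_n_ppm: float = 160.0
    csa_dipole_angle_deg: float = 17.0

    def __post_init__(self) -> None:
        for name in ("proton_frequency_mhz", "r_nh_angstrom", "csa_n_ppm"):
            if getattr(self, name) <= 0:
                raise RotationError(f"{name} must be positive")

    @property
    def b0_tesla(self) -> float:
        return 2 * math.pi * self.proton_frequency_mhz * 1e6 / c.GAMMA_H

    @property
    def omega_n(self) -> float:
        return abs(c.GAMMA_N) * self.b0_tesla

    @property
    def dipolar_p(self) -> float:
        r = self.r_nh_angstrom * c.M_PER_ANGSTROM
        return c.MU0_OVER_4PI * c.GAMMA_H * abs(c.GAMMA_N) * c.HBAR / (2 * math.sqrt(2) * r**3)

    @property
    def csa_d(self) -> float:
        return abs(c.GAMMA_N) * self.b0_tesla * self.csa_n_ppm * 1e-6 / (3 * math.sqrt(2))


def _eta_xy(tau_c_s: float, sp: SpinParams) -> float:
    def j(w: float) -> float:
        return 0.4 * tau_c_s / (1.0 + (w * tau_c_s) ** 2)

    p2 = 0.5 * (3 * math.cos(math.radians(sp.csa_dipole_angle_deg)) ** 2 - 1)
    return sp.dipolar_p * sp.csa_d * 2 * p2 * (4 * j(0.0) + 3 * j(sp.omega_n))


def tauc_to_delta_r(tau_c_ns: float, sp: SpinParams = SpinParams()) -> float:
    """Forward model: Delta_R = R_beta - R_alpha = 2 eta_xy(tau_c), s^-1."""
    if tau_c_ns <= 0:
        raise RotationError("tau_c must be positive")
    return 2.0 * _eta_xy(tau_c_ns * 1e-9, sp)


@dataclass
class TractDecayPair:
    """TROSY / anti-TROSY decay curves sharing a delay schedule."""

    delays_s: np.ndarray
    trosy: np.ndarray
    anti_trosy: np.ndarray

    def __post_init__(self) -> None:
        self.delays_s = np.asarray(self.delays_s, float)
        self.trosy = np.asarray(self.trosy, float)
        self.anti_trosy = np.asarray(self.anti_trosy, float)
        if len(self.delays_s) < 5:
            raise RotationError("need >= 5 delays")
        if len(self.trosy) != len(self.delays_s) or len(self.anti_trosy) != len(self.delays_s):
            raise RotationError("mismatched decay lengths")


def _fit_mono_exp(t: np.ndarray, y: np.ndarray) -> float:
    def model(t, i0, r):
        return i0 * np.exp(-r * t)

    span = t[-1] - t[0]
    r0 = max(1.0 / span, 1.0)
    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=[y[0], r0], maxfev=20000)
    except RuntimeError as exc:
        raise RotationError(f"exponential fit did not converge: {exc}") from None
    return float(popt[1])


def fit_tract_rates(pair: TractDecayPair) -> tuple[float, float]:
    """Independent mono-exponential fits -> (R_alpha, R_beta), s^-1."""
    r_alpha = _fit_mono_exp(pair.delays_s, pair.trosy)
    r_beta = _fit_mono_exp(pair.delays_s, pair.anti_trosy)
    return r_alpha, r_beta


def rates_to_tauc(
    delta_r: float, sp: SpinParams = SpinParams(), temperature_k: float = 298.15
) -> CorrelationTime:
    """Invert Delta_R = 2 eta_xy(tau_c) for tau_c by monotone bracketing."""
    if delta_r <= 0:
        raise RotationError("delta_R must be positive")
    lo, hi = 1e-16, 1e-5  # 0.1 fs .. 10 us
    f = lambda tau: 2.0 * _eta_xy(tau, sp) - delta_r
    if f(hi) < 0:
        raise RotationError("delta_R outside the invertible range")
    tau = optimize.brentq(f, lo, hi, xtol=1e-16, rtol=1e-12)
    return CorrelationTime(tau_c_ns=tau * 1e9, temperature_k=temperature_k, provenance="tract")


def sed_tauc(
    mw_kda: float,
    v_bar_cm3_g: float = 0.73,
    hydration_shell_angstrom: float = 3.2,
    temperature_k: float = 298.15,
    viscosity_mpas: float = 0.89,
) -> CorrelationTime:
    """Stokes-Einstein-Debye tau_c for a globular protein of given mass.

    r = (3 M v_bar / (4 pi N_A))^(1/3) + hydration shell;
    tau_c = 4 pi eta r^3 / (3 k_B T).
    """
    for name, val in (
        ("mw_kda", mw_kda),
        ("v_bar", v_bar_cm3_g),
        ("temperature", temperature_k),
        ("viscosity", viscosity_mpas),
    ):
        if val <= 0:
            raise RotationError(f"{name} must be positive")
    vol_cm3 = mw_kda * 1e3 * v_bar_cm3_g / c.N_AVOGADRO
    r_cm = (3.0 * vol_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_m = r_cm * 1e-2 + hydration_shell_angstrom * c.M_PER_ANGSTROM
    eta = viscosity_mpas * 1e-3  # Pa s
    tau = 4.0 * math.pi * eta * r_m**3 / (3.0 * c.KB_SI * temperature_k)
    return CorrelationTime(
        tau_c_ns=tau * 1e9,
        temperature_k=temperature_k,
        viscosity_mpas=viscosity_mpas,
        provenance="hydrodynamic",
    )


# ---------------------------------------------------------------------------
# solvent viscosities

_T_C = np.arange(0.0, 101.0)


def _eta_h2o(t_c: np.ndarray) -> np.ndarray:
    # Kestin-type correlation anchored at eta(20 C) = 1.0016 mPa s
    dt = 20.0 - t_c
    expo = dt * (1.2364 - 1.37e-3 * dt + 5.7e-6 * dt**2) / (t_c + 96.0)
    return 1.0016 * 10.0**expo


# smooth literature-anchored D2O/H2O viscosity ratio (1.23 at 25 C, falling with T)
_RATIO_T = np.array([0.0, 10.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0])
_RATIO_V = np.array([1.305, 1.268, 1.244, 1.230, 1.218, 1.197, 1.180, 1.166, 1.143, 1.124])

_TABLES = {
    "water": _eta_h2o(_T_C),
    "heavy_water": _eta_h2o(_T_C) * np.interp(_T_C, _RATIO_T, _RATIO_V),
}


def viscosity_mPas(temperature_k: float, solvent: str = "water") -> float:
    """Solvent viscosity from the embedded 1-degree tables (273-373 K)."""
    t_c = temperature_k - 273.15
    if not 0.0 <= t_c <= 100.0:
        raise RotationError(f"temperature {temperature_k} K outside the table range")
    if solvent not in _TABLES:
        raise RotationError(f"unknown solvent {solvent!r}")
    return float(np.interp(t_c, _T_C, _TABLES[solvent]))


def rescale_tauc(
    tc: CorrelationTime,
    t_from_k: float,
    t_to_k: float,
    viscosity_model: str | tuple[float, float] = "water",
) -> CorrelationTime:
    """Move tau_c between temperatures: tau(T2) = tau(T1) (eta2/eta1) (T1/T2).

    ``viscosity_model`` is a solvent table name or an explicit
    (eta_from, eta_to) pair in mPa s.
    """
    if isinstance(viscosity_model, str):
        eta_from = viscosity_mPas(t_from_k, viscosity_model)
        eta_to = viscosity_mPas(t_to_k, viscosity_model)
    else:
        eta_from, eta_to = viscosity_model
    tau = tc.tau_c_ns * (eta_to / eta_from) * (t_from_k / t_to_k)
    return CorrelationTime(
        tau_c_ns=tau, temperature_k=t_to_k, viscosity_mpas=eta_to, provenance="rescaled"
    )
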