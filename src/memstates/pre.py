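"""Back-calculation of membrane PREs for conformers above a spin-labelled bilayer.

The nitroxide labels (e.g. 5-doxyl PC) diffuse laterally, so a reporter at
height z above the phosphate plane sees a uniform planar distribution of
unpaired electrons at depth d below it.  Integrating the Solomon-Bloembergen
r^-6 dipolar term over that plane gives a closed form in the reporter-plane
separation Delta = z + d:

    Gamma_2 = K_SB * sigma * pi / (2 * Delta^4)

with K_SB the dipolar prefactor times the spectral-density combination
4 J(0) + 3 J(omega_H), J(omega) = tau / (1 + omega^2 tau^2).  A trans-leaflet
label layer adds the same term at Delta' = z + s - d (s = phosphate-plane
separation).  ``gamma2_discrete`` is the brute-force lattice-sum oracle for
the same quantity and exists to validate the closed form.

Intensity ratios follow the standard two-time-scale PRE observable

    I/I0 = R2_dia * exp(-Gamma_2 * t) / (R2_dia + Gamma_2)

(line broadening during acquisition plus loss over the transfer delay t).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as c
from .geometry import Conformer, MembraneFrame

__all__ = [
    "SpinLabelLayer",
    "PREModelParams",
    "PREPrediction",
    "PREMeasurement",
    "BuriedReporterWarning",
    "gamma2_analytic",
    "gamma2_discrete",
    "intensity_ratio",
    "predict_profile",
    "ensemble_profile",
    "measurement_error",
    "GAMMA2_BURIED",
]

#: Finite stand-in rate for reporters at/below the label plane (ratio -> 0).
GAMMA2_BURIED = 1e9


class PREModelError(ValueError):
    pass


class BuriedReporterWarning(UserWarning):
    """A reporter sits at or below the spin-label plane; its ratio is set to 0."""


@dataclass(frozen=True)
class SpinLabelLayer:
    """Planar nitroxide distribution(s) in the bilayer.

    Defaults describe 5 mol% 5-doxyl PC at an area per lipid of 65 A^2
    (sigma = 0.05/65 labels/A^2), nitroxide midplane 8 A below the
    phosphate plane, with the trans leaflet included at a phosphate-plane
    separation of 38 A.
    """

    label_depth_d: float = 8.0
    area_density_sigma: float = 0.05 / 65.0
    include_trans_leaflet: bool = True
    bilayer_phosphate_separation: float = 38.0

    def __post_init__(self) -> None:
        if self.area_density_sigma < 0:
            raise PREModelError("area_density_sigma must be >= 0")
        if self.include_trans_leaflet and self.bilayer_phosphate_separation <= 0:
            raise PREModelError("bilayer_phosphate_separation must be > 0")

    def plane_separations(self, height_z: float) -> list[float]:
        """Reporter distances to each included label plane (A)."""
        deltas = [height_z + self.label_depth_d]
        if self.include_trans_leaflet:
            deltas.append(
                height_z + self.bilayer_phosphate_separation - self.label_depth_d
            )
        return deltas


@dataclass(frozen=True)
class PREModelParams:
    """Electron-proton relaxation model parameters (methyl-TROSY-era defaults)."""

    tau_pre_ns: float = 5.0
    proton_frequency_mhz: float = 850.0
    r2_dia: float = 20.0
    transfer_delay_t: float = 8e-3
    electron_spin: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau_pre_ns", "proton_frequency_mhz", "r2_dia", "transfer_delay_t"):
            if getattr(self, name) <= 0:
                raise PREModelError(f"{name} must be positive")

    @property
    def dipolar_constant_K(self) -> float:
        """Solomon-Bloembergen dipolar prefactor, A^6 s^-2 (recomputed, never entered)."""
        s = self.electron_spin
        k_si = (
            (1.0 / 15.0)
            * c.MU0_OVER_4PI**2
            * c.GAMMA_H**2
            * c.G_E**2
            * c.MU_B**2
            * s
            * (s + 1.0)
        )
        return k_si * c.ANGSTROM6_PER_M6

    def spectral_density(self, omega: float) -> float:
        tau = self.tau_pre_ns * 1e-9
        return tau / (1.0 + (omega * tau) ** 2)

    @property
    def k_sb(self) -> float:
        """K = dipolar prefactor x [4 J(0) + 3 J(omega_H)], A^6 s^-1."""
        omega_h = 2 * math.pi * self.proton_frequency_mhz * 1e6
        return self.dipolar_constant_K * (
            4 * self.spectral_density(0.0) + 3 * self.spectral_density(omega_h)
        )


def gamma2_analytic(
    height_z: float, layer: SpinLabelLayer, params: PREModelParams
) -> float:
    """Closed-form plane-integrated Gamma_2 (s^-1) for a reporter at height_z (A)."""
    total = 0.0
    for delta in layer.plane_separations(height_z):
        if delta <= 0:
            raise PREModelError(
                f"reporter at z={height_z} A is at/below a label plane (Delta={delta})"
            )
        total += params.k_sb * layer.area_density_sigma * math.pi / (2.0 * delta**4)
    return total


def gamma2_discrete(
    height_z: float,
    layer: SpinLabelLayer,
    params: PREModelParams,
    lattice_spacing: float = 0.5,
    cutoff_radius: float | None = None,
) -> float:
    """Brute-force lattice-sum oracle for :func:`gamma2_analytic`.

    Point labels of area density sigma are placed on a square lattice
    (half-offset, so no label sits directly beneath the reporter) out to
    ``cutoff_radius`` and summed as K * sigma * h^2 * sum r^-6.
    """
    if lattice_spacing <= 0:
        raise PREModelError("lattice_spacing must be positive")
    deltas = layer.plane_separations(height_z)
    for delta in deltas:
        if delta <= 0:
            raise PREModelError(
                f"reporter at z={height_z} A is at/below a label plane (Delta={delta})"
            )
    if cutoff_radius is None:
        cutoff_radius = 100.0 * max(deltas)
    h = lattice_spacing
    n = int(math.ceil(cutoff_radius / h))
    xs = (np.arange(n) + 0.5) * h  # quarter plane, x->-x / y->-y symmetric
    xs2 = xs**2
    cut2 = cutoff_radius**2
    total = 0.0
    chunk = 512
    for delta in deltas:
        d2 = delta**2
        s = 0.0
        for i0 in range(0, n, chunk):
            rho2 = xs2[i0 : i0 + chunk, None] + xs2[None, :]
            rho2 = rho2[rho2 <= cut2]
            s += np.sum((rho2 + d2) ** -3)
        total += 4.0 * s  # four quadrants
    return float(params.k_sb * layer.area_density_sigma * h * h * total)


def intensity_ratio(gamma2: float, params: PREModelParams) -> float:
    """I/I0 in [0, 1] from a PRE rate Gamma_2 (s^-1)."""
    if gamma2 < 0:
        raise PREModelError("gamma2 must be non-negative")
    r2 = params.r2_dia
    return float(r2 * math.exp(-gamma2 * params.transfer_delay_t) / (r2 + gamma2))


@dataclass
class PREPrediction:
    """Per-reporter back-calculated Gamma_2 and I/I0."""

    gamma2: dict[str, float]
    ratio: dict[str, float]
    z_height: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, r in self.ratio.items():
            if not (0.0 <= r <= 1.0):
                raise PREModelError(f"reporter {rid!r}: ratio {r} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reporter_id": rid,
                "z_height_A": self.z_height.get(rid, np.nan),
                "gamma2_s1": self.gamma2[rid],
                "ratio": self.ratio[rid],
            }
            for rid in self.gamma2
        ]
        return pd.DataFrame(rows)


def predict_profile(
    conformer: Conformer,
    layer: SpinLabelLayer = SpinLabelLayer(),
    params: PREModelParams = PREModelParams(),
    frame: MembraneFrame = MembraneFrame(),
) -> PREPrediction:
    """Back-calculated PRE profile for every reporter of a conformer.

    Reporters at/below the cis label plane are flagged as fully bleached
    (ratio 0, Gamma_2 capped at ``GAMMA2_BURIED``) with a warning instead of
    raising — deeply inserted helix reporters are legitimate inputs.
    """
    gamma2: dict[str, float] = {}
    ratio: dict[str, float] = {}
    zs: dict[str, float] = {}
    for rid, xyz in conformer.reporter_table.items():
        z = float(xyz[2] - frame.phosphate_plane_z)
        zs[rid] = z
        try:
            g = gamma2_analytic(z, layer, params)
        except PREModelError:
            warnings.warn(
                f"reporter {rid!r} at z={z:.2f} A is at/below the label plane; "
                "treated as fully bleached (ratio 0)",
                BuriedReporterWarning,
                stacklevel=2,
            )
            g = GAMMA2_BURIED
        gamma2[rid] = g
        ratio[rid] = intensity_ratio(g, params)
    return PREPrediction(gamma2=gamma2, ratio=ratio, z_height=zs)


def ensemble_profile(
    conformers: list[Conformer],
    weights: np.ndarray | list[float],
    regime: str = "fast_exchange",
    layer: SpinLabelLayer = SpinLabelLayer(),
    params: PREModelParams = PREModelParams(),
    frame: MembraneFrame = MembraneFrame(),
) -> PREPrediction:
    """PRE profile of a weighted conformer ensemble.

    ``fast_exchange`` (default) weight-averages Gamma_2 per reporter before
    converting to a single intensity ratio — conformations interconvert
    faster than relaxation; ``intensity_average`` averages the ratios.
    """
    if regime not in ("fast_exchange", "intensity_average"):
        raise PREModelError(f"unknown regime {regime!r}")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(conformers) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise PREModelError("weights must be a simplex vector matching the conformers")
    preds = [predict_profile(cf, layer, params, frame) for cf in conformers]
    rids = list(preds[0].gamma2)
    for p in preds[1:]:
        if list(p.gamma2) != rids:
            raise PREModelError("mismatched reporter sets across ensemble members")
    gamma2: dict[str, float] = {}
    ratio: dict[str, float] = {}
    for rid in rids:
        gs = np.array([p.gamma2[rid] for p in preds])
        if regime == "fast_exchange":
            g_bar = float(w @ gs)
            gamma2[rid] = g_bar
            ratio[rid] = intensity_ratio(g_bar, params)
        else:
            rs = np.array([p.ratio[rid] for p in preds])
            gamma2[rid] = float(w @ gs)
            ratio[rid] = float(w @ rs)
    return PREPrediction(gamma2=gamma2, ratio=ratio)


def measurement_error(
    i_para: float, i_dia: float, sn_para: float, sn_dia: float
) -> float:
    """Uncertainty of an I_para/I_dia ratio from the spectra's signal-to-noise:

    error = (I_para/I_dia) * sqrt((1/SN_para)^2 + (1/SN_dia)^2)
    """
    if sn_para <= 0 or sn_dia <= 0:
        raise PREModelError("signal-to-noise values must be positive")
    if i_dia <= 0:
        raise PREModelError("I_dia must be positive")
    return (i_para / i_dia) * math.sqrt(sn_para**-2 + sn_dia**-2)


class PREMeasurement:
    """Experimental per-reporter PRE table (I_para, I_dia, S/N pair).

    Ratios and their errors are always computed from the raw columns,
    never read from disk.
    """

    REQUIRED = ["reporter_id", "I_para", "I_dia", "sn_para", "sn_dia"]

    def __init__(self, table: pd.DataFrame):
        missing = [col for col in self.REQUIRED if col not in table.columns]
        if missing:
            raise PREModelError(f"missing columns: {missing}")
        if table["reporter_id"].duplicated().any():
            dup = table.loc[table["reporter_id"].duplicated(), "reporter_id"].tolist()
            raise PREModelError(f"duplicate reporter ids: {dup}")
        for i, row in table.iterrows():
            if row["I_dia"] <= 0:
                raise PREModelError(f"row {i}: I_dia must be positive")
            if row["sn_para"] <= 0 or row["sn_dia"] <= 0:
                raise PREModelError(f"row {i}: S/N values must be positive")
        df = table.copy().reset_index(drop=True)
        df["ratio"] = df["I_para"] / df["I_dia"]
        df["error"] = [
            measurement_error(r.I_para, r.I_dia, r.sn_para, r.sn_dia)
            for r in df.itertuples()
        ]
        self.table = df

    @property
    def reporter_ids(self) -> list[str]:
        return self.table["reporter_id"].tolist()

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].to_numpy()

    @property
    def errors(self) -> np.ndarray:
        return self.table["error"].to_numpy()

    def with_ratios(self, ratios: np.ndarray) -> "PREMeasurement":
        """Copy with perturbed ratios (I_para rewritten; I_dia and S/N kept)."""
        df = self.table[[col for col in self.table.columns if col not in ("ratio", "error")]].copy()
        df["I_para"] = np.asarray(ratios, float) * df["I_dia"].to_numpy()
        return PREMeasurement(df)
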