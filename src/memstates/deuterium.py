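"""2H solid-state NMR chain-order analytics.

Quadrupolar Pake-doublet splittings from chain-perdeuterated lipids (or a
deuterated myristoyl anchor) are converted to segmental order parameters

    |S_CD| = dv / (3/4 * chi_Q)          (CH2)
    |S_CD| = dv / (3/4 * chi_Q * 1/3)    (CH3; C3 rotation scales the splitting)

with chi_Q the static quadrupolar coupling (default 167 kHz) and 3/4 the
90-degree powder-edge factor.  Smoothed profiles assign the sorted
splittings monotonically from the plateau toward the terminal methyl;
chain-extension profiles follow the first-order mean-torque model, which
maps |S_CD| to a mean segment projection on the bilayer normal via

    <cos b> = (1 + sqrt((8|S| - 1)/3)) / 2,   valid for |S| >= 1/8.

Inversion-recovery series for Zeeman-order relaxation are fitted to
I(t) = I_inf (1 - 2 f exp(-R1Z t)), and R1Z-vs-S^2 ("square-law") tables
summarize chain elasticity.  Order parameters can also be computed
directly from C-H unit vectors of trajectory frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator

__all__ = [
    "QuadrupoleParams",
    "SplittingTable",
    "OrderProfile",
    "ExtensionProfile",
    "RelaxationSeries",
    "R1ZFit",
    "splitting_to_order",
    "order_to_splitting",
    "smooth_profile",
    "chain_extension",
    "fit_inversion_recovery",
    "square_law_table",
    "order_from_vectors",
    "DEFAULT_IR_SCHEDULE",
]

CH2 = "CH2"
CH3 = "CH3"

#: Inversion-recovery delay schedule (s) used for the T1Z measurements.
DEFAULT_IR_SCHEDULE = (0.001, 0.007, 0.014, 0.023, 0.035, 0.07, 0.1, 0.2, 0.4, 1.0, 1.8)


class OrderError(ValueError):
    pass


@dataclass(frozen=True)
class QuadrupoleParams:
    chi_q_khz: float = 167.0
    powder_edge_factor: float = 0.75
    methyl_reduction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.chi_q_khz <= 0:
            raise OrderError("chi_q must be positive")


@dataclass
class SplittingTable:
    """Per-carbon quadrupolar splittings (kHz); carbons 1-based from the carbonyl."""

    carbons: np.ndarray
    splittings_khz: np.ndarray
    groups: list[str]

    def __post_init__(self) -> None:
        self.carbons = np.asarray(self.carbons, int)
        self.splittings_khz = np.asarray(self.splittings_khz, float)
        if len(self.carbons) != len(self.splittings_khz) or len(self.groups) != len(self.carbons):
            raise OrderError("mismatched table lengths")
        if np.any(self.splittings_khz < 0):
            raise OrderError("splittings must be >= 0")
        if len(set(self.carbons.tolist())) != len(self.carbons):
            raise OrderError("duplicate carbon indices")
        for g in self.groups:
            if g not in (CH2, CH3):
                raise OrderError(f"unknown group type {g!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"carbon_index": self.carbons, "splitting_khz": self.splittings_khz, "group": self.groups}
        )


@dataclass
class OrderProfile:
    """Carbon-indexed |S_CD| values (dimensionless, [0, 0.5])."""

    carbons: np.ndarray
    s_cd: np.ndarray
    smoothed: bool = False
    signs: np.ndarray | None = None  # raw signed values when known (trajectory route)

    def __post_init__(self) -> None:
        self.carbons = np.asarray(self.carbons, int)
        self.s_cd = np.asarray(self.s_cd, float)
        if len(self.carbons) != len(self.s_cd):
            raise OrderError("mismatched profile lengths")
        if np.any(self.s_cd < 0):
            raise OrderError("|S_CD| must be non-negative")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.carbons.tolist(), self.s_cd.tolist()))


@dataclass
class ExtensionProfile:
    """Cumulative projected distance of each carbon from the terminal CH3 (A).

    By convention the terminal methyl sits at 0; only slopes are comparable
    between chains.  ``sub_eighth`` flags carbons where |S| < 1/8 and the
    mean-torque closed form was replaced by its boundary value <cos b> = 1/2.
    """

    carbons: np.ndarray
    cumulative_A: np.ndarray
    travel_A: np.ndarray
    sub_eighth: np.ndarray

    def __post_init__(self) -> None:
        d = np.diff(self.cumulative_A[np.argsort(-self.carbons)])
        if np.any(self.cumulative_A < 0) or np.any(d < -1e-12):
            raise OrderError("cumulative extension must be non-negative, non-decreasing")


def splitting_to_order(dv_khz: float, group: str, qp: QuadrupoleParams = QuadrupoleParams()) -> float:
    """|S_CD| from a Pake 90-degree-edge splitting (kHz)."""
    if dv_khz < 0:
        raise OrderError("splitting must be >= 0")
    denom = qp.powder_edge_factor * qp.chi_q_khz
    if group == CH3:
        denom *= qp.methyl_reduction
    elif group != CH2:
        raise OrderError(f"unknown group type {group!r}")
    s = dv_khz / denom
    if s > 0.5:
        raise OrderError(f"|S_CD| = {s:.3f} > 0.5 is unphysical (dv = {dv_khz} kHz)")
    return s


def order_to_splitting(s_cd: float, group: str, qp: QuadrupoleParams = QuadrupoleParams()) -> float:
    """Forward conversion |S_CD| -> splitting (kHz); inverse of splitting_to_order."""
    if not 0.0 <= s_cd <= 0.5:
        raise OrderError("|S_CD| must lie in [0, 0.5]")
    factor = qp.powder_edge_factor * qp.chi_q_khz
    if group == CH3:
        factor *= qp.methyl_reduction
    return s_cd * factor


def smooth_profile(
    splittings: SplittingTable,
    chain_length: int,
    qp: QuadrupoleParams = QuadrupoleParams(),
) -> OrderProfile:
    """Smoothed order-parameter profile over carbons 2..chain_length.

    Resolved |S| values are sorted descending and assigned monotonically
    from the upper chain (plateau) toward the terminal methyl at the
    resolved carbon positions; unresolved carbons are filled by monotone
    shape-preserving (PCHIP) interpolation, flat-extended at the ends.
    """
    if len(splittings.carbons) < 2:
        raise OrderError("need at least 2 resolved splittings")
    if chain_length < len(splittings.carbons) + 1:
        raise OrderError("chain_length smaller than the number of splittings")
    group_of = dict(zip(splittings.carbons.tolist(), splittings.groups))
    s_vals = np.array(
        [
            splitting_to_order(dv, g, qp)
            for dv, g in zip(splittings.splittings_khz, splittings.groups)
        ]
    )
    pos = np.sort(splittings.carbons)
    vals = np.sort(s_vals)[::-1]  # largest |S| to the smallest carbon index
    carbons = np.arange(2, chain_length + 1)
    interp = PchipInterpolator(pos.astype(float), vals, extrapolate=False)
    prof = interp(carbons.astype(float))
    prof = np.where(carbons < pos[0], vals[0], prof)
    prof = np.where(carbons > pos[-1], vals[-1], prof)
    prof = np.minimum.accumulate(prof)  # enforce non-increasing toward CH3
    return OrderProfile(carbons=carbons, s_cd=prof, smoothed=True)


def _mean_cos(s_abs: float) -> tuple[float, bool]:
    if s_abs >= 0.125:
        return 0.5 * (1.0 + np.sqrt((8.0 * s_abs - 1.0) / 3.0)), False
    return 0.5, True


def chain_extension(
    profile: OrderProfile, segment_projection: float = 1.27
) -> ExtensionProfile:
    """First-order mean-torque chain-extension profile from |S_CD| values.

    ``segment_projection`` is the all-trans per-carbon travel (1.27 A, the
    C-C bond projected on the chain axis); per-carbon travel is its product
    with <cos b>.  Cumulative distances run from the terminal methyl (0)
    toward the carbonyl.
    """
    if np.any(profile.s_cd > 0.5):
        raise OrderError("|S_CD| values above 0.5 are unphysical")
    order = np.argsort(profile.carbons)
    carbons = profile.carbons[order]
    s = profile.s_cd[order]
    cos_travel = np.array([_mean_cos(v) for v in s])
    travel = segment_projection * cos_travel[:, 0]
    flagged = cos_travel[:, 1].astype(bool)
    # cumulative(i) = sum of travels of carbons strictly deeper than i
    cum = np.concatenate([np.cumsum(travel[::-1])[::-1][1:], [0.0]])
    return ExtensionProfile(
        carbons=carbons, cumulative_A=cum, travel_A=travel, sub_eighth=flagged
    )


@dataclass
class RelaxationSeries:
    """Inversion-recovery intensity series for Zeeman-order relaxation."""

    delays_s: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.delays_s = np.asarray(self.delays_s, float)
        self.intensities = np.asarray(self.intensities, float)
        if len(self.delays_s) < 5:
            raise OrderError("need >= 5 delay points")
        if np.any(np.diff(self.delays_s) <= 0):
            raise OrderError("delays must be strictly increasing")


@dataclass(frozen=True)
class R1ZFit:
    r1z: float  # s^-1
    f: float  # inversion efficiency
    i_inf: float
    r1z_ci95: tuple[float, float]


def fit_inversion_recovery(series: RelaxationSeries) -> R1ZFit:
    """Least-squares fit of I(t) = I_inf (1 - 2 f exp(-R1Z t)) with a 95% CI."""
    t, y = series.delays_s, series.intensities
    i_inf0 = y[-1] if y[-1] != 0 else 1.0
    r0 = 1.0 / max(t[len(t) // 2], 1e-6)

    def model(t, i_inf, f, r):
        return i_inf * (1.0 - 2.0 * f * np.exp(-r * t))

    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=[i_inf0, 1.0, r0], maxfev=20000
        )
    except RuntimeError as exc:
        raise OrderError(f"inversion-recovery fit did not converge: {exc}") from None
    i_inf, f, r = popt
    if r <= 0:
        raise OrderError(f"inversion-recovery fit returned non-positive rate R={r}")
    dof = max(len(t) - 3, 1)
    stderr = float(np.sqrt(np.abs(pcov[2, 2])))
    half = stats.t.ppf(0.975, dof) * stderr
    return R1ZFit(r1z=float(r), f=float(f), i_inf=float(i_inf), r1z_ci95=(r - half, r + half))


def square_law_table(
    profile: OrderProfile, rates: dict[int, float]
) -> pd.DataFrame:
    """Paired (S^2, R1Z) rows sorted by S^2 — no fit, the curvature is the readout."""
    s_of = profile.as_dict()
    shared = sorted(set(s_of) & set(rates))
    if not shared:
        raise OrderError("no shared carbon indices between profile and rates")
    df = pd.DataFrame(
        {
            "carbon_index": shared,
            "s_squared": [s_of[i] ** 2 for i in shared],
            "r1z_s1": [rates[i] for i in shared],
        }
    )
    return df.sort_values("s_squared", kind="stable").reset_index(drop=True)


def order_from_vectors(
    ch_unit_vectors: dict[int, np.ndarray], tol: float = 1e-6
) -> OrderProfile:
    """S_CD per carbon from C-H unit vectors over frames (membrane normal = +z).

    S = <(3 cos^2 theta - 1)/2> averaged over frames; the profile stores
    |S| with the signed values kept in ``signs``.
    """
    carbons = sorted(ch_unit_vectors)
    signed = []
    for ci in carbons:
        v = np.asarray(ch_unit_vectors[ci], float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise OrderError(f"carbon {ci}: expected (n_frames, 3) vectors")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > tol):
            raise OrderError(f"carbon {ci}: vectors are not unit-normalized")
        cos2 = v[:, 2] ** 2
        signed.append(float(np.mean(1.5 * cos2 - 0.5)))
    signed = np.array(signed)
    return OrderProfile(
        carbons=np.array(carbons), s_cd=np.abs(signed), smoothed=False, signs=signed
    )
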