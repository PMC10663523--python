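"""Ground-truth synthetic inputs for every stage of the pipeline.

The generators emulate the study system: a rigid G domain carrying ~41
methyl reporters tethered ~20 A above a planar bilayer by a membrane-
embedded N-terminal helix (3 reporters ~6.5 A below the phosphate plane),
interconverting between three orientational states; PRE profiles with
multiplicative intensity noise; monotone acyl-chain order profiles with
noisy splittings; and exponential relaxation decays.  Every generator is a
pure function of (spec, seed).

States are coupled to the PRE observable geometrically: each conformer is
rigidly rotated about the G-domain centroid to an orientation drawn inside
its state's (beta, gamma) bin and translated to a state-specific COM height
(defaults 18/22/26 A for S1/S2/S3), so different states bury different
reporter subsets — the way the occluded state buries the switch-I face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .deuterium import (
    DEFAULT_IR_SCHEDULE,
    OrderProfile,
    QuadrupoleParams,
    RelaxationSeries,
    SplittingTable,
    order_to_splitting,
)
from .ensembles import ConformerLibrary
from .geometry import (
    Conformer,
    DEFAULT_STATES,
    G_DOMAIN,
    MembraneFrame,
    N_HELIX,
    StateDefinition,
    rotation_from_orientation,
)
from .pre import PREMeasurement, PREModelParams, SpinLabelLayer, ensemble_profile
from .rotation import SpinParams, TractDecayPair, tauc_to_delta_r

import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "ToyDomainSpec",
    "TruthEnsemble",
    "make_toy_domain",
    "sample_library",
    "simulate_pre_measurement",
    "simulate_splittings",
    "simulate_inversion_recovery",
    "simulate_tract",
]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class ToyDomainSpec:
    """Geometry of the toy reporter construct (defaults: 41 + 3 = 44 reporters)."""

    n_gdomain_reporters: int = 41
    n_helix_reporters: int = 3
    gdomain_radius: float = 12.0
    helix_depth: float = -6.5
    center_height: float = 23.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gdomain_reporters < 1 or self.n_helix_reporters < 1:
            raise SyntheticError("reporter counts must be >= 1")


@dataclass(frozen=True)
class TruthEnsemble:
    """Ground-truth three-state mixture for library generation."""

    state_fractions: tuple[float, ...] = (0.2, 0.3, 0.5)  # S1, S2, S3
    height_means: tuple[float, ...] = (18.0, 22.0, 26.0)
    height_sds: tuple[float, ...] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.state_fractions) - 1.0) > 1e-9 or any(
            f < 0 for f in self.state_fractions
        ):
            raise SyntheticError("state_fractions must form a simplex")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic low-discrepancy points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + math.sqrt(5)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_toy_domain(spec: ToyDomainSpec = ToyDomainSpec()) -> Conformer:
    """Reference conformer: spherical G-domain reporter shell + buried helix line.

    G-domain reporters are seeded low-discrepancy sphere points (a seeded
    random rotation decorrelates the lattice between seeds), re-centred so
    their centroid sits exactly at (0, 0, center_height).  Helix reporters
    lie on a line at ``helix_depth`` below the phosphate plane.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x70F]))
    pts = _fibonacci_sphere(spec.n_gdomain_reporters) * spec.gdomain_radius
    pts = Rotation.random(rng=rng).apply(pts)
    pts = pts - pts.mean(axis=0) + np.array([0.0, 0.0, spec.center_height])
    table: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for k, xyz in enumerate(pts):
        rid = f"{17 + k}-CD1"  # pseudo residue numbers inside the G domain
        table[rid] = xyz
        roles[rid] = G_DOMAIN
    helix_res = (4, 8, 12)
    for k in range(spec.n_helix_reporters):
        res = helix_res[k] if k < 3 else 2 + k
        rid = f"{res}-CD1"
        table[rid] = np.array([10.0 + 1.5 * k, 0.0, spec.helix_depth])
        roles[rid] = N_HELIX
    return Conformer(id="reference", reporter_table=table, reporter_roles=roles)


def _sample_gamma(rng: np.random.Generator, lo: float, hi: float) -> float:
    width = (hi - lo) % 360.0 or 360.0
    return (lo + rng.uniform(0.0, width)) % 360.0


def sample_library(
    reference: Conformer,
    truth: TruthEnsemble = TruthEnsemble(),
    n_conformers: int = 2000,
    states: tuple[StateDefinition, ...] = DEFAULT_STATES,
    layer: SpinLabelLayer = SpinLabelLayer(),
    params: PREModelParams = PREModelParams(),
    frame: MembraneFrame = MembraneFrame(),
    max_resample: int = 100,
) -> tuple[ConformerLibrary, list[str]]:
    """State-structured conformer library with recorded truth labels.

    Each conformer: draw a state by its fraction, an orientation uniform in
    the state's (beta, gamma) bin, and a COM height from the state's normal
    distribution (resampled, capped, so all G-domain reporters stay above
    the cis label plane); the G domain is rigidly rotated about its centroid
    and translated to that height while the helix reporters stay anchored.
    """
    if len(truth.state_fractions) != len(states):
        raise SyntheticError("one fraction per state required")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x11B]))
    centroid = reference.coords(G_DOMAIN).mean(axis=0)
    g_pts = reference.coords(G_DOMAIN) - centroid
    min_allowed = -layer.label_depth_d + 1.0  # 1 A safety margin above label plane
    conformers: list[Conformer] = []
    labels: list[str] = []
    fractions = np.asarray(truth.state_fractions)
    for i in range(n_conformers):
        s_idx = int(rng.choice(len(states), p=fractions))
        st = states[s_idx]
        beta = rng.uniform(*st.beta_range)
        gamma = _sample_gamma(rng, *st.gamma_range)
        rot = rotation_from_orientation(beta, gamma)
        rotated = rot.apply(g_pts)
        lowest = rotated[:, 2].min()
        for attempt in range(max_resample + 1):
            h = rng.normal(truth.height_means[s_idx], truth.height_sds[s_idx])
            if h + lowest > min_allowed:
                break
        else:
            raise SyntheticError(
                f"could not draw a height keeping conformer {i} above the label plane"
            )
        table = dict(
            zip(
                reference.reporter_ids(G_DOMAIN),
                rotated + np.array([0.0, 0.0, h]),
            )
        )
        for rid in reference.reporter_ids(N_HELIX):
            table[rid] = reference.reporter_table[rid].copy()
        conformers.append(
            Conformer(
                id=f"m{i:05d}",
                reporter_table=table,
                reporter_roles=dict(reference.reporter_roles),
            )
        )
        labels.append(st.name)
    lib = ConformerLibrary.from_conformers(
        conformers, reference, layer, params, states, frame
    )
    return lib, labels


def simulate_pre_measurement(
    truth_multiset: list[Conformer],
    layer: SpinLabelLayer = SpinLabelLayer(),
    params: PREModelParams = PREModelParams(),
    noise_fraction: float = 0.15,
    sn: float = 50.0,
    seed: int = 0,
    reporter_ids: list[str] | None = None,
    i_dia: float = 1000.0,
) -> PREMeasurement:
    """Noisy PRE table from a fast-exchange ensemble of truth conformers."""
    n = len(truth_multiset)
    pred = ensemble_profile(
        truth_multiset, np.full(n, 1.0 / n), "fast_exchange", layer, params
    )
    rids = reporter_ids if reporter_ids is not None else list(pred.ratio)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E1]))
    rows = []
    for rid in rids:
        ratio = pred.ratio[rid]
        if noise_fraction > 0:
            ratio = float(
                np.clip(ratio * (1.0 + noise_fraction * rng.standard_normal()), 0.0, 1.0)
            )
        res, atom = rid.split("-", 1)
        rows.append(
            {
                "reporter_id": rid,
                "residue": int(res),
                "atom": atom,
                "I_para": ratio * i_dia,
                "I_dia": i_dia,
                "sn_para": sn,
                "sn_dia": sn,
            }
        )
    return PREMeasurement(pd.DataFrame(rows))


def simulate_splittings(
    truth_profile: OrderProfile,
    qp: QuadrupoleParams = QuadrupoleParams(),
    noise_khz: float = 0.0,
    seed: int = 0,
    mask: list[int] | None = None,
    terminal_carbon: int | None = None,
) -> SplittingTable:
    """Forward-convert an order profile to (optionally noisy, masked) splittings."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2D0]))
    term = terminal_carbon if terminal_carbon is not None else int(truth_profile.carbons.max())
    carbons, dvs, groups = [], [], []
    for ci, s in zip(truth_profile.carbons, truth_profile.s_cd):
        if mask and int(ci) in mask:
            continue
        group = "CH3" if ci == term else "CH2"
        dv = order_to_splitting(float(s), group, qp)
        if noise_khz > 0:
            dv = max(dv + noise_khz * rng.standard_normal(), 0.0)
        carbons.append(int(ci))
        dvs.append(dv)
        groups.append(group)
    return SplittingTable(np.array(carbons), np.array(dvs), groups)


def simulate_inversion_recovery(
    r1z: float,
    f: float = 1.0,
    i_inf: float = 100.0,
    schedule: tuple[float, ...] = DEFAULT_IR_SCHEDULE,
    noise: float = 0.0,
    seed: int = 0,
) -> RelaxationSeries:
    """I(t) = I_inf (1 - 2 f exp(-R1Z t)) on the delay schedule, plus noise."""
    if r1z <= 0:
        raise SyntheticError("r1z must be positive")
    t = np.asarray(schedule, float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1A2]))
    y = i_inf * (1.0 - 2.0 * f * np.exp(-r1z * t))
    if noise > 0:
        y = y + noise * i_inf * rng.standard_normal(len(t))
    return RelaxationSeries(delays_s=t, intensities=y)


def simulate_tract(
    tau_c_ns: float,
    sp: SpinParams = SpinParams(),
    schedule: tuple[float, ...] = (0.002, 0.005, 0.01, 0.02, 0.035, 0.05, 0.08, 0.12),
    noise: float = 0.0,
    seed: int = 0,
    r2_avg: float = 60.0,
    i0: float = 100.0,
) -> TractDecayPair:
    """TROSY/anti-TROSY decay pair for a rotor of the given tau_c."""
    if tau_c_ns <= 0:
        raise SyntheticError("tau_c must be positive")
    eta = 0.5 * tauc_to_delta_r(tau_c_ns, sp)
    r_alpha = r2_avg - eta
    r_beta = r2_avg + eta
    if r_alpha <= 0:
        raise SyntheticError("r2_avg too small: TROSY rate would be non-positive")
    t = np.asarray(schedule, float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7AC]))
    trosy = i0 * np.exp(-r_alpha * t)
    anti = i0 * np.exp(-r_beta * t)
    if noise > 0:
        trosy = trosy + noise * i0 * rng.standard_normal(len(t))
        anti = anti + noise * i0 * rng.standard_normal(len(t))
    return TractDecayPair(delays_s=t, trosy=trosy, anti_trosy=anti)
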