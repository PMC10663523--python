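"""Fixed-size conformer-ensemble selection against measured PRE profiles.

A library of candidate conformers (each with a precomputed per-reporter
Gamma_2 response) is searched for the N-member multiset whose fast-exchange
ensemble PRE best fits a measured I/I0 profile in the weighted-least-squares
sense.  Repeating the selection on noise-perturbed copies of the data yields
state-population estimates with uncertainties, mirroring the
16-member / 100-repeat / 15%-noise protocol used for the membrane-bound
G domain.

The optimizer has two components.  (1) An exact-fit probe: because the
fast-exchange intensity ratio is strictly monotone in Gamma_2, a measured
profile determines a unique target mean-response vector; a small integer
feasibility program (HiGHS) then asks whether any N-multiset reproduces
that target exactly.  On noise-free data generated from the library this
recovers the generating multiset (chi^2 = 0); on noisy data it is quickly
infeasible and is skipped.  (2) A seeded stochastic hill climb over
multisets: random starting multiset, random single-member replacement
proposals accepted on chi^2 decrease (optionally with a simulated-annealing
rule), followed by a deterministic steepest-descent single-swap polish
until no replacement improves chi^2; multiple restarts, best result wins.
Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    Conformer,
    MembraneFrame,
    Orientation,
    StateDefinition,
    DEFAULT_STATES,
    UNASSIGNED,
    assign_state,
    com_height,
    compute_orientation,
)
from .pre import (
    PREMeasurement,
    PREModelParams,
    PREPrediction,
    SpinLabelLayer,
    predict_profile,
)

__all__ = [
    "ConformerLibrary",
    "FitConfig",
    "SearchConfig",
    "EnsembleFit",
    "PopulationSummary",
    "chi_square",
    "select_ensemble",
    "repeat_selection",
    "compare_populations",
    "ensemble_com",
]

SIGMA_FLOOR = 0.01


class EnsembleError(ValueError):
    pass


@dataclass
class ConformerLibrary:
    """Candidate conformers with precomputed PRE responses and annotations."""

    conformers: list[Conformer]
    response_matrix: np.ndarray  # (n_conformers, n_reporters) Gamma_2, s^-1
    reporter_ids: list[str]
    state_labels: list[str]
    heights: np.ndarray  # G-domain COM heights, A
    params: PREModelParams = field(default_factory=PREModelParams)

    def __post_init__(self) -> None:
        n = len(self.conformers)
        self.response_matrix = np.asarray(self.response_matrix, float)
        self.heights = np.asarray(self.heights, float)
        if self.response_matrix.shape != (n, len(self.reporter_ids)):
            raise EnsembleError("response_matrix shape does not match library")
        if len(self.state_labels) != n or len(self.heights) != n:
            raise EnsembleError("annotation lengths do not match library")

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def ids(self) -> list[str]:
        return [cf.id for cf in self.conformers]

    @classmethod
    def from_conformers(
        cls,
        conformers: list[Conformer],
        reference: Conformer,
        layer: SpinLabelLayer = SpinLabelLayer(),
        params: PREModelParams = PREModelParams(),
        states: tuple[StateDefinition, ...] = DEFAULT_STATES,
        frame: MembraneFrame = MembraneFrame(),
    ) -> "ConformerLibrary":
        """Build responses, state labels and heights from scratch."""
        preds = [predict_profile(cf, layer, params, frame) for cf in conformers]
        rids = list(preds[0].gamma2)
        matrix = np.array([[p.gamma2[r] for r in rids] for p in preds])
        labels = [
            assign_state(compute_orientation(cf, reference), states)
            for cf in conformers
        ]
        heights = np.array([com_height(cf, frame=frame) for cf in conformers])
        return cls(conformers, matrix, rids, labels, heights, params)


@dataclass(frozen=True)
class SearchConfig:
    """Hill-climb settings: restarts x random proposals, then steepest polish.

    ``exact_probe`` additionally runs the integer feasibility program that
    recovers exact-fit multisets on noise-free data (bounded by
    ``probe_time_limit`` seconds; a no-op when no exact fit exists).
    """

    restarts: int = 20
    proposals: int = 2000
    polish: bool = True
    max_polish_sweeps: int = 200
    anneal: bool = False
    anneal_temp: float = 1.0
    exact_probe: bool = True
    probe_time_limit: float = 60.0
    probe_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.restarts < 1 or self.proposals < 0:
            raise EnsembleError("invalid search configuration")


@dataclass(frozen=True)
class FitConfig:
    """Ensemble-fit protocol settings.

    ``noise_fraction`` declares the relative random error of the data; it
    drives both the repeat perturbations and the objective: reporter
    weights are the total uncertainty sqrt(eq1_error^2 +
    (noise_fraction*ratio)^2), and the search refines chi^2 only down to
    its expected value under that uncertainty (discrepancy principle) —
    fitting further would only chase noise.  With noise_fraction = 0 the
    objective reduces to plain Eq.-1 weighting refined all the way down.
    """

    ensemble_size: int = 16
    repeats: int = 100
    noise_fraction: float = 0.15
    seed: int = 0
    search: SearchConfig = field(default_factory=SearchConfig)
    perturb: str = "data"  # "data" | "start" | "both"

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise EnsembleError("ensemble_size must be >= 1")
        if self.repeats < 1:
            raise EnsembleError("repeats must be >= 1")
        if self.perturb not in ("data", "start", "both"):
            raise EnsembleError(f"unknown perturb mode {self.perturb!r}")


@dataclass
class EnsembleFit:
    member_ids: list[str]  # multiset, repetition allowed
    member_indices: np.ndarray
    chi2: float
    state_counts: dict[str, int]
    com_mean: float

    @property
    def state_fractions(self) -> dict[str, float]:
        n = len(self.member_ids)
        return {s: c / n for s, c in self.state_counts.items()}


@dataclass
class PopulationSummary:
    """State populations (percent) over noise-perturbed selection repeats."""

    states: list[str]
    per_repeat_fractions: pd.DataFrame  # repeats x states, fractions in [0, 1]
    com_per_repeat: np.ndarray
    chi2_per_repeat: np.ndarray
    ensemble_size: int

    @property
    def mean_percent(self) -> dict[str, float]:
        return {s: 100.0 * float(self.per_repeat_fractions[s].mean()) for s in self.states}

    @property
    def sd_percent(self) -> dict[str, float]:
        return {s: 100.0 * float(self.per_repeat_fractions[s].std(ddof=1)) for s in self.states}

    @property
    def com_mean(self) -> float:
        return float(self.com_per_repeat.mean())


def _ratio_matrix(gam: np.ndarray, params: PREModelParams) -> np.ndarray:
    """Vectorized intensity_ratio for arrays of Gamma_2."""
    r2 = params.r2_dia
    return r2 * np.exp(-gam * params.transfer_delay_t) / (r2 + gam)


def chi_square(
    predicted: PREPrediction,
    measured: PREMeasurement,
    sigma_floor: float = SIGMA_FLOOR,
) -> float:
    """Weighted least-squares misfit over reporters shared by both tables."""
    shared = [r for r in measured.reporter_ids if r in predicted.ratio]
    if not shared:
        raise EnsembleError("no shared reporters between prediction and measurement")
    sub = measured.table.set_index("reporter_id").loc[shared]
    calc = np.array([predicted.ratio[r] for r in shared])
    sig = np.maximum(sub["error"].to_numpy(), sigma_floor)
    return float(np.sum(((calc - sub["ratio"].to_numpy()) / sig) ** 2))


def _prepare_arrays(
    lib: ConformerLibrary,
    measured: PREMeasurement,
    sigma_floor: float,
    noise_fraction: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cols = []
    for rid in measured.reporter_ids:
        if rid in lib.reporter_ids:
            cols.append(lib.reporter_ids.index(rid))
    if not cols:
        raise EnsembleError("no shared reporters between library and measurement")
    keep = [rid for rid in measured.reporter_ids if rid in lib.reporter_ids]
    sub = measured.table.set_index("reporter_id").loc[keep]
    g = lib.response_matrix[:, cols]
    y = sub["ratio"].to_numpy()
    err = sub["error"].to_numpy()
    sig = np.maximum(np.sqrt(err**2 + (noise_fraction * y) ** 2), sigma_floor)
    return g, y, sig


def _chi2_of(gbar: np.ndarray, y: np.ndarray, sig: np.ndarray, params: PREModelParams) -> float:
    return float(np.sum(((_ratio_matrix(gbar, params) - y) / sig) ** 2))


def _climb(
    g: np.ndarray,
    y: np.ndarray,
    sig: np.ndarray,
    params: PREModelParams,
    n_members: int,
    search: SearchConfig,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
    target: float = 0.0,
) -> tuple[np.ndarray, float]:
    n_lib = g.shape[0]
    idx = (
        np.array(start, dtype=int)
        if start is not None
        else rng.integers(0, n_lib, size=n_members)
    )
    gbar = g[idx].mean(axis=0)
    chi2 = _chi2_of(gbar, y, sig, params)
    # phase 1: random single-swap proposals
    for _ in range(search.proposals):
        if chi2 <= target:
            break
        slot = int(rng.integers(n_members))
        cand = int(rng.integers(n_lib))
        new_gbar = gbar + (g[cand] - g[idx[slot]]) / n_members
        new_chi2 = _chi2_of(new_gbar, y, sig, params)
        accept = new_chi2 < chi2
        if not accept and search.anneal and search.anneal_temp > 0:
            accept = rng.random() < np.exp((chi2 - new_chi2) / search.anneal_temp)
        if accept:
            idx[slot] = cand
            gbar, chi2 = new_gbar, new_chi2
    # phase 2: steepest-descent sweeps to a single-swap local optimum
    if search.polish:
        for _ in range(search.max_polish_sweeps):
            if chi2 <= target:
                break
            improved = False
            for slot in range(n_members):
                if chi2 <= target:
                    break
                trial = gbar[None, :] + (g - g[idx[slot]][None, :]) / n_members
                chi2_all = np.sum(
                    ((_ratio_matrix(trial, params) - y[None, :]) / sig[None, :]) ** 2,
                    axis=1,
                )
                best = int(np.argmin(chi2_all))
                if chi2_all[best] < chi2 * (1 - 1e-14) and best != idx[slot]:
                    gbar = gbar + (g[best] - g[idx[slot]]) / n_members
                    idx[slot] = best
                    chi2 = float(chi2_all[best])
                    improved = True
            if not improved:
                break
    # recompute from scratch to shed accumulated float drift
    gbar = g[idx].mean(axis=0)
    return idx, _chi2_of(gbar, y, sig, params)


_GAMMA_PROBE_MAX = 1e8  # s^-1; ratio below ratio(_GAMMA_PROBE_MAX) is non-invertible


def _invert_ratio(y: np.ndarray, params: PREModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-reporter inverse of intensity_ratio (strictly decreasing in Gamma_2).

    Returns the target Gamma_2 values and a mask of invertible reporters
    (ratios at/below the floor of the model are excluded).
    """
    from scipy.optimize import brentq

    r2, t = params.r2_dia, params.transfer_delay_t
    ratio = lambda g: r2 * np.exp(-g * t) / (r2 + g)
    y_floor = ratio(_GAMMA_PROBE_MAX)
    gstar = np.empty_like(y)
    ok = np.ones(len(y), dtype=bool)
    for j, yj in enumerate(y):
        if yj >= 1.0:
            gstar[j] = 0.0
        elif yj <= y_floor:
            ok[j] = False
            gstar[j] = np.nan
        else:
            gstar[j] = brentq(lambda g: ratio(g) - yj, 0.0, _GAMMA_PROBE_MAX,
                              xtol=1e-10, rtol=1e-15)
    return gstar, ok


def _exact_fit_probe(
    g: np.ndarray,
    y: np.ndarray,
    params: PREModelParams,
    n_members: int,
    search: SearchConfig,
) -> np.ndarray | None:
    """Integer feasibility program: is there an N-multiset whose summed
    Gamma_2 responses match the ratio-inverted target within tolerance?

    Returns the member indices of a feasible multiset, or None (infeasible,
    non-invertible data, or time limit reached).
    """
    from scipy import sparse
    from scipy.optimize import Bounds, LinearConstraint, milp

    gstar, ok = _invert_ratio(y, params)
    a0 = g[:, ok].T
    target = n_members * gstar[ok]
    if a0.shape[0] < 1:
        return None
    scale = np.maximum(np.abs(target), 1.0)
    a = sparse.csr_matrix(a0 / scale[:, None])
    t = target / scale
    eps = search.probe_tolerance
    n_lib = g.shape[0]
    cons = [
        LinearConstraint(a, t - eps, t + eps),
        LinearConstraint(sparse.csr_matrix(np.ones((1, n_lib))), n_members, n_members),
    ]
    res = milp(
        c=np.zeros(n_lib),
        constraints=cons,
        integrality=np.ones(n_lib),
        bounds=Bounds(np.zeros(n_lib), np.full(n_lib, float(n_members))),
        options={"time_limit": search.probe_time_limit, "presolve": True},
    )
    if res.x is None:
        return None
    x = np.round(res.x).astype(int)
    if x.sum() != n_members or np.any(x < 0):
        return None
    return np.repeat(np.arange(n_lib), x)


def select_ensemble(
    lib: ConformerLibrary,
    measured: PREMeasurement,
    cfg: FitConfig = FitConfig(),
    sigma_floor: float = SIGMA_FLOOR,
    _rng: np.random.Generator | None = None,
) -> EnsembleFit:
    """Best fixed-size multiset of library conformers fitting the measurement."""
    if len(lib) == 0:
        raise EnsembleError("empty conformer library")
    if cfg.ensemble_size > len(lib):
        raise EnsembleError("ensemble_size exceeds library size")
    g, y, sig = _prepare_arrays(lib, measured, sigma_floor, cfg.noise_fraction)
    # discrepancy principle: expected chi^2 contribution of the declared noise
    target = float(np.sum(np.minimum((cfg.noise_fraction * y) / sig, 1.0) ** 2))
    rng = _rng if _rng is not None else np.random.default_rng(
        np.random.SeedSequence(cfg.seed)
    )
    best_idx, best_chi2 = None, np.inf
    if cfg.search.exact_probe:
        probe = _exact_fit_probe(g, y, lib.params, cfg.ensemble_size, cfg.search)
        if probe is not None:
            best_idx = probe
            best_chi2 = _chi2_of(g[probe].mean(axis=0), y, sig, lib.params)
    for _ in range(cfg.search.restarts):
        idx, chi2 = _climb(
            g, y, sig, lib.params, cfg.ensemble_size, cfg.search, rng, target=target
        )
        if chi2 < best_chi2:
            best_idx, best_chi2 = idx, chi2
        if best_chi2 <= target:
            break
    idx = np.sort(best_idx)
    counts: dict[str, int] = {}
    for i in idx:
        lab = lib.state_labels[i]
        counts[lab] = counts.get(lab, 0) + 1
    return EnsembleFit(
        member_ids=[lib.ids[i] for i in idx],
        member_indices=idx,
        chi2=best_chi2,
        state_counts=counts,
        com_mean=float(lib.heights[idx].mean()),
    )


def repeat_selection(
    lib: ConformerLibrary,
    measured: PREMeasurement,
    cfg: FitConfig = FitConfig(),
    states: tuple[StateDefinition, ...] = DEFAULT_STATES,
    sigma_floor: float = SIGMA_FLOOR,
) -> PopulationSummary:
    """Noise-perturbed selection repeats -> state populations, mean +/- SD.

    Each repeat perturbs the measured ratios with independent Gaussian noise
    of SD = noise_fraction * ratio (clipped to [0, 1]) and reruns the
    selection with a repeat-specific child seed, so repeats are independent
    yet reproducible.
    """
    if cfg.repeats < 2:
        raise EnsembleError("repeats must be >= 2 for an SD")
    state_names = [s.name for s in states] + [UNASSIGNED]
    fractions = np.zeros((cfg.repeats, len(state_names)))
    coms = np.zeros(cfg.repeats)
    chi2s = np.zeros(cfg.repeats)
    n = cfg.ensemble_size
    for r in range(cfg.repeats):
        noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2 * r]))
        search_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2 * r + 1]))
        meas_r = measured
        if cfg.perturb in ("data", "both") and cfg.noise_fraction > 0:
            y = measured.ratios
            y_pert = np.clip(
                y * (1.0 + cfg.noise_fraction * noise_rng.standard_normal(len(y))),
                0.0,
                1.0,
            )
            meas_r = measured.with_ratios(y_pert)
        fit = select_ensemble(lib, meas_r, cfg, sigma_floor, _rng=search_rng)
        for j, s in enumerate(state_names):
            fractions[r, j] = fit.state_counts.get(s, 0) / n
        coms[r] = fit.com_mean
        chi2s[r] = fit.chi2
    return PopulationSummary(
        states=state_names,
        per_repeat_fractions=pd.DataFrame(fractions, columns=state_names),
        com_per_repeat=coms,
        chi2_per_repeat=chi2s,
        ensemble_size=n,
    )


def compare_populations(
    a: PopulationSummary, b: PopulationSummary, state: str
) -> dict[str, float]:
    """Two-sided Welch t-test on the per-repeat fractions of one state."""
    for summ in (a, b):
        if state not in summ.states:
            raise EnsembleError(f"state {state!r} absent from summary")
    xa = a.per_repeat_fractions[state].to_numpy()
    xb = b.per_repeat_fractions[state].to_numpy()
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        # degenerate zero-variance samples: identical means -> no difference
        if xa[0] == xb[0]:
            return {"t_statistic": 0.0, "p_value": 1.0}
        return {"t_statistic": np.inf if xa[0] > xb[0] else -np.inf, "p_value": 0.0}
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return {"t_statistic": float(t), "p_value": float(p)}


def ensemble_com(fit: EnsembleFit, lib: ConformerLibrary) -> float:
    """Multiplicity-weighted mean G-domain COM height of the fit members (A)."""
    id_to_height = dict(zip(lib.ids, lib.heights))
    try:
        return float(np.mean([id_to_height[m] for m in fit.member_ids]))
    except KeyError as exc:
        raise EnsembleError(f"unknown member id {exc.args[0]!r}") from None
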