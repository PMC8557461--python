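"""Fitting season-specific fitnesses to genotype count time series.

A dataset is a chronological series of collections (June and September each
year), each recording male C/G allele counts (males are hemizygous) and
female CC/CG/GG genotype counts.  Consecutive collections delimit "seasons";
within each season the forward model iterates a fixed number of discrete
generations under one set of sex-specific viabilities (v_G for males; w_GG,
w_GC for females).

Two fitting routes are provided and, on interior data, agree:

* per-season nonlinear least squares on relative frequency differences
  (three free fitnesses versus three observable degrees of freedom, so an
  interior optimum drives the objective to zero), and
* maximum likelihood under binomial (male) × multinomial (female) sampling
  of the full trajectory, whose optimum then attains the saturated
  likelihood — the operational sense in which the least-squares fit *is*
  the maximum-likelihood fit.

Uncertainty is quantified by profile-likelihood intervals (Wilks χ²₁
calibration) and by a parametric bootstrap that treats the observed
frequencies as the truth; nested model variants are compared by AIC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .model import (
    FitnessCycle,
    PopulationState,
    SeasonFitness,
    _advance_scalar,
    advance_season,
)

__all__ = [
    "CollectionSample",
    "CountsDataset",
    "FitResult",
    "ProfileCurve",
    "IntervalEstimate",
    "ModelSpec",
    "season_objective",
    "fit_season",
    "trajectory_loglik",
    "saturated_loglik",
    "fit_full_model",
    "profile_ci",
    "parametric_bootstrap_ci",
    "compare_models",
    "default_ladder",
    "FITNESS_BOUNDS",
]

MONTH_ORDER = {"June": 0, "September": 1}
FITNESS_BOUNDS = (1e-4, 10.0)
_OBJ_EPS = 1e-6  # floor for observed-frequency denominators
CHI2_95_DF1 = 3.841458820694124  # chi2.ppf(0.95, 1)


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class CollectionSample:
    """Genotype counts from one field collection."""

    year: int
    month: str
    n_male_C: int
    n_male_G: int
    n_female_CC: int
    n_female_CG: int
    n_female_GG: int

    def __post_init__(self) -> None:
        if self.month not in MONTH_ORDER:
            raise ValueError(f"month must be June or September, got {self.month!r}")
        counts = (
            self.n_male_C,
            self.n_male_G,
            self.n_female_CC,
            self.n_female_CG,
            self.n_female_GG,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("each sex needs at least one individual")

    @property
    def n_males(self) -> int:
        return self.n_male_C + self.n_male_G

    @property
    def n_females(self) -> int:
        return self.n_female_CC + self.n_female_CG + self.n_female_GG

    @property
    def male_freq(self) -> float:
        """Observed G frequency among males."""
        return self.n_male_G / self.n_males

    @property
    def female_freqs(self) -> tuple[float, float, float]:
        """Observed (CC, CG, GG) frequencies among females."""
        n = self.n_females
        return (self.n_female_CC / n, self.n_female_CG / n, self.n_female_GG / n)

    @property
    def female_allele_freq(self) -> float:
        return (2 * self.n_female_GG + self.n_female_CG) / (2 * self.n_females)

    @property
    def all_flies_allele_freq(self) -> float:
        """G frequency over all X chromosomes in the collection (1/male, 2/female)."""
        g = self.n_male_G + self.n_female_CG + 2 * self.n_female_GG
        return g / (self.n_males + 2 * self.n_females)

    def observed_state(self) -> PopulationState:
        f = self.female_freqs
        return PopulationState(p_m=self.male_freq, f_CC=f[0], f_CG=f[1], f_GG=f[2])

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.year, MONTH_ORDER[self.month])


class CountsDataset:
    """Chronologically ordered collections; consecutive pairs define seasons 1..S."""

    def __init__(self, samples: Iterable[CollectionSample]) -> None:
        self.samples = sorted(samples, key=lambda s: s.sort_key)
        keys = [s.sort_key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (year, month) collections")
        if not self.samples:
            raise ValueError("dataset is empty")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def n_seasons(self) -> int:
        return len(self.samples) - 1

    def observed_states(self) -> list[PopulationState]:
        return [s.observed_state() for s in self.samples]


@dataclass
class FitResult:
    """Estimated parameters with fit diagnostics."""

    initial: PopulationState | None
    seasons: list[SeasonFitness]
    objective: float
    loglik: float
    n_params: int
    converged: bool
    n_restarts_used: int = 0
    name: str = "full"

    def cycle(self, generations_per_season: int = 5, use: slice | None = None) -> FitnessCycle:
        seasons = self.seasons if use is None else self.seasons[use]
        return FitnessCycle(tuple(seasons), generations_per_season)


@dataclass
class ProfileCurve:
    """Profile log-likelihood of one parameter over a grid."""

    param: str
    grid: np.ndarray
    loglik: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.loglik = np.asarray(self.loglik, dtype=float)
        if self.grid.shape != self.loglik.shape:
            raise ValueError("grid and loglik must have the same shape")


@dataclass(frozen=True)
class IntervalEstimate:
    lower: float
    upper: float
    level: float = 0.95
    method: str = "profile"
    open_lower: bool = False
    open_upper: bool = False


# ---------------------------------------------------------------------------
# per-season least squares


def _forward_tuple(
    state: tuple[float, float, float, float], v: float, gc: float, gg: float, g: int
) -> tuple[float, float, float, float]:
    for _ in range(g):
        state = _advance_scalar(*state, v, gc, gg)
    return state


def _predict_season_end(
    start: PopulationState, w: SeasonFitness, g: int
) -> PopulationState:
    p_m, f_CC, f_CG, f_GG = _forward_tuple(
        (start.p_m, start.f_CC, start.f_CG, start.f_GG), w.v_G, w.w_GC, w.w_GG, g
    )
    return PopulationState(p_m=p_m, f_CC=f_CC, f_CG=f_CG, f_GG=f_GG)


def season_objective(
    w: SeasonFitness,
    start: PopulationState,
    observed_end: PopulationState,
    g: int,
) -> float:
    """Sum of squared relative differences over {male p_G, female f_GG, f_CC}.

    Observed values are the denominators, floored at 1e-6 (with a warning)
    when an observable is zero.
    """
    start_t = (start.p_m, start.f_CC, start.f_CG, start.f_GG)
    obs = (observed_end.p_m, observed_end.f_GG, observed_end.f_CC)
    return _season_objective_t(
        (w.v_G, w.w_GG, w.w_GC), start_t, obs, g, warn_zero=True
    )


def _season_objective_t(
    x: Sequence[float],
    start: tuple[float, float, float, float],
    obs: tuple[float, float, float],
    g: int,
    warn_zero: bool = False,
) -> float:
    pred = _forward_tuple(start, x[0], x[2], x[1], g)
    total = 0.0
    for o, p in zip(obs, (pred[0], pred[3], pred[1])):
        if o <= 0.0:
            if warn_zero:
                warnings.warn(
                    "observed frequency is zero; flooring relative-difference "
                    f"denominator at {_OBJ_EPS}",
                    RuntimeWarning,
                    stacklevel=3,
                )
            o = _OBJ_EPS
        total += ((p - o) / o) ** 2
    return total


_LATTICE_STARTS = [
    (a, b, c) for a in (0.5, 1.5) for b in (0.5, 1.5) for c in (0.5, 1.5)
]


def fit_season(
    start: PopulationState,
    end_sample: CollectionSample,
    g: int = 5,
    bounds: tuple[float, float] = FITNESS_BOUNDS,
    n_restarts: int = 4,
    seed: int = 0,
    extra_starts: Sequence[tuple[float, float, float]] = (),
    lattice: bool = True,
) -> FitResult:
    """Least-squares fit of one season's (v_G, w_GG, w_GC).

    Bounded quasi-Newton (L-BFGS-B) from 8 deterministic lattice starts
    (skipped when ``lattice`` is off, e.g. for warm-started refits), any
    ``extra_starts``, and ``n_restarts`` seeded log-uniform random starts;
    the best objective wins.
    """
    observed_end = end_sample.observed_state()
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    starts = [np.clip(s, lo, hi) for s in _LATTICE_STARTS] if lattice else []
    starts += [np.clip(np.asarray(s, dtype=float), lo, hi) for s in extra_starts]
    starts += [
        np.exp(rng.uniform(np.log(max(lo, 0.05)), np.log(min(hi, 5.0)), size=3))
        for _ in range(n_restarts)
    ]

    start_t = (start.p_m, start.f_CC, start.f_CG, start.f_GG)
    obs = (observed_end.p_m, observed_end.f_GG, observed_end.f_CC)

    def f(x: np.ndarray) -> float:
        return _season_objective_t(x, start_t, obs, g)

    best = None
    any_converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for x0 in starts:
            res = minimize(f, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 3)
            any_converged = any_converged or res.success
            if best is None or res.fun < best.fun:
                best = res
    w_hat = SeasonFitness(v_G=best.x[0], w_GG=best.x[1], w_GC=best.x[2])
    pred = _predict_season_end(start, w_hat, g)
    ll = _sample_loglik(end_sample, pred)
    return FitResult(
        initial=None,
        seasons=[w_hat],
        objective=float(best.fun),
        loglik=ll,
        n_params=3,
        converged=bool(any_converged),
        n_restarts_used=len(starts),
        name="season",
    )


# ---------------------------------------------------------------------------
# trajectory likelihood


def _binom_logpmf(k: int, n: int, p: float) -> float:
    if p <= 0.0:
        return 0.0 if k == 0 else -math.inf
    if p >= 1.0:
        return 0.0 if k == n else -math.inf
    return (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log(1 - p)
    )


def _multinom_logpmf(counts: Sequence[int], probs: Sequence[float]) -> float:
    total = sum(counts)
    out = math.lgamma(total + 1)
    for k, p in zip(counts, probs):
        if p <= 0.0:
            if k > 0:
                return -math.inf
            continue
        out += k * math.log(p) - math.lgamma(k + 1)
    return out


def _sample_loglik_t(
    sample: CollectionSample, pred: tuple[float, float, float, float]
) -> float:
    ll = _binom_logpmf(sample.n_male_G, sample.n_males, pred[0])
    ll += _multinom_logpmf(
        (sample.n_female_CC, sample.n_female_CG, sample.n_female_GG),
        (pred[1], pred[2], pred[3]),
    )
    return ll


def _sample_loglik(sample: CollectionSample, pred: PopulationState) -> float:
    return _sample_loglik_t(sample, (pred.p_m, pred.f_CC, pred.f_CG, pred.f_GG))


def trajectory_loglik(
    initial: PopulationState,
    fitnesses: Sequence[SeasonFitness],
    data: CountsDataset,
    g: int = 5,
) -> float:
    """Binomial × multinomial log-likelihood of the whole count series.

    Predictions iterate the forward model from ``initial``; the first
    collection is compared against ``initial`` itself.  Returns −inf when a
    predicted frequency of zero meets a positive observed count.
    """
    if len(fitnesses) != data.n_seasons:
        raise ValueError("need one SeasonFitness per season")
    pred = initial
    ll = _sample_loglik(data.samples[0], pred)
    for w, sample in zip(fitnesses, data.samples[1:]):
        pred = _predict_season_end(pred, w, g)
        ll += _sample_loglik(sample, pred)
        if ll == -math.inf:
            return ll
    return ll


def saturated_loglik(data: CountsDataset) -> float:
    """Maximum attainable log-likelihood (predicted = sample frequencies)."""
    return sum(_sample_loglik(s, s.observed_state()) for s in data.samples)


# ---------------------------------------------------------------------------
# full-model fit


def _theta_from(initial: PopulationState, seasons: Sequence[SeasonFitness]) -> np.ndarray:
    head = [initial.p_m, initial.f_GG, initial.f_CC]
    body = [x for w in seasons for x in (w.v_G, w.w_GG, w.w_GC)]
    return np.array(head + body)


def _theta_to(theta: np.ndarray, n_seasons: int) -> tuple[PopulationState, list[SeasonFitness]]:
    p_m, f_GG, f_CC = theta[:3]
    f_CG = max(1.0 - f_GG - f_CC, 0.0)
    initial = PopulationState(p_m=p_m, f_CC=f_CC, f_CG=f_CG, f_GG=f_GG)
    seasons = [
        SeasonFitness(v_G=theta[3 + 3 * s], w_GG=theta[4 + 3 * s], w_GC=theta[5 + 3 * s])
        for s in range(n_seasons)
    ]
    return initial, seasons


def _full_negloglik(theta: np.ndarray, data: CountsDataset, g: int) -> float:
    if theta[1] + theta[2] >= 1.0 - 1e-9:  # infeasible female simplex corner
        excess = theta[1] + theta[2] - (1.0 - 1e-9)
        return 1e8 * (1.0 + excess)
    initial, seasons = _theta_to(theta, data.n_seasons)
    ll = trajectory_loglik(initial, seasons, data, g)
    if ll == -math.inf:
        return 1e8
    return -ll


def _sequential_fit(
    data: CountsDataset,
    g: int,
    seed: int,
    warm: Sequence[SeasonFitness] | None = None,
) -> tuple[PopulationState, list[SeasonFitness]]:
    """Initial state at the first sample's frequencies; each season fitted by
    least squares from the previous season's *predicted* end state, then
    refined against the season's count likelihood.

    The refinement matters when an observed class is zero: the relative-
    difference objective floors that denominator at 1e-6 and over-weights
    the term, whereas the binomial/multinomial likelihood handles zero
    counts natively.
    """
    initial = data.samples[0].observed_state()
    state = initial
    seasons: list[SeasonFitness] = []
    lo, hi = FITNESS_BOUNDS
    for s in range(data.n_seasons):
        extra = []
        if warm is not None:
            w = warm[s]
            extra.append((w.v_G, w.w_GG, w.w_GC))
        fit = fit_season(
            state,
            data.samples[s + 1],
            g=g,
            seed=seed + s,
            extra_starts=extra,
            lattice=warm is None,
            n_restarts=1 if warm is not None else 4,
        )
        w_ls = fit.seasons[0]
        sample = data.samples[s + 1]
        start_t = (state.p_m, state.f_CC, state.f_CG, state.f_GG)

        def negll(x: np.ndarray) -> float:
            pred = _forward_tuple(start_t, x[0], x[2], x[1], g)
            ll = _sample_loglik_t(sample, pred)
            return 1e8 if ll == -math.inf else -ll

        res = minimize(
            negll,
            np.array([w_ls.v_G, w_ls.w_GG, w_ls.w_GC]),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * 3,
        )
        if res.fun < negll(np.array([w_ls.v_G, w_ls.w_GG, w_ls.w_GC])):
            w_ls = SeasonFitness(v_G=res.x[0], w_GG=res.x[1], w_GC=res.x[2])
        seasons.append(w_ls)
        state = _predict_season_end(state, w_ls, g)
    return initial, seasons


def fit_full_model(
    data: CountsDataset,
    g: int = 5,
    seed: int = 0,
    polish: bool = True,
    polish_maxiter: int = 200,
) -> FitResult:
    """Maximum-likelihood fit of the full model: one (v_G, w_GG, w_GC) per
    season plus three initial-state frequencies (3S + 3 parameters).

    Strategy: a sequential per-season least-squares pass (which on interior
    data already attains the saturated likelihood) followed by an optional
    joint L-BFGS-B polish of the trajectory likelihood.
    """
    if len(data) < 2:
        raise ValueError("need at least two sampling points")
    initial, seasons = _sequential_fit(data, g, seed)
    theta = _theta_from(initial, seasons)
    n_params = 3 + 3 * data.n_seasons
    converged = True
    if polish:
        lo, hi = FITNESS_BOUNDS
        bounds = [(1e-6, 1 - 1e-6)] * 3 + [(lo, hi)] * (3 * data.n_seasons)
        res = minimize(
            _full_negloglik,
            theta,
            args=(data, g),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": polish_maxiter},
        )
        if res.fun <= _full_negloglik(theta, data, g):
            theta = res.x
    initial, seasons = _theta_to(theta, data.n_seasons)
    ll = trajectory_loglik(initial, seasons, data, g)
    obj = 0.0
    state = initial
    for s in range(data.n_seasons):
        obj += season_objective(
            seasons[s], state, data.samples[s + 1].observed_state(), g
        )
        state = _predict_season_end(state, seasons[s], g)
    return FitResult(
        initial=initial,
        seasons=seasons,
        objective=obj,
        loglik=ll,
        n_params=n_params,
        converged=converged,
        name="full",
    )


# ---------------------------------------------------------------------------
# profile likelihood


_PARAM_SLOT = {"v_G": 0, "w_GG": 1, "w_GC": 2}


def parse_param_id(param: str) -> tuple[int, str]:
    """``"3:v_G"`` → (season index 3, 'v_G'); seasons are 1-based."""
    season_s, name = param.split(":")
    season = int(season_s)
    if name not in _PARAM_SLOT:
        raise ValueError(f"unknown parameter name {name!r}")
    return season, name


def _profile_at(
    value: float,
    season: int,
    name: str,
    data: CountsDataset,
    g: int,
    fitted: FitResult,
    polish: bool,
    polish_maxiter: int = 60,
    fast: bool = False,
) -> float:
    """Profile log-likelihood with one season parameter fixed.

    The fixed parameter perturbs only its own season's predicted end state;
    downstream seasons re-fit (warm-started from the MLE) to re-absorb the
    shift, so the cheap pass re-optimizes seasons s..S sequentially.  An
    optional joint polish then refines all remaining parameters.
    """
    s_idx = season - 1
    initial = fitted.initial
    seasons = list(fitted.seasons)
    state = initial
    for s in range(s_idx):
        state = _predict_season_end(state, seasons[s], g)

    # re-fit the fixed-parameter season's two free fitnesses by likelihood
    slot = _PARAM_SLOT[name]
    free_slots = [i for i in range(3) if i != slot]
    sample = data.samples[s_idx + 1]
    lo, hi = FITNESS_BOUNDS

    def negll_season(x: np.ndarray) -> float:
        vals = [0.0, 0.0, 0.0]
        vals[slot] = value
        for i, fs in zip(x, free_slots):
            vals[fs] = i
        w = SeasonFitness(v_G=vals[0], w_GG=vals[1], w_GC=vals[2])
        pred = _predict_season_end(state, w, g)
        ll = _sample_loglik(sample, pred)
        return 1e8 if ll == -math.inf else -ll

    w_mle = seasons[s_idx]
    x0 = np.array([(w_mle.v_G, w_mle.w_GG, w_mle.w_GC)[i] for i in free_slots])
    starts = [np.clip(x0, lo, hi)]
    if not fast:
        starts += [np.array([1.0, 1.0]), np.array([0.5, 1.5])]
    best = None
    for x_start in starts:
        res = minimize(
            negll_season, x_start, method="L-BFGS-B", bounds=[(lo, hi)] * 2
        )
        if best is None or res.fun < best.fun:
            best = res
    vals = [0.0, 0.0, 0.0]
    vals[slot] = value
    for xv, fs in zip(best.x, free_slots):
        vals[fs] = xv
    seasons[s_idx] = SeasonFitness(v_G=vals[0], w_GG=vals[1], w_GC=vals[2])

    # downstream seasons re-fit from the perturbed predicted state
    state_after = _predict_season_end(state, seasons[s_idx], g)
    for s in range(s_idx + 1, data.n_seasons):
        refit = fit_season(
            state_after,
            data.samples[s + 1],
            g=g,
            n_restarts=0 if fast else 1,
            seed=1000 + s,
            extra_starts=[(seasons[s].v_G, seasons[s].w_GG, seasons[s].w_GC)],
            lattice=not fast,
        )
        seasons[s] = refit.seasons[0]
        state_after = _predict_season_end(state_after, seasons[s], g)

    ll = trajectory_loglik(initial, seasons, data, g)

    if polish:
        theta = _theta_from(initial, seasons)
        fixed_idx = 3 + 3 * s_idx + slot
        free_mask = np.ones(len(theta), dtype=bool)
        free_mask[fixed_idx] = False
        bounds = [(1e-6, 1 - 1e-6)] * 3 + [FITNESS_BOUNDS] * (3 * data.n_seasons)
        free_bounds = [b for b, m in zip(bounds, free_mask) if m]

        def negll(free: np.ndarray) -> float:
            full = theta.copy()
            full[free_mask] = free
            return _full_negloglik(full, data, g)

        res = minimize(
            negll,
            theta[free_mask],
            method="L-BFGS-B",
            bounds=free_bounds,
            options={"maxiter": polish_maxiter},
        )
        ll = max(ll, -res.fun)
    return ll


def profile_curve(
    data: CountsDataset,
    fitted: FitResult,
    param: str,
    grid: Sequence[float] | None = None,
    g: int = 5,
    polish: bool = False,
    n_grid: int = 21,
) -> ProfileCurve:
    """Profile log-likelihood of ``param`` (e.g. ``"9:v_G"``) over a grid."""
    season, name = parse_param_id(param)
    if not (1 <= season <= data.n_seasons):
        raise ValueError(f"season {season} outside 1..{data.n_seasons}")
    mle = getattr(fitted.seasons[season - 1], name)
    if grid is None:
        lo = max(FITNESS_BOUNDS[0], mle / 6.0, 0.02)
        hi = min(FITNESS_BOUNDS[1], max(mle * 6.0, 2.0))
        grid = np.geomspace(lo, hi, n_grid)
        grid = np.sort(np.append(grid, mle))
    grid = np.asarray(grid, dtype=float)
    ll = np.array(
        [_profile_at(v, season, name, data, g, fitted, polish) for v in grid]
    )
    return ProfileCurve(param=param, grid=grid, loglik=ll)


def profile_curvature(
    data: CountsDataset,
    fitted: FitResult,
    param: str,
    g: int = 5,
    rel_step: float = 0.05,
) -> float:
    """Negative second difference of the profile log-likelihood at the MLE.

    Approximates the observed (profile) Fisher information of one season
    parameter; ``1/sqrt(curvature)`` is a standard-error scale.  Weakly
    identified parameters have small curvature.
    """
    season, name = parse_param_id(param)
    mle = getattr(fitted.seasons[season - 1], name)
    delta = max(rel_step * abs(mle), 1e-4)
    ll = [
        _profile_at(v, season, name, data, g, fitted, polish=False, fast=True)
        for v in (mle - delta, mle, mle + delta)
    ]
    return -(ll[0] - 2 * ll[1] + ll[2]) / delta**2


def profile_ci(
    data: CountsDataset,
    fitted: FitResult,
    param: str,
    level: float = 0.95,
    grid: Sequence[float] | None = None,
    g: int = 5,
    polish: bool = False,
    tol: float = 1e-3,
) -> tuple[ProfileCurve, IntervalEstimate]:
    """Profile-likelihood confidence interval for one season fitness.

    The interval is {θ : 2(ℓ_max − ℓ_profile(θ)) ≤ χ²₁(level)}; endpoints
    are refined by bisection to ``tol`` in the parameter.  A profile that
    never crosses the threshold before the grid boundary yields an interval
    flagged open at that end.
    """
    season, name = parse_param_id(param)
    curve = profile_curve(data, fitted, param, grid=grid, g=g, polish=polish)
    mle = getattr(fitted.seasons[season - 1], name)
    ll_max = max(fitted.loglik, curve.loglik.max())
    thresh = ll_max - 0.5 * chi2.ppf(level, 1)

    def prof(v: float) -> float:
        return _profile_at(v, season, name, data, g, fitted, polish)

    inside = curve.loglik >= thresh

    def _bisect(v_out: float, v_in: float) -> float:
        for _ in range(60):
            if abs(v_in - v_out) < tol:
                break
            mid = 0.5 * (v_in + v_out)
            if prof(mid) >= thresh:
                v_in = mid
            else:
                v_out = mid
        return 0.5 * (v_in + v_out)

    idx_in = np.nonzero(inside)[0]
    if idx_in.size == 0:  # degenerate: fall back to the MLE point
        return curve, IntervalEstimate(mle, mle, level, "profile")
    lo_i, hi_i = idx_in[0], idx_in[-1]
    open_lower = bool(lo_i == 0)
    open_upper = bool(hi_i == len(curve.grid) - 1)
    lower = (
        curve.grid[0]
        if open_lower
        else _bisect(curve.grid[lo_i - 1], curve.grid[lo_i])
    )
    upper = (
        curve.grid[-1]
        if open_upper
        else _bisect(curve.grid[hi_i + 1], curve.grid[hi_i])
    )
    return curve, IntervalEstimate(
        float(lower), float(upper), level, "profile", open_lower, open_upper
    )


# ---------------------------------------------------------------------------
# parametric bootstrap


def _resample_dataset(data: CountsDataset, rng: np.random.Generator) -> CountsDataset:
    samples = []
    for s in data.samples:
        k = int(rng.binomial(s.n_males, s.male_freq))
        f = rng.multinomial(s.n_females, s.female_freqs)
        samples.append(
            CollectionSample(
                year=s.year,
                month=s.month,
                n_male_C=s.n_males - k,
                n_male_G=k,
                n_female_CC=int(f[0]),
                n_female_CG=int(f[1]),
                n_female_GG=int(f[2]),
            )
        )
    return CountsDataset(samples)


def parametric_bootstrap_ci(
    data: CountsDataset,
    g: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    warm: FitResult | None = None,
) -> dict[str, IntervalEstimate]:
    """Percentile bootstrap CIs for every season fitness parameter.

    The observed frequencies are taken as the truth; each replicate redraws
    all counts (binomial males, multinomial females, observed sample sizes)
    and re-fits the full model.  Individual fit failures are dropped; more
    than 5% failing is an error.
    """
    rng = np.random.default_rng(seed)
    if warm is None:
        warm = fit_full_model(data, g=g, seed=seed, polish=False)
    draws: dict[str, list[float]] = {
        f"{s + 1}:{name}": [] for s in range(data.n_seasons) for name in _PARAM_SLOT
    }
    n_fail = 0
    for b in range(n_boot):
        boot = _resample_dataset(data, rng)
        try:
            _, seasons = _sequential_fit(
                boot, g, seed=seed + 17 * b + 1, warm=warm.seasons
            )
        except Exception:
            n_fail += 1
            continue
        for s, w in enumerate(seasons):
            draws[f"{s + 1}:v_G"].append(w.v_G)
            draws[f"{s + 1}:w_GG"].append(w.w_GG)
            draws[f"{s + 1}:w_GC"].append(w.w_GC)
    if n_fail > 0.05 * n_boot:
        raise RuntimeError(f"{n_fail}/{n_boot} bootstrap fits failed")
    alpha = 100 * (1 - level) / 2
    out = {}
    for key, vals in draws.items():
        lo, hi = np.percentile(vals, [alpha, 100 - alpha])
        out[key] = IntervalEstimate(float(lo), float(hi), level, "parametric_bootstrap")
    return out


# ---------------------------------------------------------------------------
# model ladder & AIC


@dataclass(frozen=True)
class ModelSpec:
    """Constraint map for a nested model variant.

    ``male`` and ``female_hom`` (v_G and w_GG): "per_season", "constant",
    a fixed float, or — for ``male`` — "tied" (equal to w_GG, i.e. selection
    acts identically in both sexes).  ``female_het`` controls the
    heterozygote via ``het_param``: either the dominance h (w_GC = 1 +
    h·(w_GG − 1)) or w_GC directly; again "per_season", "constant" or a
    fixed float.  Three initial-state frequencies are always estimated.
    """

    name: str
    male: object = "per_season"
    female_hom: object = "per_season"
    female_het: object = "per_season"
    het_param: str = "h"

    def _block_count(self, constraint: object, n_seasons: int) -> int:
        if constraint == "per_season":
            return n_seasons
        if constraint == "constant":
            return 1
        if constraint == "tied":
            return 0
        if isinstance(constraint, (int, float)):
            return 0
        raise ValueError(f"bad constraint {constraint!r}")

    def n_params(self, n_seasons: int) -> int:
        return 3 + sum(
            self._block_count(c, n_seasons)
            for c in (self.male, self.female_hom, self.female_het)
        )

    def _bounds_for(self, which: str) -> tuple[float, float]:
        if which == "het" and self.het_param == "h":
            return (-3.0, 3.0)
        return FITNESS_BOUNDS

    def unpack(
        self, theta: np.ndarray, n_seasons: int
    ) -> tuple[PopulationState, list[SeasonFitness]]:
        p_m, f_GG, f_CC = theta[:3]
        f_CG = max(1.0 - f_GG - f_CC, 0.0)
        initial = PopulationState(p_m=p_m, f_CC=f_CC, f_CG=f_CG, f_GG=f_GG)
        pos = 3

        def block(constraint: object) -> list[float] | None:
            nonlocal pos
            if constraint == "per_season":
                vals = list(theta[pos : pos + n_seasons])
                pos += n_seasons
                return vals
            if constraint == "constant":
                v = theta[pos]
                pos += 1
                return [v] * n_seasons
            if constraint == "tied":
                return None
            return [float(constraint)] * n_seasons

        hom = block(self.female_hom)
        male = block(self.male)
        het = block(self.female_het)
        if male is None:
            male = list(hom)
        seasons = []
        for s in range(n_seasons):
            w_gg = hom[s]
            if self.het_param == "h":
                w_gc = 1.0 + het[s] * (w_gg - 1.0)
            else:
                w_gc = het[s]
            seasons.append(SeasonFitness(v_G=male[s], w_GG=w_gg, w_GC=max(w_gc, 0.0)))
        return initial, seasons

    def bounds(self, n_seasons: int) -> list[tuple[float, float]]:
        out: list[tuple[float, float]] = [(1e-6, 1 - 1e-6)] * 3
        for which, constraint in (
            ("hom", self.female_hom),
            ("male", self.male),
            ("het", self.female_het),
        ):
            k = self._block_count(constraint, n_seasons)
            out += [self._bounds_for(which)] * k
        return out

    def x0(self, data: CountsDataset) -> np.ndarray:
        s0 = data.samples[0].observed_state()
        head = [s0.p_m, s0.f_GG, s0.f_CC]
        n_extra = self.n_params(data.n_seasons) - 3
        neutral_het = 0.5 if self.het_param == "h" else 1.0
        body = []
        for which, constraint in (
            ("hom", self.female_hom),
            ("male", self.male),
            ("het", self.female_het),
        ):
            k = self._block_count(constraint, data.n_seasons)
            fill = neutral_het if which == "het" else 1.0
            body += [fill] * k
        assert len(body) == n_extra
        return np.array(head + body)


def fit_model(
    data: CountsDataset,
    spec: ModelSpec,
    g: int = 5,
    seed: int = 0,
    n_restarts: int = 3,
) -> FitResult:
    """Maximum-likelihood fit of a constrained model variant."""
    n_seasons = data.n_seasons
    bounds = spec.bounds(n_seasons)

    def negll(theta: np.ndarray) -> float:
        if theta[1] + theta[2] >= 1.0 - 1e-9:
            return 1e8 * (1.0 + theta[1] + theta[2])
        initial, seasons = spec.unpack(theta, n_seasons)
        ll = trajectory_loglik(initial, seasons, data, g)
        return 1e8 if ll == -math.inf else -ll

    rng = np.random.default_rng(seed)
    x0 = spec.x0(data)
    starts = [x0]
    for _ in range(n_restarts):
        jitter = x0.copy()
        for i, (lo, hi) in enumerate(bounds):
            jitter[i] = np.clip(x0[i] * rng.uniform(0.7, 1.4) + rng.normal(0, 0.02), lo, hi)
        starts.append(jitter)
    best = None
    converged = False
    for x_start in starts:
        res = minimize(negll, x_start, method="L-BFGS-B", bounds=bounds)
        converged = converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    initial, seasons = spec.unpack(best.x, n_seasons)
    ll = -best.fun
    return FitResult(
        initial=initial,
        seasons=seasons,
        objective=float("nan"),
        loglik=float(ll),
        n_params=spec.n_params(n_seasons),
        converged=converged,
        n_restarts_used=len(starts),
        name=spec.name,
    )


FULL_MODEL_SPEC = ModelSpec(
    name="full", male="per_season", female_hom="per_season",
    female_het="per_season", het_param="w_GC",
)


def default_ladder() -> list[ModelSpec]:
    """The default nested-model ladder: neutrality, constant sexually
    antagonistic selection (free or fixed dominance), purely fluctuating
    selection (G dominant or recessive in females), and fluctuating
    sexually antagonistic selection with fixed dominance."""
    return [
        ModelSpec("neutral", male=1.0, female_hom=1.0, female_het=0.0),
        ModelSpec("const_sa_h_free", male="constant", female_hom="constant",
                  female_het="constant"),
        ModelSpec("const_sa_recessive", male="constant", female_hom="constant",
                  female_het=0.0),
        ModelSpec("const_sa_dominant", male="constant", female_hom="constant",
                  female_het=1.0),
        ModelSpec("fluct_dominant", male="tied", female_hom="per_season",
                  female_het=1.0),
        ModelSpec("fluct_recessive", male="tied", female_hom="per_season",
                  female_het=0.0),
        ModelSpec("fluct_sa_fixed_h", male="per_season", female_hom="per_season",
                  female_het=0.0),
    ]


def compare_models(
    data: CountsDataset,
    ladder: Sequence[ModelSpec] | None = None,
    g: int = 5,
    seed: int = 0,
    include_full: bool = True,
) -> list[dict]:
    """Fit a model ladder and rank by AIC (= 2k − 2ℓ); ΔAIC is relative to
    the best model.  Returns rows sorted by AIC."""
    rows = []
    if include_full:
        full = fit_full_model(data, g=g, seed=seed)
        rows.append({"name": "full", "n_params": full.n_params, "loglik": full.loglik})
    for spec in ladder if ladder is not None else default_ladder():
        fit = fit_model(data, spec, g=g, seed=seed)
        rows.append({"name": spec.name, "n_params": fit.n_params, "loglik": fit.loglik})
    for r in rows:
        r["aic"] = 2 * r["n_params"] - 2 * r["loglik"]
    best = min(r["aic"] for r in rows)
    for r in rows:
        r["delta_aic"] = r["aic"] - best
    return sorted(rows, key=lambda r: r["aic"])
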