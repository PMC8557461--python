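"""Long-term outcome of seasonally cycling, sex-specific selection.

Iterates the parameterized recursions over many repeats of a season cycle
to decide whether the polymorphism is maintained or one allele fixes,
compares fluctuating selection against its time-averaged constant
counterpart, applies dominance overrides, and propagates parameter
uncertainty by profile-likelihood-weighted resampling of fitness sets.

For *constant* fitnesses an analytical cross-check is available: each
allele's growth factor when rare follows from the 2×2 linearization of the
recursions near the opposite fixation boundary, and a protected
polymorphism requires both factors to exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inference import ProfileCurve
from .model import (
    FitnessCycle,
    PopulationState,
    SeasonFitness,
    TrajectoryRecord,
    _advance_scalar,
    weighted_allele_frequency,
)

__all__ = [
    "OutcomeClass",
    "ParameterSetSample",
    "project",
    "classify_outcome",
    "constant_average_cycle",
    "override_dominance",
    "invasion_growth_factors",
    "is_protected_polymorphism",
    "sample_parameter_sets",
    "uncertainty_sweep",
]

DEFAULT_EPS = 1e-3


@dataclass(frozen=True)
class OutcomeClass:
    """Long-term classification of a trajectory."""

    label: str  # maintained | G_fixed | C_fixed
    final_frequency: float
    seasons: int

    def __post_init__(self) -> None:
        if self.label not in ("maintained", "G_fixed", "C_fixed"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class ParameterSetSample:
    """One sampled fitness set for a full cycle: one SeasonFitness per season."""

    seasons: tuple[SeasonFitness, ...]
    provenance: str = "profile_likelihood"


def project(
    cycle: FitnessCycle,
    start: PopulationState,
    n_seasons: int,
    record: str = "census",
) -> TrajectoryRecord:
    """Iterate the dynamics for ``n_seasons`` seasons, cycling the schedule.

    ``record="all"`` keeps every generation (index 0 = the start state;
    season boundaries at multiples of g); ``record="census"`` keeps only
    the start state and each season's end — the sampled life stage.
    """
    if n_seasons < 1:
        raise ValueError("n_seasons must be >= 1")
    if record not in ("all", "census"):
        raise ValueError("record must be 'all' or 'census'")
    g = cycle.generations_per_season
    cur = (start.p_m, start.f_CC, start.f_CG, start.f_GG)
    rows = [cur]
    boundaries = []
    for s in range(n_seasons):
        w = cycle.seasons[s % len(cycle)]
        v, wgc, wgg = w.v_G, w.w_GC, w.w_GG
        for _ in range(g):
            cur = _advance_scalar(*cur, v, wgc, wgg)
            if record == "all":
                rows.append(cur)
        if record == "census":
            rows.append(cur)
        boundaries.append(len(rows) - 1)
    arr = np.array(rows)
    return TrajectoryRecord(
        arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], season_boundaries=boundaries
    )


def classify_outcome(
    traj: TrajectoryRecord,
    eps: float = DEFAULT_EPS,
    cycle_length: int | None = None,
) -> OutcomeClass:
    """Maintained iff the weighted G frequency at every census of the final
    cycle lies in [eps, 1 − eps]; otherwise the nearer boundary names the
    fixing allele (frequency → 0 means G is lost, i.e. C fixes)."""
    if not traj.season_boundaries or len(traj.season_boundaries) < 10:
        raise ValueError("need a trajectory of >= 10 seasons")
    wf = traj.weighted_allele_frequency()
    n_seasons = len(traj.season_boundaries)
    k = cycle_length or min(8, n_seasons)
    census = wf[list(traj.season_boundaries[-k:])]
    final = float(wf[traj.season_boundaries[-1]])
    if np.all((census >= eps) & (census <= 1 - eps)):
        label = "maintained"
    elif final <= 0.5:
        label = "C_fixed"
    else:
        label = "G_fixed"
    return OutcomeClass(label=label, final_frequency=final, seasons=n_seasons)


def constant_average_cycle(cycle: FitnessCycle) -> FitnessCycle:
    """Length-1 cycle with each fitness replaced by its arithmetic mean over
    the seasons — the 'no fluctuations' comparison."""
    v = float(np.mean([w.v_G for w in cycle.seasons]))
    gg = float(np.mean([w.w_GG for w in cycle.seasons]))
    gc = float(np.mean([w.w_GC for w in cycle.seasons]))
    return FitnessCycle(
        (SeasonFitness(v_G=v, w_GG=gg, w_GC=gc),), cycle.generations_per_season
    )


def override_dominance(cycle: FitnessCycle, h: float) -> FitnessCycle:
    """Force the female dominance of G to ``h`` in every season:
    w_GC := 1 + h·(w_GG − 1); male and GG fitnesses untouched."""
    seasons = tuple(
        SeasonFitness(v_G=w.v_G, w_GG=w.w_GG, w_GC=max(1.0 + h * (w.w_GG - 1.0), 0.0))
        for w in cycle.seasons
    )
    return FitnessCycle(seasons, cycle.generations_per_season)


# ---------------------------------------------------------------------------
# linearized invasion analysis (constant environments)


def _rare_matrix_G(w: SeasonFitness) -> np.ndarray:
    """One-generation linearization of (f_CG, p_m) near fixation of C."""
    return np.array(
        [[w.w_GC / 2.0, w.w_GC], [w.v_G / 2.0, 0.0]]
    )


def _rare_matrix_C(w: SeasonFitness) -> np.ndarray:
    """Linearization of (f_CG, q_m) near fixation of G; selection is relative
    to the resident GG/G genotypes."""
    if w.w_GG <= 0 or w.v_G <= 0:
        raise ValueError("resident fitness must be positive for invasion analysis")
    a = w.w_GC / w.w_GG
    return np.array([[a / 2.0, a], [1.0 / (2.0 * w.v_G), 0.0]])


def invasion_growth_factors(cycle: FitnessCycle) -> tuple[float, float]:
    """Per-cycle growth factors (λ_G, λ_C) of each allele when rare.

    Leading eigenvalue modulus of the product of per-generation rare-allele
    matrices over one full cycle (g generations per season).  λ > 1 means
    the allele invades; both > 1 is a protected polymorphism.
    """
    g = cycle.generations_per_season
    prod_G = np.eye(2)
    prod_C = np.eye(2)
    for w in cycle.seasons:
        mg = np.linalg.matrix_power(_rare_matrix_G(w), g)
        mc = np.linalg.matrix_power(_rare_matrix_C(w), g)
        prod_G = mg @ prod_G
        prod_C = mc @ prod_C
    lam_G = float(np.max(np.abs(np.linalg.eigvals(prod_G))))
    lam_C = float(np.max(np.abs(np.linalg.eigvals(prod_C))))
    # report per-generation geometric mean so magnitudes are comparable
    n_gen = g * len(cycle)
    return lam_G ** (1.0 / n_gen), lam_C ** (1.0 / n_gen)


def is_protected_polymorphism(cycle: FitnessCycle) -> bool:
    lam_G, lam_C = invasion_growth_factors(cycle)
    return lam_G > 1.0 and lam_C > 1.0


# ---------------------------------------------------------------------------
# uncertainty propagation


def sample_parameter_sets(
    profiles: dict[str, ProfileCurve],
    n: int = 20_000,
    seed: int = 0,
    n_seasons: int = 8,
) -> list[ParameterSetSample]:
    """Draw fitness sets with each parameter sampled independently from its
    discretized profile likelihood (normalized to sum 1).

    ``profiles`` maps parameter ids ``"<season>:<name>"`` (seasons 1-based,
    names v_G/w_GG/w_GC) to profile curves; better-fitting values are
    sampled proportionally more often.  Parameter correlations are ignored,
    matching the independent-sampling construction.
    """
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for s in range(1, n_seasons + 1):
        for name in ("v_G", "w_GG", "w_GC"):
            key = f"{s}:{name}"
            if key not in profiles:
                raise KeyError(f"missing profile for parameter {key}")
            curve = profiles[key]
            ll = curve.loglik
            finite = np.isfinite(ll)
            if not finite.any():
                raise ValueError(f"profile for {key} is degenerate (all -inf)")
            w = np.zeros_like(ll)
            w[finite] = np.exp(ll[finite] - ll[finite].max())
            w /= w.sum()
            draws[key] = rng.choice(curve.grid, size=n, p=w)
    out = []
    for i in range(n):
        seasons = tuple(
            SeasonFitness(
                v_G=float(draws[f"{s}:v_G"][i]),
                w_GG=float(draws[f"{s}:w_GG"][i]),
                w_GC=float(draws[f"{s}:w_GC"][i]),
            )
            for s in range(1, n_seasons + 1)
        )
        out.append(ParameterSetSample(seasons=seasons))
    return out


def uncertainty_sweep(
    sets: Sequence[ParameterSetSample],
    start: PopulationState,
    n_seasons: int = 500,
    eps: float = DEFAULT_EPS,
    generations_per_season: int = 5,
) -> dict:
    """Classify the long-term outcome of every sampled fitness set.

    Returns the fraction of sets maintaining the polymorphism under the
    fluctuating cycle, the fraction of *those* that also maintain it under
    the constant time-averaged cycle, and per-set time-averaged fitnesses
    for the maintained sets (fluctuating-only vs both)."""
    if not sets:
        raise ValueError("sets must be nonempty")
    n_maint = 0
    n_const = 0
    averaged: list[dict] = []
    for ps in sets:
        cycle = FitnessCycle(ps.seasons, generations_per_season)
        traj = project(cycle, start, n_seasons, record="census")
        out = classify_outcome(traj, eps=eps, cycle_length=len(cycle))
        if out.label != "maintained":
            continue
        n_maint += 1
        avg = constant_average_cycle(cycle)
        traj_c = project(avg, start, n_seasons, record="census")
        out_c = classify_outcome(traj_c, eps=eps, cycle_length=1)
        both = out_c.label == "maintained"
        n_const += both
        w = avg.seasons[0]
        averaged.append(
            {"v_G": w.v_G, "w_GG": w.w_GG, "w_GC": w.w_GC, "constant_ok": both}
        )
    frac_maint = n_maint / len(sets)
    frac_const = n_const / n_maint if n_maint else float("nan")
    return {
        "n_sets": len(sets),
        "fraction_maintained": frac_maint,
        "fraction_constant_of_maintained": frac_const,
        "time_averaged_fitnesses": averaged,
    }
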