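"""Deterministic forward recursions for a biallelic X-linked locus.

The model tracks a single X-linked SNP with alleles C (reference) and G
(derived) in a large population with discrete, non-overlapping generations,
a 50:50 sex ratio and random union of gametes.  Males are hemizygous, so
the male state is a single allele frequency; the female state is the triple
of genotype frequencies (CC, CG, GG).  Viability selection acts between the
zygote and the adult census, with sex-specific relative fitnesses that may
change from season to season.  All fitnesses are relative to the C male /
CC female reference, which is fixed at 1.

Census convention: every :class:`PopulationState` handled here represents
*adults after selection* — the life stage caught in field traps — unless a
function explicitly says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PopulationState",
    "SeasonFitness",
    "FitnessCycle",
    "TrajectoryRecord",
    "zygote_state",
    "viability_select",
    "advance_generation",
    "advance_season",
    "weighted_allele_frequency",
    "NEUTRAL",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class PopulationState:
    """Adult population state: male G frequency and female genotype frequencies.

    Parameters
    ----------
    p_m : float
        Frequency of the G allele among males (hemizygous), in [0, 1].
    f_CC, f_CG, f_GG : float
        Genotype frequencies among females, summing to 1.
    """

    p_m: float
    f_CC: float
    f_CG: float
    f_GG: float

    def __post_init__(self) -> None:
        for name in ("p_m", "f_CC", "f_CG", "f_GG"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        total = self.f_CC + self.f_CG + self.f_GG
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"female genotype frequencies sum to {total}, not 1")
        # absorb tiny floating-point drift so downstream invariants hold exactly
        object.__setattr__(self, "p_m", min(max(self.p_m, 0.0), 1.0))
        if abs(total - 1.0) > _NORM_TOL:
            object.__setattr__(self, "f_CC", self.f_CC / total)
            object.__setattr__(self, "f_CG", self.f_CG / total)
            object.__setattr__(self, "f_GG", self.f_GG / total)

    @property
    def p_egg(self) -> float:
        """G frequency among eggs produced by these females."""
        return self.f_GG + 0.5 * self.f_CG

    @property
    def female_freqs(self) -> tuple[float, float, float]:
        return (self.f_CC, self.f_CG, self.f_GG)

    @classmethod
    def from_allele_frequency(cls, p: float) -> "PopulationState":
        """Neutral-equilibrium state at allele frequency ``p`` in both sexes."""
        q = 1.0 - p
        return cls(p_m=p, f_CC=q * q, f_CG=2 * p * q, f_GG=p * p)


@dataclass(frozen=True)
class SeasonFitness:
    """Relative viabilities for one season (C male and CC female = 1).

    ``v_G`` is the viability of G males relative to C males; ``w_GG`` and
    ``w_GC`` are the viabilities of GG and GC females relative to CC.
    """

    v_G: float
    w_GG: float
    w_GC: float

    def __post_init__(self) -> None:
        for name in ("v_G", "w_GG", "w_GC"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def is_neutral(self) -> bool:
        return self.v_G == 1.0 and self.w_GG == 1.0 and self.w_GC == 1.0

    @property
    def dominance(self) -> float:
        """Dominance h of G in females, w_GC = 1 + h (w_GG - 1)."""
        if self.w_GG == 1.0:
            return float("nan")
        return (self.w_GC - 1.0) / (self.w_GG - 1.0)


NEUTRAL = SeasonFitness(1.0, 1.0, 1.0)


@dataclass(frozen=True)
class FitnessCycle:
    """An ordered seasonal schedule of fitnesses.

    ``generations_per_season`` discrete generations elapse within each
    season; the default of 5 reflects roughly two generations per month in
    summer plus overwintering.
    """

    seasons: tuple[SeasonFitness, ...]
    generations_per_season: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "seasons", tuple(self.seasons))
        if len(self.seasons) < 1:
            raise ValueError("cycle needs at least one season")
        if self.generations_per_season < 1:
            raise ValueError("generations_per_season must be >= 1")

    def __len__(self) -> int:
        return len(self.seasons)


class TrajectoryRecord:
    """Per-generation record of iterated dynamics.

    Stores the state components as parallel arrays; index 0 is the initial
    state.  ``season_boundaries`` lists the generation indices at which a
    new season's fitnesses take over.
    """

    def __init__(
        self,
        p_m: Sequence[float],
        f_CC: Sequence[float],
        f_CG: Sequence[float],
        f_GG: Sequence[float],
        season_boundaries: Sequence[int] = (),
    ) -> None:
        self.p_m = np.asarray(p_m, dtype=float)
        self.f_CC = np.asarray(f_CC, dtype=float)
        self.f_CG = np.asarray(f_CG, dtype=float)
        self.f_GG = np.asarray(f_GG, dtype=float)
        self.season_boundaries = tuple(int(i) for i in season_boundaries)
        n = len(self.p_m)
        if not (len(self.f_CC) == len(self.f_CG) == len(self.f_GG) == n):
            raise ValueError("component arrays must have equal length")

    def __len__(self) -> int:
        return len(self.p_m)

    def state(self, i: int) -> PopulationState:
        return PopulationState(
            p_m=float(self.p_m[i]),
            f_CC=float(self.f_CC[i]),
            f_CG=float(self.f_CG[i]),
            f_GG=float(self.f_GG[i]),
        )

    @property
    def states(self) -> list[PopulationState]:
        return [self.state(i) for i in range(len(self))]

    @property
    def final(self) -> PopulationState:
        return self.state(len(self) - 1)

    def weighted_allele_frequency(self) -> np.ndarray:
        """Population-wide G frequency per generation (2/3 female, 1/3 male)."""
        p_f = self.f_GG + 0.5 * self.f_CG
        return (2.0 * p_f + self.p_m) / 3.0


def zygote_state(p_egg: float, p_sperm: float) -> PopulationState:
    """Pre-selection zygote frequencies from random union of gametes.

    Females receive one X from each parent; males receive their single X
    maternally, so the male zygote G frequency equals the egg frequency.
    """
    if not (0.0 <= p_egg <= 1.0 and 0.0 <= p_sperm <= 1.0):
        raise ValueError("gamete frequencies must lie in [0, 1]")
    return PopulationState(
        p_m=p_egg,
        f_CC=(1 - p_egg) * (1 - p_sperm),
        f_CG=p_egg * (1 - p_sperm) + (1 - p_egg) * p_sperm,
        f_GG=p_egg * p_sperm,
    )


class DegenerateSelectionError(ValueError):
    """All genotypes in one sex have zero weighted frequency."""


def viability_select(state: PopulationState, w: SeasonFitness) -> PopulationState:
    """Apply one round of viability selection and renormalize."""
    if w.is_neutral:
        return state
    male_total = (1 - state.p_m) + w.v_G * state.p_m
    if male_total <= 0:
        raise DegenerateSelectionError("male frequencies all zero after selection")
    female = (state.f_CC, w.w_GC * state.f_CG, w.w_GG * state.f_GG)
    female_total = sum(female)
    if female_total <= 0:
        raise DegenerateSelectionError("female frequencies all zero after selection")
    return PopulationState(
        p_m=w.v_G * state.p_m / male_total,
        f_CC=female[0] / female_total,
        f_CG=female[1] / female_total,
        f_GG=female[2] / female_total,
    )


def _advance_scalar(
    p_m: float,
    f_CC: float,
    f_CG: float,
    f_GG: float,
    v_G: float,
    w_GC: float,
    w_GG: float,
) -> tuple[float, float, float, float]:
    """One generation on raw floats (hot path for long projections)."""
    pe = f_GG + 0.5 * f_CG
    ps = p_m
    # zygotes
    z_CC = (1 - pe) * (1 - ps)
    z_CG = pe * (1 - ps) + (1 - pe) * ps
    z_GG = pe * ps
    # viability selection
    mt = (1 - pe) + v_G * pe
    ft = z_CC + w_GC * z_CG + w_GG * z_GG
    if mt <= 0 or ft <= 0:
        raise DegenerateSelectionError("zero total fitness in one sex")
    return (v_G * pe / mt, z_CC / ft, w_GC * z_CG / ft, w_GG * z_GG / ft)


def advance_generation(state: PopulationState, w: SeasonFitness) -> PopulationState:
    """One full life cycle: gametes → zygotes → viability selection → adults."""
    p_m, f_CC, f_CG, f_GG = _advance_scalar(
        state.p_m, state.f_CC, state.f_CG, state.f_GG, w.v_G, w.w_GC, w.w_GG
    )
    return PopulationState(p_m=p_m, f_CC=f_CC, f_CG=f_CG, f_GG=f_GG)


def advance_season(
    state: PopulationState, w: SeasonFitness, g: int
) -> TrajectoryRecord:
    """Iterate ``g`` generations under one season's fitnesses.

    Returns the full g+1 state trajectory; the dynamics between sampling
    points are often non-monotonic (male frequencies lag the female gamete
    pool by one generation), so intermediate states are of direct interest.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    cur = (state.p_m, state.f_CC, state.f_CG, state.f_GG)
    rows = [cur]
    for _ in range(g):
        cur = _advance_scalar(*cur, w.v_G, w.w_GC, w.w_GG)
        rows.append(cur)
    arr = np.array(rows)
    return TrajectoryRecord(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def weighted_allele_frequency(state: PopulationState) -> float:
    """Population-wide G frequency, (2·p_female_gamete + p_m)/3.

    Females carry two of every three X chromosomes, hence the 2:1 weighting.
    """
    return (2.0 * state.p_egg + state.p_m) / 3.0
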