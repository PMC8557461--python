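"""Synthetic data generators for every pipeline stage.

Generates (i) per-collection genotype count datasets with the sampling
structure of a twice-yearly field survey — 10 collections (June/September
over 5 years), 22–90 genotyped males per collection (515 total) and 84–132
females (1,028 total) — with true frequencies produced by the forward
model; (ii) phenotype tables with a known dominance coefficient; and
(iii) starvation-mortality time courses with a known LT50.  All generators
are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inference import CollectionSample, CountsDataset
from .model import FitnessCycle, PopulationState, SeasonFitness, advance_season
from .phenotypes import PhenotypeRecord, SurvivalCounts

__all__ = [
    "ScenarioSpec",
    "simulate_counts",
    "true_frequencies",
    "preset_scenarios",
    "simulate_phenotypes",
    "simulate_survival",
    "PRESETS",
]

MONTHS = ("June", "September")


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified simulation scenario.

    ``collections`` lists (year, month, n_males, n_females) in chronological
    order; consecutive collections are separated by one season of the truth
    cycle (cycled if the cycle is shorter than the number of seasons).
    """

    truth: FitnessCycle
    initial: PopulationState
    collections: tuple[tuple[int, str, int, int], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "collections", tuple(tuple(c) for c in self.collections)
        )
        prev = None
        for year, month, n_m, n_f in self.collections:
            if n_m < 1 or n_f < 1:
                raise ValueError("sample sizes must be positive")
            if month not in MONTHS:
                raise ValueError(f"month must be one of {MONTHS}")
            key = (year, MONTHS.index(month))
            if prev is not None and key <= prev:
                raise ValueError("collections must be chronological")
            prev = key

    @property
    def n_seasons(self) -> int:
        return len(self.collections) - 1


def true_frequencies(spec: ScenarioSpec) -> list[PopulationState]:
    """Adult (post-selection) frequencies at each collection under the truth."""
    states = [spec.initial]
    g = spec.truth.generations_per_season
    for s in range(spec.n_seasons):
        w = spec.truth.seasons[s % len(spec.truth)]
        states.append(advance_season(states[-1], w, g).final)
    return states


def simulate_counts(spec: ScenarioSpec) -> CountsDataset:
    """Draw a count dataset: binomial male allele counts, multinomial female
    genotype counts, at the truth frequencies and the spec's sample sizes."""
    rng = np.random.default_rng(spec.seed)
    states = true_frequencies(spec)
    samples = []
    for (year, month, n_m, n_f), st in zip(spec.collections, states):
        k_g = int(rng.binomial(n_m, st.p_m))
        f_counts = rng.multinomial(n_f, [st.f_CC, st.f_CG, st.f_GG])
        samples.append(
            CollectionSample(
                year=year,
                month=month,
                n_male_C=n_m - k_g,
                n_male_G=k_g,
                n_female_CC=int(f_counts[0]),
                n_female_CG=int(f_counts[1]),
                n_female_GG=int(f_counts[2]),
            )
        )
    return CountsDataset(samples)


def _field_survey_sizes(rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Per-collection sample sizes: uniform draws inside the survey's ranges,
    rescaled to the survey's totals (515 males, 1,028 females)."""

    def draw(lo: int, hi: int, total: int, k: int = 10) -> list[int]:
        sizes = rng.integers(lo, hi + 1, size=k).astype(float)
        sizes *= total / sizes.sum()
        out = np.clip(np.round(sizes).astype(int), lo, hi)
        # nudge to the exact total while staying inside the range
        diff = total - out.sum()
        i = 0
        while diff != 0:
            j = i % k
            step = 1 if diff > 0 else -1
            if lo <= out[j] + step <= hi:
                out[j] += step
                diff -= step
            i += 1
        return out.tolist()

    return draw(22, 90, 515), draw(84, 132, 1028)


def _schedule(rng: np.random.Generator) -> tuple[tuple[int, str, int, int], ...]:
    males, females = _field_survey_sizes(rng)
    cols = []
    i = 0
    for year in range(2016, 2021):
        for month in MONTHS:
            cols.append((year, month, males[i], females[i]))
            i += 1
    return tuple(cols)


def _sa_fluct_cycle(rng: np.random.Generator, n_seasons: int = 9) -> FitnessCycle:
    """Sexually antagonistic, seasonally fluctuating truth: G beneficial in
    females and deleterious in males in most seasons, mostly recessive."""
    seasons = []
    for s in range(n_seasons):
        if s == n_seasons - 2:  # one seasonal reversal, as real data suggest
            v, wgg = 1.0 + rng.uniform(0.1, 0.3), 1.0 - rng.uniform(0.1, 0.3)
        else:
            v, wgg = 1.0 - rng.uniform(0.05, 0.35), 1.0 + rng.uniform(0.05, 0.4)
        h = rng.uniform(0.0, 0.3)
        seasons.append(SeasonFitness(v_G=v, w_GG=wgg, w_GC=1 + h * (wgg - 1)))
    return FitnessCycle(tuple(seasons), generations_per_season=5)


def preset_scenarios(name: str, seed: int = 0) -> ScenarioSpec:
    """Named scenario presets; ``field_survey`` mirrors the field survey's
    structure (10 collections, 9 seasons, totals 515 males / 1,028 females)."""
    rng = np.random.default_rng(seed)
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    collections = _schedule(rng)
    initial = PopulationState.from_allele_frequency(0.35)
    if name == "neutral":
        cycle = FitnessCycle((SeasonFitness(1, 1, 1),) * 9)
    elif name == "sexually_antagonistic":
        seasons = tuple(
            SeasonFitness(v_G=0.8, w_GG=1.3, w_GC=1 + 0.2 * 0.3) for _ in range(9)
        )
        cycle = FitnessCycle(seasons)
    elif name == "fluctuating":
        seasons = tuple(
            SeasonFitness(v_G=w, w_GG=w, w_GC=w)
            for w in (1.25 if s % 2 == 0 else 0.8 for s in range(9))
        )
        cycle = FitnessCycle(seasons)
    else:  # field_survey
        cycle = _sa_fluct_cycle(rng)
    return ScenarioSpec(
        truth=cycle, initial=initial, collections=collections, seed=int(seed)
    )


PRESETS = ("neutral", "sexually_antagonistic", "fluctuating", "field_survey")


def simulate_phenotypes(
    means: dict[str, float],
    sd: float,
    n_per_class: int,
    seed: int = 0,
    background: str = "SYN",
    stage: str = "adult",
    trait: str = "synthetic_trait",
) -> list[PhenotypeRecord]:
    """Normal phenotype noise around per-genotype means ``{'CC':…, 'CG':…, 'GG':…}``.

    The implied true dominance is (μ_CG − μ_CC)/(μ_GG − μ_CC).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for genotype in ("CC", "CG", "GG"):
        values = rng.normal(means[genotype], sd, size=n_per_class)
        records.extend(
            PhenotypeRecord(background, stage, trait, genotype, float(v))
            for v in values
        )
    return records


def simulate_survival(
    lt50: float,
    slope: float,
    times: Sequence[float],
    n: int,
    seed: int = 0,
) -> SurvivalCounts:
    """Starvation time course: individual death times from a logistic law
    with median ``lt50`` (hours), observed as cumulative dead at ``times``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    times = list(times)
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    death_times = rng.logistic(loc=lt50, scale=1.0 / slope, size=n)
    rows = [(float(t), int(np.sum(death_times <= t)), n) for t in times]
    return SurvivalCounts(rows)
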