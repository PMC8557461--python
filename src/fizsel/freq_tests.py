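"""Statistical tests for allele-frequency differences between sexes and seasons.

Males are hemizygous (one X allele each); females contribute two alleles.
The tests operate on exact allele counts per collection, which matters
because sample sizes differ between sexes, seasons and years:

* a stratified Cochran–Mantel–Haenszel (CMH) test on 2×2 G/C allele-count
  tables (strata = collections for the sex contrast, years for the season
  contrast);
* a bootstrap test on the cumulative G-frequency difference across strata,
  with replicates drawn binomially at the pooled observed frequency of each
  stratum and the observed sample sizes, one-sided in the direction of the
  observed difference;
* per-collection Hardy–Weinberg χ² tests on female genotype counts with
  Bonferroni correction;
* binomial confidence intervals for per-collection frequencies;
* a bootstrap test of whether the between-collection variance in G
  frequency differs between the sexes; and
* a simulation-based power estimate for a consistent seasonal frequency
  shift in males.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.proportion import proportion_confint

from .inference import CollectionSample, CountsDataset, IntervalEstimate

__all__ = [
    "StratifiedTables",
    "BootstrapTestResult",
    "cmh_test",
    "sex_allele_tables",
    "season_allele_tables",
    "bootstrap_cumulative_diff_test",
    "hwe_test",
    "binomial_ci",
    "variance_sex_test",
    "seasonal_power",
]


class StratifiedTables:
    """A list of 2×2 allele-count tables (rows: groups; cols: G, C)."""

    def __init__(self, tables: Iterable[Sequence[Sequence[int]]]) -> None:
        self.tables = [np.asarray(t, dtype=int) for t in tables]
        for t in self.tables:
            if t.shape != (2, 2):
                raise ValueError("each stratum must be a 2x2 table")
            if np.any(t < 0):
                raise ValueError("counts must be >= 0")
            if t.sum() < 1:
                raise ValueError("each stratum needs a positive total")

    def __len__(self) -> int:
        return len(self.tables)


@dataclass(frozen=True)
class BootstrapTestResult:
    statistic: float  # cumulative G-frequency difference over strata
    mean_diff: float  # statistic / number of strata
    n_replicates: int
    p_value: float
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def cmh_test(
    tables: StratifiedTables, continuity: bool = True
) -> tuple[float, float]:
    """Cochran–Mantel–Haenszel χ² (1 df) across the strata; two-sided p.

    Strata with a zero row or column margin carry no information and are
    dropped with a warning.  Continuity correction on by default.
    """
    keep = []
    for i, t in enumerate(tables.tables):
        if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
            warnings.warn(
                f"dropping stratum {i}: zero margin", RuntimeWarning, stacklevel=2
            )
            continue
        keep.append(t)
    if not keep:
        raise ValueError("all strata are degenerate")
    res = StratifiedTable(keep).test_null_odds(correction=continuity)
    return float(res.statistic), float(res.pvalue)


def sex_allele_tables(dataset: CountsDataset) -> StratifiedTables:
    """One 2×2 table per collection: rows (female, male) × cols (G, C)."""
    tables = []
    for s in dataset:
        f_g = 2 * s.n_female_GG + s.n_female_CG
        f_c = 2 * s.n_female_CC + s.n_female_CG
        tables.append([[f_g, f_c], [s.n_male_G, s.n_male_C]])
    return StratifiedTables(tables)


def season_allele_tables(dataset: CountsDataset, sex: str) -> StratifiedTables:
    """One 2×2 table per year: rows (September, June) × cols (G, C) for one sex."""
    by_year: dict[int, dict[str, CollectionSample]] = {}
    for s in dataset:
        by_year.setdefault(s.year, {})[s.month] = s
    tables = []
    for year in sorted(by_year):
        pair = by_year[year]
        if "June" not in pair or "September" not in pair:
            raise ValueError(f"year {year} is missing a June or September collection")
        rows = []
        for month in ("September", "June"):
            c = pair[month]
            if sex == "M":
                rows.append([c.n_male_G, c.n_male_C])
            elif sex == "F":
                rows.append(
                    [
                        2 * c.n_female_GG + c.n_female_CG,
                        2 * c.n_female_CC + c.n_female_CG,
                    ]
                )
            else:
                raise ValueError("sex must be 'F' or 'M'")
        tables.append(rows)
    return StratifiedTables(tables)


def _sex_strata(dataset: CountsDataset) -> list[tuple[int, int, float, float, float]]:
    """(n_female_alleles, n_male_alleles, f_freq, m_freq, pooled) per collection."""
    out = []
    for s in dataset:
        nf = 2 * s.n_females
        nm = s.n_males
        fg = 2 * s.n_female_GG + s.n_female_CG
        pooled = (fg + s.n_male_G) / (nf + nm)
        out.append((nf, nm, fg / nf, s.male_freq, pooled))
    return out


def _season_strata(
    dataset: CountsDataset, sex: str
) -> list[tuple[int, int, float, float, float]]:
    """(n_sep, n_jun alleles, sep_freq, jun_freq, pooled-by-year) per year."""
    by_year: dict[int, dict[str, CollectionSample]] = {}
    for s in dataset:
        by_year.setdefault(s.year, {})[s.month] = s
    out = []
    for year in sorted(by_year):
        pair = by_year[year]
        if "June" not in pair or "September" not in pair:
            raise ValueError(f"year {year} is missing a June or September collection")

        def allele_counts(c: CollectionSample) -> tuple[int, int]:
            if sex == "M":
                return c.n_male_G, c.n_males
            if sex == "F":
                return 2 * c.n_female_GG + c.n_female_CG, 2 * c.n_females
            raise ValueError("sex must be 'F' or 'M'")

        g_sep, n_sep = allele_counts(pair["September"])
        g_jun, n_jun = allele_counts(pair["June"])
        pooled = (g_sep + g_jun) / (n_sep + n_jun)
        out.append((n_sep, n_jun, g_sep / n_sep, g_jun / n_jun, pooled))
    return out


def bootstrap_cumulative_diff_test(
    dataset: CountsDataset,
    contrast: str,
    sex: str = "F",
    n_rep: int = 10_000,
    seed: int = 0,
) -> BootstrapTestResult:
    """Bootstrap test on the cumulative G-frequency difference across strata.

    ``contrast="sex"`` compares females minus males per collection;
    ``contrast="season"`` compares September minus June per year for one
    sex.  Null replicates redraw each group's allele counts binomially at
    the stratum's pooled observed frequency with the observed sample sizes.
    The p-value is the fraction of replicates whose cumulative difference
    (in the fixed group order: female − male, or September − June) is
    greater than or equal to the observed value; a negative observed
    difference therefore yields a large p-value.
    """
    if contrast == "sex":
        strata = _sex_strata(dataset)
    elif contrast == "season":
        strata = _season_strata(dataset, sex)
    else:
        raise ValueError("contrast must be 'sex' or 'season'")
    n1 = np.array([s[0] for s in strata])
    n2 = np.array([s[1] for s in strata])
    observed = float(np.sum([s[2] - s[3] for s in strata]))
    pooled = np.array([s[4] for s in strata])
    rng = np.random.default_rng(seed)
    k1 = rng.binomial(n1, pooled, size=(n_rep, len(strata)))
    k2 = rng.binomial(n2, pooled, size=(n_rep, len(strata)))
    diffs = (k1 / n1 - k2 / n2).sum(axis=1)
    p = float(np.mean(diffs >= observed))
    return BootstrapTestResult(
        statistic=observed,
        mean_diff=observed / len(strata),
        n_replicates=n_rep,
        p_value=p,
        seed=seed,
    )


def hwe_test(
    sample: CollectionSample,
    allele_freq_source: str = "all_flies",
    n_tests: int = 1,
) -> dict:
    """χ² (1 df) test of female genotype counts against Hardy–Weinberg
    proportions at the G frequency from all flies (default) or females only;
    Bonferroni-adjusted p capped at 1.  Flags expected cells below 1."""
    if sample.n_females < 5:
        raise ValueError("need at least 5 females")
    if allele_freq_source == "all_flies":
        p = sample.all_flies_allele_freq
    elif allele_freq_source == "females_only":
        p = sample.female_allele_freq
    else:
        raise ValueError("allele_freq_source must be 'all_flies' or 'females_only'")
    q = 1.0 - p
    n = sample.n_females
    expected = np.array([q * q, 2 * p * q, p * p]) * n
    observed = np.array(
        [sample.n_female_CC, sample.n_female_CG, sample.n_female_GG], dtype=float
    )
    small_cells = bool(np.any(expected < 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    p_value = float(chi2.sf(stat, df=1))
    return {
        "chi2": stat,
        "p": p_value,
        "p_adjusted": min(1.0, p_value * n_tests),
        "allele_freq": p,
        "small_expected_cells": small_cells,
    }


def binomial_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> IntervalEstimate:
    """Binomial CI for a frequency: Wilson (default) or Clopper–Pearson."""
    if n == 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError("method must be 'wilson' or 'clopper_pearson'")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=sm_method)
    # boundary counts pin the corresponding bound exactly
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return IntervalEstimate(lo, hi, level, method)


def variance_sex_test(
    dataset: CountsDataset, n_rep: int = 10_000, seed: int = 0
) -> BootstrapTestResult:
    """Bootstrap test of excess between-collection variance in female vs male
    G frequency.

    Statistic: var(female per-collection frequency) − var(male).  Null
    replicates redraw both sexes' allele counts binomially from each
    collection's pooled frequency at the observed sample sizes, so the null
    keeps sampling error but removes any true sex difference."""
    if len(dataset) < 3:
        raise ValueError("need at least 3 collections")
    strata = _sex_strata(dataset)
    nf = np.array([s[0] for s in strata])
    nm = np.array([s[1] for s in strata])
    f_obs = np.array([s[2] for s in strata])
    m_obs = np.array([s[3] for s in strata])
    pooled = np.array([s[4] for s in strata])
    observed = float(np.var(f_obs, ddof=1) - np.var(m_obs, ddof=1))
    rng = np.random.default_rng(seed)
    kf = rng.binomial(nf, pooled, size=(n_rep, len(strata)))
    km = rng.binomial(nm, pooled, size=(n_rep, len(strata)))
    stat = np.var(kf / nf, axis=1, ddof=1) - np.var(km / nm, axis=1, ddof=1)
    p = float(np.mean(stat >= observed))
    return BootstrapTestResult(
        statistic=observed,
        mean_diff=observed,
        n_replicates=n_rep,
        p_value=p,
        seed=seed,
    )


def seasonal_power(
    sample_sizes: Sequence[tuple[int, int]],
    effect: float = 0.04,
    alpha: float = 0.05,
    base_freq: float = 0.3,
    n_sim: int = 1000,
    test: str = "bootstrap",
    n_rep: int = 2000,
    seed: int = 0,
) -> dict:
    """Power to detect a consistent seasonal frequency shift in males.

    ``sample_sizes`` lists (n_June, n_September) male counts per year.  Each
    simulation draws June counts at ``base_freq`` and September counts at
    ``base_freq + effect``, runs the chosen seasonal test (bootstrap default,
    or CMH) and counts p ≤ alpha.  Returns the power with its binomial SE.
    """
    if not (0 < base_freq < 1) or not (0 < base_freq + effect < 1):
        raise ValueError("effect pushes the frequency outside (0, 1)")
    rng = np.random.default_rng(seed)
    hits = 0
    years = list(range(2000, 2000 + len(sample_sizes)))
    for i in range(n_sim):
        samples = []
        for year, (n_jun, n_sep) in zip(years, sample_sizes):
            k_jun = int(rng.binomial(n_jun, base_freq))
            k_sep = int(rng.binomial(n_sep, base_freq + effect))
            # female counts are fillers: the seasonal male tests ignore them
            for month, n, k in (("June", n_jun, k_jun), ("September", n_sep, k_sep)):
                samples.append(
                    CollectionSample(
                        year=year,
                        month=month,
                        n_male_C=n - k,
                        n_male_G=k,
                        n_female_CC=1,
                        n_female_CG=1,
                        n_female_GG=1,
                    )
                )
        ds = CountsDataset(samples)
        if test == "bootstrap":
            res = bootstrap_cumulative_diff_test(
                ds, contrast="season", sex="M", n_rep=n_rep,
                seed=int(rng.integers(2**31 - 1)),
            )
            p = res.p_value
        elif test == "cmh":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                _, p = cmh_test(season_allele_tables(ds, "M"))
        else:
            raise ValueError("test must be 'bootstrap' or 'cmh'")
        hits += p <= alpha
    power = hits / n_sim
    se = float(np.sqrt(power * (1 - power) / n_sim))
    return {"power": power, "se": se, "n_sim": n_sim, "test": test, "effect": effect}
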