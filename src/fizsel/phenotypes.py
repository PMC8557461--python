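"""Dominance-coefficient estimation from phenotype data, and LT50.

The degree of dominance of the derived G allele for a quantitative trait is

    h = (X̄_CG − X̄_CC) / (X̄_GG − X̄_CC)

on the transformed trait scale: h = 0 means G fully recessive, h = 1 fully
dominant, 0.5 codominant, and h < 0 a heterozygote more extreme than the CC
homozygote.  h is invariant under affine transforms of the trait, so the
log-square-root transform (= 0.5·log) used to normalize most traits leaves
h identical to a plain log transform.

LT50 (median lethal time under starvation) is estimated by binomial
regression of the dead/alive split on time with a logit link; the standard
error comes from the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "PhenotypeRecord",
    "DominanceEstimate",
    "SurvivalCounts",
    "estimate_h",
    "bootstrap_h",
    "per_het_dominance",
    "transform_trait",
    "weighted_genotype_covariate",
    "lt50",
    "percent_change",
    "UndefinedDominanceError",
    "DOMINANCE_CLASSES",
]

FEMALE_GENOTYPES = ("CC", "CG", "GG")
MALE_GENOTYPES = ("C", "G")


@dataclass(frozen=True)
class PhenotypeRecord:
    """One trait measurement: genetic background, stage, trait, genotype, value."""

    background: str
    stage: str
    trait: str
    genotype: str
    value: float

    def __post_init__(self) -> None:
        if self.genotype not in FEMALE_GENOTYPES + MALE_GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if not math.isfinite(self.value):
            raise ValueError("value must be finite")


@dataclass(frozen=True)
class DominanceEstimate:
    h: float
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")
    resampled_mean: float = float("nan")
    n_boot: int = 0
    n_undefined: int = 0
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.n_boot and not (self.ci_lower <= self.ci_upper):
            raise ValueError("ci_lower must be <= ci_upper")


class SurvivalCounts:
    """Cumulative mortality time course: (time_h, n_dead, n_total) rows."""

    def __init__(self, rows: Iterable[tuple[float, int, int]]) -> None:
        self.rows = [(float(t), int(d), int(n)) for t, d, n in rows]
        times = [t for t, _, _ in self.rows]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        for t, d, n in self.rows:
            if not (0 <= d <= n):
                raise ValueError(f"n_dead={d} outside [0, n_total={n}] at t={t}")

    def __len__(self) -> int:
        return len(self.rows)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = np.array(self.rows, dtype=float)
        return a[:, 0], a[:, 1], a[:, 2]


class UndefinedDominanceError(ValueError):
    """Homozygote class means coincide; h has a zero denominator."""


def _class_values(
    records: Iterable[PhenotypeRecord], transform: str = "identity"
) -> dict[str, np.ndarray]:
    out: dict[str, list[float]] = {g: [] for g in FEMALE_GENOTYPES}
    for r in records:
        if r.genotype in out:
            out[r.genotype].append(r.value)
    missing = [g for g, v in out.items() if not v]
    if missing:
        raise ValueError(f"no records for genotype class(es) {missing}")
    return {g: transform_trait(np.array(v), transform) for g, v in out.items()}


def _h_from_means(m_cc: float, m_cg: float, m_gg: float) -> float:
    denom = m_gg - m_cc
    if denom == 0:
        raise UndefinedDominanceError("mean(GG) equals mean(CC)")
    return (m_cg - m_cc) / denom


def estimate_h(
    records: Iterable[PhenotypeRecord], transform: str = "identity"
) -> DominanceEstimate:
    """Point estimate of dominance from one background/stage/trait's records."""
    vals = _class_values(records, transform)
    h = _h_from_means(
        vals["CC"].mean(), vals["CG"].mean(), vals["GG"].mean()
    )
    return DominanceEstimate(h=float(h))


def bootstrap_h(
    records: Iterable[PhenotypeRecord],
    n_boot: int = 10_000,
    seed: int = 0,
    transform: str = "identity",
) -> DominanceEstimate:
    """Percentile bootstrap CI for h, resampling within each genotype class.

    Replicates with a zero denominator are dropped and counted; the result
    is flagged if more than 20% are undefined.
    """
    vals = _class_values(records, transform)
    for g, v in vals.items():
        if len(v) < 2:
            raise ValueError(f"need >= 2 records in class {g} to bootstrap")
    point = _h_from_means(vals["CC"].mean(), vals["CG"].mean(), vals["GG"].mean())
    rng = np.random.default_rng(seed)
    means = {}
    for g, v in vals.items():
        idx = rng.integers(0, len(v), size=(n_boot, len(v)))
        means[g] = v[idx].mean(axis=1)
    denom = means["GG"] - means["CC"]
    ok = denom != 0
    h_rep = (means["CG"][ok] - means["CC"][ok]) / denom[ok]
    n_undef = int(n_boot - ok.sum())
    if h_rep.size == 0:
        raise UndefinedDominanceError("all bootstrap replicates undefined")
    lo, hi = np.percentile(h_rep, [2.5, 97.5])
    return DominanceEstimate(
        h=float(point),
        ci_lower=float(lo),
        ci_upper=float(hi),
        resampled_mean=float(h_rep.mean()),
        n_boot=n_boot,
        n_undefined=n_undef,
        flagged=n_undef > 0.2 * n_boot,
    )


def per_het_dominance(
    het_values: Sequence[float], mean_cc: float, mean_gg: float
) -> np.ndarray:
    """Individual dominance value for each heterozygote, rescaled by the
    homozygote class means; their mean equals the point estimate of h."""
    denom = mean_gg - mean_cc
    if denom == 0:
        raise UndefinedDominanceError("mean(GG) equals mean(CC)")
    return (np.asarray(het_values, dtype=float) - mean_cc) / denom


def transform_trait(values: np.ndarray, kind: str = "identity") -> np.ndarray:
    """Trait normalization: ``log_sqrt`` (= 0.5·log x), ``sqrt`` or ``identity``."""
    values = np.asarray(values, dtype=float)
    if kind == "identity":
        return values
    if kind == "sqrt":
        bad = np.nonzero(values < 0)[0]
        if bad.size:
            raise ValueError(f"sqrt transform needs values >= 0; offending indices {bad.tolist()}")
        return np.sqrt(values)
    if kind == "log_sqrt":
        bad = np.nonzero(values <= 0)[0]
        if bad.size:
            raise ValueError(f"log_sqrt transform needs values > 0; offending indices {bad.tolist()}")
        return np.log(np.sqrt(values))
    raise ValueError(f"unknown transform {kind!r}")


DOMINANCE_CLASSES = {
    "recessive": 0.0,
    "partially_recessive": 0.25,
    "codominant": 0.5,
    "partially_dominant": 0.75,
    "dominant": 1.0,
    "heterozygote_extreme": -1.0,
}


def weighted_genotype_covariate(
    genotypes: Sequence[str],
    h: float | None = None,
    scheme: str = "estimated",
    dominance_class: str | None = None,
):
    """Numeric (or categorical) genotype covariate for downstream ANOVAs.

    CC → 0 and GG → 1 always; heterozygotes are weighted by the estimated
    dominance (``estimated``), by a canonical class value (``class``), or
    left as unordered labels (``categorical``).  The linear-model fit itself
    is left to standard least-squares machinery.
    """
    for g in genotypes:
        if g not in FEMALE_GENOTYPES:
            raise ValueError(f"unknown genotype label {g!r}")
    if scheme == "categorical":
        return list(genotypes)
    if scheme == "estimated":
        if h is None:
            raise ValueError("scheme='estimated' requires h")
        het = float(h)
    elif scheme == "class":
        if dominance_class not in DOMINANCE_CLASSES:
            raise ValueError(f"dominance_class must be one of {sorted(DOMINANCE_CLASSES)}")
        het = DOMINANCE_CLASSES[dominance_class]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    mapping = {"CC": 0.0, "CG": het, "GG": 1.0}
    return np.array([mapping[g] for g in genotypes])


def lt50(data: SurvivalCounts) -> tuple[float, float, bool]:
    """Median lethal time and its delta-method SE from a mortality course.

    Fits dead/alive ~ time by binomial GLM (logit); LT50 = −β₀/β₁.  On
    complete separation (mortality jumping 0→100% in one step) the counts
    are smoothed by a half-count continuity correction and the result is
    flagged.  Returns (LT50 hours, SE, flagged).
    """
    if len(data) < 3:
        raise ValueError("need >= 3 timepoints")
    t, dead, total = data.arrays()
    if np.any(np.diff(dead) < 0):
        raise ValueError("cumulative deaths must be nondecreasing")

    def _fit(d):
        endog = np.column_stack([d, total - d])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, sm.add_constant(t), family=sm.families.Binomial()).fit()
        return res

    flagged = False
    frac = dead / total
    separated = np.all((frac == 0) | (frac == 1))
    if separated:
        flagged = True
        dead = np.clip(dead.astype(float), 0.5, total - 0.5)
    res = _fit(dead)
    b0, b1 = res.params
    if b1 == 0:
        raise ValueError("zero slope; LT50 undefined")
    est = -b0 / b1
    # delta method: grad = (-1/b1, b0/b1**2)
    grad = np.array([-1.0 / b1, b0 / b1**2])
    se = float(np.sqrt(grad @ res.cov_params() @ grad))
    if not res.converged or abs(b1) > 1e3:
        flagged = True
    return float(est), se, flagged


def percent_change(a: float, b: float, decimals: int = 1) -> float:
    """Signed percent change of ``b`` relative to reference ``a``."""
    if a <= 0:
        raise ValueError("reference value must be > 0")
    return round(100.0 * (b - a) / a, decimals)
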