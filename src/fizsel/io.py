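"""Readers/writers for the package's TSV and JSON dialects, and run config.

Tabular data is plain tab-separated UTF-8 with a header row; lines starting
with ``#`` are comments.  Structured results are JSON with a schema-version
field.  All randomness in a pipeline run flows from the single configured
seed through named substreams.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import longterm
from .inference import (
    CollectionSample,
    CountsDataset,
    FitResult,
    compare_models,
    fit_full_model,
    parametric_bootstrap_ci,
)
from .freq_tests import (
    bootstrap_cumulative_diff_test,
    cmh_test,
    hwe_test,
    season_allele_tables,
    sex_allele_tables,
    variance_sex_test,
)
from .phenotypes import PhenotypeRecord, SurvivalCounts

SCHEMA_VERSION = "1.0"

COUNTS_COLUMNS = [
    "year",
    "month",
    "male_C",
    "male_G",
    "female_CC",
    "female_CG",
    "female_GG",
]

PHENOTYPE_COLUMNS = ["background", "stage", "trait", "genotype", "value"]
SURVIVAL_COLUMNS = ["group", "time_h", "n_dead", "n_total"]


@dataclass
class RunConfig:
    """Validated knobs for a full pipeline run."""

    generations_per_season: int = 5
    bounds: tuple[float, float] = (1e-4, 10.0)
    n_restarts: int = 4
    n_boot: int = 200
    n_rep: int = 10_000
    eps: float = 1e-3
    seed: int = 0
    cycle_order: str = "1-8"  # or "2-9"
    cmh_continuity: bool = True
    hwe_freq_source: str = "all_flies"
    ci_method: str = "profile"
    sweep_n: int = 2000
    sweep_seasons: int = 500

    def __post_init__(self) -> None:
        if self.generations_per_season < 1:
            raise ValueError("generations_per_season must be >= 1")
        if self.bounds[0] < 0 or self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must satisfy 0 <= lo < hi")
        if self.cycle_order not in ("1-8", "2-9"):
            raise ValueError("cycle_order must be '1-8' or '2-9'")
        if self.hwe_freq_source not in ("all_flies", "females_only"):
            raise ValueError("bad hwe_freq_source")
        if not (0 < self.eps < 0.5):
            raise ValueError("eps must be in (0, 0.5)")
        for name in ("n_restarts", "n_boot", "n_rep", "sweep_n", "sweep_seasons"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bounds" in raw:
            raw["bounds"] = tuple(raw["bounds"])
        return cls(**raw)

    def substream(self, name: str) -> int:
        """Deterministic per-stage seed below 2**31, derived from the run seed."""
        h = np.uint32(self.seed)
        for ch in name:
            h = np.uint32(h * np.uint32(31) + np.uint32(ord(ch)))
        return int(h % np.uint32(2**31 - 1))


# ---------------------------------------------------------------------------
# counts I/O


def read_counts(path: str | Path) -> CountsDataset:
    """Read a per-collection counts TSV and return a chronologically sorted,
    validated dataset.  Malformed or negative rows fail with a line number."""
    path = Path(path)
    samples = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != COUNTS_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: header must be {COUNTS_COLUMNS}, got {header}"
                    )
                continue
            if len(fields) != len(COUNTS_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(COUNTS_COLUMNS)} fields")
            try:
                year = int(fields[0])
                counts = [int(x) for x in fields[2:]]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            if any(c < 0 for c in counts):
                raise ValueError(f"{path}:{lineno}: negative count")
            try:
                samples.append(
                    CollectionSample(
                        year=year,
                        month=fields[1],
                        n_male_C=counts[0],
                        n_male_G=counts[1],
                        n_female_CC=counts[2],
                        n_female_CG=counts[3],
                        n_female_GG=counts[4],
                    )
                )
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    if header is None:
        raise ValueError(f"{path}: empty file")
    return CountsDataset(samples)


def write_counts(dataset: CountsDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COUNTS_COLUMNS) + "\n")
        for s in dataset:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.year,
                        s.month,
                        s.n_male_C,
                        s.n_male_G,
                        s.n_female_CC,
                        s.n_female_CG,
                        s.n_female_GG,
                    )
                )
                + "\n"
            )


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if list(df.columns) != PHENOTYPE_COLUMNS:
        raise ValueError(f"phenotype TSV must have columns {PHENOTYPE_COLUMNS}")
    return [
        PhenotypeRecord(r.background, r.stage, r.trait, r.genotype, float(r.value))
        for r in df.itertuples()
    ]


def write_phenotypes(records: list[PhenotypeRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_survival(path: str | Path) -> dict[str, SurvivalCounts]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != SURVIVAL_COLUMNS:
        raise ValueError(f"survival TSV must have columns {SURVIVAL_COLUMNS}")
    out = {}
    for group, sub in df.groupby("group"):
        out[str(group)] = SurvivalCounts(
            list(zip(sub.time_h, sub.n_dead, sub.n_total))
        )
    return out


def fit_result_to_dict(fit: FitResult) -> dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "name": fit.name,
        "objective": fit.objective,
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "converged": fit.converged,
        "seasons": [
            {"v_G": w.v_G, "w_GG": w.w_GG, "w_GC": w.w_GC} for w in fit.seasons
        ],
    }
    if fit.initial is not None:
        s = fit.initial
        d["initial"] = {"p_m": s.p_m, "f_CC": s.f_CC, "f_CG": s.f_CG, "f_GG": s.f_GG}
    return d


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig, counts_path: str | Path, out_dir: str | Path) -> dict:
    """End-to-end analysis of a counts file: frequency tests, full-model fit,
    bootstrap CIs, AIC ladder, and long-term projections.  Artifacts are
    written under ``out_dir``; partial results are preserved on failure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = read_counts(counts_path)
    g = config.generations_per_season
    results: dict = {"schema_version": SCHEMA_VERSION, "config": asdict(config)}
    timings: dict[str, float] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            results[name] = fn()
        except Exception as e:  # preserve partial results
            results[name] = {"error": str(e)}
            results.setdefault("failed_stages", []).append(name)
        timings[name] = round(time.perf_counter() - t0, 3)

    def _tests():
        out = {}
        stat, p = cmh_test(sex_allele_tables(data), continuity=config.cmh_continuity)
        out["cmh_sex"] = {"statistic": stat, "p": p}
        for sex in ("F", "M"):
            stat, p = cmh_test(
                season_allele_tables(data, sex), continuity=config.cmh_continuity
            )
            out[f"cmh_season_{sex}"] = {"statistic": stat, "p": p}
        b = bootstrap_cumulative_diff_test(
            data, "sex", n_rep=config.n_rep, seed=config.substream("boot_sex")
        )
        out["bootstrap_sex"] = {"delta": b.mean_diff, "p": b.p_value}
        for sex in ("F", "M"):
            b = bootstrap_cumulative_diff_test(
                data, "season", sex=sex, n_rep=config.n_rep,
                seed=config.substream(f"boot_season_{sex}"),
            )
            out[f"bootstrap_season_{sex}"] = {"delta": b.mean_diff, "p": b.p_value}
        v = variance_sex_test(
            data, n_rep=config.n_rep, seed=config.substream("variance")
        )
        out["variance_sex"] = {"statistic": v.statistic, "p": v.p_value}
        out["hwe"] = [
            hwe_test(s, config.hwe_freq_source, n_tests=len(data)) for s in data
        ]
        return out

    stage("freq_tests", _tests)

    fit_holder: dict = {}

    def _fit():
        fit = fit_full_model(data, g=g, seed=config.substream("fit"))
        fit_holder["fit"] = fit
        return fit_result_to_dict(fit)

    stage("full_fit", _fit)

    def _bootstrap():
        cis = parametric_bootstrap_ci(
            data, g=g, n_boot=config.n_boot, seed=config.substream("bootstrap"),
            warm=fit_holder.get("fit"),
        )
        return {k: [ci.lower, ci.upper] for k, ci in cis.items()}

    stage("bootstrap_ci", _bootstrap)

    def _aic():
        return compare_models(data, g=g, seed=config.substream("aic"))

    stage("aic", _aic)

    def _project():
        fit = fit_holder["fit"]
        if config.cycle_order == "1-8":
            use = slice(0, min(8, data.n_seasons))
        else:
            use = slice(max(0, data.n_seasons - 8), data.n_seasons)
        cycle = fit.cycle(g, use=use)
        start = data.samples[-1].observed_state()
        n_seasons = config.sweep_seasons
        traj = longterm.project(cycle, start, n_seasons, record="census")
        out = longterm.classify_outcome(traj, eps=config.eps, cycle_length=len(cycle))
        avg = longterm.constant_average_cycle(cycle)
        traj_c = longterm.project(avg, start, n_seasons, record="census")
        out_c = longterm.classify_outcome(traj_c, eps=config.eps, cycle_length=1)
        over = longterm.override_dominance(cycle, 0.715)
        traj_o = longterm.project(over, start, n_seasons, record="census")
        out_o = longterm.classify_outcome(traj_o, eps=config.eps, cycle_length=len(cycle))
        return {
            "fluctuating": asdict(out),
            "constant_average": asdict(out_c),
            "dominance_override_0.715": asdict(out_o),
        }

    stage("projection", _project)

    results["timings_s"] = timings
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results
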