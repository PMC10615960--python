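"""The Monte Carlo replication engine: generate, fit, test, aggregate.

Empirical power for a parameter is the proportion of simulated samples in
which its H0: parameter = 0 is rejected.  Each replication draws a fresh
sample from the population model conditional on the fixed design, fits the
analysis model, and runs the requested tests for every free and defined
parameter.  Aggregation reports, per parameter: the average estimate, the
average bias against the population value (flagged when |bias| >= 0.10),
the coverage of the delta-method CI, and power per method.

Seeding: replication r uses SeedSequence([seed, r]) for data and
SeedSequence([seed, r, 1]) for the MCCI draws, so results are reproducible
for any worker count and the interval noise is decoupled from the data
noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datagen import generate_multigroup_sample, generate_sample
from .design import DesignMatrix
from .estimate import fit_path_model
from .infer import TestResult, delta_test, mcci, wald_test
from .model import ModelError, ModelSpec

__all__ = ["StudySpec", "ReplicationRecord", "PowerSummary",
           "run_power_study", "summarize", "power_curve"]

BIAS_FLAG_THRESHOLD = 0.10
CONVERGENCE_WARNING_RATE = 0.95


@dataclass(frozen=True)
class StudySpec:
    """A full Monte Carlo power study.

    ``population`` generates the data; ``analysis`` is fitted to each sample
    (they may differ, e.g. a heteroskedastic truth analysed under
    constraints).  ``design`` is a DesignMatrix for single-group models or a
    mapping group name -> DesignMatrix | group size for multigroup models.
    """

    population: ModelSpec
    analysis: ModelSpec
    design: DesignMatrix | Mapping[str, object]
    nrep: int = 1000
    seed: int | tuple = 12345
    alpha: float = 0.05
    methods: tuple[str, ...] = ("delta", "mcci")
    mcci_draws: int = 20_000
    name: str = "study"

    def __post_init__(self):
        if self.nrep < 1:
            raise ModelError("nrep must be at least 1")
        if not 0 < self.alpha < 1:
            raise ModelError("alpha must be in (0, 1)")
        bad = set(self.methods) - {"delta", "mcci"}
        if bad:
            raise ModelError(f"unknown test methods {sorted(bad)}")


@dataclass(frozen=True)
class ReplicationRecord:
    index: int
    converged: bool
    estimates: dict[str, float] = field(default_factory=dict)
    defined_values: dict[str, float] = field(default_factory=dict)
    tests: dict[tuple[str, str], TestResult] = field(default_factory=dict)


@dataclass(frozen=True)
class PowerSummary:
    """Per-parameter aggregation of a power study."""

    table: pd.DataFrame  # indexed by parameter
    n_converged: int
    nrep: int
    alpha: float

    def power(self, parameter: str, method: str = "delta") -> float:
        return float(self.table.loc[parameter, f"power_{method}"])

    def to_dataframe(self) -> pd.DataFrame:
        return self.table.reset_index(names="parameter")


def _seed_list(seed) -> list[int]:
    if isinstance(seed, (tuple, list)):
        return [int(s) for s in seed]
    return [int(seed)]


def population_values_for(analysis: ModelSpec,
                          population: ModelSpec) -> dict[str, float | None]:
    """Population value per analysis parameter (free labels and defined).

    Each analysis label's value is read from the population matrices at the
    cells the label binds; a shared label bound to cells whose population
    values disagree has no single population value (None -> bias/coverage
    reported as missing).  Nuisance intercepts (no mean structure) are 0 in
    the population.  Defined parameters are evaluated at the label values.
    """
    out: dict[str, float | None] = {}
    for lab, cells in analysis.free_index.items():
        vals = set()
        ok = True
        for g, role, idx in cells:
            mats = population.groups.get(g)
            if mats is None or role not in mats:
                ok = False
                break
            vals.add(float(mats[role].population[idx]))
        if ok and len(vals) == 1:
            out[lab] = vals.pop()
        else:
            out[lab] = None
    if not population.meanstructure:
        # nuisance intercepts: population intercept is zero without mean structure
        for v in analysis.endogenous:
            out.setdefault(f"_alpha.{v}", 0.0)
            for g in analysis.group_names:
                out.setdefault(f"_alpha.{v}.{g}", 0.0)
    scope: dict[str, float] = {k: v for k, v in out.items() if v is not None}
    for d in analysis.defined:
        try:
            val = d.expression.evaluate(scope)
            scope[d.name] = val
            out[d.name] = float(val)
        except Exception:
            out[d.name] = None
    return out


def _run_one(study: StudySpec, r: int) -> ReplicationRecord:
    data_seed = np.random.SeedSequence(_seed_list(study.seed) + [r])
    if isinstance(study.design, DesignMatrix):
        data = generate_sample(study.population, study.design, data_seed)
    else:
        data = generate_multigroup_sample(study.population, dict(study.design),
                                          data_seed)
    fit = fit_path_model(study.analysis, data)
    if not fit.converged or fit.vcov is None:
        return ReplicationRecord(index=r, converged=False)

    tests: dict[tuple[str, str], TestResult] = {}
    for lab in fit.labels:
        se = fit.se(lab)
        if se > 0 and np.isfinite(se):
            tests[(lab, "delta")] = wald_test(lab, fit.estimates[lab], se,
                                              study.alpha)
    for d in study.analysis.defined:
        tests[(d.name, "delta")] = delta_test(fit, d, study.alpha)
    if "mcci" in study.methods and study.analysis.defined:
        mcci_seed = np.random.SeedSequence(_seed_list(study.seed) + [r, 1])
        for t in mcci(fit, study.analysis.defined, draws=study.mcci_draws,
                      alpha=study.alpha, seed=mcci_seed):
            tests[(t.parameter, "mcci")] = t
    return ReplicationRecord(index=r, converged=True,
                             estimates=dict(fit.estimates),
                             defined_values=dict(fit.defined_values),
                             tests=tests)


def run_power_study(study: StudySpec,
                    progress: bool = False
                    ) -> tuple[PowerSummary, list[ReplicationRecord]]:
    """Replicate generate -> fit -> test and aggregate the results."""
    records = [_run_one(study, r) for r in range(study.nrep)]
    n_conv = sum(rec.converged for rec in records)
    if n_conv == 0:
        raise ModelError("no replication converged; check the study spec")
    if n_conv < CONVERGENCE_WARNING_RATE * study.nrep:
        warnings.warn(
            f"only {n_conv}/{study.nrep} replications converged",
            stacklevel=2)
    pop_values = population_values_for(study.analysis, study.population)
    summary = summarize(records, pop_values, study.alpha, nrep=study.nrep)
    return summary, records


def summarize(records: Sequence[ReplicationRecord],
              population_values: Mapping[str, float | None],
              alpha: float, nrep: int | None = None) -> PowerSummary:
    """Aggregate replication records into a per-parameter summary table."""
    conv = [r for r in records if r.converged]
    if not conv:
        raise ModelError("no converged replications to summarize")
    params: list[str] = []
    for rec in conv:
        for p in list(rec.estimates) + list(rec.defined_values):
            if p not in params:
                params.append(p)
    rows = []
    for p in params:
        ests = np.array([rec.estimates.get(p, rec.defined_values.get(p))
                         for rec in conv], dtype=float)
        est_avg = float(np.nanmean(ests))
        pop = population_values.get(p)
        bias = est_avg - pop if pop is not None else np.nan
        delta_ts = [rec.tests.get((p, "delta")) for rec in conv]
        delta_ts = [t for t in delta_ts if t is not None]
        power_delta = (np.mean([t.reject for t in delta_ts])
                       if delta_ts else np.nan)
        if pop is not None and delta_ts:
            coverage = float(np.mean([t.ci_low <= pop <= t.ci_high
                                      for t in delta_ts]))
        else:
            coverage = np.nan
        mcci_ts = [rec.tests.get((p, "mcci")) for rec in conv]
        mcci_ts = [t for t in mcci_ts if t is not None]
        power_mcci = (np.mean([t.reject for t in mcci_ts])
                      if mcci_ts else np.nan)
        rows.append({
            "parameter": p,
            "estimate_average": est_avg,
            "average_bias": float(bias) if bias == bias else np.nan,
            "bias_flag": bool(abs(bias) >= BIAS_FLAG_THRESHOLD)
                         if bias == bias else False,
            "coverage": coverage,
            "power_delta": float(power_delta),
            "power_mcci": float(power_mcci),
        })
    table = pd.DataFrame(rows).set_index("parameter")
    return PowerSummary(table=table, n_converged=len(conv),
                        nrep=nrep if nrep is not None else len(records),
                        alpha=alpha)


def power_curve(study_builder, n_grid: Sequence[int],
                seed: int | None = None) -> pd.DataFrame:
    """Power as a function of per-cell (or per-group) sample size.

    ``study_builder(n)`` must return the StudySpec for one grid point —
    including re-solving the standardization, whose covariate moments depend
    on n through the unbiased divisor.  Grid points get independent seed
    substreams.  Returns a long table (N, parameter, method, power) sorted
    by N.
    """
    grid = sorted(set(int(n) for n in n_grid))
    if not grid:
        raise ModelError("sample-size grid is empty")
    rows = []
    for i, n in enumerate(grid):
        study = study_builder(n)
        if seed is not None:
            study = replace(study, seed=(seed, 7000 + i))
        summary, _ = run_power_study(study)
        for p, row in summary.table.iterrows():
            for method in study.methods:
                val = row[f"power_{method}"]
                if val == val:
                    rows.append({"N": study_n(study), "n_per_cell": n,
                                 "parameter": p, "method": method,
                                 "power": float(val)})
    return pd.DataFrame(rows)


def study_n(study: StudySpec) -> int:
    """Total number of observations per replication."""
    if isinstance(study.design, DesignMatrix):
        return study.design.n
    total = 0
    for d in study.design.values():
        total += d.n if isinstance(d, DesignMatrix) else int(d)
    return total
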