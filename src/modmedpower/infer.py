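"""Hypothesis tests for estimated and defined parameters.

Two tests of H0: parameter = 0 are provided, matching the two ways power is
usually reported for indirect effects:

* delta-method Wald test — z = estimate / SE with the delta-method SE; its
  normal-theory CI is symmetric and can over- or under-cover for products of
  coefficients in small samples;
* Monte Carlo confidence interval (MCCI) — a parametric bootstrap on the
  parameter sampling distribution: draw parameter vectors from
  N(theta_hat, V_hat), evaluate the defined expression for each draw, and
  take empirical percentiles.  Only the coefficients themselves are assumed
  normal, not their product, which is why the MCCI typically has more power
  for indirect effects at modest n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimate import FitResult, _chain_value, delta_se
from .expressions import DefinedParameter, expand_labels
from .model import ModelError

__all__ = ["TestResult", "wald_test", "delta_test", "mcci"]

MIN_MCCI_DRAWS = 100


@dataclass(frozen=True)
class TestResult:
    """One two-sided test of H0: parameter = 0."""

    parameter: str
    method: str  # "delta" | "mcci"
    estimate: float
    se: float | None
    ci_low: float
    ci_high: float
    reject: bool
    alpha: float
    p_value: float | None = None


def wald_test(parameter: str, estimate: float, se: float,
              alpha: float = 0.05) -> TestResult:
    """Two-sided Wald z test with its symmetric normal-theory CI."""
    if not np.isfinite(se) or se <= 0:
        raise ModelError(f"invalid standard error {se} for {parameter!r}")
    z = estimate / se
    crit = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(z))
    return TestResult(
        parameter=parameter, method="delta", estimate=float(estimate),
        se=float(se), ci_low=float(estimate - crit * se),
        ci_high=float(estimate + crit * se), reject=bool(abs(z) > crit),
        alpha=alpha, p_value=float(p))


def delta_test(fit: FitResult, target: DefinedParameter | str,
               alpha: float = 0.05) -> TestResult:
    """Wald test of a defined parameter using its delta-method SE."""
    if isinstance(target, str):
        matches = [d for d in fit.defined if d.name == target]
        if not matches:
            raise ModelError(f"unknown defined parameter {target!r}")
        target = matches[0]
    est = fit.defined_values.get(target.name)
    if est is None:
        est = float(_chain_value(target, fit.defined, dict(fit.estimates)))
    se = delta_se(fit, target)
    return wald_test(target.name, est, se, alpha)


def mcci(fit: FitResult, defined: Sequence[DefinedParameter] | None = None,
         draws: int = 20_000, alpha: float = 0.05,
         seed=None) -> list[TestResult]:
    """Monte Carlo (parametric-bootstrap) CIs for defined parameters.

    Draws ``draws`` parameter vectors from the multivariate normal sampling
    distribution of the labels the expressions use, evaluates every
    expression per draw (chained definitions resolve in declaration order),
    and reports empirical alpha/2 and 1-alpha/2 percentiles.  Rejects H0 iff
    0 lies outside the interval.
    """
    if defined is None:
        defined = fit.defined
    if draws < MIN_MCCI_DRAWS:
        raise ModelError(
            f"MCCI needs at least {MIN_MCCI_DRAWS} draws for stable "
            f"percentiles; got {draws}")
    if fit.vcov is None:
        raise ModelError("asymptotic covariance unavailable for this fit")
    if seed is None:
        raise ModelError("MCCI requires an explicit seed")
    known = expand_labels(defined)
    used = sorted(set().union(*known.values()) & set(fit.labels)) or []
    rng = np.random.default_rng(seed)
    mean = np.array([fit.estimates[l] for l in used])
    V = fit.vcov_sub(used)
    # symmetrize + tiny jitter guard for numerically semidefinite V
    V = (V + V.T) / 2
    try:
        L = np.linalg.cholesky(V + 1e-14 * np.eye(len(used)))
    except np.linalg.LinAlgError:
        raise ModelError("sampling covariance not positive semidefinite")
    sample = mean + rng.standard_normal((draws, len(used))) @ L.T
    env: dict[str, np.ndarray] = {l: sample[:, i] for i, l in enumerate(used)}
    results = []
    for d in defined:
        vals = d.expression.evaluate(env)
        env[d.name] = vals
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        est = fit.defined_values.get(
            d.name, float(_chain_value(d, defined, dict(fit.estimates))))
        results.append(TestResult(
            parameter=d.name, method="mcci", estimate=float(est), se=None,
            ci_low=float(lo), ci_high=float(hi),
            reject=bool(lo > 0 or hi < 0), alpha=alpha))
    return results
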