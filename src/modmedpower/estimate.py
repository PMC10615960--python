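"""Maximum-likelihood fitting of recursive path models with fixed covariates.

Because the models are recursive with diagonal residual covariance, the
conditional (fixed-x) Gaussian log-likelihood factorizes into one linear
regression per endogenous variable per group:

    l = sum_e [ -n_e/2 log(2 pi psi_e) - SS_e(beta_e) / (2 psi_e) ]

Free parameters are the distinct labels of the model specification; a label
bound in several cells (across equations or groups) is a single
equality-constrained parameter.  When no label is shared, the ML solution is
per-equation ordinary least squares with residual variance SS/n, and the fit
takes that closed form.  Otherwise a quasi-Newton optimizer (BFGS with
analytic gradient; residual variances on the log scale to stay positive)
starts from the OLS solution projected onto the constraints.

Standard errors come from the observed information (analytic second
derivatives of the factorized likelihood, assembled across equations on the
natural scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .datagen import Dataset
from .expressions import DefinedParameter, expand_labels, resolve_defined
from .model import ModelSpec, ModelError

__all__ = ["FitResult", "fit_path_model", "evaluate_defined", "delta_se"]

_PSI_FLOOR = 1e-10


@dataclass(frozen=True)
class FitResult:
    """Point estimates, asymptotic covariance, and defined-parameter values."""

    labels: tuple[str, ...]
    estimates: dict[str, float]
    vcov: np.ndarray | None
    loglik: float
    converged: bool
    boundary: bool
    n_per_group: dict[str, int]
    defined: tuple[DefinedParameter, ...] = ()
    defined_values: dict[str, float] = field(default_factory=dict)

    def se(self, label: str) -> float:
        if self.vcov is None:
            raise ModelError("asymptotic covariance unavailable for this fit")
        i = self.labels.index(label)
        return float(np.sqrt(self.vcov[i, i]))

    def vcov_sub(self, labels: Sequence[str]) -> np.ndarray:
        if self.vcov is None:
            raise ModelError("asymptotic covariance unavailable for this fit")
        idx = [self.labels.index(l) for l in labels]
        return self.vcov[np.ix_(idx, idx)]


class _Equation:
    """One regression equation: response, free-column design, fixed offset."""

    __slots__ = ("y", "Z", "coef_idx", "psi_idx", "psi_fixed", "n", "name")

    def __init__(self, y, Z, coef_idx, psi_idx, psi_fixed, name):
        self.y = y
        self.Z = Z
        self.coef_idx = coef_idx  # theta index per column of Z
        self.psi_idx = psi_idx    # theta index of psi, or None if fixed
        self.psi_fixed = psi_fixed
        self.n = len(y)
        self.name = name


def _compile(spec: ModelSpec, data: Dataset):
    """Flatten the model into per-(group, equation) regression problems."""
    endo = list(spec.endogenous)
    cov = list(spec.covariates)
    codes = data.group_codes()
    if codes.max() != spec.n_groups:
        raise ModelError(
            f"data has {codes.max()} group(s) but model has {spec.n_groups}")
    label_order: list[str] = []
    label_pos: dict[str, int] = {}

    def pos(lab: str) -> int:
        if lab not in label_pos:
            label_pos[lab] = len(label_order)
            label_order.append(lab)
        return label_pos[lab]

    equations: list[_Equation] = []
    start_acc: dict[int, list[float]] = {}
    for gcode, gname in enumerate(spec.group_names, start=1):
        rows = np.flatnonzero(codes == gcode)
        if rows.size == 0:
            raise ModelError(f"group {gname!r} has no observations")
        sub = data.table.iloc[rows]
        X = sub[cov].to_numpy(dtype=float) if cov else np.zeros((rows.size, 0))
        Y = sub[list(endo)].to_numpy(dtype=float)
        mats = spec.groups[gname]
        KA, BE, PS = mats["KA"], mats["BE"], mats["PS"]
        AL = mats.get("AL")
        for j, vname in enumerate(endo):
            y = Y[:, j].copy()
            cols: list[np.ndarray] = []
            idxs: list[int] = []
            # intercept: from AL when a mean structure is modelled, otherwise a
            # free nuisance intercept so means are unrestricted (saturated)
            if AL is not None:
                cell = AL.free[j]
                if isinstance(cell, str):
                    cols.append(np.ones(rows.size))
                    idxs.append(pos(cell))
                elif cell != 0.0:
                    y -= float(cell)
            else:
                cols.append(np.ones(rows.size))
                idxs.append(pos(f"_alpha.{vname}.{gname}" if spec.n_groups > 1
                                else f"_alpha.{vname}"))
            for k in range(len(cov)):
                cell = KA.free[j, k]
                if isinstance(cell, str):
                    cols.append(X[:, k])
                    idxs.append(pos(cell))
                elif cell != 0.0:
                    y -= float(cell) * X[:, k]
            for k in range(len(endo)):
                cell = BE.free[j, k]
                if isinstance(cell, str):
                    cols.append(Y[:, k])
                    idxs.append(pos(cell))
                elif cell != 0.0:
                    y -= float(cell) * Y[:, k]
            Z = np.column_stack(cols) if cols else np.zeros((rows.size, 0))
            psi_cell = PS.free[j, j]
            if isinstance(psi_cell, str):
                psi_idx, psi_fixed = pos(psi_cell), None
            else:
                psi_idx, psi_fixed = None, float(psi_cell)
            eq = _Equation(y, Z, np.array(idxs, dtype=int), psi_idx, psi_fixed,
                           f"{vname}({gname})")
            equations.append(eq)
            # OLS start, accumulated per label (averaged for shared labels)
            if Z.shape[1]:
                beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            else:
                beta = np.zeros(0)
            resid = y - Z @ beta
            for c, i in enumerate(idxs):
                start_acc.setdefault(i, []).append(float(beta[c]))
            if psi_idx is not None:
                start_acc.setdefault(psi_idx, []).append(
                    max(float(resid @ resid) / rows.size, _PSI_FLOOR))
    psi_set = {e.psi_idx for e in equations if e.psi_idx is not None}
    start = np.array([float(np.mean(start_acc.get(i, [0.0])))
                      for i in range(len(label_order))])
    return equations, label_order, sorted(psi_set), start


def _is_unconstrained(equations, n_labels) -> bool:
    counts = np.zeros(n_labels, dtype=int)
    for e in equations:
        for i in e.coef_idx:
            counts[i] += 1
        if e.psi_idx is not None:
            counts[e.psi_idx] += 1
    return bool(np.all(counts <= 1))


def _neg_loglik_and_grad(w, equations, psi_set, n_labels):
    """Negative log-likelihood and gradient; psi entries of w are on log scale."""
    theta = w.copy()
    for i in psi_set:
        theta[i] = np.exp(w[i])
    nll = 0.0
    grad = np.zeros(n_labels)
    for e in equations:
        beta = theta[e.coef_idx]
        psi = theta[e.psi_idx] if e.psi_idx is not None else e.psi_fixed
        r = e.y - e.Z @ beta if e.Z.shape[1] else e.y.copy()
        ss = float(r @ r)
        nll += 0.5 * e.n * np.log(2 * np.pi * psi) + ss / (2 * psi)
        if e.Z.shape[1]:
            gb = -(e.Z.T @ r) / psi
            np.add.at(grad, e.coef_idx, gb)
        if e.psi_idx is not None:
            # d(-l)/d log psi
            grad[e.psi_idx] += 0.5 * e.n - ss / (2 * psi)
    return nll, grad


def _loglik(theta, equations):
    ll = 0.0
    for e in equations:
        beta = theta[e.coef_idx]
        psi = theta[e.psi_idx] if e.psi_idx is not None else e.psi_fixed
        r = e.y - e.Z @ beta if e.Z.shape[1] else e.y.copy()
        ll -= 0.5 * e.n * np.log(2 * np.pi * psi) + float(r @ r) / (2 * psi)
    return ll


def _observed_information(theta, equations, n_labels):
    """Observed information (negative Hessian of the log-likelihood) on the
    natural scale, assembled analytically across equations."""
    H = np.zeros((n_labels, n_labels))
    for e in equations:
        beta = theta[e.coef_idx]
        psi = theta[e.psi_idx] if e.psi_idx is not None else e.psi_fixed
        r = e.y - e.Z @ beta if e.Z.shape[1] else e.y.copy()
        ss = float(r @ r)
        if e.Z.shape[1]:
            ZtZ = e.Z.T @ e.Z / psi
            for a, ia in enumerate(e.coef_idx):
                for b, ib in enumerate(e.coef_idx):
                    H[ia, ib] += ZtZ[a, b]
            if e.psi_idx is not None:
                Ztr = e.Z.T @ r / psi**2
                for a, ia in enumerate(e.coef_idx):
                    H[ia, e.psi_idx] += Ztr[a]
                    H[e.psi_idx, ia] += Ztr[a]
        if e.psi_idx is not None:
            H[e.psi_idx, e.psi_idx] += -e.n / (2 * psi**2) + ss / psi**3
    return H


def fit_path_model(analysis: ModelSpec, data: Dataset) -> FitResult:
    """Fit an analysis model to one dataset by conditional Gaussian ML."""
    equations, labels, psi_set, start = _compile(analysis, data)
    n_labels = len(labels)
    codes = data.group_codes()
    n_per_group = {g: int(np.sum(codes == i))
                   for i, g in enumerate(analysis.group_names, start=1)}

    if _is_unconstrained(equations, n_labels):
        theta = start.copy()
        converged = True
    else:
        w0 = start.copy()
        for i in psi_set:
            w0[i] = np.log(max(start[i], _PSI_FLOOR))
        res = optimize.minimize(
            _neg_loglik_and_grad, w0, args=(equations, psi_set, n_labels),
            jac=True, method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500})
        converged = bool(res.success or np.linalg.norm(res.jac) < 1e-5)
        theta = res.x.copy()
        for i in psi_set:
            theta[i] = np.exp(res.x[i])

    boundary = any(theta[i] < 1e-7 for i in psi_set)
    ll = _loglik(theta, equations)

    vcov: np.ndarray | None = None
    if converged and not boundary:
        H = _observed_information(theta, equations, n_labels)
        try:
            Hc = np.linalg.cholesky(H)
            vcov = np.linalg.inv(Hc.T) @ np.linalg.inv(Hc)
        except np.linalg.LinAlgError:
            vcov = None

    estimates = {lab: float(theta[i]) for i, lab in enumerate(labels)}
    defined_values = {
        k: float(v)
        for k, v in resolve_defined(analysis.defined, estimates).items()}
    return FitResult(
        labels=tuple(labels),
        estimates=estimates,
        vcov=vcov,
        loglik=float(ll),
        converged=converged,
        boundary=boundary,
        n_per_group=n_per_group,
        defined=analysis.defined,
        defined_values=defined_values,
    )


def evaluate_defined(fit: FitResult,
                     defined: Sequence[DefinedParameter]) -> dict[str, float]:
    """Evaluate defined-parameter expressions at the point estimates."""
    return {k: float(v)
            for k, v in resolve_defined(defined, fit.estimates).items()}


def _chain_value(target: DefinedParameter, context: Sequence[DefinedParameter],
                 env: dict) -> float:
    """Evaluate ``target`` allowing references to earlier definitions."""
    scope = dict(env)
    for d in context:
        if d.name == target.name:
            break
        scope[d.name] = d.expression.evaluate(scope)
    return target.expression.evaluate(scope)


def delta_se(fit: FitResult, target: DefinedParameter | str,
             rel_step: float = 1e-6) -> float:
    """Delta-method standard error of a defined parameter.

    SE = sqrt(g' V g), with g the gradient of the expression with respect to
    the estimated labels it (transitively) uses, by central finite differences
    with step ``rel_step * max(1, |estimate|)`` per coordinate.  For ``ab``
    with cov(a, b) = 0 this reduces to the Sobel formula
    sqrt(b^2 SE_a^2 + a^2 SE_b^2).
    """
    if isinstance(target, str):
        matches = [d for d in fit.defined if d.name == target]
        if not matches:
            raise ModelError(f"unknown defined parameter {target!r}")
        target = matches[0]
    if fit.vcov is None:
        raise ModelError("asymptotic covariance unavailable for this fit")
    context = fit.defined
    known = expand_labels(context)
    if target.name in known:
        used = sorted(known[target.name])
    else:
        base: set[str] = set()
        for nm in target.expression.names:
            base |= known.get(nm, frozenset({nm}))
        used = sorted(base)
    used = [u for u in used if u in fit.estimates]
    g = np.empty(len(used))
    for i, lab in enumerate(used):
        h = rel_step * max(1.0, abs(fit.estimates[lab]))
        up = dict(fit.estimates)
        dn = dict(fit.estimates)
        up[lab] += h
        dn[lab] -= h
        g[i] = (_chain_value(target, context, up)
                - _chain_value(target, context, dn)) / (2 * h)
    V = fit.vcov_sub(used)
    return float(np.sqrt(max(g @ V @ g, 0.0)))
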