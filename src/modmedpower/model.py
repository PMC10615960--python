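"""Path-model specification: parameter matrices, constraints, standardization.

A recursive path model with fixed covariates is written per group g as

    y_i = alpha_g + B_g y_i + K_g x_i + zeta_i,    zeta_i ~ N(0, Psi_g)

where y are the endogenous variables (mediator, outcome), x the fixed
covariates (dummy codes and products), K the covariate slopes, B the
endogenous slopes (strictly lower-triangular under some ordering — the model
is recursive), Psi the residual covariance (diagonal here), and alpha the
intercepts (only when a mean structure is requested).

Each matrix entry is either fixed to a value or free with a label; a label
appearing in several cells (possibly across groups) denotes a single
equality-constrained parameter.  Alongside the free/fixed pattern every cell
carries a population value used for data generation.

The standardization solver turns standardized slopes into residual variances:
walking the endogenous variables in topological order it computes each
variable's explained variance from the joint covariance of the covariates and
previously solved endogenous variables, and sets the residual variance to the
target total variance (1 by default) minus the explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .design import CovariateMoments
from .expressions import DefinedParameter, resolve_defined

__all__ = [
    "ParameterMatrix",
    "ModelSpec",
    "make_parameter_matrix",
    "assemble_model",
    "validate_recursive",
    "solve_residual_variances",
    "implied_covariance",
    "scale_group_variances",
    "intercept_offsets",
]

ROLES = ("KA", "BE", "PS", "AL")


class ModelError(ValueError):
    """Invalid model specification."""


def _as_object_array(pattern) -> np.ndarray:
    arr = np.empty(np.shape(pattern), dtype=object)
    flat_in = np.asarray(pattern, dtype=object).ravel()
    flat = arr.ravel()
    for i, v in enumerate(flat_in):
        if isinstance(v, str):
            flat[i] = v
        elif v is None:
            raise ModelError("cells must be a fixed number or a label string")
        else:
            flat[i] = float(v)
    return arr


@dataclass(frozen=True)
class ParameterMatrix:
    """One model matrix with its free/fixed pattern and population values.

    ``free`` is an object array: a string marks a free parameter with that
    label, a number a fixed value.  ``population`` carries the value used for
    data generation in every cell.  AL is one-dimensional (a vector of
    intercepts); the other roles are two-dimensional.
    """

    role: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...] | None
    free: np.ndarray
    population: np.ndarray

    def __post_init__(self):
        if self.role not in ROLES:
            raise ModelError(f"unknown matrix role {self.role!r}")
        expected = (len(self.row_labels),) if self.col_labels is None else (
            len(self.row_labels), len(self.col_labels))
        if self.free.shape != expected or self.population.shape != expected:
            raise ModelError(
                f"{self.role}: pattern/population shape {self.free.shape}/"
                f"{self.population.shape} does not match labels {expected}")
        if self.role == "BE":
            if self.free.ndim != 2 or self.free.shape[0] != self.free.shape[1]:
                raise ModelError("BE must be square")
            for i in range(self.free.shape[0]):
                if isinstance(self.free[i, i], str) or self.free[i, i] != 0.0:
                    raise ModelError("BE diagonal must be structurally zero")
        if self.role == "PS":
            if not np.allclose(self.population, self.population.T):
                raise ModelError("PS population must be symmetric")
            if np.any(np.diag(self.population) < 0):
                raise ModelError("PS diagonal population values must be >= 0")

    def is_free(self, *idx) -> bool:
        return isinstance(self.free[idx], str)

    def labels(self) -> list[tuple[str, tuple]]:
        out = []
        for idx in np.ndindex(self.free.shape):
            if isinstance(self.free[idx], str):
                out.append((self.free[idx], idx))
        return out

    def structural_nonzero(self, *idx) -> bool:
        cell = self.free[idx]
        return isinstance(cell, str) or cell != 0.0 or self.population[idx] != 0.0

    def with_population(self, values: np.ndarray) -> "ParameterMatrix":
        return replace(self, population=np.asarray(values, dtype=float))


def make_parameter_matrix(
    role: str,
    free_pattern,
    population,
    row_labels: Sequence[str],
    col_labels: Sequence[str] | None = None,
) -> ParameterMatrix:
    """Pair a free/fixed pattern with population values into one matrix.

    A cell fixed to a value must carry the same value in the population slot;
    disagreement is almost always a user error, so it raises rather than
    silently preferring one slot.
    """
    free = _as_object_array(free_pattern)
    pop = np.asarray(population, dtype=float)
    if free.shape != pop.shape:
        raise ModelError(
            f"{role}: free pattern shape {free.shape} != population {pop.shape}")
    for idx in np.ndindex(free.shape):
        cell = free[idx]
        if not isinstance(cell, str) and cell != pop[idx]:
            raise ModelError(
                f"{role}{list(idx)}: fixed value {cell} disagrees with "
                f"population value {pop[idx]}")
    row_labels = tuple(row_labels)
    cols = None if col_labels is None else tuple(col_labels)
    return ParameterMatrix(role=role, row_labels=row_labels, col_labels=cols,
                           free=free, population=pop)


def validate_recursive(BE: ParameterMatrix) -> list[str]:
    """Topological order of the endogenous variables implied by BE.

    BE[j, k] structurally nonzero means k -> j.  Ties are broken by
    declaration order (Kahn's algorithm with a stable frontier), so an
    all-zero BE returns the declaration order unchanged.
    """
    names = list(BE.row_labels)
    p = len(names)
    depends = {j: {k for k in range(p) if BE.structural_nonzero(j, k)}
               for j in range(p)}
    order: list[int] = []
    remaining = list(range(p))
    while remaining:
        ready = [j for j in remaining if not (depends[j] - set(order))]
        if not ready:
            cyc = ", ".join(names[j] for j in remaining)
            raise ModelError(f"endogenous structure is not recursive: {cyc}")
        nxt = ready[0]
        order.append(nxt)
        remaining.remove(nxt)
    return [names[j] for j in order]


@dataclass(frozen=True)
class ModelSpec:
    """A per-group set of parameter matrices plus defined parameters.

    ``groups`` maps group name -> {role: ParameterMatrix}.  Groups are coded
    1..G in data in the order given here.  ``free_index`` maps each distinct
    label to the cells it binds; a label bound in several cells (within or
    across groups) is one equality-constrained parameter.
    """

    groups: dict[str, dict[str, ParameterMatrix]]
    endogenous: tuple[str, ...]
    covariates: tuple[str, ...]
    meanstructure: bool
    defined: tuple[DefinedParameter, ...] = ()
    free_index: dict[str, list[tuple[str, str, tuple]]] = field(default_factory=dict)
    topo_order: tuple[str, ...] = ()

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def matrices(self, group: str) -> dict[str, ParameterMatrix]:
        return self.groups[group]

    def population_label_values(self) -> dict[str, float]:
        """Population value per free label (error if a shared label binds
        cells whose population values disagree)."""
        out: dict[str, float] = {}
        for lab, cells in self.free_index.items():
            vals = {float(self.groups[g][role].population[idx])
                    for g, role, idx in cells}
            if len(vals) > 1:
                raise ModelError(
                    f"label {lab!r} binds cells with differing population "
                    f"values {sorted(vals)}")
            out[lab] = vals.pop()
        return out

    def population_defined_values(self) -> dict[str, float]:
        return {k: float(v) for k, v in
                resolve_defined(self.defined, self.population_label_values()).items()}


def assemble_model(
    groups: Mapping[str, Mapping[str, ParameterMatrix]],
    endogenous: Sequence[str],
    covariates: Sequence[str],
    defined: Sequence[DefinedParameter | str] = (),
    meanstructure: bool = False,
) -> ModelSpec:
    """Validate and index a per-group collection of parameter matrices."""
    endogenous = tuple(endogenous)
    covariates = tuple(covariates)
    groups_out: dict[str, dict[str, ParameterMatrix]] = {}
    order: tuple[str, ...] | None = None
    for gname, mats in groups.items():
        mats = dict(mats)
        for role in ("KA", "BE", "PS"):
            if role not in mats:
                raise ModelError(f"group {gname!r} missing {role} matrix")
        if meanstructure and "AL" not in mats:
            raise ModelError(f"group {gname!r} missing AL with meanstructure on")
        if not meanstructure:
            mats.pop("AL", None)
        ka = mats["KA"]
        if ka.row_labels != endogenous or ka.col_labels != covariates:
            raise ModelError(f"group {gname!r}: KA labels do not match model")
        for role in ("BE", "PS"):
            m = mats[role]
            if m.row_labels != endogenous or m.col_labels != endogenous:
                raise ModelError(f"group {gname!r}: {role} labels mismatch")
        g_order = tuple(validate_recursive(mats["BE"]))
        if order is None:
            order = g_order
        elif g_order != order:
            raise ModelError("groups imply different topological orders")
        groups_out[gname] = mats

    free_index: dict[str, list[tuple[str, str, tuple]]] = {}
    for gname, mats in groups_out.items():
        for role in ROLES:
            if role not in mats:
                continue
            for lab, idx in mats[role].labels():
                free_index.setdefault(lab, []).append((gname, role, idx))
            if role == "PS":
                # symmetric: count each off-diagonal pair once
                ps = mats[role]
                for (lab, idx) in ps.labels():
                    i, j = idx
                    if i > j:
                        free_index[lab].remove((gname, role, idx))

    defined_out: list[DefinedParameter] = []
    seen: set[str] = set(free_index)
    for d in defined:
        if isinstance(d, str):
            d = DefinedParameter.from_string(d)
        if d.name in seen:
            raise ModelError(f"duplicate defined name {d.name!r}")
        missing = d.expression.names - seen
        if missing:
            raise ModelError(
                f"defined parameter {d.name!r} references unknown labels "
                f"{sorted(missing)}")
        seen.add(d.name)
        defined_out.append(d)

    return ModelSpec(
        groups=groups_out,
        endogenous=endogenous,
        covariates=covariates,
        meanstructure=meanstructure,
        defined=tuple(defined_out),
        free_index=free_index,
        topo_order=order or endogenous,
    )


def _reduced_form(mats: Mapping[str, ParameterMatrix]):
    B = mats["BE"].population
    K = mats["KA"].population
    Psi = mats["PS"].population
    p = B.shape[0]
    IB = np.eye(p) - B
    try:
        IBinv = np.linalg.inv(IB)
    except np.linalg.LinAlgError:  # pragma: no cover - recursive B is invertible
        raise ModelError("I - B is singular; model is not recursive")
    return IBinv @ K, IBinv, Psi


def implied_covariance(spec: ModelSpec, moments: CovariateMoments,
                       group: str | None = None) -> np.ndarray:
    """Model-implied covariance of the endogenous variables for one group.

    Reduced form: y = (I-B)^{-1} (K x + zeta), so
    Cov(y) = Pi Sigma_x Pi' + (I-B)^{-1} Psi (I-B)^{-T} with Pi = (I-B)^{-1} K.
    """
    gname = group if group is not None else spec.group_names[0]
    mats = spec.groups[gname]
    Pi, IBinv, Psi = _reduced_form(mats)
    Sx = moments.sub(spec.covariates).covariance if spec.covariates else np.zeros((0, 0))
    return Pi @ Sx @ Pi.T + IBinv @ Psi @ IBinv.T


def solve_residual_variances(
    spec: ModelSpec,
    moments: CovariateMoments,
    target_total_variance: Mapping[str, float] | float = 1.0,
    group: str | None = None,
) -> np.ndarray:
    """Residual variances that standardize each endogenous total variance.

    Walks the endogenous variables in topological order maintaining the joint
    covariance S of (covariates, solved endogenous).  For variable j with
    predictor weights w (covariate slopes and endogenous slopes stacked),
    explained variance = w' S w and psi_j = target_j - explained_j.  With
    those psi the model-implied total variances equal the targets exactly.
    """
    gname = group if group is not None else spec.group_names[0]
    mats = spec.groups[gname]
    K = mats["KA"].population
    B = mats["BE"].population
    endo = list(spec.endogenous)
    cov_names = list(spec.covariates)
    if np.isscalar(target_total_variance):
        targets = {v: float(target_total_variance) for v in endo}
    else:
        targets = {v: float(target_total_variance[v]) for v in endo}

    mom = moments.sub(cov_names) if cov_names else None
    nx = len(cov_names)
    # joint covariance over covariates + endogenous (filled in topo order)
    p = len(endo)
    S = np.zeros((nx + p, nx + p))
    if mom is not None:
        S[:nx, :nx] = mom.covariance
    solved: list[int] = []
    psi = np.zeros(p)
    for name in spec.topo_order:
        j = endo.index(name)
        w = np.zeros(nx + p)
        w[:nx] = K[j, :]
        for k in solved:
            w[nx + k] = B[j, k]
        explained = float(w @ S @ w)
        resid = targets[name] - explained
        if resid <= 0:
            raise ModelError(
                f"explained variance {explained:.6f} of {name!r} meets or "
                f"exceeds its target total variance {targets[name]}; "
                f"standardization infeasible")
        psi[j] = resid
        col = S @ w
        S[:, nx + j] = col
        S[nx + j, :] = col
        S[nx + j, nx + j] = targets[name]
        solved.append(j)
    return psi


def apply_solved_psi(spec: ModelSpec, psi_by_group: Mapping[str, np.ndarray]) -> ModelSpec:
    """Return a spec whose PS population diagonals are replaced per group."""
    groups = {}
    for gname, mats in spec.groups.items():
        mats = dict(mats)
        if gname in psi_by_group:
            ps = mats["PS"]
            pop = ps.population.copy()
            np.fill_diagonal(pop, np.asarray(psi_by_group[gname], dtype=float))
            mats["PS"] = ps.with_population(pop)
        groups[gname] = mats
    return replace(spec, groups=groups)


def scale_group_variances(spec: ModelSpec, factor: float, group: str) -> ModelSpec:
    """Multiply one group's residual-variance diagonal by ``factor``.

    This is how heteroskedasticity across moderator groups is injected into a
    population model (e.g. treatment-group residual variances 50% higher).
    """
    if factor <= 0:
        raise ModelError("variance scale factor must be positive")
    if group not in spec.groups:
        raise ModelError(f"unknown group {group!r}")
    ps = spec.groups[group]["PS"]
    pop = ps.population.copy()
    np.fill_diagonal(pop, np.diag(pop) * factor)
    groups = dict(spec.groups)
    groups[group] = {**groups[group], "PS": ps.with_population(pop)}
    return replace(spec, groups=groups)


def intercept_offsets(
    effects: Mapping[str, float],
    endogenous: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Split between-group effects into symmetric intercept offsets.

    When a dummy-coded predictor becomes the grouping factor, its effect on an
    endogenous variable turns into an intercept difference: the control group
    gets -effect/2 and the treatment group +effect/2, so the grand mean stays
    zero and the difference equals the effect exactly.
    """
    control = np.zeros(len(endogenous))
    treatment = np.zeros(len(endogenous))
    for var, eff in effects.items():
        if var not in endogenous:
            raise ModelError(f"unknown endogenous variable {var!r}")
        j = list(endogenous).index(var)
        control[j] = -eff / 2.0
        treatment[j] = +eff / 2.0
    return control, treatment
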