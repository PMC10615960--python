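"""Sample generation conditional on a fixed design matrix.

Covariate columns are copied verbatim from the design in every replication —
only the endogenous variables are random.  Residuals are multivariate normal
per group (Cholesky of Psi; independent normals for the diagonal models used
here), and endogenous values are filled in topological order from

    y = alpha_g + B_g y + K_g x + zeta .

Reproducibility contract: a replication is seeded by a ``SeedSequence``
spawned from the master seed and the replication index, so results are
identical for any worker count and any subset of replications rerun.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .model import ModelSpec, ModelError

__all__ = ["Dataset", "generate_sample", "generate_multigroup_sample"]

GROUP_COLUMN = "group"


@dataclass(frozen=True)
class Dataset:
    """One simulated sample: fixed covariates plus generated endogenous values.

    ``table`` column order is covariates, endogenous, then the group column
    (last) when present.  Group codes are sequential integers starting at 1.
    """

    table: pd.DataFrame
    covariates: tuple[str, ...]
    endogenous: tuple[str, ...]
    group_column: str | None = None
    seed: object = None

    @property
    def n(self) -> int:
        return len(self.table)

    def group_codes(self) -> np.ndarray:
        if self.group_column is None:
            return np.ones(self.n, dtype=int)
        return self.table[self.group_column].to_numpy(dtype=int)


def _draw_group(mats, order, endo, x, rng) -> np.ndarray:
    """Generate endogenous values for one group given covariate rows x."""
    n = x.shape[0]
    K = mats["KA"].population
    B = mats["BE"].population
    Psi = mats["PS"].population
    alpha = mats["AL"].population if "AL" in mats else np.zeros(len(endo))
    try:
        L = np.linalg.cholesky(Psi)
    except np.linalg.LinAlgError:
        # semidefinite (e.g. zero-noise) Psi: factor via eigendecomposition
        vals, vecs = np.linalg.eigh(Psi)
        if np.any(vals < -1e-10):
            raise ModelError(
                "residual covariance Psi is not positive semidefinite")
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    zeta = rng.standard_normal((n, len(endo))) @ L.T
    y = np.zeros((n, len(endo)))
    base = x @ K.T + alpha + zeta
    for name in order:
        j = endo.index(name)
        y[:, j] = base[:, j] + y @ B[j, :]
    return y


def generate_sample(spec: ModelSpec, design: DesignMatrix, seed) -> Dataset:
    """One sample from a single-group population model on a fixed design."""
    if spec.n_groups != 1:
        raise ModelError("use generate_multigroup_sample for multigroup specs")
    if seed is None:
        raise ModelError("a seed is required for reproducible generation")
    rng = np.random.default_rng(seed)
    gname = spec.group_names[0]
    x = design.values(list(spec.covariates))
    y = _draw_group(spec.groups[gname], spec.topo_order, list(spec.endogenous),
                    x, rng)
    table = design.table[list(spec.covariates)].reset_index(drop=True).copy()
    for j, name in enumerate(spec.endogenous):
        table[name] = y[:, j]
    return Dataset(table=table, covariates=spec.covariates,
                   endogenous=spec.endogenous, seed=seed)


def generate_multigroup_sample(
    spec: ModelSpec,
    designs: dict[str, DesignMatrix] | dict[str, int],
    seed,
) -> Dataset:
    """Concatenated per-group generation; group column appended last, coded 1..G.

    ``designs`` maps each group name to either a DesignMatrix (covariates
    fixed within that group) or a plain sample size (no within-group
    covariates, as in the intercept-offset formulation of a group contrast).
    """
    if seed is None:
        raise ModelError("a seed is required for reproducible generation")
    if set(designs) != set(spec.group_names):
        raise ModelError(
            f"designs given for {sorted(designs)} but model groups are "
            f"{sorted(spec.group_names)}")
    rng = np.random.default_rng(seed)
    frames = []
    endo = list(spec.endogenous)
    for code, gname in enumerate(spec.group_names, start=1):
        d = designs[gname]
        if isinstance(d, DesignMatrix):
            x = d.values(list(spec.covariates))
            cov_tab = d.table[list(spec.covariates)].reset_index(drop=True).copy()
        else:
            n_g = int(d)
            if n_g < 1:
                raise ModelError(f"group {gname!r} has no observations")
            if spec.covariates:
                raise ModelError(
                    "model has covariates; pass a DesignMatrix per group")
            x = np.zeros((n_g, 0))
            cov_tab = pd.DataFrame(index=range(n_g))
        y = _draw_group(spec.groups[gname], spec.topo_order, endo, x, rng)
        tab = cov_tab
        for j, name in enumerate(endo):
            tab[name] = y[:, j]
        tab[GROUP_COLUMN] = code
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)
    return Dataset(table=table, covariates=spec.covariates,
                   endogenous=spec.endogenous, group_column=GROUP_COLUMN,
                   seed=seed)
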