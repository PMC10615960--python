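"""Fixed experimental design matrices.

In a randomized experiment the predictors are not sampled: they are assigned.
Data generation therefore conditions on a fixed matrix of dummy codes (and
their products, for interactions) that is identical across Monte Carlo
replications.  This module builds balanced (or deliberately unbalanced)
fully-crossed two-level designs and computes the covariate moments that the
standardization solver needs to convert standardized path coefficients into
residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "CovariateMoments",
    "build_factorial_design",
    "add_interaction",
    "covariate_moments",
]


class DesignError(ValueError):
    """Invalid design specification."""


@dataclass(frozen=True)
class DesignMatrix:
    """Fixed covariate values per observation.

    ``table`` holds one numeric column per covariate (0/1 dummy codes or
    their products).  ``group_column``, if set, names a column whose values
    are the sequential integer codes 1..G of a grouping factor; that column
    is not a covariate.
    """

    table: pd.DataFrame
    group_column: str | None = None

    def __post_init__(self):
        for col in self.covariates:
            vals = self.table[col].to_numpy()
            if not np.issubdtype(vals.dtype, np.number):
                raise DesignError(f"column {col!r} is not numeric")
        if self.group_column is not None:
            if self.group_column not in self.table.columns:
                raise DesignError(f"group column {self.group_column!r} missing")
            g = self.table[self.group_column].to_numpy()
            levels = np.unique(g)
            if not np.array_equal(levels, np.arange(1, len(levels) + 1)):
                raise DesignError(
                    "group codes must be sequential integers starting at 1")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.table.columns if c != self.group_column]

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_groups(self) -> int:
        if self.group_column is None:
            return 1
        return int(self.table[self.group_column].max())

    def group_indices(self, code: int) -> np.ndarray:
        if self.group_column is None:
            raise DesignError("design has no grouping column")
        return np.flatnonzero(self.table[self.group_column].to_numpy() == code)

    def values(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.covariates
        return self.table[cols].to_numpy(dtype=float)

    def with_group_column(self, name: str, codes: np.ndarray) -> "DesignMatrix":
        tab = self.table.copy()
        tab[name] = np.asarray(codes, dtype=int)
        return DesignMatrix(table=tab, group_column=name)


@dataclass(frozen=True)
class CovariateMoments:
    """First and second moments of the design's covariate columns."""

    names: tuple[str, ...]
    means: np.ndarray
    covariance: np.ndarray
    divisor: Literal["unbiased", "population"]

    def sub(self, names: Sequence[str]) -> "CovariateMoments":
        idx = [self.names.index(n) for n in names]
        return CovariateMoments(
            names=tuple(names),
            means=self.means[idx],
            covariance=self.covariance[np.ix_(idx, idx)],
            divisor=self.divisor,
        )


def build_factorial_design(
    factors: Sequence[str],
    n_per_cell: int | Sequence[int],
) -> DesignMatrix:
    """Balanced fully-crossed design of two-level (0/1 dummy-coded) factors.

    Factors vary slowest-to-fastest in declaration order and cells are
    contiguous blocks of rows.  ``n_per_cell`` may be a single size (balanced)
    or one size per cell in that cell order.
    """
    factors = list(factors)
    if len(factors) == 0:
        raise DesignError("at least one factor required")
    if len(set(factors)) != len(factors):
        raise DesignError("factor names must be unique")
    n_cells = 2 ** len(factors)
    if np.isscalar(n_per_cell):
        sizes = [int(n_per_cell)] * n_cells
    else:
        sizes = [int(s) for s in n_per_cell]
        if len(sizes) != n_cells:
            raise DesignError(
                f"expected {n_cells} cell sizes, got {len(sizes)}")
    if any(s < 1 for s in sizes):
        raise DesignError("cell sizes must be positive")

    rows = []
    for cell in range(n_cells):
        # first factor in the highest bit: slowest-varying
        codes = [(cell >> (len(factors) - 1 - k)) & 1 for k in range(len(factors))]
        rows.append(np.tile(codes, (sizes[cell], 1)))
    table = pd.DataFrame(np.vstack(rows), columns=factors, dtype=float)
    return DesignMatrix(table=table)


def add_interaction(design: DesignMatrix, parent_a: str, parent_b: str,
                    name: str | None = None) -> DesignMatrix:
    """Append the elementwise product of two existing columns."""
    for p in (parent_a, parent_b):
        if p not in design.table.columns:
            raise DesignError(f"unknown parent column {p!r}")
    name = name or f"{parent_a}{parent_b}"
    tab = design.table.copy()
    tab[name] = tab[parent_a] * tab[parent_b]
    if design.group_column is not None:
        # keep the grouping column last for export compatibility
        cols = [c for c in tab.columns if c != design.group_column]
        tab = tab[cols + [design.group_column]]
    return DesignMatrix(table=tab, group_column=design.group_column)


def covariate_moments(
    design: DesignMatrix,
    divisor: Literal["unbiased", "population"] = "unbiased",
) -> CovariateMoments:
    """Means and covariance matrix of the covariate columns.

    The unbiased (n-1) divisor is the default: it is the convention under
    which standardized slopes reproduce the residual variances used by the
    reference workflow this package emulates.
    """
    if divisor not in ("unbiased", "population"):
        raise DesignError(f"unknown divisor convention {divisor!r}")
    x = design.values()
    n = x.shape[0]
    if n < 2 and divisor == "unbiased":
        raise DesignError("need at least 2 rows for unbiased moments")
    means = x.mean(axis=0)
    xc = x - means
    ddof = 1 if divisor == "unbiased" else 0
    cov = xc.T @ xc / (n - ddof)
    return CovariateMoments(
        names=tuple(design.covariates),
        means=means,
        covariance=cov,
        divisor=divisor,
    )
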