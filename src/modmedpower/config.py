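"""Declarative study configuration (YAML or JSON).

A study file either names a preset with its parameters, or spells the model
out: a design section (factors, cell sizes, interaction columns), a model
section (per-group parameter matrices whose cells are a number for a fixed
value or ``"label = value"`` for a free parameter with its population value;
PS diagonal cells may be ``auto`` to request the standardizing residual
variance), a monte_carlo section and an output section.  Unknown keys are
rejected so typos fail loudly rather than silently using a default.
"""

from __future__ import annotations

import json
import numbers
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import presets
from .design import (DesignMatrix, add_interaction, build_factorial_design,
                     covariate_moments)
from .model import (apply_solved_psi, assemble_model, make_parameter_matrix,
                    solve_residual_variances)
from .power import StudySpec

__all__ = ["load_config", "build_study", "ConfigError"]

_PRESETS = {
    "simple_mediation": presets.simple_mediation_study,
    "multigroup_mediation": presets.multigroup_mediation_study,
    "moderated_mediation": presets.moderated_mediation_study,
    "multigroup_moderated_mediation":
        presets.multigroup_moderated_mediation_study,
}

_MC_KEYS = {"nrep", "seed", "alpha", "methods", "mcci_draws"}
_TOP_KEYS = {"study", "preset", "design", "model", "monte_carlo", "output"}
_DESIGN_KEYS = {"factors", "n_per_cell", "interactions", "per_group",
                "group_sizes"}
_MODEL_KEYS = {"endogenous", "covariates", "meanstructure", "defined",
               "groups"}
_OUTPUT_KEYS = {"dir", "save_replications"}
_CELL_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_.]*)\s*=\s*([-+0-9.eE]+)\s*$")


class ConfigError(ValueError):
    """Invalid study configuration, with the offending key path."""


def _check_keys(section: Mapping, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _parse_cell(cell, path: str, allow_auto: bool = False):
    """Return (free_entry, population_value) or ('auto', None)."""
    if isinstance(cell, numbers.Number) and not isinstance(cell, bool):
        return float(cell), float(cell)
    if isinstance(cell, str):
        if cell.strip() == "auto":
            if not allow_auto:
                raise ConfigError(f"{path}: 'auto' only valid on the PS diagonal")
            return "auto", None
        m = _CELL_RE.match(cell)
        if m:
            return m.group(1), float(m.group(2))
        raise ConfigError(
            f"{path}: cell must be a number, 'label = value', or 'auto'; "
            f"got {cell!r}")
    raise ConfigError(f"{path}: unsupported cell {cell!r}")


def load_config(path, **overrides) -> StudySpec:
    """Read and validate a study file, returning a ready StudySpec.

    ``overrides`` (nrep, seed, alpha, methods, mcci_draws, n_per_cell) take
    precedence over file values — the command line maps its flags here.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return build_study(cfg, **overrides)


def _mc_settings(cfg: Mapping, overrides: dict) -> dict:
    mc = dict(cfg.get("monte_carlo") or {})
    _check_keys(mc, _MC_KEYS, "monte_carlo")
    for k in _MC_KEYS:
        if overrides.get(k) is not None:
            mc[k] = overrides[k]
    if "alpha" in mc and not 0 < float(mc["alpha"]) < 1:
        raise ConfigError(f"monte_carlo.alpha: must be in (0, 1), got {mc['alpha']}")
    if "nrep" in mc and int(mc["nrep"]) < 1:
        raise ConfigError("monte_carlo.nrep: must be >= 1")
    if "methods" in mc:
        mc["methods"] = tuple(mc["methods"])
    return mc


def build_study(cfg: Mapping, n_per_cell: int | None = None,
                **overrides) -> StudySpec:
    """Turn a parsed configuration mapping into a StudySpec."""
    _check_keys(cfg, _TOP_KEYS, "config")
    if cfg.get("study") is not None:
        _check_keys(cfg["study"], {"name"}, "study")
    if cfg.get("output") is not None:
        _check_keys(cfg["output"], _OUTPUT_KEYS, "output")
    mc = _mc_settings(cfg, overrides)

    if "preset" in cfg:
        pre = dict(cfg["preset"])
        _check_keys(pre, {"name", "params"}, "preset")
        name = pre.get("name")
        if name not in _PRESETS:
            raise ConfigError(
                f"preset.name: unknown preset {name!r}; choose from "
                f"{sorted(_PRESETS)}")
        params = dict(pre.get("params") or {})
        if n_per_cell is not None:
            key = ("n_per_cell" if name == "moderated_mediation"
                   else "n_per_group")
            params[key] = n_per_cell
        return _PRESETS[name](**params, **mc)

    if "model" not in cfg:
        raise ConfigError("config needs either a 'preset' or a 'model' section")
    return _build_explicit(cfg, n_per_cell, mc)


def _build_design(dcfg: Mapping, n_override, path: str) -> DesignMatrix:
    _check_keys(dcfg, _DESIGN_KEYS, path)
    factors = dcfg.get("factors")
    if not factors:
        raise ConfigError(f"{path}.factors: at least one factor required")
    n = n_override if n_override is not None else dcfg.get("n_per_cell")
    if n is None:
        raise ConfigError(f"{path}.n_per_cell: required")
    design = build_factorial_design(list(factors), n)
    for pair in dcfg.get("interactions") or []:
        if len(pair) != 2:
            raise ConfigError(f"{path}.interactions: each entry needs 2 parents")
        design = add_interaction(design, pair[0], pair[1])
    return design


def _build_explicit(cfg: Mapping, n_override, mc: dict) -> StudySpec:
    mcfg = dict(cfg["model"])
    _check_keys(mcfg, _MODEL_KEYS, "model")
    endo = list(mcfg.get("endogenous") or [])
    cov = list(mcfg.get("covariates") or [])
    if not endo:
        raise ConfigError("model.endogenous: required")
    meanstructure = bool(mcfg.get("meanstructure", False))
    groups_cfg = mcfg.get("groups")
    if not groups_cfg:
        raise ConfigError("model.groups: at least one group required")

    dcfg = dict(cfg.get("design") or {})
    multigroup = len(groups_cfg) > 1
    designs: dict[str, object] = {}
    single_design: DesignMatrix | None = None
    if multigroup:
        per_group = dcfg.get("per_group")
        sizes = dcfg.get("group_sizes")
        if per_group:
            _check_keys(dcfg, _DESIGN_KEYS, "design")
            for g in groups_cfg:
                if g not in per_group:
                    raise ConfigError(f"design.per_group: missing group {g!r}")
                designs[g] = _build_design(per_group[g], n_override,
                                           f"design.per_group.{g}")
        elif sizes:
            _check_keys(dcfg, _DESIGN_KEYS, "design")
            for g in groups_cfg:
                if g not in sizes:
                    raise ConfigError(f"design.group_sizes: missing group {g!r}")
                designs[g] = int(n_override if n_override is not None
                                 else sizes[g])
        else:
            raise ConfigError(
                "design: multigroup models need 'per_group' or 'group_sizes'")
    else:
        if cov:
            single_design = _build_design(dcfg, n_override, "design")
            missing = [c for c in cov if c not in single_design.covariates]
            if missing:
                raise ConfigError(
                    f"model.covariates {missing} not produced by the design")
        else:
            raise ConfigError("single-group models need covariates and a design")

    groups = {}
    auto_cells: dict[str, list[int]] = {}
    for gname, gmats in groups_cfg.items():
        gmats = dict(gmats)
        _check_keys(gmats, {"KA", "BE", "PS", "AL"}, f"model.groups.{gname}")
        mats = {}
        # KA: rows endogenous x columns covariates
        free = np.zeros((len(endo), len(cov)), dtype=object)
        pop = np.zeros((len(endo), len(cov)))
        for r, rv in (gmats.get("KA") or {}).items():
            if r not in endo:
                raise ConfigError(f"model.groups.{gname}.KA: unknown row {r!r}")
            for cname, cell in rv.items():
                if cname not in cov:
                    raise ConfigError(
                        f"model.groups.{gname}.KA.{r}: unknown column {cname!r}")
                f, p = _parse_cell(cell, f"model.groups.{gname}.KA.{r}.{cname}")
                free[endo.index(r), cov.index(cname)] = f
                pop[endo.index(r), cov.index(cname)] = p
        mats["KA"] = make_parameter_matrix("KA", free, pop, endo, cov)

        free = np.zeros((len(endo), len(endo)), dtype=object)
        pop = np.zeros((len(endo), len(endo)))
        for r, rv in (gmats.get("BE") or {}).items():
            for cname, cell in rv.items():
                if r not in endo or cname not in endo:
                    raise ConfigError(
                        f"model.groups.{gname}.BE: unknown variable "
                        f"{r!r}/{cname!r}")
                f, p = _parse_cell(cell, f"model.groups.{gname}.BE.{r}.{cname}")
                free[endo.index(r), endo.index(cname)] = f
                pop[endo.index(r), endo.index(cname)] = p
        mats["BE"] = make_parameter_matrix("BE", free, pop, endo, endo)

        free = np.zeros((len(endo), len(endo)), dtype=object)
        pop = np.zeros((len(endo), len(endo)))
        for r, cell in (gmats.get("PS") or {}).items():
            if r not in endo:
                raise ConfigError(f"model.groups.{gname}.PS: unknown row {r!r}")
            f, p = _parse_cell(cell, f"model.groups.{gname}.PS.{r}",
                               allow_auto=True)
            j = endo.index(r)
            if f == "auto":
                auto_cells.setdefault(gname, []).append(j)
                free[j, j] = f"psi.{r}" if not multigroup else f"psi.{r}.{gname}"
                pop[j, j] = 1.0  # placeholder until solved
            else:
                free[j, j] = f
                pop[j, j] = p
        mats["PS"] = make_parameter_matrix("PS", free, pop, endo, endo)

        if "AL" in gmats:
            free = np.zeros(len(endo), dtype=object)
            pop = np.zeros(len(endo))
            for r, cell in gmats["AL"].items():
                if r not in endo:
                    raise ConfigError(f"model.groups.{gname}.AL: unknown row {r!r}")
                f, p = _parse_cell(cell, f"model.groups.{gname}.AL.{r}")
                free[endo.index(r)] = f
                pop[endo.index(r)] = p
            mats["AL"] = make_parameter_matrix("AL", free, pop, endo)
        groups[gname] = mats

    spec = assemble_model(groups, endogenous=endo, covariates=cov,
                          defined=list(mcfg.get("defined") or []),
                          meanstructure=meanstructure)

    if auto_cells:
        psi_by_group = {}
        for gname, rows in auto_cells.items():
            if single_design is not None:
                moments = covariate_moments(single_design)
            elif isinstance(designs.get(gname), DesignMatrix):
                moments = covariate_moments(designs[gname])
            else:
                raise ConfigError(
                    f"model.groups.{gname}.PS: 'auto' needs a design with "
                    f"covariates to standardize against")
            try:
                psi = solve_residual_variances(spec, moments, group=gname)
            except ValueError as e:
                raise ConfigError(f"model.groups.{gname}.PS: {e}") from e
            current = np.diag(spec.groups[gname]["PS"].population).copy()
            for j in rows:
                current[j] = psi[j]
            psi_by_group[gname] = current
        spec = apply_solved_psi(spec, psi_by_group)

    name = (cfg.get("study") or {}).get("name", "study")
    return StudySpec(population=spec, analysis=spec,
                     design=single_design if single_design is not None else designs,
                     name=name, **{**dict(nrep=1000, seed=12345, alpha=0.05,
                                          methods=("delta", "mcci"),
                                          mcci_draws=20_000), **mc})
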