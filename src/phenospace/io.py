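"""Configuration files, scenario execution and tabular output.

Models and scenarios are plain YAML; matrices and tables are written as
TSV, scalar results and provenance as JSON.  Every run_scenario output
directory carries a provenance record (scenario echo, package version,
wall-clock) so results are reproducible and diff-able.
"""

from __future__ import annotations

import json
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design_space import DesignSpace, build_design_space, default_clock_slice
from .fitness import (
    CLOCK_CLASSES,
    LAC_TOLERANCE,
    ToleranceData,
    aggregate_distribution,
    fit_bias_parameters,
    fitness_profile,
    selection_for_fraction,
    time_zero_distribution,
)
from .model import GMAEquation, GMASystem, PowerLawTerm, build_clock_model
from .mutation import MutationModel, build_transition_matrix
from .population import (
    FitnessProfile,
    PopulationState,
    equilibrium,
    frequency_rate,
    grow_absolute,
    integrate_frequencies,
)

__all__ = [
    "load_model",
    "save_model",
    "packaged_path",
    "load_scenario",
    "Scenario",
    "run_scenario",
]


class SchemaError(ValueError):
    """A config file violates the documented schema."""

    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.field_path = path


def packaged_path(name: str) -> Path:
    """Path to a packaged data file (e.g. 'clock.yaml', 'scenarios/fig5_neutral_bias.yaml')."""
    return Path(str(resources.files("phenospace").joinpath("data", name)))


def _term_to_dict(term: PowerLawTerm) -> dict:
    return {"coefficient": term.coefficient, "exponents": dict(term.exponents)}


def _term_from_dict(data: dict, where: str) -> PowerLawTerm:
    try:
        return PowerLawTerm(float(data["coefficient"]), dict(data.get("exponents", {})))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(where, f"bad power-law term: {exc}") from exc


def save_model(system: GMASystem, path: str | Path) -> None:
    doc = {
        "dependent_variables": list(system.dependent_variables),
        "auxiliary_variables": list(system.auxiliary_variables),
        "parameters": dict(system.parameters),
        "kinetic_orders": dict(system.kinetic_orders),
        "equations": [
            {
                "target": eq.target,
                "kind": eq.kind,
                "positive_terms": [_term_to_dict(t) for t in eq.positive_terms],
                "negative_terms": [_term_to_dict(t) for t in eq.negative_terms],
            }
            for eq in system.equations
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> GMASystem:
    """Load a GMA system from YAML ('clock' resolves to the packaged fixture)."""
    if str(path) == "clock":
        path = packaged_path("clock.yaml")
    doc = yaml.safe_load(Path(path).read_text())
    for key in ("dependent_variables", "auxiliary_variables", "parameters", "equations"):
        if key not in doc:
            raise SchemaError(key, "missing required key")
    equations = []
    for i, eq in enumerate(doc["equations"]):
        where = f"equations[{i}]"
        for key in ("target", "kind", "positive_terms", "negative_terms"):
            if key not in eq:
                raise SchemaError(f"{where}.{key}", "missing required key")
        equations.append(
            GMAEquation(
                target=eq["target"],
                kind=eq["kind"],
                positive_terms=tuple(
                    _term_from_dict(t, f"{where}.positive_terms") for t in eq["positive_terms"]
                ),
                negative_terms=tuple(
                    _term_from_dict(t, f"{where}.negative_terms") for t in eq["negative_terms"]
                ),
            )
        )
    return GMASystem(
        equations=tuple(equations),
        dependent_variables=tuple(doc["dependent_variables"]),
        auxiliary_variables=tuple(doc["auxiliary_variables"]),
        parameters={k: float(v) for k, v in doc["parameters"].items()},
        kinetic_orders={k: float(v) for k, v in doc.get("kinetic_orders", {}).items()},
    )


class Scenario:
    """A named, reproducible pipeline run (see data/scenarios/*.yaml)."""

    KINDS = (
        "enumerate",
        "equilibrium",
        "trajectory-impose",
        "trajectory-remove",
        "chemostat",
        "fit-bias",
        "back-select",
        "time-zero",
    )

    def __init__(self, doc: dict, name: str = "scenario"):
        self.name = name
        self.doc = doc
        self.kind = self._get("run", str)
        if self.kind not in self.KINDS:
            raise SchemaError("run", f"unknown run kind {self.kind!r}")
        self.model_ref = doc.get("model", "clock")
        mut = doc.get("mutation", {})
        try:
            self.mutation = MutationModel(
                lam=float(mut.get("lambda", 0.6)),
                delta=float(mut.get("delta", 1.85)),
                pi=float(mut.get("pi", 6.0)),
                m=float(mut.get("m", 1e-7)),
            )
        except ValueError as exc:
            raise SchemaError("mutation", str(exc)) from exc
        fit = doc.get("fitness", {})
        self.fitness_mode = fit.get("mode", "neutral")
        self.mu_star = float(fit.get("mu7_star", 1.0))
        self.horizon = float(doc.get("horizon", 1e9))
        self.target_total = float(doc.get("target_total", 1e13))
        self.target_fraction = float(doc.get("target_fraction", 0.60))
        self.founder = int(doc.get("founder", 7))
        self.seed = int(doc.get("seed", 0))

    def _get(self, key, typ):
        if key not in self.doc:
            raise SchemaError(key, "missing required key")
        value = self.doc[key]
        if not isinstance(value, typ):
            raise SchemaError(key, f"expected {typ.__name__}, got {type(value).__name__}")
        return value


def load_scenario(path: str | Path) -> Scenario:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise SchemaError("<root>", "scenario file must be a mapping")
    return Scenario(doc, name=path.stem)


def build_clock_space(width: float = 6.0) -> DesignSpace:
    system = build_clock_model(2, 2)
    return build_design_space(system, default_clock_slice(system, width=width))


def _space_table(space: DesignSpace) -> pd.DataFrame:
    rows = []
    for num in space.numbers:
        r = space.regions[num]
        free = space.slice.free_parameters
        rows.append(
            {
                "phenotype": num,
                "signature": str(r.signature),
                "area": r.area,
                **{f"tol_{p}_min": r.tolerances[p][0] for p in free},
                **{f"tol_{p}_max": r.tolerances[p][1] for p in free},
                **{f"centroid_{p}": r.centroid[p] for p in free},
                "n_positive_real": r.eigen.n_positive_real,
                "has_complex_pair": r.eigen.has_complex_pair,
                "zero_area": r.zero_area,
            }
        )
    return pd.DataFrame(rows)


def _state_table(state: PopulationState) -> pd.DataFrame:
    return pd.DataFrame(
        {"phenotype": list(state.R), "frequency": list(state.R.values())}
    )


def run_scenario(scenario: Scenario, out_dir: str | Path) -> dict:
    """Execute a scenario; writes TSV/JSON outputs plus a provenance record."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    system = load_model(scenario.model_ref)
    space = build_design_space(system, default_clock_slice(system, width=scenario.mutation.pi))
    tm = build_transition_matrix(space, scenario.mutation)
    numbers = space.numbers
    fitness = fitness_profile(
        scenario.fitness_mode, numbers=numbers, space=space, mu_star=scenario.mu_star
    )
    m = scenario.mutation.m
    meta: dict = {"scenario": scenario.doc, "version": __version__, "kind": scenario.kind}

    if scenario.kind == "enumerate":
        _space_table(space).to_csv(out / "design_space.tsv", sep="\t", index=False)
    elif scenario.kind == "equilibrium":
        eq = equilibrium(tm, fitness, m)
        _state_table(eq).to_csv(out / "equilibrium.tsv", sep="\t", index=False)
        meta["aggregates"] = aggregate_distribution(eq)
        rates = np.abs(list(frequency_rate(eq, tm, fitness, m).values()))
        meta["residual"] = float(rates.max())
    elif scenario.kind in ("trajectory-impose", "trajectory-remove"):
        neutral_like = FitnessProfile(mu=fitness.mu, selected=fitness.selected, mu_star=1.0)
        selecting = FitnessProfile(
            mu=fitness.mu, selected=fitness.selected, mu_star=scenario.mu_star
        )
        if scenario.kind == "trajectory-impose":
            start, run_fit = equilibrium(tm, neutral_like, m), selecting
        else:
            start, run_fit = equilibrium(tm, selecting, m), neutral_like
        frame, events = integrate_frequencies(start, tm, run_fit, m, scenario.horizon)
        frame.to_csv(out / "trajectory.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"tau": e.tau, "a": e.pair[0], "b": e.pair[1]} for e in events]
        ).to_csv(out / "rank_changes.tsv", sep="\t", index=False)
        meta["last_rank_change"] = events[-1].tau if events else None
    elif scenario.kind == "chemostat":
        pop = grow_absolute(scenario.founder, tm, fitness, m, scenario.target_total)
        pd.DataFrame(
            {"phenotype": list(pop.N), "cells": list(pop.N.values())}
        ).to_csv(out / "chemostat.tsv", sep="\t", index=False)
        meta["generations"] = pop.tau
    elif scenario.kind == "fit-bias":
        data = scenario.doc.get("tolerance_data")
        tol = (
            ToleranceData(**data) if data else LAC_TOLERANCE
        )
        lam, delta = fit_bias_parameters(tol, space, donor=7, parameter="K_N")
        meta["fit"] = {"lambda": lam, "delta": delta}
    elif scenario.kind == "back-select":
        mu_star = selection_for_fraction(scenario.target_fraction, tm, fitness, m)
        meta["back_select"] = {
            "mu7_star": mu_star,
            "selection_coefficient": mu_star - 1.0,
        }
    elif scenario.kind == "time-zero":
        dist = time_zero_distribution(space, scenario.mutation, donor=7, parameter="K_N")
        meta["time_zero"] = dist.by_class()

    meta["wall_clock_s"] = time.time() - t0
    (out / "provenance.json").write_text(json.dumps(meta, indent=2, default=str))
    return meta
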