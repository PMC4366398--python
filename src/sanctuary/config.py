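"""Scenario config files (YAML), tabular output, and shipped fixtures.

A scenario file names its kind and supplies the parameter blocks the
builders need.  Supported kinds:

``two_compartment``
    explicit ``compartments`` (beta/alpha/drug), ``drug_response``,
    ``mutation`` {u}, ``migration`` {v, topology}, ``n_genotypes``,
    ``census`` mapping "genotype,compartment" -> count.
``two_lesion`` / ``ring`` / ``onion``
    keyword blocks mirroring the corresponding scenario dataclasses.
``pathway``
    a ``landscape`` block (b00..d11) plus u and v.

Unknown keys are rejected; every field filled from a default is reported so
a run's resolved configuration can be echoed for provenance.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .fitness import CompartmentSpec, DrugResponseParams, RateTable, build_rate_table
from .model import BranchingModel, MigrationSpec, MutationSpec, build_model
from .pathways import PathwayLandscape
from .pgf import PopulationCensus
from .scenarios import (
    OnionScenario,
    RingScenario,
    TwoLesionScenario,
    build_onion,
    build_ring,
    build_two_lesion,
)

__all__ = ["ScenarioConfig", "load_config", "write_table", "fixture_path", "list_fixtures"]

KINDS = ("two_compartment", "two_lesion", "ring", "onion", "pathway")


@dataclass
class ScenarioConfig:
    """A parsed scenario: kind, raw resolved mapping, and defaulted fields."""

    kind: str
    data: dict
    defaulted: list[str]
    path: str | None = None

    def build(self):
        """Instantiate (BranchingModel, PopulationCensus) or a pathway spec."""
        if self.kind == "two_compartment":
            return _build_two_compartment(self.data)
        if self.kind == "two_lesion":
            return build_two_lesion(TwoLesionScenario(**_scenario_kwargs(self.data)))
        if self.kind == "ring":
            start = self.data.get("start_compartment")
            return build_ring(
                RingScenario(**_scenario_kwargs(self.data, drop=("start_compartment",))),
                start_compartment=start,
            )
        if self.kind == "onion":
            return build_onion(OnionScenario(**_scenario_kwargs(self.data)))
        if self.kind == "pathway":
            land = self.data["landscape"]
            return (
                PathwayLandscape(**land),
                float(self.data["mutation"]["u"]),
                float(self.data["migration"]["v"]),
            )
        raise ConfigurationError(f"unknown scenario kind {self.kind!r}")

    def save(self, path) -> None:
        """Echo the resolved config (for provenance / reproducibility)."""
        payload = {"kind": self.kind, **self.data}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigurationError(f"missing required field {context}.{key}")
    return mapping[key]


_DATACLASS_FOR_KIND = {
    "two_lesion": TwoLesionScenario,
    "ring": RingScenario,
    "onion": OnionScenario,
}


def _scenario_kwargs(data: dict, drop=()) -> dict:
    kwargs = {k: v for k, v in data.items() if k not in drop}
    if "drug_response" in kwargs:
        kwargs["drug_response"] = DrugResponseParams(**kwargs["drug_response"])
    return kwargs


def _build_two_compartment(data: dict):
    n = int(data.get("n_genotypes", 2))
    if "drug_response" in data:
        comps = [CompartmentSpec(**c) for c in _require(data, "compartments", "config")]
        rates = build_rate_table(comps, n, DrugResponseParams(**data["drug_response"]))
    elif "birth" in data:
        rates = RateTable(
            birth=np.asarray(data["birth"], dtype=float),
            death=np.asarray(data["death"], dtype=float),
        )
    else:
        raise ConfigurationError(
            "two_compartment config needs either a drug_response block or "
            "explicit birth/death matrices"
        )
    mut = MutationSpec(float(_require(_require(data, "mutation", "config"), "u", "mutation")))
    mig_block = _require(data, "migration", "config")
    mig = MigrationSpec(
        float(_require(mig_block, "v", "migration")),
        mig_block.get("topology", "pairwise"),
    )
    model = build_model(rates, mut, mig)
    census_map = {
        tuple(int(x) for x in key.split(",")): count
        for key, count in _require(data, "census", "config").items()
    }
    return model, PopulationCensus.from_dict(model, census_map)


def load_config(path) -> ScenarioConfig:
    """Parse and validate a scenario YAML file.

    Raises ConfigurationError naming the offending field for schema
    violations; unknown keys are rejected rather than ignored.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    kind = raw.pop("kind", None)
    if kind not in KINDS:
        raise ConfigurationError(f"config.kind must be one of {KINDS}, got {kind!r}")
    defaulted: list[str] = []
    if kind == "two_compartment":
        _check_keys(
            raw,
            {"compartments", "drug_response", "birth", "death", "n_genotypes",
             "mutation", "migration", "census"},
            "two_compartment config",
        )
        for key in ("mutation", "migration", "census"):
            _require(raw, key, "config")
        if "drug_response" in raw:
            _require(raw, "compartments", "config")
        _require(raw["mutation"], "u", "mutation")
        _require(raw["migration"], "v", "migration")
    elif kind == "pathway":
        _check_keys(raw, {"landscape", "mutation", "migration"}, "pathway config")
        land = _require(raw, "landscape", "config")
        _check_keys(land, {"b00", "d00", "b10", "d10", "b01", "d01", "b11", "d11"},
                    "pathway landscape")
        for key in ("b00", "d00", "b10", "d10", "b01", "d01", "b11", "d11"):
            _require(land, key, "landscape")
        _require(_require(raw, "mutation", "config"), "u", "mutation")
        _require(_require(raw, "migration", "config"), "v", "migration")
    else:
        cls = _DATACLASS_FOR_KIND[kind]
        allowed = {f.name for f in dataclasses.fields(cls)}
        if kind == "ring":
            allowed.add("start_compartment")
        _check_keys(raw, allowed, f"{kind} config")
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                defaulted.append(f.name)
    cfg = ScenarioConfig(kind=kind, data=raw, defaulted=defaulted, path=str(path))
    cfg.build()  # validate eagerly so errors point at the file
    return cfg


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a TSV with a header row and full-precision scientific floats."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.17e")


def fixture_path(name: str) -> Path:
    """Path of a shipped scenario fixture, e.g. ``fixture_path('two_lesion_worst_case')``."""
    if not name.endswith(".yaml"):
        name = name + ".yaml"
    base = importlib.resources.files("sanctuary") / "data" / "scenarios" / name
    if not base.is_file():
        raise ConfigurationError(f"no shipped scenario named {name!r}")
    return Path(str(base))


def list_fixtures() -> list[str]:
    base = importlib.resources.files("sanctuary") / "data" / "scenarios"
    return sorted(p.name.removesuffix(".yaml") for p in base.iterdir() if p.name.endswith(".yaml"))
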