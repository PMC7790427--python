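"""YAML configuration round-tripping for run parameters and treatment arms.

A config file has a top-level ``params`` mapping (any subset of the
simulation parameters; nested blocks for ``recruit``, ``activation`` and
``standin``) and an optional ``treatment`` mapping.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import yaml

from .agents import ActivationParams
from .engine import SimParams
from .grid import Neighborhood
from .intracellular import StandInConstants
from .recruitment import RecruitParams
from .treatment import TreatmentSpec

_NESTED = {
    "recruit": RecruitParams,
    "activation": ActivationParams,
    "standin": StandInConstants,
}


def params_from_dict(d: dict) -> SimParams:
    d = dict(d or {})
    for key, cls in _NESTED.items():
        if key in d and isinstance(d[key], dict):
            block = dict(d[key])
            if cls is StandInConstants:
                for tup in ("alpha", "beta"):
                    if tup in block:
                        block[tup] = tuple(block[tup])
            d[key] = cls(**block)
    if "neighborhood" in d and isinstance(d["neighborhood"], str):
        d["neighborhood"] = Neighborhood(d["neighborhood"])
    if "cytokine_ranges" in d:
        d["cytokine_ranges"] = {k: tuple(v) for k, v in d["cytokine_ranges"].items()}
    return SimParams(**d)


def treatment_from_dict(d: Optional[dict]) -> Optional[TreatmentSpec]:
    if not d:
        return None
    return TreatmentSpec(**d)


def load_config(path: str | Path) -> tuple[SimParams, Optional[TreatmentSpec]]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return params_from_dict(doc.get("params", {})), treatment_from_dict(doc.get("treatment"))


def dump_config(params: SimParams, treatment: Optional[TreatmentSpec],
                path: str | Path) -> None:
    doc: dict = {"params": dataclasses.asdict(params)}
    doc["params"]["neighborhood"] = params.neighborhood.value
    if treatment is not None:
        doc["treatment"] = dataclasses.asdict(treatment)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
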