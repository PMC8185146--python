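"""Structured run configuration (YAML or JSON).

A config file names either input match logs or a simulation block,
plus field geometry and analysis options::

    geometry:
      total_length: 120
      boundary_yardlines: [0, 20, 45, 75, 100, 120]
    simulation:          # either this ...
      n_matches: 14
      seed: 1
      quarters: 4
      points_per_quarter: 12
    inputs:              # ... or a list of log files
      - game1.csv
    analysis:
      po_denominator: pulls     # or: possessions
      alpha: 0.05
    output:
      format: csv               # log serialization format
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import yaml

from .game_model import FieldGeometry
from .simulate import SimulationParams

_SIM_KEYS = {
    "quarters",
    "points_per_quarter",
    "turnover_downfield_prob",
    "period_end_prob",
    "callahan_prob",
    "allow_own_end_score",
    "home_team",
    "away_team",
    "home_receives_first",
    "seed",
    "pull_landing_dist",
    "outcome_given_origin",
}


@dataclass
class RunConfig:
    geometry: FieldGeometry = field(default_factory=FieldGeometry)
    inputs: List[Path] = field(default_factory=list)
    simulation: Optional[Dict] = None
    n_matches: int = 14
    po_denominator: str = "pulls"
    alpha: float = 0.05
    log_format: str = "csv"

    def simulation_params(self, seed: Optional[int] = None) -> SimulationParams:
        block = dict(self.simulation or {})
        block.pop("n_matches", None)
        unknown = set(block) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        if seed is not None:
            block["seed"] = seed
        return SimulationParams(**block)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")

    geom_block = doc.get("geometry", {})
    geometry = FieldGeometry(
        total_length=float(geom_block.get("total_length", 120)),
        boundary_yardlines=tuple(
            float(b) for b in geom_block.get("boundary_yardlines", (0, 20, 45, 75, 100, 120))
        ),
    )
    sim_block = doc.get("simulation")
    analysis = doc.get("analysis", {})
    output = doc.get("output", {})
    cfg = RunConfig(
        geometry=geometry,
        inputs=[Path(p) for p in doc.get("inputs", [])],
        simulation=sim_block,
        n_matches=int((sim_block or {}).get("n_matches", 14)),
        po_denominator=analysis.get("po_denominator", "pulls"),
        alpha=float(analysis.get("alpha", 0.05)),
        log_format=output.get("format", "csv"),
    )
    if cfg.po_denominator not in ("pulls", "possessions"):
        raise ValueError("analysis.po_denominator must be 'pulls' or 'possessions'")
    if cfg.log_format not in ("csv", "json"):
        raise ValueError("output.format must be 'csv' or 'json'")
    if not cfg.inputs and cfg.simulation is None:
        raise ValueError("config must provide either 'inputs' or a 'simulation' block")
    return cfg
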