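"""YAML/JSON configuration for the simulation front ends.

Schema (all keys optional; defaults in parentheses)::

    growth:
      A0: 20.0          # μm²
      Amax: 120.0       # μm²
      T_unperturbed: 100.0   # min
      m: 0.3            # μm²·min⁻¹
    cycles:
      unperturbed: {mean: 100.0, sd: 10.0}      # min
      sac_active:  {mean: 200.0, delay: 200.0}  # min
    sim:
      n_cells: 200
      n_cycles: 20
      dt: 10.0          # min
      seed: 0
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .growth import CycleTimeModel, GrowthParams

__all__ = ["SimConfig", "load_config"]


@dataclass
class SimConfig:
    growth: GrowthParams = field(default_factory=GrowthParams)
    unperturbed: CycleTimeModel = field(default_factory=CycleTimeModel.unperturbed)
    sac_active: CycleTimeModel = field(default_factory=CycleTimeModel.sac_active)
    n_cells: int = 200
    n_cycles: int = 20
    dt: float = 10.0
    seed: int = 0


def load_config(path: str | Path) -> SimConfig:
    """Read a YAML or JSON config file into a :class:`SimConfig`."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    growth = GrowthParams(**raw.get("growth", {}))
    cycles = raw.get("cycles", {})
    unp = CycleTimeModel.unperturbed(**cycles.get("unperturbed", {}))
    sac = CycleTimeModel.sac_active(**cycles.get("sac_active", {}))
    sim = raw.get("sim", {})
    return SimConfig(
        growth=growth,
        unperturbed=unp,
        sac_active=sac,
        n_cells=int(sim.get("n_cells", 200)),
        n_cycles=int(sim.get("n_cycles", 20)),
        dt=float(sim.get("dt", 10.0)),
        seed=int(sim.get("seed", 0)),
    )
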