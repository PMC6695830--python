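"""Run configuration (YAML) and potential-spec sidecars."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine import EngineConfig
from .errors import ParameterError
from .model import PotentialSpec, Well
from .supervision import SupervisionConfig

__all__ = [
    "RunConfig",
    "write_potential_yaml",
    "read_potential_yaml",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run.

    ``system`` either carries the generator keywords of the built-in funnel
    model (``{"generated": {...}}``) or points at a PDB file
    (``{"pdb": "path"}``); referenced paths must exist at load time.
    """

    system: dict = field(default_factory=lambda: {"generated": {}})
    engine: EngineConfig = field(default_factory=EngineConfig)
    supervision: SupervisionConfig = field(default_factory=SupervisionConfig)
    analysis: dict = field(default_factory=dict)
    output_dir: str = "sumd_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        system = raw.get("system", {"generated": {}})
        if "pdb" in system and not Path(system["pdb"]).exists():
            raise ParameterError(f"system PDB path does not exist: {system['pdb']}")
        return cls(
            system=system,
            engine=EngineConfig(**raw.get("engine", {})),
            supervision=SupervisionConfig(**raw.get("supervision", {})),
            analysis=raw.get("analysis", {}),
            output_dir=raw.get("output_dir", "sumd_out"),
            log_level=raw.get("log_level", "INFO"),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "system": self.system,
            "engine": asdict(self.engine),
            "supervision": {
                k: v for k, v in asdict(self.supervision).items() if v is not None
            },
            "analysis": self.analysis,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def write_potential_yaml(spec: PotentialSpec, path: str | Path) -> None:
    """Serialise a :class:`PotentialSpec` as a YAML sidecar."""
    payload = {
        "wells": [
            {
                "center": [float(x) for x in w.center],
                "depth": float(w.depth),
                "width": float(w.width),
                "label": w.label,
            }
            for w in spec.wells
        ],
        "bead_positions": np.asarray(spec.bead_positions).tolist(),
        "bead_epsilon": float(spec.bead_epsilon),
        "bead_sigma": float(spec.bead_sigma),
        "bead_charges": (
            None if spec.bead_charges is None else np.asarray(spec.bead_charges).tolist()
        ),
        "ligand_charge": float(spec.ligand_charge),
        "dielectric": float(spec.dielectric),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_potential_yaml(path: str | Path) -> PotentialSpec:
    raw = yaml.safe_load(Path(path).read_text())
    return PotentialSpec(
        wells=[
            Well(np.array(w["center"]), w["depth"], w["width"], w.get("label", ""))
            for w in raw.get("wells", [])
        ],
        bead_positions=np.array(raw.get("bead_positions", []), dtype=float).reshape(-1, 3),
        bead_epsilon=raw.get("bead_epsilon", 1.0),
        bead_sigma=raw.get("bead_sigma", 2.5),
        bead_charges=(
            None if raw.get("bead_charges") is None else np.array(raw["bead_charges"])
        ),
        ligand_charge=raw.get("ligand_charge", 0.0),
        dielectric=raw.get("dielectric", 1.0),
    )
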