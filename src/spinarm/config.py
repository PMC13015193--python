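"""Declarative plant/wiring configuration (YAML export and loading).

The circuit variants and plant constants are defined in code (they carry
invariants a flat file cannot express), but every run can be audited
against the shipped YAML tables: one wiring table per variant (one row
per synapse: pre, post, sign) plus the plant parameter block.  A test
asserts the shipped tables and the constructors agree.
"""

from __future__ import annotations

from dataclasses import asdict
from importlib import resources
from pathlib import Path

import yaml

from . import afferents, mechanics
from .circuits import VARIANTS, build_topology

_CONFIG_PKG = "spinarm.data"


def plant_config() -> dict:
    """The full plant parameter block as a plain dictionary."""
    return {
        "segments": [asdict(s) for s in
                     (mechanics.HUMERUS, mechanics.FOREARM, mechanics.HAND)],
        "muscles": {
            "biceps": asdict(mechanics.biceps_params()),
            "triceps": asdict(mechanics.triceps_params()),
        },
        "afferents": {
            "flexor_spindle": asdict(afferents.flexor_spindle_params()),
            "extensor_spindle": asdict(afferents.extensor_spindle_params()),
            "gto": asdict(afferents.GTOParams()),
        },
        "joint": {
            "inertia": mechanics.forearm_inertia(),
            "damping": mechanics.DEFAULT_JOINT_DAMPING,
            "angle_range_deg": [mechanics.ANGLE_MIN, mechanics.ANGLE_MAX],
        },
    }


def wiring_table(variant: str) -> dict:
    """Wiring and parameter-target lists of one variant as a dictionary."""
    topo = build_topology(variant)
    return {
        "variant": variant,
        "parameter_count": topo.parameter_count,
        "neurons": topo.neuron_names,
        "afferents": list(topo.afferents),
        "synapses": [
            {"pre": s.pre, "post": s.post, "sign": s.sign,
             "max_conductance": s.max_conductance}
            for s in topo.synapses
        ],
        "set_neuron_targets": list(topo.set_neuron_targets),
        "set_synapse_targets": [list(k) for k in topo.set_synapse_targets],
        "go_targets": list(topo.go_targets),
    }


def export_all(directory: Path) -> list[Path]:
    """Write the plant block and all five wiring tables to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    p = directory / "plant.yaml"
    p.write_text(yaml.safe_dump(plant_config(), sort_keys=False))
    written.append(p)
    for variant in VARIANTS:
        p = directory / f"wiring_{variant}.yaml"
        p.write_text(yaml.safe_dump(wiring_table(variant), sort_keys=False))
        written.append(p)
    return written


def load_shipped(name: str) -> dict:
    """Load one of the YAML tables shipped inside the package."""
    with resources.files(_CONFIG_PKG).joinpath(name).open() as fh:
        return yaml.safe_load(fh)
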