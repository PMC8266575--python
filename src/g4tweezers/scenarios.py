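"""Packaged simulation scenarios.

A scenario bundles everything needed to simulate and analyse one G4 design:
its sequence annotation, the conformational ensemble (Bell states built from
peak forces by modal-force inversion at a fixed transition-state distance),
the ramp protocol, elasticity and noise constants, refolding kinetics, and —
for melting scenarios — a melting temperature and transition width.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .bell import BellState, RampProtocol, state_from_modal_force
from .config import noise_from_config, polymer_from_config, protocol_from_config
from .polymer import PolymerParams
from .sequences import (
    FoldingTopology,
    SequenceAnnotation,
    expected_step_nt,
    load_reference_sequences,
)
from .simulate import NoiseModel, StateMixture

__all__ = ["Scenario", "load_scenario", "list_scenarios", "load_melting_scenario",
           "list_melting_scenarios"]

_TOPOLOGY_LABELS = {
    "full": FoldingTopology.FULL,
    "gvbq_5p": FoldingTopology.GVBQ_5P,
    "gvbq_3p": FoldingTopology.GVBQ_3P,
}


@dataclass(frozen=True)
class Scenario:
    """One named simulation condition with its ground-truth parameters."""

    name: str
    description: str
    annotation: SequenceAnnotation | None
    mixture: StateMixture
    protocol: RampProtocol
    polymer: PolymerParams
    noise: NoiseModel
    p_st: float
    k_fold: float
    truth_modal_forces: tuple[float, ...]
    truth_weights: tuple[float, ...]  # fractions of cycles

    @property
    def truth_event_weights(self) -> tuple[float, ...]:
        total = sum(self.truth_weights)
        return tuple(w / total for w in self.truth_weights)


def _raw() -> dict:
    text = resources.files("g4tweezers").joinpath("data/scenarios.yaml").read_text()
    return yaml.safe_load(text)


def list_scenarios() -> list[str]:
    return sorted(_raw()["scenarios"].keys())


def list_melting_scenarios() -> list[str]:
    return sorted(_raw()["melting_scenarios"].keys())


def load_scenario(name: str) -> Scenario:
    raw = _raw()
    try:
        entry = raw["scenarios"][name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(list_scenarios())}"
        ) from None
    defaults = raw["defaults"]
    cfg = {
        "polymer": defaults["polymer"],
        "protocol": defaults["protocol"],
        "noise": defaults["noise"],
    }
    protocol = protocol_from_config(cfg)
    polymer = polymer_from_config(cfg)
    noise = noise_from_config(cfg)
    dx = float(entry.get("dx_nm", defaults["dx_nm"]))

    annotation = None
    if entry.get("sequence"):
        annotation = load_reference_sequences()[entry["sequence"]]

    states: list[BellState] = []
    weights: list[float] = []
    modal_forces: list[float] = []
    for spec in entry["states"]:
        state = state_from_modal_force(
            spec["modal_force_pN"],
            dx=spec.get("dx_nm", dx),
            protocol=protocol,
            step_nt=spec["step_nt"],
            label=spec["label"],
        )
        # Cross-check declared step sizes against the sequence topology when
        # the label names one.
        topology = _TOPOLOGY_LABELS.get(spec["label"])
        if topology is not None and annotation is not None:
            expected = expected_step_nt(annotation, topology)
            if expected != spec["step_nt"]:
                raise ValueError(
                    f"{name}/{spec['label']}: step_nt {spec['step_nt']} "
                    f"inconsistent with sequence-derived {expected}"
                )
        states.append(state)
        weights.append(float(spec["weight"]))
        modal_forces.append(float(spec["modal_force_pN"]))

    mixture = StateMixture(
        states=tuple(states),
        weights=tuple(weights),
        w_unfolded=float(entry.get("w_unfolded", 0.0)),
    )
    kin = entry["kinetics"]
    return Scenario(
        name=name,
        description=entry.get("description", "").strip(),
        annotation=annotation,
        mixture=mixture,
        protocol=protocol,
        polymer=polymer,
        noise=noise,
        p_st=float(kin["p_st"]),
        k_fold=float(kin["k_fold_per_s"]),
        truth_modal_forces=tuple(modal_forces),
        truth_weights=tuple(weights),
    )


def load_melting_scenario(name: str) -> dict:
    raw = _raw()
    try:
        entry = raw["melting_scenarios"][name]
    except KeyError:
        raise KeyError(
            f"unknown melting scenario {name!r}; available: "
            f"{', '.join(list_melting_scenarios())}"
        ) from None
    return {"tm": float(entry["tm_C"]), "width": float(entry["width_C"])}
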