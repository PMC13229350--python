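"""Graded schizophrenia perturbations of the microcircuit.

A condition is a triple of reduction fractions: PV interneuron output
(synaptic GABA and PV-attributed tonic inhibition), NMDA input onto PV
interneurons (Pyr→PV and stimulus→PV NMDA conductance), and SST output
(synaptic GABA and SST-attributed tonic inhibition).  The reference disease
model pairs a 22% PV output reduction with a 20% NMDA input reduction, as
estimated from postmortem expression changes; graded variants pair equal
percentages.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from .circuit import CircuitGraph
from .config import TonicInhibitionParams

__all__ = ["Condition", "make_condition", "apply_condition", "HEALTHY", "preset"]


@dataclass(frozen=True)
class Condition:
    pv_output_reduction: float = 0.0
    pv_nmda_input_reduction: float = 0.0
    sst_reduction: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("pv_output_reduction", "pv_nmda_input_reduction", "sst_reduction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                "c_pv{:g}_nmda{:g}_sst{:g}".format(
                    self.pv_output_reduction,
                    self.pv_nmda_input_reduction,
                    self.sst_reduction,
                ),
            )

    @property
    def is_healthy(self) -> bool:
        return (
            self.pv_output_reduction == 0.0
            and self.pv_nmda_input_reduction == 0.0
            and self.sst_reduction == 0.0
        )


def make_condition(
    pv_output: float = 0.0,
    pv_nmda: float = 0.0,
    sst: float = 0.0,
    label: str = "",
) -> Condition:
    return Condition(pv_output, pv_nmda, sst, label)


HEALTHY = Condition(0.0, 0.0, 0.0, "HEALTHY")


def preset(name: str) -> Condition:
    """Named disease presets.

    ``SCZ_20`` is the reference model (22% PV output with 20% NMDA input).
    ``SCZ_x`` for x in {10,30,40,50} pairs equal output/NMDA percentages.
    Suffixes select single mechanisms or populations: ``SCZ_x_output``,
    ``SCZ_x_NMDA``, ``SCZ_x_SST``, ``SCZ_x_PV`` (= both PV mechanisms),
    ``SCZ_x_PV+SST`` (all three at x).
    """

    key = name.strip()
    if key.upper() == "HEALTHY":
        return HEALTHY
    if not key.upper().startswith("SCZ_"):
        raise ValueError(f"unknown condition preset {name!r}")
    parts = key.split("_", 2)
    x = float(parts[1]) / 100.0
    mech = parts[2] if len(parts) > 2 else ""
    if mech == "" or mech.upper() == "PV":
        if parts[1] == "20" and mech == "":
            return Condition(0.22, 0.20, 0.0, "SCZ_20")
        return Condition(x, x, 0.0, key)
    mech_u = mech.upper()
    if mech_u == "SST":
        return Condition(0.0, 0.0, x, key)
    if mech_u == "PV+SST":
        return Condition(x, x, x, key)
    if mech_u == "OUTPUT":
        return Condition(x, 0.0, 0.0, key)
    if mech_u == "NMDA":
        return Condition(0.0, x, 0.0, key)
    raise ValueError(f"unknown condition preset {name!r}")


def apply_condition(
    circuit: CircuitGraph,
    tonic: TonicInhibitionParams,
    condition: Condition,
) -> tuple[CircuitGraph, TonicInhibitionParams]:
    """Return a perturbed copy of (circuit, tonic params); originals untouched.

    Scaling is linear and compartment-agnostic on the edge list:

    - GABA conductance of PV-presynaptic edges × (1 − pv_output)
    - GABA conductance of SST-presynaptic edges × (1 − sst)
    - NMDA conductance of Pyr→PV edges × (1 − pv_nmda); AMPA untouched
    - tonic conductance: PV-attributed share × (1 − pv_output),
      SST-attributed share × (1 − sst), for all neurons
    """

    out = circuit.copy()
    tonic_out = copy.deepcopy(tonic)
    if condition.is_healthy:
        return out, tonic_out

    types = circuit.neurons.set_index("id")["type"]
    pre_type = out.edges["pre"].map(types)
    post_type = out.edges["post"].map(types)

    if condition.pv_output_reduction:
        mask = (pre_type == "PV").to_numpy()
        out.edges.loc[mask, "g_gaba_nS"] *= 1.0 - condition.pv_output_reduction
    if condition.sst_reduction:
        mask = (pre_type == "SST").to_numpy()
        out.edges.loc[mask, "g_gaba_nS"] *= 1.0 - condition.sst_reduction
    if condition.pv_nmda_input_reduction:
        mask = ((pre_type == "Pyr") & (post_type == "PV")).to_numpy()
        out.edges.loc[mask, "g_nmda_nS"] *= 1.0 - condition.pv_nmda_input_reduction

    # fractions now encode the surviving share of each source; they need not
    # sum to 1 under disease (attribute assignment skips __post_init__)
    tonic_out.pv_fraction = tonic.pv_fraction * (1.0 - condition.pv_output_reduction)
    tonic_out.sst_fraction = tonic.sst_fraction * (1.0 - condition.sst_reduction)
    return out, tonic_out
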