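"""Randomized microcircuit construction.

Neurons are placed i.i.d. uniformly in a tissue block spanning human L2/3
(z measured as depth below the pia, positive downward), typed by
largest-remainder rounding of the population fractions, and connected
independently per ordered pair according to per-class Bernoulli
probabilities with compartment targeting (PV→Pyr basal/somatic, SST→Pyr
apical) and receptor content split by the AMPA:NMDA ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CircuitConfig, CircuitVolume, ConnectionRule, PopulationSpec

__all__ = [
    "CircuitGraph",
    "place_neurons",
    "sample_connectivity",
    "build_circuit",
    "type_counts",
]


def type_counts(n: int, populations: list[PopulationSpec]) -> dict[str, int]:
    """Deterministic per-type counts: round(fraction*n) with largest-remainder
    correction so the counts sum to n (independent of any seed)."""

    if n <= 0:
        raise ValueError("n must be positive")
    fracs = np.array([p.fraction for p in populations], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("population fractions must sum to 1")
    raw = fracs * n
    counts = np.floor(raw + 0.5).astype(int)  # round-half-up, platform-stable
    remainders = raw - np.floor(raw)
    # fix the total by adjusting the largest/smallest remainders
    while counts.sum() > n:
        counts[np.argmin(np.where(counts > 0, remainders, np.inf))] -= 1
    while counts.sum() < n:
        counts[np.argmax(remainders)] += 1
    return {p.name: int(c) for p, c in zip(populations, counts)}


def place_neurons(
    n: int,
    populations: list[PopulationSpec],
    volume: CircuitVolume,
    seed: int,
) -> pd.DataFrame:
    """Place ``n`` neurons uniformly in ``volume`` and assign types.

    Returns a DataFrame with columns id, type, x_um, y_um, z_um; ids are
    0-based and grouped by population in the order given.
    """

    counts = type_counts(n, populations)
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(0.0, 1.0, size=(n, 3))
    xyz[:, 0] *= volume.x_extent
    xyz[:, 1] *= volume.y_extent
    xyz[:, 2] = volume.depth_offset + xyz[:, 2] * volume.z_extent
    types = np.concatenate(
        [np.full(counts[p.name], p.name, dtype=object) for p in populations]
    )
    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "type": types,
            "x_um": xyz[:, 0],
            "y_um": xyz[:, 1],
            "z_um": xyz[:, 2],
        }
    )


def sample_connectivity(
    neurons: pd.DataFrame,
    rules: list[ConnectionRule],
    seed: int,
) -> pd.DataFrame:
    """Draw the synaptic edge list.

    Each ordered pair of distinct neurons (pre, post) is connected
    independently with its class probability.  Edges carry effective peak
    conductances: excitatory classes g_AMPA = peak and g_NMDA = peak * ratio
    (the stated 1:ratio convention); inhibitory classes g_GABA = peak.

    Returns a DataFrame with columns pre, post, compartment, g_ampa_nS,
    g_nmda_nS, g_gaba_nS.
    """

    rng = np.random.default_rng(seed)
    ids_by_type = {
        t: neurons.loc[neurons["type"] == t, "id"].to_numpy()
        for t in neurons["type"].unique()
    }
    chunks = []
    for rule in rules:
        pre_ids = ids_by_type.get(rule.pre)
        post_ids = ids_by_type.get(rule.post)
        if pre_ids is None or post_ids is None or rule.probability == 0.0:
            continue
        mask = rng.random((pre_ids.size, post_ids.size)) < rule.probability
        if rule.pre == rule.post:
            np.fill_diagonal(mask, False)  # no self-connections
        pre_idx, post_idx = np.nonzero(mask)
        if pre_idx.size == 0:
            continue
        if rule.receptor_set == "AMPA+NMDA":
            g_ampa = rule.peak_conductance
            g_nmda = rule.peak_conductance * rule.ampa_nmda_ratio
            g_gaba = 0.0
        else:
            g_ampa = g_nmda = 0.0
            g_gaba = rule.peak_conductance
        chunks.append(
            pd.DataFrame(
                {
                    "pre": pre_ids[pre_idx],
                    "post": post_ids[post_idx],
                    "compartment": rule.target_compartment,
                    "g_ampa_nS": g_ampa,
                    "g_nmda_nS": g_nmda,
                    "g_gaba_nS": g_gaba,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["pre", "post", "compartment", "g_ampa_nS", "g_nmda_nS", "g_gaba_nS"]
        )
    edges = pd.concat(chunks, ignore_index=True)
    edges.sort_values(["pre", "post", "compartment"], inplace=True, kind="mergesort")
    edges.reset_index(drop=True, inplace=True)
    return edges


@dataclass
class CircuitGraph:
    """One randomized microcircuit instance: neuron table, edge table, and the
    config + seeds that produced it."""

    neurons: pd.DataFrame
    edges: pd.DataFrame
    config: CircuitConfig
    seed_record: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def ids_of(self, population: str) -> np.ndarray:
        return self.neurons.loc[self.neurons["type"] == population, "id"].to_numpy()

    def counts(self) -> dict[str, int]:
        return self.neurons["type"].value_counts().to_dict()

    def copy(self) -> "CircuitGraph":
        return CircuitGraph(
            self.neurons.copy(), self.edges.copy(), self.config, dict(self.seed_record)
        )

    # -- serialization ---------------------------------------------------
    def to_csv(self, neurons_path, edges_path) -> None:
        self.neurons.to_csv(neurons_path, index=False)
        self.edges.to_csv(edges_path, index=False)

    @staticmethod
    def from_csv(neurons_path, edges_path, config: CircuitConfig) -> "CircuitGraph":
        neurons = pd.read_csv(neurons_path)
        edges = pd.read_csv(edges_path)
        return CircuitGraph(neurons, edges, config)


def build_circuit(config: CircuitConfig, seed: int) -> CircuitGraph:
    """Build one randomized circuit: placement and connectivity are both
    redrawn per seed, from independent named streams derived from ``seed``."""

    ss = np.random.SeedSequence(seed)
    placement_seed, connectivity_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)
    )
    neurons = place_neurons(config.n_neurons, config.populations, config.volume, placement_seed)
    edges = sample_connectivity(neurons, config.rules, connectivity_seed)
    return CircuitGraph(
        neurons,
        edges,
        config,
        seed_record={
            "master": int(seed),
            "placement": placement_seed,
            "connectivity": connectivity_seed,
        },
    )
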