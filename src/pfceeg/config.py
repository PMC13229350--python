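"""Declarative configuration for the microcircuit, dynamics and analysis chain.

Every tunable quantity in the package lives here as a dataclass field with
units in the field name or docstring.  ``default_config()`` returns the
calibrated defaults used throughout; a TOML file with the same nesting can
override any subset via :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field


POPULATIONS = ("Pyr", "PV", "SST", "VIP")


@dataclass
class PopulationSpec:
    """One neuron population: its name, fraction of the circuit, and the key
    into the neuron-parameter table."""

    name: str
    fraction: float
    neuron_params_ref: str = ""

    def __post_init__(self) -> None:
        if self.name not in POPULATIONS:
            raise ValueError(f"unknown population {self.name!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if not self.neuron_params_ref:
            self.neuron_params_ref = self.name


def default_populations() -> list[PopulationSpec]:
    # Human PFC L2/3: 72% pyramidal, 28% interneurons split 9/5/14 PV/SST/VIP.
    return [
        PopulationSpec("Pyr", 0.72),
        PopulationSpec("PV", 0.09),
        PopulationSpec("SST", 0.05),
        PopulationSpec("VIP", 0.14),
    ]


@dataclass
class CircuitVolume:
    """Tissue block the somata occupy, in micrometres.  Depth is measured
    below the pia (positive downward); the default block spans human L2/3."""

    x_extent: float = 500.0
    y_extent: float = 500.0
    z_extent: float = 950.0
    depth_offset: float = 250.0

    def __post_init__(self) -> None:
        if min(self.x_extent, self.y_extent, self.z_extent) <= 0:
            raise ValueError("volume extents must be positive")


@dataclass
class ConnectionRule:
    """Probabilistic connection class between two populations.

    ``peak_conductance`` is the effective per-connection conductance in nS
    (per-contact conductance times contact count, collapsed).  Excitatory
    rules carry AMPA+NMDA with ``g_NMDA = g_AMPA * ampa_nmda_ratio``;
    inhibitory rules carry GABA_A only.
    """

    pre: str
    post: str
    probability: float
    target_compartment: str = "basal_somatic"  # or "apical"
    receptor_set: str = "AMPA+NMDA"  # or "GABA_A"
    peak_conductance: float = 1.0
    ampa_nmda_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(
                f"connection probability {self.probability} outside [0, 1]"
            )
        if self.target_compartment not in ("basal_somatic", "apical"):
            raise ValueError(f"bad compartment {self.target_compartment!r}")
        if self.receptor_set not in ("AMPA+NMDA", "GABA_A"):
            raise ValueError(f"bad receptor set {self.receptor_set!r}")
        if self.peak_conductance < 0:
            raise ValueError("peak conductance must be >= 0")


def default_connection_rules() -> list[ConnectionRule]:
    """Connection-probability and conductance table.

    Only the Pyr→Pyr probability (0.15) is a measured human value; the rest
    follow standard rodent L2/3 motifs — strong PV→Pyr/PV→PV perisomatic
    inhibition, SST→everything-but-SST dendritic inhibition, VIP
    predominantly disinhibiting through SST — and are free calibration
    parameters.  Pyr→Pyr recurrence lands on the apical dendrite
    (lateral/top-down excitation); interneurons are single-compartment so
    their afferents use the somatic compartment.  PV→Pyr targets the
    basal/somatic compartment and SST→Pyr the apical dendrite.
    """

    E, I = "AMPA+NMDA", "GABA_A"
    r = ConnectionRule
    return [
        # excitatory
        r("Pyr", "Pyr", 0.15, "apical", E, 2.00, 1.0),
        r("Pyr", "PV", 0.30, "basal_somatic", E, 0.80, 0.2),
        r("Pyr", "SST", 0.15, "basal_somatic", E, 0.80, 1.0),
        r("Pyr", "VIP", 0.10, "basal_somatic", E, 0.35, 1.0),
        # PV: perisomatic inhibition
        r("PV", "Pyr", 0.35, "basal_somatic", I, 2.00),
        r("PV", "PV", 0.35, "basal_somatic", I, 1.50),
        r("PV", "SST", 0.15, "basal_somatic", I, 0.60),
        r("PV", "VIP", 0.10, "basal_somatic", I, 0.60),
        # SST: dendritic inhibition, avoids other SST
        r("SST", "Pyr", 0.30, "apical", I, 2.00),
        r("SST", "PV", 0.20, "basal_somatic", I, 0.60),
        r("SST", "SST", 0.0, "basal_somatic", I, 0.0),
        r("SST", "VIP", 0.10, "basal_somatic", I, 0.30),
        # VIP: disinhibitory, SST-dominant
        r("VIP", "Pyr", 0.03, "apical", I, 0.20),
        r("VIP", "PV", 0.05, "basal_somatic", I, 0.30),
        r("VIP", "SST", 0.25, "basal_somatic", I, 0.50),
        r("VIP", "VIP", 0.03, "basal_somatic", I, 0.20),
    ]


@dataclass
class NeuronParams:
    """Adaptive-exponential integrate-and-fire soma, with (Pyr only) a
    passive coupled apical compartment.

    Units: capacitance pF, conductance nS, voltage mV, time ms, current pA,
    area cm^2.  ``d_um`` is the sink–source separation used for the current
    dipole (Pyr only).
    """

    C_m: float  # somatic capacitance, pF
    g_L: float  # somatic leak, nS
    E_L: float  # leak reversal, mV
    V_T: float  # exponential threshold, mV
    delta_T: float  # slope factor, mV
    V_reset: float  # post-spike reset, mV
    a: float  # subthreshold adaptation coupling, nS
    b: float  # spike-triggered adaptation increment, pA
    tau_w: float  # adaptation time constant, ms
    t_ref: float = 2.0  # absolute refractory period, ms
    V_peak: float = 0.0  # spike detection level, mV
    area_cm2: float = 1.5e-5  # somatic-compartment membrane area
    # apical compartment (Pyr only; zero C_a marks single-compartment cells)
    C_a: float = 0.0
    g_La: float = 0.0
    g_c: float = 0.0  # inter-compartment coupling, nS
    d_um: float = 0.0  # dipole separation, um
    area_apical_cm2: float = 0.0

    @property
    def two_compartment(self) -> bool:
        return self.C_a > 0


def default_neuron_params() -> dict[str, NeuronParams]:
    """Per-type reduced neuron models.

    Pyr: regular spiking with slow adaptation (the adaptation loop paces the
    circuit's alpha-band rhythm); PV: fast spiking, negligible adaptation;
    SST: adapting; VIP: adapting, high input resistance.
    """

    return {
        "Pyr": NeuronParams(
            C_m=150.0, g_L=9.0, E_L=-71.0, V_T=-50.0, delta_T=2.0,
            V_reset=-60.0, a=4.0, b=150.0, tau_w=120.0,
            area_cm2=1.5e-5,
            C_a=90.0, g_La=3.5, g_c=12.0, d_um=400.0,
            area_apical_cm2=2.0e-5,
        ),
        "PV": NeuronParams(
            C_m=90.0, g_L=9.0, E_L=-68.0, V_T=-49.0, delta_T=0.8,
            V_reset=-56.0, a=0.0, b=3.0, tau_w=15.0,
            area_cm2=1.0e-5,
        ),
        "SST": NeuronParams(
            C_m=110.0, g_L=6.5, E_L=-64.0, V_T=-50.0, delta_T=1.5,
            V_reset=-58.0, a=3.0, b=35.0, tau_w=150.0,
            area_cm2=1.0e-5,
        ),
        "VIP": NeuronParams(
            C_m=70.0, g_L=5.0, E_L=-66.0, V_T=-50.0, delta_T=1.5,
            V_reset=-58.0, a=2.0, b=25.0, tau_w=120.0,
            area_cm2=0.8e-5,
        ),
    }


@dataclass
class SynapseKinetics:
    """Double-exponential receptor kinetics (ms) and reversal potentials (mV)."""

    tau_rise_ampa: float = 0.3
    tau_decay_ampa: float = 3.0
    tau_rise_nmda: float = 2.0
    tau_decay_nmda: float = 65.0
    tau_rise_gaba: float = 1.0
    tau_decay_gaba: float = 10.0
    E_exc: float = 0.0
    E_inh: float = -80.0
    delay_ms: float = 0.5
    mg_mM: float = 1.0

    def __post_init__(self) -> None:
        for rec in ("ampa", "nmda", "gaba"):
            tr = getattr(self, f"tau_rise_{rec}")
            td = getattr(self, f"tau_decay_{rec}")
            if not (td > tr > 0):
                raise ValueError(f"need tau_decay > tau_rise > 0 for {rec}")


@dataclass
class TonicInhibitionParams:
    """Outward-rectifying tonic GABA conductance.

    ``G_tonic`` is a density (mS/cm^2) converted to nS through the
    compartment membrane area.  The rectification sigmoid opens with
    depolarization (midpoint ``V50``, slope ``k``).  ``pv_fraction`` /
    ``sst_fraction`` attribute the tonic conductance to the two interneuron
    sources for disease scaling; on Pyr cells the PV-attributed share sits on
    the basal/somatic compartment and the SST share on the apical dendrite,
    mirroring their synaptic targeting.
    """

    G_tonic: float = 0.938  # mS/cm^2
    V50: float = -60.0
    k: float = 10.0
    E_rev: float = -80.0
    pv_fraction: float = 0.5
    sst_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.G_tonic < 0:
            raise ValueError("G_tonic must be >= 0")
        if abs(self.pv_fraction + self.sst_fraction - 1.0) > 1e-9:
            raise ValueError("tonic attribution fractions must sum to 1")


@dataclass
class OUParams:
    """Excitatory Ornstein–Uhlenbeck background drive (reversal 0 mV).

    ``base_pS`` is the per-process mean conductance in pS per population.
    Pyr cells additionally receive ``apical_fractions`` processes on the
    apical dendrite, each scaled by exp(x_rel).  ``sigma_frac`` is the
    stationary SD as a fraction of the mean; conductances are clipped at 0.
    ``scale`` holds the per-population calibration factors found by
    ``calibrate_background`` (multiplies the mean; SD follows).
    """

    base_pS: dict[str, float] = field(
        default_factory=lambda: {"Pyr": 28.0, "PV": 280.0, "SST": 30.0, "VIP": 66.0}
    )
    tau_ms: float = 3.0  # somatic processes
    tau_apical_ms: float = 25.0  # apical processes (slow envelope of background input)
    sigma_frac: float = 0.70
    apical_scale: float = 0.3  # calibration share applied to the apical processes
    apical_fractions: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    update_every_ms: float = 0.2  # OU substep (held between updates)
    heterogeneity_cv: float = 0.4  # per-neuron lognormal spread of the OU mean
    scale: dict[str, float] = field(
        # calibrated factors for the default circuit (healthy targets
        # 0.94 / 7.44 / 3.28 / 2.22 Hz); recomputed by calibrate_background
        default_factory=lambda: {"Pyr": 177.7, "PV": 15.5, "SST": 109.8, "VIP": 36.8}
    )


@dataclass
class SimParams:
    """Integration settings."""

    dt_ms: float = 0.025
    transient_ms: float = 500.0  # discarded from all statistics
    duration_resting_ms: float = 4500.0
    duration_trial_ms: float = 2000.0
    stimulus_onset_ms: float = 1600.0  # tone onset within an oddball trial

    def __post_init__(self) -> None:
        if not (0 < self.dt_ms <= 0.1):
            raise ValueError("dt must be in (0, 0.1] ms")


@dataclass
class CircuitConfig:
    """Everything needed to build and simulate one microcircuit."""

    n_neurons: int = 1000
    populations: list[PopulationSpec] = field(default_factory=default_populations)
    volume: CircuitVolume = field(default_factory=CircuitVolume)
    rules: list[ConnectionRule] = field(default_factory=default_connection_rules)
    neuron_params: dict[str, NeuronParams] = field(default_factory=default_neuron_params)
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    tonic: TonicInhibitionParams = field(default_factory=TonicInhibitionParams)
    ou: OUParams = field(default_factory=OUParams)
    sim: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {total}, not 1")


def default_config() -> CircuitConfig:
    return CircuitConfig()


def _update_dataclass(obj, data: dict):
    for key, value in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key {key!r} for {type(obj).__name__}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value)
        elif isinstance(current, dict) and isinstance(value, dict):
            current.update(value)
        else:
            setattr(obj, key, value)
    return obj


def load_config(path) -> CircuitConfig:
    """Load a TOML override file on top of the defaults.

    Top-level tables mirror the CircuitConfig nesting, e.g.::

        n_neurons = 500
        [ou]
        sigma_frac = 0.4
        [ou.scale]
        Pyr = 80.0
    """

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cfg = default_config()
    rules = data.pop("rules", None)
    pops = data.pop("populations", None)
    _update_dataclass(cfg, data)
    if rules is not None:
        cfg.rules = [ConnectionRule(**r) for r in rules]
    if pops is not None:
        cfg.populations = [PopulationSpec(**p) for p in pops]
    return cfg


def config_to_dict(cfg: CircuitConfig) -> dict:
    """JSON-serializable snapshot of a config (provenance records)."""

    return dataclasses.asdict(cfg)
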