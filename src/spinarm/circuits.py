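"""Non-spiking neurons, graded synapses and the named spinal circuit variants.

Each spinal unit is a leaky integrator standing in for the mean activity of
a neuron population: C dV/dt = g_leak (rest - V) + sum g_i (E_i - V) + I.
Transmission is graded: the postsynaptic conductance rises linearly from 0
at the presynaptic threshold potential to the maximal conductance at the
presynaptic saturation potential.

The full network has 12 spinal neurons (alpha and gamma motoneurons,
propriospinal, Ia, Ib and Renshaw interneurons, one of each per muscle),
four afferent nodes (Ia and Ib per muscle, driven algebraically by the
afferent models) and two muscle-membrane nodes.  SET commands target the
12 spinal neurons and the 30 spinal synapse gains; GO commands target the
8 interneurons.  Reduced variants delete afferents/interneurons wholesale;
their descending-parameter counts (50, 36, 14, 34, 38) name the variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EXC = "excitatory"
INH = "inhibitory"

# Node name lists.  Muscle-membrane nodes are integrated alongside neurons;
# afferent nodes are algebraic (set each tick by the afferent models).
SPINAL_NEURONS = (
    "FlxAlpha", "ExtAlpha", "FlxGamma", "ExtGamma", "FlxPN", "ExtPN",
    "FlxIaIN", "ExtIaIN", "FlxIbIN", "ExtIbIN", "FlxRenshaw", "ExtRenshaw",
)
MUSCLE_NODES = ("FlxMuscle", "ExtMuscle")
AFFERENT_NODES = ("Flx1a", "Ext1a", "Flx1b", "Ext1b")

REST_NEURON = -60.0  # mV
REST_AFFERENT = -65.0  # mV
E_EXC = -10.0  # mV
E_INH = -70.0  # mV
PRE_THRESHOLD = -60.0  # mV
PRE_SATURATION = -20.0  # mV
TAU_MEMBRANE = 0.010  # s
G_LEAK = 1.0  # conductance unit; injected currents are in g_leak * mV
# Hyperpolarization floor: injected current cannot drive a membrane far
# below the inhibitory reversal, so a hyperpolarizing SET command parks a
# neuron a recoverable ~20 mV under threshold instead of arbitrarily deep.
MEMBRANE_FLOOR = -80.0  # mV


@dataclass(frozen=True)
class NeuronSpec:
    name: str
    rest_potential: float = REST_NEURON  # mV
    membrane_time_constant: float = TAU_MEMBRANE  # s
    leak_conductance: float = G_LEAK

    def __post_init__(self) -> None:
        if self.membrane_time_constant <= 0 or self.leak_conductance <= 0:
            raise ValueError(f"{self.name}: time constant and leak must be > 0")


@dataclass(frozen=True)
class SynapseSpec:
    pre: str
    post: str
    sign: str  # excitatory | inhibitory
    max_conductance: float = 2.0
    pre_threshold: float = PRE_THRESHOLD  # mV
    pre_saturation: float = PRE_SATURATION  # mV
    reversal_potential: float | None = None  # mV; defaults by sign

    def __post_init__(self) -> None:
        if self.sign not in (EXC, INH):
            raise ValueError(f"unknown synapse sign {self.sign!r}")
        if self.pre_saturation <= self.pre_threshold:
            raise ValueError("pre_saturation must exceed pre_threshold")
        if self.reversal_potential is None:
            object.__setattr__(
                self, "reversal_potential", E_EXC if self.sign == EXC else E_INH
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.pre, self.post)


def graded_conductance(v_pre: float, syn: SynapseSpec, gain_multiplier: float = 1.0) -> float:
    """Piecewise-linear presynaptic-potential -> conductance map."""
    if gain_multiplier < 0:
        raise ValueError("gain_multiplier must be >= 0")
    frac = (v_pre - syn.pre_threshold) / (syn.pre_saturation - syn.pre_threshold)
    frac = min(1.0, max(0.0, frac))
    return gain_multiplier * syn.max_conductance * frac


def neuron_step(v: float, synaptic_inputs, injected_current: float,
                spec: NeuronSpec, dt: float) -> float:
    """One exact-exponential update of the leaky integrator.

    ``synaptic_inputs`` is an iterable of (conductance, reversal mV) pairs
    held constant across the step.  With constant inputs the ODE is linear,
    so the update uses the closed-form exponential relaxation toward
    V_inf = (g_l*rest + sum g_i*E_i + I) / (g_l + sum g_i).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    import math
    if not math.isfinite(v):
        raise FloatingPointError("non-finite membrane potential")
    g_total = spec.leak_conductance
    drive = spec.leak_conductance * spec.rest_potential + injected_current
    for g, e in synaptic_inputs:
        g_total += g
        drive += g * e
    v_inf = drive / g_total
    c = spec.membrane_time_constant * spec.leak_conductance
    return max(MEMBRANE_FLOOR, v_inf + (v - v_inf) * math.exp(-g_total / c * dt))


def _mirror(pre: str, post: str, sign: str) -> list[tuple[str, str, str]]:
    """Expand one Flx-side synapse into the Flx and Ext mirror pair."""
    def flip(name: str) -> str:
        if name.startswith("Flx"):
            return "Ext" + name[3:]
        if name.startswith("Ext"):
            return "Flx" + name[3:]
        return name
    return [(pre, post, sign), (flip(pre), flip(post), sign)]


def _full_synapses() -> list[tuple[str, str, str]]:
    """The 30 SET-adjustable spinal synapses of the full model.

    Mirror-symmetric, 15 per side: monosynaptic stretch reflex, Ia and Ib
    relays onto the propriospinal interneuron, reciprocal Ia inhibition,
    autogenic and crossed Ib inhibition, crossed propriospinal inhibition,
    and the Renshaw recurrent loop.
    """
    rows: list[tuple[str, str, str]] = []
    for pre, post, sign in (
        ("Flx1a", "FlxAlpha", EXC),     # monosynaptic stretch reflex
        ("Flx1a", "FlxPN", EXC),        # Ia relay to propriospinal IN
        ("Flx1a", "FlxIaIN", EXC),      # reciprocal-inhibition drive
        ("Flx1b", "FlxIbIN", EXC),      # tendon-organ relay
        ("Flx1b", "FlxPN", EXC),        # Ib assistive drive to PN
        ("FlxPN", "FlxAlpha", EXC),     # propriospinal excitation of MN
        ("FlxAlpha", "FlxRenshaw", EXC),
        ("FlxRenshaw", "FlxAlpha", INH),  # recurrent inhibition
        ("FlxRenshaw", "FlxIaIN", INH),
        ("FlxIaIN", "ExtAlpha", INH),   # reciprocal inhibition of antagonist
        ("FlxIaIN", "ExtIaIN", INH),    # mutual IaIN inhibition
        ("FlxIbIN", "FlxAlpha", INH),   # autogenic Ib inhibition
        ("FlxIbIN", "ExtAlpha", INH),   # crossed Ib action
        ("FlxIbIN", "ExtIbIN", INH),
        ("FlxPN", "ExtPN", INH),        # crossed propriospinal inhibition
    ):
        rows.extend(_mirror(pre, post, sign))
    return rows


# Fixed neuromuscular junctions (always present, not SET targets).
MUSCLE_SYNAPSES = (
    ("FlxAlpha", "FlxMuscle", EXC),
    ("ExtAlpha", "ExtMuscle", EXC),
)
MUSCLE_SYNAPSE_GAIN = 6.0

VARIANTS = ("full50", "noIb36", "iaOnly14", "noIa34", "noFeedback38")


@dataclass
class CircuitTopology:
    """Named wiring variant plus its SET/GO parameter-target lists."""

    variant: str
    neurons: list[NeuronSpec]
    synapses: list[SynapseSpec]
    set_neuron_targets: list[str]
    set_synapse_targets: list[tuple[str, str]]
    go_targets: list[str]
    afferents: list[str] = field(default_factory=lambda: list(AFFERENT_NODES))

    @property
    def parameter_count(self) -> int:
        return (len(self.set_neuron_targets) + len(self.set_synapse_targets)
                + len(self.go_targets))

    @property
    def neuron_names(self) -> list[str]:
        return [n.name for n in self.neurons]

    def synapse(self, pre: str, post: str) -> SynapseSpec:
        for s in self.synapses:
            if s.key == (pre, post):
                return s
        raise KeyError((pre, post))


def build_topology(variant: str, go_includes_alpha: bool = False) -> CircuitTopology:
    """Construct one of the named circuit variants.

    full50       12 SET neurons + 30 SET synapses + 8 GO interneurons
    noIb36       tendon-organ afferents, Ib INs and their synapses removed
    iaOnly14     only Ia->MN and Ia->PN->MN, no crossed connections
    noIa34       spindle afferents and Ia INs removed (gamma MNs retained
                 as SET targets)
    noFeedback38 all interneurons, no proprioceptive afferents (gamma MNs
                 dropped: without spindles they are inert)
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")

    rows = _full_synapses()
    neurons = list(SPINAL_NEURONS)
    afferents = list(AFFERENT_NODES)
    go = ["FlxPN", "ExtPN", "FlxIaIN", "ExtIaIN", "FlxIbIN", "ExtIbIN",
          "FlxRenshaw", "ExtRenshaw"]

    def drop_nodes(*names: str) -> None:
        nonlocal rows, neurons, afferents, go
        gone = set(names)
        rows = [r for r in rows if r[0] not in gone and r[1] not in gone]
        neurons = [n for n in neurons if n not in gone]
        afferents = [a for a in afferents if a not in gone]
        go = [g for g in go if g not in gone]

    if variant == "noIb36":
        drop_nodes("Flx1b", "Ext1b", "FlxIbIN", "ExtIbIN")
    elif variant == "iaOnly14":
        drop_nodes("Flx1b", "Ext1b", "FlxIbIN", "ExtIbIN",
                   "FlxIaIN", "ExtIaIN", "FlxRenshaw", "ExtRenshaw")
        rows = [r for r in rows if r[0][:3] == r[1][:3]]  # no crossed edges
    elif variant == "noIa34":
        drop_nodes("Flx1a", "Ext1a", "FlxIaIN", "ExtIaIN")
    elif variant == "noFeedback38":
        drop_nodes("Flx1a", "Ext1a", "Flx1b", "Ext1b", "FlxGamma", "ExtGamma")

    specs = [NeuronSpec(n) for n in neurons]
    specs += [NeuronSpec(n) for n in MUSCLE_NODES]

    synapses = [SynapseSpec(pre, post, sign) for pre, post, sign in rows]
    set_synapse_targets = [s.key for s in synapses]
    synapses += [
        SynapseSpec(pre, post, sign, max_conductance=MUSCLE_SYNAPSE_GAIN)
        for pre, post, sign in MUSCLE_SYNAPSES
    ]

    set_neurons = list(neurons)
    if go_includes_alpha:
        go = go + ["FlxAlpha", "ExtAlpha"]

    return CircuitTopology(
        variant=variant,
        neurons=specs,
        synapses=synapses,
        set_neuron_targets=set_neurons,
        set_synapse_targets=set_synapse_targets,
        go_targets=go,
        afferents=afferents,
    )
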