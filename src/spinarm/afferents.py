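"""Ia muscle-spindle and Ib Golgi-tendon-organ afferent models.

The spindle is a miniature Hill element riding in parallel with its host
muscle: it shares the muscle's length trajectory, and its serial-elastic
tension and tension rate encode muscle length and stretch velocity.  A
single mixed gamma motoneuron per muscle adds an active drive to the
spindle's contractile element, raising both the tonic (positional) and the
transient (rate) sensitivity.  When the shortening muscle lets the spindle
fall slack (zero serial tension) the Ia output clamps at its rest
potential: a released, passive spindle is silent, and only gamma drive can
restore a response during release.

The tendon organ is a memoryless saturating affine map of whole-muscle
tension; the paper's Ib activity tracks muscle force, so a minimal monotone
transducer suffices (plumbing, not a contribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .mechanics import MuscleParams, MuscleState, activation, tension_rate

GAMMA_THRESHOLD = -60.0  # mV; gamma drive engages above this


def _spindle_hill(name: str, slack_length: float) -> MuscleParams:
    """Miniature intrafusal Hill element: soft springs, negligible force."""
    return MuscleParams(
        name=name,
        damping_B=0.5,
        parallel_stiffness_Kpe=2.0,
        serial_stiffness_Kse=20.0,
        natural_length=slack_length,
        initial_length=slack_length,
        max_tension=5.0,
        # wide flat bell: length-tension scaling ~1 over the operating range
        lt_width_Lwidth=2.0,
        lt_resting_length=slack_length,
        st_amplitude=2.0,
        st_steepness=0.4,
        st_x_offset=-20.0,
        st_y_offset=-0.0225,  # zero active force at -60 mV after clamping
        length_at_angle_lo=slack_length,
        length_at_angle_hi=slack_length + 0.1,
    )


@dataclass(frozen=True)
class SpindleParams:
    """Spindle transducer constants.

    tension_gain_kT   mV of Ia depolarization per N of spindle tension
    tension_rate_gain_kdT  mV s / N on the tension rate ("acceleration"
                      component carried by the serial-spring velocity)
    gamma_gain        N of intrafusal drive per mV of suprathreshold gamma
                      motoneuron potential
    """

    hill_params: MuscleParams
    tension_gain_kT: float = 200.0  # mV/N
    tension_rate_gain_kdT: float = 8.0  # mV s / N
    rest_potential: float = -65.0  # mV
    gamma_gain: float = 0.002  # N/mV
    saturation: float = -10.0  # mV

    def __post_init__(self) -> None:
        if min(self.tension_gain_kT, self.tension_rate_gain_kdT, self.gamma_gain) < 0:
            raise ValueError("spindle gains must be >= 0")


def flexor_spindle_params() -> SpindleParams:
    """Flexor spindle slack at the shortest in-range flexor length (0.25 m)."""
    return SpindleParams(hill_params=_spindle_hill("flexor-spindle", 0.25))


def extensor_spindle_params() -> SpindleParams:
    """Extensor spindle slack at the shortest in-range extensor length (0.275 m)."""
    return SpindleParams(hill_params=_spindle_hill("extensor-spindle", 0.275))


@dataclass(frozen=True)
class GTOParams:
    """Golgi tendon organ: Ib potential = rest + kB * tension, saturating."""

    tension_gain_kB: float = 0.2  # mV/N
    rest_potential: float = -65.0  # mV
    saturation: float = -10.0  # mV

    def __post_init__(self) -> None:
        if self.tension_gain_kB < 0:
            raise ValueError("tension_gain_kB must be >= 0")
        if self.saturation <= self.rest_potential:
            raise ValueError("saturation must exceed rest_potential")


def gamma_drive(gamma_potential: float, p: SpindleParams) -> float:
    """Active intrafusal force (N) from the gamma motoneuron potential."""
    return p.gamma_gain * max(0.0, gamma_potential - GAMMA_THRESHOLD)


def spindle_tension_rate(spindle_tension: float, length: float, length_rate: float,
                         gamma_potential: float, p: SpindleParams) -> float:
    """dT/dt of the intrafusal Hill element (used by the coupled integrator)."""
    a = gamma_drive(gamma_potential, p)
    return tension_rate(spindle_tension, length, length_rate, a, p.hill_params)


def ia_potential(spindle_tension: float, spindle_tension_rate_: float,
                 p: SpindleParams) -> float:
    """Ia afferent potential (mV) from spindle tension and its rate.

    A slack spindle (zero tension) is clamped at rest regardless of the
    rate term; output saturates above, and is floored at rest - 10 mV so
    unloading transients stay bounded.
    """
    if spindle_tension <= 0.0:
        return p.rest_potential
    v = (p.rest_potential + p.tension_gain_kT * spindle_tension
         + p.tension_rate_gain_kdT * spindle_tension_rate_)
    return min(p.saturation, max(p.rest_potential - 10.0, v))


def spindle_step(spindle_state: MuscleState, imposed_length: float,
                 gamma_potential: float, dt: float, p: SpindleParams) -> tuple[float, MuscleState]:
    """Advance the spindle one step and return (Ia potential mV, new state).

    The intrafusal element tracks the imposed (muscle) length; gamma drive
    sets its active force.  Standalone convenience wrapper around the same
    dynamics the closed-loop integrator uses.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    ldot = (imposed_length - spindle_state.length) / dt
    a = gamma_drive(gamma_potential, p)

    def f(t_local: float, tension: float) -> float:
        length = spindle_state.length + ldot * t_local
        return tension_rate(tension, length, ldot, a, p.hill_params)

    t0 = spindle_state.tension
    k1 = f(0.0, t0)
    k2 = f(dt / 2, t0 + dt / 2 * k1)
    k3 = f(dt / 2, t0 + dt / 2 * k2)
    k4 = f(dt, t0 + dt * k3)
    t_new = max(0.0, t0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4))
    rate_now = f(dt, t_new) if t_new > 0 else 0.0
    out = ia_potential(t_new, rate_now, p)
    new_state = MuscleState(
        length=imposed_length, length_rate=ldot, tension=t_new,
        activation_A=a, membrane_potential=out,
    )
    return out, new_state


def gto_output(muscle_tension: float, p: GTOParams) -> float:
    """Ib afferent potential (mV) for a muscle tension (N)."""
    if muscle_tension < 0:
        raise ValueError("muscle tension must be >= 0")
    if not math.isfinite(muscle_tension):
        raise FloatingPointError("non-finite tension")
    return min(p.saturation, p.rest_potential + p.tension_gain_kB * muscle_tension)
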