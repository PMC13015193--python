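"""Forward dynamics of a single-hinge elbow driven by two antagonistic Hill muscles.

The plant is a forearm+hand compound rotating about the elbow in zero
gravity, flexed by a biceps-like muscle and extended by a triceps-like
muscle.  Each muscle is a linear Hill element: a serial spring ``Kse`` in
series with the parallel combination of a damper ``B``, a parallel spring
``Kpe`` and an active contractile force ``A``.  The active force is the
product of a sigmoidal stimulus-tension curve of the muscle membrane
potential and an inverted-parabola length-tension factor.

Joint angle is measured in degrees, 0 deg = full elbow extension,
120 deg = full flexion (hard stops at both ends).  Muscle length is an
affine function of joint angle (constant moment arm), anchored at the two
endpoint lengths of each muscle's operating range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

ANGLE_MIN = 0.0
ANGLE_MAX = 120.0
REST_POTENTIAL_MV = -60.0

DEG2RAD = math.pi / 180.0


@dataclass(frozen=True)
class SegmentSpec:
    """A rigid limb segment (uniform density bone model)."""

    name: str
    length: float  # m
    mass: float  # kg

    def __post_init__(self) -> None:
        if self.length <= 0 or self.mass <= 0:
            raise ValueError(f"segment {self.name}: length and mass must be > 0")


# Upper-limb segment table (lengths in m, masses in kg).
HUMERUS = SegmentSpec("humerus", 0.3370911395, 1.164)
FOREARM = SegmentSpec("forearm", 0.2831808226, 0.802)
HAND = SegmentSpec("hand", 0.19321, 0.966)


def forearm_inertia(forearm: SegmentSpec = FOREARM, hand: SegmentSpec = HAND) -> float:
    """Moment of inertia (kg m^2) of forearm+hand about the elbow.

    Forearm as a uniform rod pivoted at one end (m L^2 / 3); hand as a
    point mass at forearm length plus half the hand length.
    """
    i_forearm = forearm.mass * forearm.length**2 / 3.0
    r_hand = forearm.length + hand.length / 2.0
    return i_forearm + hand.mass * r_hand**2


@dataclass(frozen=True)
class MuscleParams:
    """Constants of one linear Hill muscle.

    ``st_steepness`` is per-millivolt after rescaling: the raw table value
    divided by ``ST_STEEPNESS_SCALE`` (default 500, i.e. 0.2/mV) so that the
    sigmoid is numerically well-behaved, yields zero force (after the
    ``st_y_offset`` shift and the clamp at 0) at the -60 mV rest potential,
    and spans its rise over the physiologically reachable -45..0 mV band.

    ``natural_length`` is the slack length of the parallel elastic element;
    it defaults to the top of the muscle's operating range so the passive
    plant is quiescent at every reachable posture.  ``initial_length`` keeps
    the muscle length at the full-extension start posture as metadata.
    """

    name: str
    damping_B: float  # N s / m
    parallel_stiffness_Kpe: float  # N / m
    serial_stiffness_Kse: float  # N / m
    natural_length: float  # m (parallel-spring slack length)
    initial_length: float  # m (length at the 0 deg posture)
    max_tension: float  # N
    lt_width_Lwidth: float  # m
    lt_resting_length: float  # m
    st_amplitude: float  # N
    st_steepness: float  # 1 / mV (already rescaled)
    st_x_offset: float  # mV
    st_y_offset: float  # N
    length_at_angle_lo: float  # m
    length_at_angle_hi: float  # m
    angle_lo: float = ANGLE_MIN  # deg
    angle_hi: float = ANGLE_MAX  # deg

    def __post_init__(self) -> None:
        if min(self.parallel_stiffness_Kpe, self.serial_stiffness_Kse) <= 0:
            raise ValueError(f"muscle {self.name}: stiffnesses must be > 0")
        if self.damping_B <= 0:
            raise ValueError(f"muscle {self.name}: damping must be > 0")
        if self.max_tension <= 0:
            raise ValueError(f"muscle {self.name}: max_tension must be > 0")
        if self.lt_width_Lwidth <= 0:
            raise ValueError(f"muscle {self.name}: Lwidth must be > 0")
        if self.length_at_angle_lo == self.length_at_angle_hi:
            raise ValueError(f"muscle {self.name}: degenerate length-angle map")

    @property
    def length_slope(self) -> float:
        """dL/d(angle) in m/deg (signed; negative for a flexor)."""
        return (self.length_at_angle_hi - self.length_at_angle_lo) / (
            self.angle_hi - self.angle_lo
        )

    @property
    def moment_arm(self) -> float:
        """Constant moment arm magnitude in m/rad."""
        return abs(self.length_slope) / DEG2RAD

    @property
    def is_flexor(self) -> bool:
        """A flexor shortens as the elbow flexes (negative length slope)."""
        return self.length_slope < 0


ST_STEEPNESS_SCALE = 500.0


def biceps_params() -> MuscleParams:
    """Elbow flexor: operating range 34 cm (0 deg) -> 25 cm (120 deg)."""
    return MuscleParams(
        name="biceps",
        damping_B=1.0,
        parallel_stiffness_Kpe=100.0,
        serial_stiffness_Kse=1000.0,
        natural_length=0.34,
        initial_length=0.33898,
        max_tension=400.0,
        lt_width_Lwidth=0.14,
        lt_resting_length=0.385,
        st_amplitude=400.0,
        st_steepness=100.0 / ST_STEEPNESS_SCALE,
        st_x_offset=-20.0,
        st_y_offset=-4.5,
        length_at_angle_lo=0.34,
        length_at_angle_hi=0.25,
    )


def triceps_params() -> MuscleParams:
    """Elbow extensor: operating range 27.5 cm (0 deg) -> 34.5 cm (120 deg)."""
    return MuscleParams(
        name="triceps",
        damping_B=1.0,
        parallel_stiffness_Kpe=100.0,
        serial_stiffness_Kse=1000.0,
        natural_length=0.345,
        initial_length=0.2725,
        max_tension=300.0,
        lt_width_Lwidth=0.35,
        lt_resting_length=0.385,
        st_amplitude=300.0,
        st_steepness=100.0 / ST_STEEPNESS_SCALE,
        st_x_offset=-30.0,
        st_y_offset=-4.0,
        length_at_angle_lo=0.275,
        length_at_angle_hi=0.345,
    )


@dataclass
class MuscleState:
    """Dynamic state of one Hill muscle."""

    length: float  # m
    length_rate: float = 0.0  # m/s
    tension: float = 0.0  # N
    activation_A: float = 0.0  # N
    membrane_potential: float = REST_POTENTIAL_MV  # mV

    def __post_init__(self) -> None:
        if not math.isfinite(self.membrane_potential):
            raise ValueError("membrane potential must be finite")
        self.tension = max(0.0, self.tension)
        self.activation_A = max(0.0, self.activation_A)


@dataclass
class JointState:
    """Elbow hinge state; angle in degrees (0 = full extension)."""

    angle: float = 0.0  # deg
    angular_velocity: float = 0.0  # deg/s
    inertia: float = field(default_factory=forearm_inertia)  # kg m^2

    def __post_init__(self) -> None:
        if not ANGLE_MIN <= self.angle <= ANGLE_MAX:
            raise ValueError(f"angle {self.angle} outside [{ANGLE_MIN}, {ANGLE_MAX}]")
        if self.inertia <= 0:
            raise ValueError("inertia must be > 0")


def muscle_length_of_angle(angle: float, muscle: MuscleParams) -> float:
    """Affine muscle length (m) at a joint angle (deg) within the hard stops."""
    if not ANGLE_MIN <= angle <= ANGLE_MAX:
        raise ValueError(f"angle {angle} outside [{ANGLE_MIN}, {ANGLE_MAX}] deg")
    return muscle.length_at_angle_lo + muscle.length_slope * (angle - muscle.angle_lo)


def stimulus_tension(v: float, muscle: MuscleParams) -> float:
    """Sigmoidal active drive (N) of the muscle membrane potential (mV).

    Zero (after clamping) at the -60 mV rest potential, saturating at
    ``st_amplitude + st_y_offset``.
    """
    if not math.isfinite(v):
        raise ValueError("membrane potential must be finite")
    z = muscle.st_steepness * (muscle.st_x_offset - v)
    # guard exp overflow for strongly hyperpolarized inputs
    if z > 500.0:
        sig = 0.0
    else:
        sig = muscle.st_amplitude / (1.0 + math.exp(z))
    return max(0.0, sig + muscle.st_y_offset)


def length_tension(length: float, muscle: MuscleParams) -> float:
    """Inverted-parabola length-tension factor in [0, 1].

    1 at the length-tension resting length, 0 at rest +/- Lwidth.  With the
    tabulated constants this spans ~0.07-0.90 over the flexor operating
    range and ~0.90-0.99 over the extensor range.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    x = (length - muscle.lt_resting_length) / muscle.lt_width_Lwidth
    return max(0.0, 1.0 - x * x)


def activation(v: float, length: float, muscle: MuscleParams) -> float:
    """Active contractile force A (N), clamped at max_tension."""
    a = stimulus_tension(v, muscle) * length_tension(length, muscle)
    return min(a, muscle.max_tension)


def tension_rate(tension: float, length: float, length_rate: float, a: float,
                 muscle: MuscleParams) -> float:
    """dT/dt of the linear Hill element.

    dT/dt = (Kse/B) * (Kpe*dx + B*dL/dt - (1 + Kpe/Kse)*T + A)

    with dx = max(0, L - slack length): the parallel spring engages only
    under stretch beyond its slack length.
    """
    kse = muscle.serial_stiffness_Kse
    kpe = muscle.parallel_stiffness_Kpe
    b = muscle.damping_B
    dx = max(0.0, length - muscle.natural_length)
    return (kse / b) * (kpe * dx + b * length_rate - (1.0 + kpe / kse) * tension + a)


def isometric_steady_tension(length: float, a: float, muscle: MuscleParams) -> float:
    """Closed-form fixed point of the Hill ODE at constant length and drive."""
    kpe = muscle.parallel_stiffness_Kpe
    kse = muscle.serial_stiffness_Kse
    dx = max(0.0, length - muscle.natural_length)
    return max(0.0, (kpe * dx + a) / (1.0 + kpe / kse))


def hill_step(state: MuscleState, driven_length: float, dt: float,
              muscle: MuscleParams) -> MuscleState:
    """Advance one muscle by ``dt`` seconds with its length imposed externally.

    RK4 on the scalar tension ODE; the length and its rate are interpolated
    linearly across the step.  Tension is clamped non-negative.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not (math.isfinite(state.tension) and math.isfinite(driven_length)):
        raise FloatingPointError("non-finite muscle state")
    ldot = (driven_length - state.length) / dt
    a = activation(state.membrane_potential, state.length, muscle)

    def f(t_local: float, tension: float) -> float:
        length = state.length + ldot * t_local
        return tension_rate(tension, length, ldot, a, muscle)

    t0 = state.tension
    k1 = f(0.0, t0)
    k2 = f(dt / 2, t0 + dt / 2 * k1)
    k3 = f(dt / 2, t0 + dt / 2 * k2)
    k4 = f(dt, t0 + dt * k3)
    t_new = t0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return replace(
        state,
        length=driven_length,
        length_rate=ldot,
        tension=max(0.0, t_new),
        activation_A=a,
    )


DEFAULT_JOINT_DAMPING = 0.3  # N m s / rad


def joint_step(joint: JointState, flexor_tension: float, extensor_tension: float,
               dt: float, flexor: MuscleParams | None = None,
               extensor: MuscleParams | None = None,
               joint_damping: float = DEFAULT_JOINT_DAMPING) -> JointState:
    """Advance the hinge by ``dt`` seconds under the two muscle tensions.

    alpha = (r_flex*T_flex - r_ext*T_ext - b*omega) / I, no gravity torque;
    the angle is clipped to the [0, 120] deg stops with the velocity zeroed
    there.  Semi-implicit Euler (velocity first) at the caller's dt.

    The viscous term stands in for all unmodelled passive dissipation at
    the joint (tissue, ligaments); without it the arm coasts for seconds
    after the muscles fall silent and no movement can settle.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    flexor = flexor or biceps_params()
    extensor = extensor or triceps_params()
    omega_rad = joint.angular_velocity * DEG2RAD
    torque = (flexor.moment_arm * flexor_tension
              - extensor.moment_arm * extensor_tension
              - joint_damping * omega_rad)
    alpha_rad = torque / joint.inertia
    omega_rad += alpha_rad * dt
    angle = joint.angle + omega_rad / DEG2RAD * dt
    velocity = omega_rad / DEG2RAD
    if angle <= ANGLE_MIN:
        angle, velocity = ANGLE_MIN, 0.0
    elif angle >= ANGLE_MAX:
        angle, velocity = ANGLE_MAX, 0.0
    return JointState(angle=angle, angular_velocity=velocity, inertia=joint.inertia)
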