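"""Closed-loop trial execution.

One trial integrates the coupled plant + spindle + tendon-organ + network
dynamics for 10 s under a decoded SET/GO command schedule.  The continuous
state is

    [theta, omega, T_flex, T_ext, Tsp_flex, Tsp_ext, V_1 ... V_n]

(joint angle/velocity in radians, muscle and spindle serial tensions in N,
membrane potentials of all integrated nodes in mV).  The four afferent
potentials are algebraic functions of that state, evaluated synchronously
inside the derivative, so transmission is delay-free and the whole system
is one smooth ODE between command switch times.  Integration is classic
fixed-step RK4 at 1 ms, run in three phases (pre-SET, SET, SET+GO) with
piecewise-constant commands; recordings are decimated to 10 ms.

Trials that blow up numerically are returned with ``failed=True`` rather
than raising, so exploration loops can treat them as invalid movements.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import afferents as aff
from . import mechanics as mech
from .circuits import AFFERENT_NODES, MEMBRANE_FLOOR, CircuitTopology
from .commands import CommandSchedule, CommandVector, CommandRanges, decode

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _NUMBA = True
except Exception:  # pragma: no cover
    _NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap

DEG2RAD = mech.DEG2RAD


@dataclass(frozen=True)
class SimConfig:
    physics_dt: float = 0.001  # s
    record_dt: float = 0.01  # s
    duration: float = 10.0  # s
    rng_seed: int = 0
    initial_angle: float = 0.0  # deg
    joint_damping: float = mech.DEFAULT_JOINT_DAMPING

    def __post_init__(self) -> None:
        if self.physics_dt > self.record_dt:
            raise ValueError("physics_dt must not exceed record_dt")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class LesionSpec:
    """Clamped nodes (label -> mV) and suppressed synapses ((pre, post) pairs)."""

    clamped_neurons: dict = field(default_factory=dict)
    suppressed_synapses: frozenset = frozenset()

    def validate(self, topology: CircuitTopology) -> None:
        known = set(topology.neuron_names) | set(topology.afferents)
        for name in self.clamped_neurons:
            if name not in known:
                raise KeyError(f"lesion targets unknown node {name!r}")
        keys = {s.key for s in topology.synapses}
        for pair in self.suppressed_synapses:
            if tuple(pair) not in keys:
                warnings.warn(
                    f"lesion suppresses absent synapse {pair}; no-op", stacklevel=2
                )


@dataclass
class SimTrace:
    """Uniformly sampled recording of one trial."""

    time: np.ndarray  # s
    angle: np.ndarray  # deg
    speed: np.ndarray  # deg/s
    potentials: dict  # label -> mV series (neurons, muscles, afferents)
    tensions: dict  # muscle label -> N series
    failed: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def flexor_emg(self) -> np.ndarray:
        """EMG envelope = flexor muscle membrane potential."""
        return self.potentials["FlxMuscle"]

    @property
    def extensor_emg(self) -> np.ndarray:
        return self.potentials["ExtMuscle"]

    def to_frame(self):
        import pandas as pd

        data = {"time": self.time, "angle": self.angle, "speed": self.speed}
        for k, v in self.potentials.items():
            data[f"V_{k}"] = v
        for k, v in self.tensions.items():
            data[f"T_{k}"] = v
        return pd.DataFrame(data)

    def write(self, csv_path, meta_path=None) -> None:
        """Tidy CSV (one row per sample) plus a JSON sidecar of configs."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        side = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
        side.write_text(json.dumps({"failed": self.failed, **self.meta}, indent=2))

    @classmethod
    def read(cls, csv_path, meta_path=None) -> "SimTrace":
        import pandas as pd

        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        side = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        failed = bool(meta.pop("failed", False))
        pots = {c[2:]: df[c].to_numpy() for c in df if c.startswith("V_")}
        tens = {c[2:]: df[c].to_numpy() for c in df if c.startswith("T_")}
        return cls(df["time"].to_numpy(), df["angle"].to_numpy(),
                   df["speed"].to_numpy(), pots, tens, failed, meta)


# ---------------------------------------------------------------------------
# compiled inner loop


@njit(cache=True)
def _deriv(y, dy, n_int, rest, g_leak, cap, inj, clamp_mask,
           syn_pre, syn_post, syn_g, syn_e, syn_thr, syn_sat,
           mus, geo, r_arm, mus_idx, spn, gamma_idx, gto, aff_clamp_mask,
           aff_clamp_val, inertia, b_joint, aff_out):
    theta = y[0]
    omega = y[1]
    theta_deg = theta / DEG2RAD
    omega_deg = omega / DEG2RAD

    # afferent potentials (algebraic)
    for m in range(2):
        length = geo[m, 0] + geo[m, 1] * theta_deg
        ldot = geo[m, 1] * omega_deg
        tmus = y[2 + m]
        tsp = y[4 + m]
        # spindle tension rate
        if gamma_idx[m] >= 0:
            vg = y[6 + gamma_idx[m]]
        else:
            vg = -60.0
        a_sp = spn[m, 9] * max(0.0, vg + 60.0)
        kse_s, kpe_s, b_s, slack_s = spn[m, 0], spn[m, 1], spn[m, 2], spn[m, 3]
        dts = (kse_s / b_s) * (kpe_s * max(0.0, length - slack_s) + b_s * ldot
                               - (1.0 + kpe_s / kse_s) * tsp + a_sp)
        dy[4 + m] = dts
        if tsp <= 0.0:
            v_ia = spn[m, 6]
            if dy[4 + m] < 0.0:
                dy[4 + m] = 0.0
        else:
            v_ia = spn[m, 6] + spn[m, 4] * tsp + spn[m, 5] * dts
            if v_ia > spn[m, 7]:
                v_ia = spn[m, 7]
            if v_ia < spn[m, 8]:
                v_ia = spn[m, 8]
        v_ib = gto[m, 1] + gto[m, 0] * max(0.0, tmus)
        if v_ib > gto[m, 2]:
            v_ib = gto[m, 2]
        aff_out[m] = v_ia
        aff_out[2 + m] = v_ib
    for k in range(4):
        if aff_clamp_mask[k]:
            aff_out[k] = aff_clamp_val[k]

    # muscle tension dynamics
    for m in range(2):
        length = geo[m, 0] + geo[m, 1] * theta_deg
        ldot = geo[m, 1] * omega_deg
        tmus = y[2 + m]
        vm = y[6 + mus_idx[m]]
        kse, kpe, b = mus[m, 0], mus[m, 1], mus[m, 2]
        slack = mus[m, 3]
        z = mus[m, 5] * (mus[m, 6] - vm)
        if z > 500.0:
            st = 0.0
        else:
            st = mus[m, 4] / (1.0 + math.exp(z))
        st = max(0.0, st + mus[m, 7])
        x = (length - mus[m, 8]) / mus[m, 9]
        lt = max(0.0, 1.0 - x * x)
        a = st * lt
        if a > mus[m, 10]:
            a = mus[m, 10]
        dt_m = (kse / b) * (kpe * max(0.0, length - slack) + b * ldot
                            - (1.0 + kpe / kse) * tmus + a)
        if tmus <= 0.0 and dt_m < 0.0:
            dt_m = 0.0
        dy[2 + m] = dt_m

    # network
    n_syn = syn_pre.shape[0]
    for i in range(n_int):
        dy[6 + i] = g_leak[i] * (rest[i] - y[6 + i]) + inj[i]
    for s in range(n_syn):
        p = syn_pre[s]
        if p < n_int:
            vpre = y[6 + p]
        else:
            vpre = aff_out[p - n_int]
        frac = (vpre - syn_thr[s]) / (syn_sat[s] - syn_thr[s])
        if frac < 0.0:
            frac = 0.0
        elif frac > 1.0:
            frac = 1.0
        g = syn_g[s] * frac
        q = syn_post[s]
        dy[6 + q] += g * (syn_e[s] - y[6 + q])
    for i in range(n_int):
        if clamp_mask[i]:
            dy[6 + i] = 0.0
        else:
            dy[6 + i] /= cap[i]

    # joint
    torque = (r_arm[0] * max(0.0, y[2]) - r_arm[1] * max(0.0, y[3])
              - b_joint * omega)
    dy[0] = omega
    dy[1] = torque / inertia


@njit(cache=True)
def _run_phase(y, n_steps, dt, step0, record_every,
               rec_angle, rec_speed, rec_v, rec_t_mus,
               n_int, rest, g_leak, cap, inj, clamp_mask, clamp_val,
               syn_pre, syn_post, syn_g, syn_e, syn_thr, syn_sat,
               mus, geo, r_arm, mus_idx, spn, gamma_idx, gto,
               aff_clamp_mask, aff_clamp_val, inertia, b_joint,
               theta_min, theta_max, v_floor):
    n = y.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    aff_out = np.empty(4)
    for i in range(n_int):
        if clamp_mask[i]:
            y[6 + i] = clamp_val[i]
    for step in range(n_steps):
        gstep = step0 + step
        if gstep % record_every == 0:
            _deriv(y, k1, n_int, rest, g_leak, cap, inj, clamp_mask,
                   syn_pre, syn_post, syn_g, syn_e, syn_thr, syn_sat,
                   mus, geo, r_arm, mus_idx, spn, gamma_idx, gto,
                   aff_clamp_mask, aff_clamp_val, inertia, b_joint, aff_out)
            ridx = gstep // record_every
            rec_angle[ridx] = y[0] / DEG2RAD
            rec_speed[ridx] = y[1] / DEG2RAD
            for i in range(n_int):
                rec_v[ridx, i] = y[6 + i]
            for k in range(4):
                rec_v[ridx, n_int + k] = aff_out[k]
            rec_t_mus[ridx, 0] = max(0.0, y[2])
            rec_t_mus[ridx, 1] = max(0.0, y[3])

        _deriv(y, k1, n_int, rest, g_leak, cap, inj, clamp_mask,
               syn_pre, syn_post, syn_g, syn_e, syn_thr, syn_sat,
               mus, geo, r_arm, mus_idx, spn, gamma_idx, gto,
               aff_clamp_mask, aff_clamp_val, inertia, b_joint, aff_out)
        for i in range(n):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _deriv(yt, k2, n_int, rest, g_leak, cap, inj, clamp_mask,
               syn_pre, syn_post, syn_g, syn_e, syn_thr, syn_sat,
               mus, geo, r_arm, mus_idx, spn, gamma_idx, gto,
               aff_clamp_mask, aff_clamp_val, inertia, b_joint, aff_out)
        for i in range(n):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _deriv(yt, k3, n_int, rest, g_leak, cap, inj, clamp_mask,
               syn_pre, syn_post, syn_g, syn_e, syn_thr, syn_sat,
               mus, geo, r_arm, mus_idx, spn, gamma_idx, gto,
               aff_clamp_mask, aff_clamp_val, inertia, b_joint, aff_out)
        for i in range(n):
            yt[i] = y[i] + dt * k3[i]
        _deriv(yt, k4, n_int, rest, g_leak, cap, inj, clamp_mask,
               syn_pre, syn_post, syn_g, syn_e, syn_thr, syn_sat,
               mus, geo, r_arm, mus_idx, spn, gamma_idx, gto,
               aff_clamp_mask, aff_clamp_val, inertia, b_joint, aff_out)
        for i in range(n):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

        # clamps and hard stops
        for i in range(2, 6):
            if y[i] < 0.0:
                y[i] = 0.0
        if y[0] <= theta_min:
            y[0] = theta_min
            if y[1] < 0.0:
                y[1] = 0.0
        elif y[0] >= theta_max:
            y[0] = theta_max
            if y[1] > 0.0:
                y[1] = 0.0
        for i in range(n_int):
            if y[6 + i] < v_floor:
                y[6 + i] = v_floor
            if clamp_mask[i]:
                y[6 + i] = clamp_val[i]
        ok = True
        for i in range(n):
            if not math.isfinite(y[i]):
                ok = False
                break
        if not ok:
            return gstep
    return -1


# ---------------------------------------------------------------------------
# trial assembly


class _CompiledModel:
    """Topology + plant compiled to the flat arrays the kernel consumes."""

    def __init__(self, topology: CircuitTopology,
                 flexor: mech.MuscleParams, extensor: mech.MuscleParams,
                 flx_spindle: aff.SpindleParams, ext_spindle: aff.SpindleParams,
                 gto_params: aff.GTOParams, joint: mech.JointState):
        self.topology = topology
        names = topology.neuron_names
        self.int_names = names
        self.n_int = len(names)
        self.index = {n: i for i, n in enumerate(names)}
        self.aff_index = {n: i for i, n in enumerate(AFFERENT_NODES)}

        self.rest = np.array([n.rest_potential for n in topology.neurons])
        self.g_leak = np.array([n.leak_conductance for n in topology.neurons])
        self.cap = np.array(
            [n.membrane_time_constant * n.leak_conductance for n in topology.neurons]
        )

        self.syn_specs = topology.synapses
        self.syn_pre = np.array(
            [self.index.get(s.pre, self.n_int + self.aff_index.get(s.pre, -99))
             for s in self.syn_specs], dtype=np.int64)
        self.syn_post = np.array([self.index[s.post] for s in self.syn_specs],
                                 dtype=np.int64)
        self.syn_gmax = np.array([s.max_conductance for s in self.syn_specs])
        self.syn_e = np.array([s.reversal_potential for s in self.syn_specs])
        self.syn_thr = np.array([s.pre_threshold for s in self.syn_specs])
        self.syn_sat = np.array([s.pre_saturation for s in self.syn_specs])
        self.adjustable = {s.key: i for i, s in enumerate(self.syn_specs)}
        self.fixed_gain = np.array(
            [0.0 if s.key in set(topology.set_synapse_targets) else 1.0
             for s in self.syn_specs])

        def mus_row(p: mech.MuscleParams):
            return [p.serial_stiffness_Kse, p.parallel_stiffness_Kpe, p.damping_B,
                    p.natural_length, p.st_amplitude, p.st_steepness,
                    p.st_x_offset, p.st_y_offset, p.lt_resting_length,
                    p.lt_width_Lwidth, p.max_tension]

        self.flexor, self.extensor = flexor, extensor
        self.mus = np.array([mus_row(flexor), mus_row(extensor)])
        self.geo = np.array(
            [[p.length_at_angle_lo, p.length_slope] for p in (flexor, extensor)]
        )
        self.r_arm = np.array([flexor.moment_arm, extensor.moment_arm])
        self.mus_idx = np.array(
            [self.index["FlxMuscle"], self.index["ExtMuscle"]], dtype=np.int64
        )

        def spn_row(p: aff.SpindleParams):
            h = p.hill_params
            return [h.serial_stiffness_Kse, h.parallel_stiffness_Kpe,
                    h.damping_B, h.natural_length, p.tension_gain_kT,
                    p.tension_rate_gain_kdT, p.rest_potential, p.saturation,
                    p.rest_potential - 10.0, p.gamma_gain]

        self.spindles = (flx_spindle, ext_spindle)
        self.spn = np.array([spn_row(flx_spindle), spn_row(ext_spindle)])
        self.gamma_idx = np.array(
            [self.index.get("FlxGamma", -1), self.index.get("ExtGamma", -1)],
            dtype=np.int64)
        self.gto = np.array(
            [[gto_params.tension_gain_kB, gto_params.rest_potential,
              gto_params.saturation]] * 2)
        self.joint = joint


def default_model(topology: CircuitTopology) -> _CompiledModel:
    return _CompiledModel(
        topology,
        mech.biceps_params(), mech.triceps_params(),
        aff.flexor_spindle_params(), aff.extensor_spindle_params(),
        aff.GTOParams(), mech.JointState(),
    )


def run_trial(vector: CommandVector, topology: CircuitTopology,
              model: _CompiledModel | None = None,
              sim: SimConfig | None = None,
              lesion: LesionSpec | None = None,
              ranges: CommandRanges | None = None,
              schedule: CommandSchedule | None = None) -> SimTrace:
    """Simulate one 10 s trial and return its recorded trace.

    Deterministic given identical inputs.  ``model`` may be prebuilt (and
    reused across trials) from :func:`default_model`; ``schedule`` may be
    passed directly instead of a vector for replay experiments.
    """
    sim = sim or SimConfig()
    model = model or default_model(topology)
    if schedule is None:
        schedule = decode(vector, topology, ranges)

    n_int = model.n_int
    clamp_mask = np.zeros(n_int, dtype=np.bool_)
    clamp_val = np.zeros(n_int)
    aff_clamp_mask = np.zeros(4, dtype=np.bool_)
    aff_clamp_val = np.zeros(4)
    syn_supp = np.ones(len(model.syn_specs))
    if lesion is not None:
        lesion.validate(topology)
        for name, v in lesion.clamped_neurons.items():
            if name in model.index:
                clamp_mask[model.index[name]] = True
                clamp_val[model.index[name]] = v
            else:
                k = model.aff_index[name]
                aff_clamp_mask[k] = True
                aff_clamp_val[k] = v
        for pair in lesion.suppressed_synapses:
            idx = model.adjustable.get(tuple(pair))
            if idx is not None:
                syn_supp[idx] = 0.0

    # per-phase injected currents and synapse gains
    inj_pre = np.zeros(n_int)
    inj_set = np.zeros(n_int)
    inj_go = np.zeros(n_int)
    for name, cur in schedule.set_currents.items():
        inj_set[model.index[name]] += cur
        inj_go[model.index[name]] += cur
    for name, cur in schedule.go_currents.items():
        inj_go[model.index[name]] += cur

    gain_pre = model.fixed_gain.copy()
    gain_set = model.fixed_gain.copy()
    for key, g in schedule.synapse_gains.items():
        gain_set[model.adjustable[key]] = g
    g_pre = model.syn_gmax * gain_pre * syn_supp
    g_set = model.syn_gmax * gain_set * syn_supp

    # initial state: posture at initial_angle, everything at steady rest
    theta0 = sim.initial_angle * DEG2RAD
    y = np.zeros(6 + n_int)
    y[0] = theta0
    y[6:] = model.rest
    for m in range(2):
        length = model.geo[m, 0] + model.geo[m, 1] * sim.initial_angle
        kse, kpe = model.mus[m, 0], model.mus[m, 1]
        y[2 + m] = max(0.0, kpe * max(0.0, length - model.mus[m, 3]) / (1 + kpe / kse))
        kse_s, kpe_s = model.spn[m, 0], model.spn[m, 1]
        y[4 + m] = max(
            0.0, kpe_s * max(0.0, length - model.spn[m, 3]) / (1 + kpe_s / kse_s)
        )

    dt = sim.physics_dt
    record_every = int(round(sim.record_dt / dt))
    n_steps_total = int(round(sim.duration / dt))
    n_rec = n_steps_total // record_every + 1
    rec_angle = np.zeros(n_rec)
    rec_speed = np.zeros(n_rec)
    rec_v = np.zeros((n_rec, n_int + 4))
    rec_t = np.zeros((n_rec, 2))

    phases = [
        (0, int(round(schedule.set_time / dt)), inj_pre, g_pre),
        (int(round(schedule.set_time / dt)), int(round(schedule.go_time / dt)),
         inj_set, g_set),
        (int(round(schedule.go_time / dt)), n_steps_total, inj_go, g_set),
    ]
    failed_at = -1
    for start, stop, inj, g_eff in phases:
        if stop <= start:
            continue
        out = _run_phase(
            y, stop - start, dt, start, record_every,
            rec_angle, rec_speed, rec_v, rec_t,
            n_int, model.rest, model.g_leak, model.cap, inj,
            clamp_mask, clamp_val,
            model.syn_pre, model.syn_post, g_eff, model.syn_e,
            model.syn_thr, model.syn_sat,
            model.mus, model.geo, model.r_arm, model.mus_idx,
            model.spn, model.gamma_idx, model.gto,
            aff_clamp_mask, aff_clamp_val,
            model.joint.inertia, sim.joint_damping,
            mech.ANGLE_MIN * DEG2RAD, mech.ANGLE_MAX * DEG2RAD,
            MEMBRANE_FLOOR,
        )
        if out >= 0:
            failed_at = out
            break

    # final sample
    if failed_at < 0:
        aff_out = np.empty(4)
        scratch = np.empty_like(y)
        _deriv(y, scratch, n_int, model.rest, model.g_leak, model.cap, inj_go,
               clamp_mask, model.syn_pre, model.syn_post, g_set, model.syn_e,
               model.syn_thr, model.syn_sat, model.mus, model.geo, model.r_arm,
               model.mus_idx, model.spn, model.gamma_idx, model.gto,
               aff_clamp_mask, aff_clamp_val, model.joint.inertia,
               sim.joint_damping, aff_out)
        rec_angle[-1] = y[0] / DEG2RAD
        rec_speed[-1] = y[1] / DEG2RAD
        rec_v[-1, :n_int] = y[6:]
        rec_v[-1, n_int:] = aff_out
        rec_t[-1, 0] = max(0.0, y[2])
        rec_t[-1, 1] = max(0.0, y[3])

    time = np.arange(n_rec) * sim.record_dt
    pots = {name: rec_v[:, i].copy() for i, name in enumerate(model.int_names)}
    for k, name in enumerate(AFFERENT_NODES):
        if name in topology.afferents:
            pots[name] = rec_v[:, n_int + k].copy()
    tensions = {"flexor": rec_t[:, 0].copy(), "extensor": rec_t[:, 1].copy()}
    return SimTrace(
        time=time, angle=rec_angle, speed=rec_speed, potentials=pots,
        tensions=tensions, failed=failed_at >= 0,
        meta={"variant": topology.variant, "physics_dt": dt,
              "record_dt": sim.record_dt, "duration": sim.duration},
    )
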