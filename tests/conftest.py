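"""Shared fixtures: topologies, compiled models, and synthetic traces.

The expensive closed-loop fixtures (seed search + exploration archives)
are session-scoped so the whole suite shares one run of each.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from spinarm import circuits, explore, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from spinarm.evaluate import minjerk_template
from spinarm.simulate import SimTrace


@pytest.fixture(scope="session")
def full50():
    return circuits.build_topology("full50")


@pytest.fixture(scope="session")
def full50_model(full50):
    return simulate.default_model(full50)


@pytest.fixture(scope="session")
def noib36():
    return circuits.build_topology("noIb36")


def make_trace(angle, flx_mn=None, ext_mn=None, flx_emg=None, ext_emg=None,
               record_dt=0.01):
    """Assemble a synthetic SimTrace from channel arrays (rest-filled)."""
    angle = np.asarray(angle, dtype=float)
    n = angle.size
    time = np.arange(n) * record_dt
    speed = np.gradient(angle, record_dt)
    rest = np.full(n, -60.0)

    def ch(x):
        return rest.copy() if x is None else np.asarray(x, dtype=float)

    pots = {name: rest.copy() for name in circuits.SPINAL_NEURONS}
    pots["FlxAlpha"] = ch(flx_mn)
    pots["ExtAlpha"] = ch(ext_mn)
    pots["FlxMuscle"] = ch(flx_emg)
    pots["ExtMuscle"] = ch(ext_emg)
    for name in circuits.AFFERENT_NODES:
        pots[name] = np.full(n, -65.0)
    tensions = {"flexor": np.zeros(n), "extensor": np.zeros(n)}
    return SimTrace(time=time, angle=angle, speed=speed, potentials=pots,
                    tensions=tensions)


def template_trace(amplitude, duration, onset=5.0, noise_sd=0.0, seed=0,
                   start=0.0):
    """A 10 s synthetic trace following an exact minimum-jerk flexion."""
    t = np.arange(1001) * 0.01
    angle = start + minjerk_template(amplitude, duration, onset, t)
    if noise_sd:
        angle = angle + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return make_trace(angle)


@pytest.fixture(scope="session")
def seeded_archive(full50, full50_model):
    """Scaled-down seeded exploration on the full model (shared run).

    A CMA-ES seed search followed by the goal-exploration loop at reduced
    budget; used by the validity-filter, archive-invariant and
    triphasic-pattern checks.
    """
    seeds = explore.seed_search(
        full50,
        explore.SeederConfig(budget=2500, target_amplitude=30.0,
                             target_duration=0.6, rng_seed=1, n_restarts=2),
        model=full50_model,
    )
    assert seeds, "seed search found no valid movement at test budget"
    archive, history = explore.run_gep(
        seeds, full50,
        explore.GEPConfig(n_extend_rounds=60, n_fill_rounds=8, rng_seed=2),
        model=full50_model,
    )
    return {"seeds": seeds, "archive": archive, "history": history}
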