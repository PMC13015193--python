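"""Mechanism analyses: lesion/replay screens and peak-amplitude correlations.

A lesion screen replays an archived movement's exact command vector with a
node clamped or a synapse suppressed and classifies the outcome against
the intact baseline (no-movement, overshoot, second-flexor-peak abolished,
unchanged).  The correlation analysis generalizes single-example ablation
findings across an archive: over all movements whose alpha-motoneuron
potentials show the triphasic betweenness pattern, it reports Pearson
correlations (with Fisher-z confidence intervals) between the burst peak
amplitudes of the neurons implicated in the second flexor burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .circuits import CircuitTopology
from .evaluate import TriphasicLabel, classify_triphasic, detect_peaks
from .explore import ArchiveEntry
from .simulate import LesionSpec, SimConfig, SimTrace, _CompiledModel, \
    default_model, run_trial

V_THR = -60.0
NO_MOVEMENT_DEG = 1.0
OVERSHOOT_DEG = 10.0


def mn_level_triphasic(trace: SimTrace) -> TriphasicLabel:
    """Triphasic betweenness applied to the alpha-MN potentials.

    Same betweenness rule as the EMG classifier but on FlxAlpha/ExtAlpha
    with the -60 mV synaptic threshold as baseline: motoneuron bursts too
    weak to elicit muscle force still count here, but only movement-phase
    (post-GO) bursts are considered.
    """
    from .evaluate import GO_TIME, filter_peaks

    flx = filter_peaks(
        detect_peaks(trace.potentials["FlxAlpha"], trace.time, baseline=V_THR),
        t_min=GO_TIME)
    ext = filter_peaks(
        detect_peaks(trace.potentials["ExtAlpha"], trace.time, baseline=V_THR),
        t_min=GO_TIME)
    return classify_triphasic(flx, ext)


@dataclass
class LesionReport:
    lesion: LesionSpec
    baseline: SimTrace
    lesioned: SimTrace
    outcomes: frozenset  # labels
    peak_deltas: dict = field(default_factory=dict)  # channel -> mV change


def _flexor_second_peak(trace: SimTrace):
    ps = detect_peaks(trace.potentials["FlxAlpha"], trace.time, baseline=V_THR)
    return ps.peaks[1] if len(ps) >= 2 else None


def classify_outcome(baseline: SimTrace, lesioned: SimTrace) -> frozenset:
    labels = set()
    if lesioned.failed:
        return frozenset({"unstable"})
    same_angle = np.allclose(lesioned.angle, baseline.angle, atol=1e-9)
    same_mn = all(
        np.allclose(lesioned.potentials[ch], baseline.potentials[ch], atol=1e-9)
        for ch in ("FlxAlpha", "ExtAlpha"))
    if same_angle and same_mn:
        return frozenset({"unchanged"})
    moved_base = float(np.max(np.abs(baseline.angle - baseline.angle[0])))
    moved = float(np.max(np.abs(lesioned.angle - lesioned.angle[0])))
    if moved < NO_MOVEMENT_DEG <= moved_base:
        labels.add("no-movement")
    base_final = float(np.mean(baseline.angle[baseline.time >= 9.5]))
    if float(np.max(lesioned.angle)) > base_final + OVERSHOOT_DEG:
        labels.add("overshoot")
    p2_base = _flexor_second_peak(baseline)
    p2_les = _flexor_second_peak(lesioned)
    if p2_base is not None and p2_les is None:
        labels.add("2nd-peak-abolished")
    return frozenset(labels)


def lesion_screen(entry: ArchiveEntry, lesions, topology: CircuitTopology,
                  model: _CompiledModel | None = None,
                  sim: SimConfig | None = None) -> list:
    """Replay one archived movement under each lesion and classify outcomes."""
    model = model or default_model(topology)
    sim = sim or SimConfig()
    baseline = run_trial(entry.vector, topology, model=model, sim=sim)
    reports = []
    for lesion in lesions:
        lesion.validate(topology)
        lesioned = run_trial(entry.vector, topology, model=model, sim=sim,
                             lesion=lesion)
        deltas = {}
        for ch in ("FlxAlpha", "ExtAlpha", "FlxMuscle", "ExtMuscle"):
            deltas[ch] = float(np.max(lesioned.potentials[ch])
                               - np.max(baseline.potentials[ch]))
        reports.append(LesionReport(
            lesion=lesion, baseline=baseline, lesioned=lesioned,
            outcomes=classify_outcome(baseline, lesioned), peak_deltas=deltas))
    return reports


@dataclass
class CorrelationReport:
    pair: tuple  # (x label, y label)
    n: int
    r: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    computed: bool = True


def pearson_with_ci(x, y, alpha: float = 0.05) -> CorrelationReport:
    """Pearson r with a Fisher-z (1 - alpha) confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return CorrelationReport(("x", "y"), n, None, None, None, None, False)
    r, p = stats.pearsonr(x, y)
    r = float(r)
    z = np.arctanh(np.clip(r, -0.9999999, 0.9999999))
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    lo = min(float(np.tanh(z - zc * se)), r)
    hi = max(float(np.tanh(z + zc * se)), r)
    return CorrelationReport(("x", "y"), n, r, lo, hi, float(p))


# channel -> which burst peak amplitude to extract (1-based index)
DEFAULT_PAIRS = (
    (("Ext1a", 1), ("ExtAlpha", 1)),
    (("Ext1b", 1), ("ExtPN", 1)),
    (("ExtPN", 1), ("ExtAlpha", 1)),
    (("Ext1b", 1), ("FlxPN", 2)),
    (("Ext1b", 1), ("FlxAlpha", 2)),
    (("ExtAlpha", 1), ("FlxAlpha", 2)),
)


def _peak_amplitude(trace: SimTrace, channel: str, which: int,
                    baseline: float = V_THR):
    if channel not in trace.potentials:
        return None
    from .evaluate import GO_TIME, filter_peaks

    base = -65.0 if channel.endswith(("1a", "1b")) else baseline
    ps = filter_peaks(
        detect_peaks(trace.potentials[channel], trace.time, baseline=base),
        t_min=GO_TIME)
    if len(ps) < which:
        return None
    return ps.amplitudes[which - 1]


def peak_correlations(archive, topology: CircuitTopology, pairs=DEFAULT_PAIRS,
                      model: _CompiledModel | None = None,
                      sim: SimConfig | None = None,
                      traces: dict | None = None) -> list:
    """Correlate burst-peak amplitudes across MN-level triphasic movements.

    Each archived movement is replayed (or looked up in ``traces`` keyed by
    entry id); movements without the MN-level triphasic pattern are
    skipped.  For each (channel, k-th peak) pair the Pearson r, Fisher-z
    95% CI and p-value are reported; pairs with fewer than 3 complete
    observations are returned as not-computed.
    """
    model = model or default_model(topology)
    sim = sim or SimConfig()
    samples: dict[tuple, list] = {p: [] for p in pairs}
    for e in archive:
        if traces is not None and e.entry_id in traces:
            trace = traces[e.entry_id]
        else:
            trace = run_trial(e.vector, topology, model=model, sim=sim)
        if not mn_level_triphasic(trace).is_triphasic:
            continue
        for (cx, kx), (cy, ky) in pairs:
            ax = _peak_amplitude(trace, cx, kx)
            ay = _peak_amplitude(trace, cy, ky)
            if ax is not None and ay is not None:
                samples[((cx, kx), (cy, ky))].append((ax, ay))
    reports = []
    for p in pairs:
        data = samples[p]
        label = (f"{p[0][0]} peak{p[0][1]}", f"{p[1][0]} peak{p[1][1]}")
        if len(data) < 3:
            reports.append(CorrelationReport(label, len(data), None, None,
                                             None, None, False))
            continue
        x, y = zip(*data)
        rep = pearson_with_ci(x, y)
        rep.pair = label
        reports.append(rep)
    return reports
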