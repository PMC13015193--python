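"""Movement scoring: minimum-jerk fit, cost, validity, EMG peaks, triphasic label.

A produced trial is scored against the minimum-jerk ideal of voluntary
reaching: the angle trace on t in [2, 10] s is compared to a template that
stays at the start angle until an onset >= 5 s (the GO time) and then
follows A * (10 tau^3 - 15 tau^4 + 6 tau^5).  The cost is the mean squared
tracking error (deg^2) plus co-contraction penalties over the preparatory
([2, 5] s) and maintained ([7, 10] s) windows; a movement is valid when
cost < 1, its amplitude lies in [10, 110] deg, its (5-95%) duration is at
most 2 s, and it is a flexion.

EMG analysis works on the muscle membrane potentials (the model's EMG
envelopes, at -60 mV before and after movement): every local maximum above
baseline is a burst peak, and a movement is triphasic when the flexor
shows two peaks with an extensor peak strictly between them (AG1/ANT/AG2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize

from .simulate import SimTrace

V_THR = -60.0  # mV
BASELINE_MV = -60.0


def _force_onset_potential(muscle) -> float:
    """Membrane potential above which the stimulus-tension curve leaves 0."""
    import math

    return muscle.st_x_offset - math.log(
        muscle.st_amplitude / abs(muscle.st_y_offset) - 1.0
    ) / muscle.st_steepness
COEFF_PENALTY = 100.0
PREP_WINDOW = (2.0, 5.0)
MAIN_WINDOW = (7.0, 10.0)
COST_WINDOW = (2.0, 10.0)
AMPLITUDE_RANGE = (10.0, 110.0)
MAX_DURATION = 2.0  # s
GO_TIME = 5.0


def minjerk_template(amplitude: float, duration: float, onset: float, t) -> np.ndarray:
    """Minimum-jerk angle profile theta(t) = A (10 tau^3 - 15 tau^4 + 6 tau^5)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    tau = np.clip((np.asarray(t, dtype=float) - onset) / duration, 0.0, 1.0)
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def minjerk_peak_speed(amplitude: float, duration: float) -> float:
    """Peak template speed, 1.875 A / D at the movement midpoint."""
    return 1.875 * amplitude / duration


def _phase(p: float) -> float:
    """tau at which the normalized min-jerk profile reaches fraction p."""
    return brentq(lambda x: 10 * x**3 - 15 * x**4 + 6 * x**5 - p, 0.0, 1.0)


_TAU_05 = None
_TAU_95 = None


def duration_5_95(fit_duration: float) -> float:
    """Movement duration measured 5% -> 95% of amplitude along the template."""
    global _TAU_05, _TAU_95
    if _TAU_05 is None:
        _TAU_05, _TAU_95 = _phase(0.05), _phase(0.95)
    return (_TAU_95 - _TAU_05) * fit_duration


@dataclass
class MinJerkFit:
    amplitude: float  # deg (plateau minus initial angle; signed)
    duration: float  # s (template rise time)
    onset_time: float  # s
    mse: float  # deg^2, mean over the cost window
    desired_trajectory: np.ndarray  # deg, on the trace's cost-window grid
    wrong_direction: bool = False


def fit_minjerk(trace: SimTrace, go_time: float = GO_TIME) -> MinJerkFit:
    """Fit amplitude/onset/duration of a minimum-jerk template to a trace.

    Amplitude is measured (final-plateau mean minus initial angle); onset
    (>= GO time) and duration are found by a coarse grid followed by
    Nelder-Mead refinement of the mean squared error over t in [2, 10] s,
    with the template flat at the start angle before onset.
    """
    t = trace.time
    theta = trace.angle
    # initial posture from the pre-command hold (robust to measurement noise)
    start = float(np.mean(theta[t <= 0.5]))
    plateau = float(np.mean(theta[t >= t[-1] - 0.5]))
    amplitude = plateau - start

    sel = (t >= COST_WINDOW[0]) & (t <= COST_WINDOW[1])
    tw, xw = t[sel], theta[sel] - start

    if abs(amplitude) < 0.5:
        # essentially flat trace: template degenerates to a constant
        mse = float(np.mean(xw**2))
        return MinJerkFit(amplitude=amplitude, duration=1.0, onset_time=go_time,
                          mse=mse, desired_trajectory=np.full_like(tw, start),
                          wrong_direction=amplitude < 0)

    def mse_of(onset: float, duration: float) -> float:
        tmpl = minjerk_template(amplitude, duration, onset, tw)
        return float(np.mean((xw - tmpl) ** 2))

    # vectorized coarse grid over (onset, duration), on a decimated time grid
    stride = max(1, tw.size // 270)
    tc, xc = tw[::stride], xw[::stride]
    onsets = np.arange(go_time, min(go_time + 3.0, COST_WINDOW[1]), 0.1)
    durations = np.arange(0.1, 3.5, 0.1)
    tau = (tc[None, None, :] - onsets[:, None, None]) / durations[None, :, None]
    np.clip(tau, 0.0, 1.0, out=tau)
    tmpl = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    mse_grid = np.mean((xc[None, None, :] - tmpl) ** 2, axis=2)
    i, j = np.unravel_index(int(np.argmin(mse_grid)), mse_grid.shape)
    best = (float(onsets[i]), float(durations[j]),
            mse_of(float(onsets[i]), float(durations[j])))
    if best[2] > 25.0:
        # far from any template: local refinement cannot make it valid
        desired = start + minjerk_template(amplitude, best[1], best[0], tw)
        return MinJerkFit(amplitude=amplitude, duration=best[1],
                          onset_time=best[0], mse=best[2],
                          desired_trajectory=desired,
                          wrong_direction=amplitude < 0)

    def obj(p):
        onset, duration = p
        if duration <= 0.01 or onset < go_time or onset > COST_WINDOW[1]:
            return 1e9
        return mse_of(onset, duration)

    res = minimize(obj, x0=[best[0], best[1]], method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-12, "maxiter": 400})
    onset, duration = (res.x if res.fun <= best[2] else best[:2])
    mse = min(float(res.fun), best[2])
    desired = start + minjerk_template(amplitude, duration, onset, tw)
    return MinJerkFit(
        amplitude=amplitude, duration=float(duration), onset_time=float(onset),
        mse=mse, desired_trajectory=desired, wrong_direction=amplitude < 0,
    )


@dataclass
class CostBreakdown:
    tracking_term: float  # deg^2
    penalty_prep: float
    penalty_main: float
    coeff_prep: float = COEFF_PENALTY
    coeff_main: float = COEFF_PENALTY
    v_thr: float = V_THR

    @property
    def total_cost(self) -> float:
        return self.tracking_term + self.penalty_prep + self.penalty_main


def cocontraction_penalty(flex_mn, ext_mn, time, window=PREP_WINDOW,
                          coeff: float = COEFF_PENALTY, v_thr: float = V_THR) -> float:
    """Time-averaged product of suprathreshold antagonist MN depolarizations.

    Each factor (V - V_thr) is clamped at zero below threshold, so the
    penalty is positive only where BOTH motoneurons are simultaneously
    above threshold; it is then scaled by ``coeff``.
    """
    time = np.asarray(time, dtype=float)
    sel = (time >= window[0]) & (time <= window[1])
    if not np.any(sel):
        raise ValueError("window outside trace")
    f = np.maximum(0.0, np.asarray(flex_mn, dtype=float)[sel] - v_thr)
    e = np.maximum(0.0, np.asarray(ext_mn, dtype=float)[sel] - v_thr)
    return float(np.mean(f * e) * coeff)


def cost(trace: SimTrace, fit: MinJerkFit) -> CostBreakdown:
    """Tracking MSE over [2, 10] s plus the two co-contraction penalties."""
    t = trace.time
    sel = (t >= COST_WINDOW[0]) & (t <= COST_WINDOW[1])
    tracking = float(np.mean((trace.angle[sel] - fit.desired_trajectory) ** 2))
    flex_mn = trace.potentials["FlxAlpha"]
    ext_mn = trace.potentials["ExtAlpha"]
    p_prep = cocontraction_penalty(flex_mn, ext_mn, t, PREP_WINDOW)
    p_main = cocontraction_penalty(flex_mn, ext_mn, t, MAIN_WINDOW)
    return CostBreakdown(tracking, p_prep, p_main)


@dataclass(frozen=True)
class Peak:
    time: float  # s
    potential: float  # mV
    left_min_time: float
    right_min_time: float


@dataclass
class PeakSet:
    peaks: list = field(default_factory=list)
    baseline: float = BASELINE_MV

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def times(self) -> list:
        return [p.time for p in self.peaks]

    @property
    def amplitudes(self) -> list:
        """Peak heights above baseline (mV)."""
        return [p.potential - self.baseline for p in self.peaks]


def detect_peaks(emg, time=None, baseline: float = BASELINE_MV,
                 tol: float = 1e-9) -> PeakSet:
    """Every local maximum above baseline, with its flanking minima.

    Plateaus of exactly equal samples report a single peak at the plateau
    center.  The detector has no amplitude floor beyond the baseline:
    even the smallest suprabaseline bump is reported.
    """
    x = np.asarray(emg, dtype=float)
    n = x.size
    t = np.asarray(time, dtype=float) if time is not None else np.arange(n, dtype=float)

    # run-length encode to handle plateaus
    starts = [0]
    for i in range(1, n):
        if x[i] != x[starts[-1]]:
            starts.append(i)
    ends = starts[1:] + [n]

    apex: list[int] = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        v = x[s]
        if v <= baseline + tol:
            continue
        left_ok = k > 0 and x[starts[k - 1]] < v
        right_ok = k < len(starts) - 1 and x[starts[k + 1]] < v
        if left_ok and right_ok:
            apex.append((s + e - 1) // 2)

    peaks = []
    for j, i in enumerate(apex):
        lo = apex[j - 1] if j > 0 else 0
        hi = apex[j + 1] if j + 1 < len(apex) else n - 1
        left_i = lo + int(np.argmin(x[lo:i + 1])) if i > lo else lo
        right_i = i + int(np.argmin(x[i:hi + 1])) if hi > i else hi
        peaks.append(Peak(float(t[i]), float(x[i]), float(t[left_i]), float(t[right_i])))
    return PeakSet(peaks=peaks, baseline=baseline)


@dataclass
class TriphasicLabel:
    is_triphasic: bool
    ag1: Peak | None = None
    ag2: Peak | None = None
    ant: Peak | None = None
    overlap: bool = False  # no silent period between AG1 and AG2


def classify_triphasic(flexor_peaks: PeakSet, extensor_peaks: PeakSet,
                       baseline: float = BASELINE_MV, tol: float = 1e-6) -> TriphasicLabel:
    """Triphasic iff two flexor peaks bracket an extensor peak.

    The pattern requires an extensor burst (ANT) with flexor bursts on
    both sides of it in time; ANT is the strongest such extensor peak,
    AG1 the last flexor peak before it and AG2 the first one after it.
    A silent period between AG1 and AG2 is reported but not required.
    """
    if len(flexor_peaks) < 2 or len(extensor_peaks) < 1:
        return TriphasicLabel(False)
    f_times = flexor_peaks.times
    ants = [p for p in extensor_peaks.peaks
            if min(f_times) < p.time < max(f_times)
            and any(ft < p.time for ft in f_times)
            and any(ft > p.time for ft in f_times)]
    if not ants:
        return TriphasicLabel(False)
    ant = max(ants, key=lambda p: p.potential)
    ag1 = max((p for p in flexor_peaks.peaks if p.time < ant.time),
              key=lambda p: p.time)
    ag2 = min((p for p in flexor_peaks.peaks if p.time > ant.time),
              key=lambda p: p.time)
    # silent period: flexor returns to baseline between its two bursts
    valley = min(ag1.right_min_time, ag2.left_min_time)
    overlap = not (ag1.right_min_time <= ag2.time and valley >= ag1.time)
    return TriphasicLabel(True, ag1=ag1, ag2=ag2, ant=ant, overlap=overlap)


def filter_peaks(ps: PeakSet, t_min: float | None = None,
                 min_potential: float | None = None) -> PeakSet:
    """Restrict a peak set to a time window and/or an amplitude floor."""
    kept = [p for p in ps.peaks
            if (t_min is None or p.time >= t_min)
            and (min_potential is None or p.potential >= min_potential)]
    return PeakSet(peaks=kept, baseline=ps.baseline)


def emg_triphasic(trace: SimTrace, go_time: float = GO_TIME) -> TriphasicLabel:
    """Triphasic classification of the muscle (EMG) potentials.

    Only movement-phase bursts count (t >= GO), and a burst must be strong
    enough to elicit force: pseudo-patterns whose second agonist ripple
    produces no muscle tension are rejected, as are preparatory-phase
    transients.
    """
    from .mechanics import biceps_params, triceps_params

    flx_floor = _force_onset_potential(biceps_params())
    ext_floor = _force_onset_potential(triceps_params())
    flx = filter_peaks(detect_peaks(trace.flexor_emg, trace.time),
                       t_min=go_time, min_potential=flx_floor)
    ext = filter_peaks(detect_peaks(trace.extensor_emg, trace.time),
                       t_min=go_time, min_potential=ext_floor)
    return classify_triphasic(flx, ext)


@dataclass
class MovementMetrics:
    amplitude: float  # deg
    max_speed: float  # deg/s
    duration: float  # s (5-95%)
    cost: float
    valid: bool
    rejection_reasons: frozenset
    fit: MinJerkFit | None = None
    breakdown: CostBreakdown | None = None
    triphasic: TriphasicLabel | None = None


def evaluate_movement(trace: SimTrace) -> MovementMetrics:
    """Score one trace and apply the validity rules."""
    if trace.failed:
        return MovementMetrics(0.0, 0.0, 0.0, np.inf, False,
                               frozenset({"unstable"}))
    fit = fit_minjerk(trace)
    breakdown = cost(trace, fit)
    dur = duration_5_95(fit.duration)
    sel = trace.time >= GO_TIME
    max_speed = float(np.max(trace.angle[sel] * 0.0 + trace.speed[sel]))
    reasons = set()
    if breakdown.total_cost >= 1.0:
        reasons.add("cost")
    if fit.wrong_direction or fit.amplitude <= 0:
        reasons.add("wrong-direction")
    elif not AMPLITUDE_RANGE[0] <= fit.amplitude <= AMPLITUDE_RANGE[1]:
        reasons.add("amplitude-range")
    if dur > MAX_DURATION:
        reasons.add("too-slow")
    tri = emg_triphasic(trace)
    return MovementMetrics(
        amplitude=fit.amplitude, max_speed=max_speed, duration=dur,
        cost=breakdown.total_cost, valid=not reasons,
        rejection_reasons=frozenset(reasons), fit=fit, breakdown=breakdown,
        triphasic=tri,
    )
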