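"""Pool-size and rate estimation from segment series.

Core quantities:

* ``Rss`` — steady-state response per AP, from an exponential-tail fit to the
  late train (a plain tail mean is biased by residual relaxation on short
  trains);
* ``alpha_fixed`` — the unique constant unitary recruitment rate satisfying
  the self-consistency condition RRP0 = Rss * nu / alpha, found by bisection
  against the recruitment-correction iteration;
* ``RRP0`` — cumulative response minus cumulative recruitment, under four
  recruitment models: the fixed-alpha correction, constant bulk rate from
  train onset (back-extrapolation; maximal recruitment, hence the smallest
  RRP0), no recruitment until steady state (minimal recruitment, hence the
  largest RRP0), and the accelerating-schedule correction;
* derived indices: p_v bounds, quantal content, frequency-jump increase,
  paired-train recovery, and the fraction of the pool depleted at 100 Hz.

Note on conventions: ``rrp0_pC`` equals the transmitter released from pool
content present at train onset (cumulative - recruited), which by conservation
is RRP0 minus the pool content remaining at train end.  When the train drives
the pool to a non-empty steady state this undershoots the capacity;
``rrp0_capacity_pC`` adds the standing occupancy back via the single-class
inversion RRP_ss / RRP0 = Rss / R1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .engine import (AlphaSchedule, RecruitmentResult, accelerating_schedule,
                     fixed_schedule, simulate_recruit)
from .errors import EstimationError, SteadyStateError
from .protocols import StimulusProtocol
from .traces import SegmentSeries

RRP0_METHODS = ("fixed_alpha", "back_extrapolation", "none_until_ss", "accelerating")


@dataclass
class SteadyStateStats:
    """Steady-state train statistics (charges in pC)."""

    Rss: float                 # response per AP at steady state
    steady_rate: float         # Rss * nu, pC/s
    frequency: float           # nu of the final epoch, /s
    first_response: float      # R1, charge of the first AP segment
    n_tail: int                # AP segments used for the tail fit
    rms_tail: float            # residual RMS of the tail around Rss

    @property
    def rss_over_r1(self) -> float:
        return self.Rss / self.first_response if self.first_response else np.nan


@dataclass
class RRPEstimate:
    """One RRP0 estimate with the recruitment model that produced it."""

    method: str
    rrp0_pC: float
    rrp0_capacity_pC: float
    cumulative_pC: float
    cumulative_recruited_pC: float
    alpha_used: float | AlphaSchedule | None
    stats: SteadyStateStats

    def quanta(self, mepsc_charge_fC: float, kyn_scale: float,
               capacity: bool = True) -> int:
        rrp0 = self.rrp0_capacity_pC if capacity else self.rrp0_pC
        return quantal_content(rrp0, mepsc_charge_fC, kyn_scale)


# ---------------------------------------------------------------------------
# steady state


def _exp_tail_rss(y: np.ndarray, k_last: int = 10) -> tuple:
    """Asymptote of c + A exp(-lam k) fitted to the late-train AP charges.

    Falls back to the mean of the last ``k_last`` values when the exponential
    is not identifiable (transient still large at the window end, or the decay
    pinned at a bound) — on a flat noisy tail c and A trade off freely as
    lam -> 0.
    """
    k = np.arange(y.size, dtype=float)
    mean_tail = float(y[-k_last:].mean())
    c0 = max(mean_tail, 0.0)
    A0 = max(float(y[0] - c0), 1e-12)

    def f(k, c, A, lam):
        return c + A * np.exp(-lam * k)

    try:
        popt, _ = curve_fit(f, k, y, p0=[c0, A0, 0.3],
                            bounds=([0.0, 0.0, 0.02], [np.inf, np.inf, 2.0]),
                            maxfev=5000)
        c, A, lam = popt
        resid = y - f(k, *popt)
        rms = float(np.sqrt(np.mean(resid ** 2)))
        transient_end = A * np.exp(-lam * (y.size - 1))
        if lam <= 0.021 or transient_end > 0.25 * max(c, 1e-300):
            raise RuntimeError("exponential not identifiable")
        return max(float(c), 0.0), rms
    except Exception:
        resid = y[-k_last:] - mean_tail
        return c0, float(np.sqrt(np.mean(resid ** 2)))


def steady_state_stats(series: SegmentSeries, protocol: StimulusProtocol,
                       k_last: int = 10, rss_method: str = "exp_tail",
                       rms_tol: float = 0.15) -> SteadyStateStats:
    """Steady-state response per AP over the final epoch.

    Gate: the last ``k_last`` AP segments must vary less than ``rms_tol``
    (RMS, relative to their mean); a declining tail fails this check.  The
    default tolerance assumes replicate-averaged traces — shot noise on a
    single stochastic trial with tens of quanta per segment alone reaches
    15-25% RMS.  ``rss_method="exp_tail"`` (default) extrapolates residual
    relaxation out of the tail with a ``c + A exp(-lam k)`` fit;
    ``"tail_mean"`` is the plain mean of the last ``k_last`` AP segments.
    """
    ap = series.ap_charges
    if ap.size < 2 * k_last:
        raise SteadyStateError(f"need >= {2 * k_last} AP segments, got {ap.size}")
    last = ap[-k_last:]
    m_last = last.mean()
    exhausted = m_last < 0.02 * max(ap[0], 0.0)  # pool fully drained: a steady
    if not exhausted:                            # state at (near) zero
        if m_last <= 0:
            raise SteadyStateError("non-positive tail mean")
        rel_rms = float(np.sqrt(np.mean((last - m_last) ** 2))) / m_last
        if rel_rms > rms_tol:
            raise SteadyStateError(
                f"last {k_last} AP segments vary {rel_rms:.0%} RMS around their "
                f"mean (tol {rms_tol:.0%}); no steady state")
    if exhausted:
        nu = protocol.frequency_at_end()
        rss = max(float(m_last), 0.0)
        return SteadyStateStats(Rss=rss, steady_rate=rss * nu, frequency=nu,
                                first_response=float(ap[0]), n_tail=k_last,
                                rms_tail=float(np.sqrt(np.mean((last - m_last) ** 2))))
    nu = protocol.frequency_at_end()
    if rss_method == "tail_mean":
        rss = float(m_last)
        rms = float(np.sqrt(np.mean((last - rss) ** 2)))
        n_tail = k_last
    elif rss_method == "exp_tail":
        n_tail = min(30, ap.size)
        rss, rms = _exp_tail_rss(ap[-n_tail:], k_last)
    else:
        raise EstimationError(f"unknown rss_method {rss_method!r}")
    return SteadyStateStats(Rss=rss, steady_rate=rss * nu, frequency=nu,
                            first_response=float(ap[0]), n_tail=n_tail,
                            rms_tail=rms)


# ---------------------------------------------------------------------------
# alpha estimation (self-consistency search)


def trim_to_train(series: SegmentSeries) -> SegmentSeries:
    """Drop trailing post-train segments: the recruitment iteration is defined
    on the stimulated span only (extra empty segments would accrue recruitment
    that never happened)."""
    if not series.has_ap.any():
        raise EstimationError("series contains no AP segments")
    last = int(np.flatnonzero(series.has_ap)[-1])
    if last == series.n_segments - 1:
        return series
    return SegmentSeries(series.segment_length, series.charges[:last + 1],
                         series.t_start[:last + 1], series.ap_counts[:last + 1])


def _recruit_for(series: SegmentSeries, schedule: AlphaSchedule) -> RecruitmentResult:
    return simulate_recruit(series.charges, schedule, series.segment_length,
                            ap_counts=series.ap_counts)


def _bisect(g, lo: float, hi: float, tol: float):
    """First sign change on a coarse log grid, refined by bisection.

    g can re-cross at unphysically large alpha (the linearised recruitment
    overshoots once alpha * seglen approaches 1), so the physical root is the
    first one above the lower bracket edge.
    """
    grid = np.geomspace(lo, hi, 48)
    vals = [g(x) for x in grid]
    j = next((i for i in range(len(grid) - 1)
              if vals[i] == 0 or vals[i] * vals[i + 1] < 0), None)
    if j is None:
        return (lo if vals[0] > 0 else hi), False
    lo, hi = grid[j], grid[j + 1]
    glo = vals[j]
    if glo == 0:
        return lo, True
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if glo * g(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi), True


def estimate_alpha_fixed(series: SegmentSeries, protocol: StimulusProtocol,
                         bracket: tuple = (0.05, 50.0), tol: float = 1e-4,
                         stats: SteadyStateStats | None = None) -> float:
    """Unique constant recruitment rate with RRP0 = Rss * nu / alpha.

    Bisection on g(alpha) = [cumulative - recruited(alpha)] - Rss * nu / alpha
    over ``bracket``; g is monotone on depressing trains.  If the bracket
    shows no sign change (e.g. a pure-depletion train with Rss ~ 0), the
    nearer bracket edge is returned with a warning.
    """
    series = trim_to_train(series)
    st = stats or steady_state_stats(series, protocol)
    cum = series.total

    def g(a):
        return (cum - _recruit_for(series, fixed_schedule(a)).total) \
            - st.steady_rate / a

    root, ok = _bisect(g, bracket[0], bracket[1], tol)
    if not ok:
        warnings.warn("no sign change in the alpha bracket; returning the "
                      f"bracket edge {root}/s (g({bracket[0]})={g(bracket[0]):.3g}, "
                      f"g({bracket[1]})={g(bracket[1]):.3g})",
                      stacklevel=2)
    return float(root)


def _fit_alpha_max(series: SegmentSeries, protocol: StimulusProtocol,
                   schedule: AlphaSchedule, stats: SteadyStateStats,
                   bracket: tuple = (0.05, 50.0), tol: float = 1e-4) -> float:
    """alpha_max of an accelerating schedule fixed by the same self-consistency
    condition, evaluated at the schedule's end-of-train rate."""
    cum = series.total
    n_ap = int(series.ap_counts.sum())
    engaged_end = 1.0 - np.exp(-n_ap / schedule.tau_ap)

    def g(amax):
        s = schedule.with_alpha_max(amax)
        rec = _recruit_for(series, s).total
        return (cum - rec) - stats.steady_rate / (amax * engaged_end)

    root, ok = _bisect(g, bracket[0], bracket[1], tol)
    if not ok:
        warnings.warn("no sign change fitting alpha_max; returning bracket edge",
                      stacklevel=2)
    return float(root)


# ---------------------------------------------------------------------------
# RRP0 estimation


def _steady_onset_index(series: SegmentSeries, rss: float,
                        rel_tol: float = 0.05, default_s: float = 0.100) -> int:
    """First AP segment from which the running tail mean stays within
    ``rel_tol`` of Rss; falls back to ``default_s`` after train onset."""
    ap_idx = np.flatnonzero(series.has_ap)
    y = series.charges[ap_idx]
    tail_means = (np.cumsum(y[::-1]) / np.arange(1, y.size + 1))[::-1]
    ok = np.abs(tail_means - rss) <= rel_tol * max(rss, 1e-300)
    if ok.any():
        return int(ap_idx[int(np.argmax(ok))])
    t_def = series.t_start[0] + default_s
    return int(np.searchsorted(series.t_start, t_def))


def estimate_rrp0(series: SegmentSeries, protocol: StimulusProtocol,
                  method: str = "fixed_alpha",
                  schedule: AlphaSchedule | None = None,
                  alpha: float | None = None,
                  stats: SteadyStateStats | None = None) -> RRPEstimate:
    """RRP0 = cumulative response - cumulative recruited, per recruitment model.

    On a depressing train the estimates order as
    back_extrapolation <= fixed_alpha <= none_until_ss (recruitment estimates
    order the opposite way).  See the module note on ``rrp0_capacity_pC``.
    """
    if method not in RRP0_METHODS:
        raise EstimationError(f"unknown method {method!r}")
    series = trim_to_train(series)
    st = stats or steady_state_stats(series, protocol)
    cum = series.total
    duration = series.n_segments * series.segment_length
    alpha_used: float | AlphaSchedule | None

    if method == "fixed_alpha":
        a = alpha if alpha is not None else estimate_alpha_fixed(series, protocol,
                                                                 stats=st)
        recruited = _recruit_for(series, fixed_schedule(a)).total
        alpha_used = a
    elif method == "accelerating":
        if schedule is None:
            raise EstimationError("accelerating method needs an AlphaSchedule")
        if schedule.alpha_max is None:
            amax = _fit_alpha_max(series, protocol, schedule, st)
            schedule = schedule.with_alpha_max(amax)
        recruited = _recruit_for(series, schedule).total
        alpha_used = schedule
    elif method == "back_extrapolation":
        recruited = st.steady_rate * duration
        alpha_used = None
    else:  # none_until_ss
        onset = _steady_onset_index(series, st.Rss)
        recruited = st.steady_rate * (duration - onset * series.segment_length)
        alpha_used = None

    rrp0 = cum - recruited
    if rrp0 <= 0:
        raise EstimationError(f"non-positive RRP0 under method {method!r}")
    r = st.rss_over_r1
    capacity = rrp0 / (1.0 - r) if 0 <= r < 1 else rrp0
    return RRPEstimate(method=method, rrp0_pC=float(rrp0),
                       rrp0_capacity_pC=float(capacity), cumulative_pC=float(cum),
                       cumulative_recruited_pC=float(recruited),
                       alpha_used=alpha_used, stats=st)


def quantal_content(rrp0_pC: float, mepsc_charge_fC: float,
                    kyn_scale: float) -> int:
    """Convert a (recruitment-corrected) charge to a vesicle count.

    quanta = rrp0 / (mEPSC charge * kyn_scale); the mEPSC charge is measured
    before KYN so the train charge must be un-scaled by the KYN factor.
    """
    if mepsc_charge_fC <= 0 or kyn_scale <= 0 or rrp0_pC <= 0:
        raise EstimationError("all quantal-content inputs must be positive")
    return int(round(rrp0_pC / (mepsc_charge_fC * 1.0e-3 * kyn_scale)))


# ---------------------------------------------------------------------------
# p_v bounds (first response over aggregate pool release)


def smooth3(x: np.ndarray) -> np.ndarray:
    """Three-segment moving average (smooths the AP / async-only alternation
    of a 100 Hz epoch on the 3.33 ms grid)."""
    k = np.ones(3) / 3.0
    return np.convolve(x, k, mode="same")


def jump_onset_index(series: SegmentSeries) -> int:
    """First segment of the high-frequency epoch in a frequency-jump series."""
    ap = series.ap_counts
    if series.n_segments and ap.max() > 1:
        return int(np.argmax(ap > 1))
    has = series.has_ap
    for i in range(series.n_segments - 1):
        if has[i] and has[i + 1]:
            return i
    raise EstimationError("no frequency jump found in series")


def post_jump_excess(jump_series: SegmentSeries,
                     matched100: SegmentSeries | None = None) -> SegmentSeries:
    """Post-jump series with the matched 100 Hz response rate subtracted.

    With a matched 100 Hz series the 3-segment smoothed baseline is subtracted
    segment-by-segment; otherwise the pre-jump steady rate (last 30 segments
    before the jump, per-segment mean) is used.
    """
    jump_series = trim_to_train(jump_series)
    j = jump_onset_index(jump_series)
    if matched100 is not None:
        if matched100.n_segments < jump_series.n_segments or \
                not np.isclose(matched100.segment_length, jump_series.segment_length):
            raise EstimationError("matched 100 Hz series grid does not align")
        base = smooth3(matched100.charges)[j:jump_series.n_segments]
    else:
        k = min(30, j)
        base = np.full(jump_series.n_segments - j,
                       jump_series.charges[j - k:j].mean())
    out = jump_series.charges[j:] - base
    return SegmentSeries(jump_series.segment_length, out,
                         jump_series.t_start[j:], jump_series.ap_counts[j:])


def pv_bounds(series: SegmentSeries, protocol: StimulusProtocol,
              scope: str = "full_rrp",
              baseline100: SegmentSeries | None = None,
              stats: SteadyStateStats | None = None) -> tuple:
    """(lower, upper) bounds on mean p_v: first response / aggregate release.

    ``full_rrp``: the whole train from rest; the aggregate is RRP0 under the
    minimal-recruitment model (lower bound on p_v) or the maximal-recruitment
    back-extrapolation (upper bound).  ``steady_supply``: the post-jump excess
    series, bounding p_v of the standing 100 Hz supply.
    """
    if scope == "steady_supply":
        ser = post_jump_excess(series, baseline100)
        st = None
    elif scope == "full_rrp":
        ser, st = series, stats
    else:
        raise EstimationError(f"unknown scope {scope!r}")
    first = ser.ap_charges[0] if ser.has_ap.any() else 0.0
    if first <= 0:
        raise EstimationError("zero first response")
    st = st or steady_state_stats(ser, protocol)
    hi_pool = estimate_rrp0(ser, protocol, "none_until_ss", stats=st).rrp0_pC
    lo_pool = estimate_rrp0(ser, protocol, "back_extrapolation", stats=st).rrp0_pC
    return float(first / hi_pool), float(first / lo_pool)


# ---------------------------------------------------------------------------
# protocol-level indices


def _window_sum(series: SegmentSeries, t0: float, window: float) -> float:
    sel = (series.t_start >= t0 - 1e-9) & (series.t_start < t0 + window - 1e-9)
    return float(series.charges[sel].sum())


def jump_increase_index(jump_series: SegmentSeries, rest300_series: SegmentSeries,
                        matched100_series: SegmentSeries | None = None,
                        window: float = 0.150,
                        jump_time: float | None = None) -> tuple:
    """Release increase caused by a frequency jump, assumption-free.

    index = (sum of jump-series charge over the first ``window`` after the
    jump) / (sum of the rest-start 300 Hz series over its first ``window``);
    the baseline index uses the matched maintained-100 Hz series over the same
    absolute window.  Returns ``(index, baseline_index)`` (baseline NaN if no
    matched series is supplied).
    """
    if jump_time is None:
        t_jump = jump_series.t_start[jump_onset_index(jump_series)]
    else:
        t_jump = jump_time
    denom = _window_sum(rest300_series, rest300_series.t_start[0], window)
    if denom <= 0:
        raise EstimationError("empty rest-start reference window")
    if t_jump + window > jump_series.t_start[-1] + jump_series.segment_length + 1e-9:
        raise EstimationError("window exceeds the post-jump record")
    index = _window_sum(jump_series, t_jump, window) / denom
    baseline = np.nan
    if matched100_series is not None:
        if not np.isclose(matched100_series.segment_length,
                          jump_series.segment_length):
            raise EstimationError("misaligned protocols")
        baseline = _window_sum(matched100_series, t_jump, window) / denom
    return float(index), float(baseline)


def recovery_index(pair_series, zero_interval_pair) -> list:
    """Fractional RRP replenishment vs rest interval from paired trains.

    ``pair_series`` is an iterable of ``(interval_s, first_train_series,
    second_train_series)``; ``zero_interval_pair`` is the interleaved
    nominally-zero-interval pair that calibrates ongoing recruitment:
    recovery(D) = (r(D) - r(0)) / (1 - r(0)) with r = I2 / I1.
    """
    def ratio(pair):
        i1 = pair[0].total if isinstance(pair[0], SegmentSeries) else float(pair[0])
        i2 = pair[1].total if isinstance(pair[1], SegmentSeries) else float(pair[1])
        if i1 <= 0:
            raise EstimationError("non-positive first-train integral")
        return i2 / i1

    r0 = ratio(zero_interval_pair)
    if r0 >= 1.0:
        raise EstimationError(f"zero-interval ratio {r0:.3f} >= 1; pools not exhausted")
    out = []
    for interval, s1, s2 in pair_series:
        r = ratio((s1, s2))
        out.append((float(interval), float((r - r0) / (1.0 - r0))))
    return out


def depletion_fraction(series100: SegmentSeries, protocol: StimulusProtocol,
                       schedule: AlphaSchedule) -> float:
    """Fraction of the pool depleted by the 100 Hz epoch of a jump series.

    The post-jump cumulative (corrected for recruitment with ``schedule``)
    measures the standing pool content RRP_SS100; the whole-train corrected
    cumulative measures RRP0; the depletion is 1 - RRP_SS100 / RRP0.
    """
    series100 = trim_to_train(series100)
    j = jump_onset_index(series100)
    if schedule.mode == "accelerating" and schedule.alpha_max is None:
        st = steady_state_stats(series100, protocol)
        schedule = schedule.with_alpha_max(
            _fit_alpha_max(series100, protocol, schedule, st))
    res = _recruit_for(series100, schedule)
    net = series100.charges - res.recruit
    rrp0 = float(net.sum())
    rrp_ss = float(net[j:].sum())
    if rrp0 <= 0:
        raise EstimationError("non-positive corrected cumulative")
    return float(1.0 - rrp_ss / rrp0)
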