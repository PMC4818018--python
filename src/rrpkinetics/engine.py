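"""Kinetic core: recruitment-rate schedules and the recruitment-correction iteration.

The pool obeys a two-state release-site balance

    dRRP_t/dt = alpha_t * (RRP_0 - RRP_t) - beta_t * RRP_t

where ``alpha_t`` is the unitary recruitment rate (per vacant site) and
``beta_t`` the unitary release rate (per occupied site).  This module owns

* :class:`AlphaSchedule` — the time course of ``alpha_t``: fixed, accelerating
  (each AP engages the recruitment mechanism by a constant fraction, with an
  optional slow linear fatigue), rest-decay (the double-exponential
  disengagement during rest intervals), or an arbitrary lookup table;
* :func:`simulate_recruit` — the discrete per-segment vacancy iteration that
  splits a measured response train into pool release vs. newly recruited
  transmitter;
* :func:`replenishment_fraction` — the closed-form fractional refilling of an
  empty pool during a rest interval, ``1 - exp(-integral of alpha)``;
* :func:`fit_replenishment` — least-squares recovery of the rest-decay
  parameters from measured recovery time courses.

The engine is unit-agnostic in amplitude (works in pC throughout); rates are
per second and times in seconds, except ``tau_ap`` which is counted in action
potentials so that the acceleration time constant scales with stimulation
frequency (tau = tau_ap / nu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import EstimationError, ParameterError

#: rest gaps longer than this do not advance the fatigue clock (fatigue
#: accrues only during stimulation)
FATIGUE_GAP_S = 0.05


@dataclass(frozen=True)
class AlphaSchedule:
    """Time course of the unitary recruitment rate alpha_t (per second).

    Parameters
    ----------
    mode:
        ``"fixed"``, ``"accelerating"``, ``"rest_decay"`` or ``"tabulated"``.
    alpha_fixed:
        Constant rate for ``fixed`` mode, /s.
    alpha_max:
        Plateau rate for ``accelerating`` / ``rest_decay`` modes, /s (default
        4.3 /s).  ``None`` in accelerating mode marks the value as free, to be
        determined from data by the estimators.
    tau_ap:
        Acceleration constant in action potentials (default 10); the wall-time
        constant is ``tau_ap / nu`` at stimulation frequency ``nu``.
    fatigue_rate:
        Linear use-dependent decrease of ``alpha_max``, fraction per second of
        stimulation (default 0; the measured value is 0.10 /s).
    w, tau_f, tau_s, alpha_inf:
        Rest-decay (disengagement) parameters: alpha(t) =
        (alpha_max - alpha_inf) * [w exp(-t/tau_f) + (1-w) exp(-t/tau_s)] + alpha_inf,
        with t the time since the end of stimulation.  Defaults w=0.95,
        tau_f=50 ms, tau_s=7 s, alpha_inf=1/12 /s.
    table:
        (n, 2) array of (time s, rate /s) rows for ``tabulated`` mode; lookup
        is nearest-time with ties broken toward the earlier entry.
    """

    mode: str = "fixed"
    alpha_fixed: float = 4.65
    alpha_max: float | None = 4.3
    tau_ap: float = 10.0
    fatigue_rate: float = 0.0
    w: float = 0.95
    tau_f: float = 0.050
    tau_s: float = 7.0
    alpha_inf: float = 1.0 / 12.0
    table: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("fixed", "accelerating", "rest_decay", "tabulated"):
            raise ParameterError(f"unknown schedule mode {self.mode!r}")
        for name in ("alpha_fixed", "alpha_max", "fatigue_rate", "tau_ap",
                     "tau_f", "tau_s", "alpha_inf"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        if not 0.0 <= self.w <= 1.0:
            raise ParameterError(f"w must be in [0, 1], got {self.w}")
        if self.mode == "tabulated":
            tab = np.atleast_2d(np.asarray(self.table, dtype=float))
            if tab.shape[1] != 2:
                raise ParameterError("table must have (time, rate) columns")
            if tab.shape[0] > 1 and not np.all(np.diff(tab[:, 0]) > 0):
                raise ParameterError("tabulated times must be increasing")
            if np.any(tab[:, 1] < 0):
                raise ParameterError("tabulated rates must be >= 0")
            object.__setattr__(self, "table", tab)
        if self.mode in ("accelerating", "rest_decay") and self.mode == "rest_decay" \
                and self.alpha_max is None:
            raise ParameterError("rest_decay mode needs alpha_max")

    def with_alpha_max(self, alpha_max: float) -> "AlphaSchedule":
        return replace(self, alpha_max=alpha_max)


def fixed_schedule(alpha: float) -> AlphaSchedule:
    return AlphaSchedule(mode="fixed", alpha_fixed=alpha)


def accelerating_schedule(alpha_max: float | None = 4.3, tau_ap: float = 10.0,
                          fatigue_rate: float = 0.0) -> AlphaSchedule:
    return AlphaSchedule(mode="accelerating", alpha_max=alpha_max,
                         tau_ap=tau_ap, fatigue_rate=fatigue_rate)


def rest_decay_schedule(alpha_max: float = 4.3, w: float = 0.95,
                        tau_f: float = 0.050, tau_s: float = 7.0,
                        alpha_inf: float = 1.0 / 12.0) -> AlphaSchedule:
    return AlphaSchedule(mode="rest_decay", alpha_max=alpha_max, w=w,
                         tau_f=tau_f, tau_s=tau_s, alpha_inf=alpha_inf)


def tabulated_schedule(table) -> AlphaSchedule:
    return AlphaSchedule(mode="tabulated", table=np.asarray(table, dtype=float))


# ---------------------------------------------------------------------------
# evaluating schedules


def lookup_table(table: np.ndarray, t: float) -> float:
    """Nearest-time lookup, ties toward the earlier entry (first minimum)."""
    i = int(np.argmin(np.abs(table[:, 0] - t)))
    return float(table[i, 1])


def _fatigue_factor(schedule: AlphaSchedule, stim_elapsed: float) -> float:
    return max(0.0, 1.0 - schedule.fatigue_rate * stim_elapsed)


def alpha_value(schedule: AlphaSchedule, t: float, ap_count: int = 0,
                epoch_frequency: float | None = None,
                stim_elapsed: float | None = None) -> float:
    """Unitary recruitment rate at time ``t`` (/s).

    ``t`` is measured from train onset for fixed/accelerating/tabulated modes
    and from rest onset for ``rest_decay``; ``ap_count`` is the number of APs
    delivered so far (drives acceleration); ``stim_elapsed`` is the cumulative
    stimulation time used by the fatigue clock (defaults to ``t``).
    """
    if t < 0:
        raise ParameterError("t must be >= 0")
    if schedule.mode == "fixed":
        return schedule.alpha_fixed
    if schedule.mode == "tabulated":
        return lookup_table(schedule.table, t)
    if schedule.mode == "accelerating":
        if schedule.alpha_max is None:
            raise ParameterError("alpha_max is unset (free) on this schedule")
        se = t if stim_elapsed is None else stim_elapsed
        engaged = 1.0 - np.exp(-ap_count / schedule.tau_ap)
        return schedule.alpha_max * engaged * _fatigue_factor(schedule, se)
    # rest_decay: double-exponential disengagement toward the resting rate
    a0, ai = schedule.alpha_max, schedule.alpha_inf
    return (a0 - ai) * (schedule.w * np.exp(-t / schedule.tau_f)
                        + (1 - schedule.w) * np.exp(-t / schedule.tau_s)) + ai


def integrated_alpha(schedule: AlphaSchedule, t0: float, t1: float,
                     ap_count: int = 0, stim_elapsed: float = 0.0) -> float:
    """Integral of alpha over [t0, t1] (dimensionless).

    Fixed/accelerating/tabulated modes treat alpha as constant over the
    interval (its value at the interval's state); rest-decay integrates the
    double exponential in closed form.
    """
    if t1 < t0:
        raise ParameterError("t1 must be >= t0")
    dt = t1 - t0
    if schedule.mode == "rest_decay":
        return _rest_decay_integral(schedule, t1) - _rest_decay_integral(schedule, t0)
    if schedule.mode == "tabulated":
        return lookup_table(schedule.table, 0.5 * (t0 + t1)) * dt
    return alpha_value(schedule, t0, ap_count=ap_count,
                       stim_elapsed=stim_elapsed) * dt


def _rest_decay_integral(s: AlphaSchedule, t: float) -> float:
    a0, ai = s.alpha_max, s.alpha_inf
    return ((a0 - ai) * (s.w * s.tau_f * (1 - np.exp(-t / s.tau_f))
                         + (1 - s.w) * s.tau_s * (1 - np.exp(-t / s.tau_s)))
            + ai * t)


def replenishment_fraction(t, schedule: AlphaSchedule):
    """Fractional refilling of an initially empty pool after ``t`` s of rest.

    With no release during rest the site balance integrates to
    ``1 - exp(-integral_0^t alpha)``.  Accepts scalars or arrays; bounded in
    [0, 1) and monotone non-decreasing in ``t``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ParameterError("t must be >= 0")
    if schedule.mode == "fixed":
        integral = schedule.alpha_fixed * t_arr
    elif schedule.mode == "rest_decay":
        integral = np.array([_rest_decay_integral(schedule, ti) for ti in t_arr])
    else:
        raise ParameterError("replenishment_fraction needs a fixed or rest_decay schedule")
    out = 1.0 - np.exp(-integral)
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


# ---------------------------------------------------------------------------
# the per-segment recruitment-correction iteration


@dataclass
class RecruitmentResult:
    """Output of :func:`simulate_recruit` (same units as the input responses).

    ``recruit[i]`` is the transmitter recruited and released in segment i;
    ``vacancy[i]`` is the empty pool space (RRP_0 - RRP_t) at segment i.
    """

    recruit: np.ndarray
    vacancy: np.ndarray
    alpha_used: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.recruit)

    @property
    def total(self) -> float:
        return float(self.recruit.sum())


def schedule_lut(schedule: AlphaSchedule, n_segments: int, segment_length: float,
                 ap_counts: np.ndarray | None = None) -> np.ndarray:
    """Render a schedule as a (time, rate) lookup table on segment midpoints.

    ``ap_counts`` gives the number of APs in each segment (from
    :meth:`StimulusProtocol.ap_counts_per_segment` or a SegmentSeries); the AP
    counter continues across frequency changes, so at a frequency jump the
    acceleration picks up where the low-frequency epoch left it.
    """
    if schedule.mode == "tabulated":
        return schedule.table
    mid = (np.arange(n_segments) + 0.5) * segment_length
    if schedule.mode == "fixed":
        return np.column_stack([mid, np.full(n_segments, schedule.alpha_fixed)])
    if schedule.mode == "accelerating":
        if ap_counts is None:
            raise ParameterError("accelerating schedule needs per-segment AP counts")
        ap_counts = np.asarray(ap_counts)
        cum_ap = np.cumsum(ap_counts)
        # fatigue clock: stimulation-only elapsed time at each midpoint
        seg = np.full(n_segments, segment_length)
        active = np.where(ap_counts > 0, seg, 0.0)
        stim_elapsed = np.cumsum(active) - 0.5 * segment_length
        rates = np.array([
            alpha_value(schedule, t, ap_count=int(c), stim_elapsed=max(se, 0.0))
            for t, c, se in zip(mid, cum_ap, stim_elapsed)
        ])
        return np.column_stack([mid, rates])
    rates = np.array([alpha_value(schedule, t) for t in mid])
    return np.column_stack([mid, rates])


def simulate_recruit(responses, schedule_or_lut, segment_length: float,
                     ap_counts: np.ndarray | None = None) -> RecruitmentResult:
    """Split a response train into pool release and newly recruited transmitter.

    Faithful per-segment iteration (vacancy bookkeeping)::

        Vacancy(1) = 0;  Recruit(1) = 0
        Vacancy(i) = Vacancy(i-1) + Resp(i-1) - Recruit(i-1)
        Recruit(i) = Vacancy(i) * alpha((i - 1.5) * seglen) * seglen

    where alpha is looked up by nearest time (first minimum on ties).  The
    vacancy is RRP(0) - RRP(t); by construction
    ``Vacancy(i) = sum(Resp(<i)) - sum(Recruit(<i))`` exactly.  Precondition:
    the responses have reached a steady state by the end of the train.
    """
    resps = np.asarray(responses, dtype=float)
    if resps.ndim != 1 or resps.size < 2:
        raise EstimationError("need at least 2 segments of responses")
    # noise makes async-only segments dip slightly negative; only clearly
    # negative responses indicate an uncorrected baseline
    if np.any(resps < -0.02 * np.abs(resps).max()):
        raise EstimationError("negative responses; baseline-correct the series first")
    if isinstance(schedule_or_lut, AlphaSchedule):
        lut = schedule_lut(schedule_or_lut, resps.size, segment_length, ap_counts)
    else:
        lut = np.atleast_2d(np.asarray(schedule_or_lut, dtype=float))
    if np.any(lut[:, 1] * segment_length >= 1.0):
        raise ParameterError("alpha * segment_length must be < 1 for a stable iteration")

    n = resps.size
    vac = np.zeros(n)
    rec = np.zeros(n)
    alphas = np.zeros(n)
    for i in range(1, n):
        vac[i] = vac[i - 1] + resps[i - 1] - rec[i - 1]
        # 1-based segment index is i+1; lookup time is ((i+1) - 1 - 0.5) * seglen,
        # i.e. the midpoint of the *previous* segment
        a = lookup_table(lut, (i - 0.5) * segment_length)
        alphas[i] = a
        rec[i] = vac[i] * a * segment_length
    return RecruitmentResult(recruit=rec, vacancy=vac, alpha_used=alphas)


# ---------------------------------------------------------------------------
# replenishment fitting


@dataclass
class ReplenishmentFit:
    schedule: AlphaSchedule
    residuals: np.ndarray
    ssr: float
    single_exp_rate: float
    single_exp_ssr: float
    single_exp_adequate: bool


def fit_replenishment(recovery_points, alpha_max: float = 4.3) -> ReplenishmentFit:
    """Fit the rest-decay parameters (w, tau_f, tau_s, alpha_inf) to recovery data.

    ``recovery_points`` is a sequence of ``(rest_interval_s, recovered_fraction)``
    pairs with ``alpha_max`` held fixed at the value extracted from train
    analysis.  A single-exponential model (constant alpha) is fitted alongside;
    ``single_exp_adequate`` flags data that a constant rate explains equally
    well, i.e. no evidence for a disengaging acceleration mechanism.
    """
    pts = np.asarray(list(recovery_points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise EstimationError("need >=4 (interval, fraction) recovery points")
    t, y = pts[:, 0], pts[:, 1]
    if np.allclose(y, y[0]):
        raise EstimationError("degenerate recovery data (all fractions equal)")

    def model(params):
        w, tau_f, tau_s, alpha_inf = params
        s = AlphaSchedule(mode="rest_decay", alpha_max=alpha_max, w=w,
                          tau_f=tau_f, tau_s=tau_s, alpha_inf=alpha_inf)
        return np.array([replenishment_fraction(ti, s) for ti in t])

    def resid(params):
        return model(params) - y

    x0 = np.array([0.9, 0.05, 5.0, 0.1])
    lb = np.array([0.0, 1e-4, 0.1, 0.0])
    ub = np.array([1.0, 1.0, 60.0, alpha_max])
    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    w, tau_f, tau_s, alpha_inf = sol.x
    fitted = AlphaSchedule(mode="rest_decay", alpha_max=alpha_max, w=w,
                           tau_f=tau_f, tau_s=tau_s, alpha_inf=alpha_inf)
    ssr = float(np.sum(sol.fun ** 2))

    def resid1(params):
        return 1.0 - np.exp(-params[0] * t) - y

    sol1 = least_squares(resid1, np.array([alpha_max]), bounds=([1e-6], [1e3]))
    ssr1 = float(np.sum(sol1.fun ** 2))
    adequate = ssr1 <= ssr * 1.05 + 1e-12
    return ReplenishmentFit(schedule=fitted, residuals=sol.fun, ssr=ssr,
                            single_exp_rate=float(sol1.x[0]),
                            single_exp_ssr=ssr1, single_exp_adequate=adequate)
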