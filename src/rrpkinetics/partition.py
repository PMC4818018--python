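"""Steady-state pool partitioning: the flow-through-pool calculus.

During sustained submaximal (100 Hz) stimulation the pool settles to a
steady-state supply of low-release-probability vesicles.  Setting
dRRP/dt = 0 in the site balance turns a handful of measured steady-state
quantities into strong constraints:

* mean p_v of the standing supply (release per AP over standing content);
* the unitary release rate beta_ss = alpha_ss * (RRP0 / RRP_ss - 1);
* for sequential priming, the implied low-to-high maturation rate and dwell
  times in the low-p_v state;
* for parallel models, the steady-state fullness of the low-p_v division
  LpD_ss = alpha / (alpha + beta) * LpD0 and hence the division's share of
  all release sites, LpD0 / RRP0;
* an a-posteriori heterogeneity check: the implied mean p_v of everything in
  the pool vs the measured p_v of the standing supply;
* the p_v of the intrinsically fast sites implied by the mixture.

All operations are closed-form arithmetic on measured rates; infeasible
combinations raise rather than clamp, because they are exactly the
observations that falsify a model class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import EstimationError, InfeasibleModelError


@dataclass
class PoolPartition:
    """Bundle of steady-state partition quantities (rates /s, fractions unitless)."""

    pv_ss: float | None = None
    alpha_ss: float | None = None
    beta_ss: float | None = None
    seq_rate: float | None = None
    dwell_conditional: float | None = None
    dwell_mean: float | None = None
    lpd_steady_fraction: float | None = None
    lpd0_over_rrp0: float | None = None
    pv_total: float | None = None
    pv_low: float | None = None
    pv_hi_range: tuple | None = None
    lpd_recruit_bounds: tuple | None = None
    heterogeneity_ratio: float | None = None
    heterogeneous: bool | None = None

    def rounded(self) -> dict:
        """Reported values at conventional precision (rates 1 d.p., fractions
        2 d.p., percentages nearest integer); unrounded values stay on self."""
        out = {}
        for name in ("alpha_ss", "beta_ss", "seq_rate"):
            v = getattr(self, name)
            if v is not None:
                out[name] = round(v, 1)
        if self.lpd_steady_fraction is not None:
            out["lpd_steady_fraction"] = round(self.lpd_steady_fraction, 2)
        if self.lpd0_over_rrp0 is not None:
            out["lpd0_over_rrp0_percent"] = round(100 * self.lpd0_over_rrp0)
        if self.pv_ss is not None:
            out["pv_ss_percent"] = round(100 * self.pv_ss, 1)
        return out


def pv_steady(Rss: float, RRP_ss: float) -> float:
    """Mean p_v of the standing supply: release per AP over standing content."""
    if RRP_ss <= 0:
        raise EstimationError("RRP_ss must be positive")
    return float(Rss / RRP_ss)


def beta_steady(alpha_ss: float, f_ss: float) -> float:
    """Unitary release rate at steady state, from dRRP/dt = 0:

    beta_ss = alpha_ss * (RRP0 / RRP_ss - 1) = alpha_ss * (1 / f_ss - 1)
    with f_ss the steady-state fullness RRP_ss / RRP0.
    """
    if not 0.0 < f_ss < 1.0:
        raise EstimationError(f"f_ss must be in (0, 1), got {f_ss}")
    return float(alpha_ss * (1.0 / f_ss - 1.0))


def sequential_rates(beta_ss: float, pv_low: float, nu: float) -> tuple:
    """Sequential-priming decomposition of the steady-state release rate.

    Vesicles in the standing supply leave it either by direct exocytosis at
    unitary rate ``pv_low * nu`` or by maturing onward; the residual
    ``seq_rate = beta_ss - pv_low * nu`` is a lower bound on the full
    maturation-then-release sequence.  Returns ``(seq_rate, dwell_conditional,
    dwell_mean)`` where the conditional dwell (1/seq_rate) applies to vesicles
    that mature before releasing and the mean dwell is 1/beta_ss.
    """
    direct = pv_low * nu
    if beta_ss <= direct:
        raise InfeasibleModelError(
            f"beta_ss = {beta_ss}/s does not exceed the direct release rate "
            f"{direct}/s; a sequential model is infeasible here")
    seq = beta_ss - direct
    return float(seq), float(1.0 / seq), float(1.0 / beta_ss)


def parallel_steady_fraction(alpha_lpd: float, beta_lpd: float) -> float:
    """Steady-state fullness of the low-p_v division:
    LpD_ss / LpD0 = alpha / (alpha + beta)."""
    if alpha_lpd < 0 or beta_lpd < 0:
        raise EstimationError("rates must be >= 0")
    tot = alpha_lpd + beta_lpd
    if tot == 0:
        raise EstimationError("alpha + beta must be positive")
    return float(alpha_lpd / tot)


def lpd0_fraction(lpd_ss_over_rrp0: float, steady_fraction: float) -> float:
    """Share of all release sites with intrinsically low p_v:
    LpD0 / RRP0 = (LpD_ss / RRP0) / (LpD_ss / LpD0)."""
    if steady_fraction <= 0:
        raise EstimationError("steady_fraction must be positive")
    out = lpd_ss_over_rrp0 / steady_fraction
    if out > 1.0 + 1e-9:
        raise InfeasibleModelError(
            f"LpD0/RRP0 = {out:.3f} > 1: inputs are inconsistent with a "
            "subdivision of the pool")
    return float(out)


def lpd_recruit_bounds(jump_series, rest300_series, rrp_ss100: float | None = None,
                       protocol=None) -> tuple:
    """Bounds on the unitary recruitment rate to low-p_v sites.

    The jump-induced increase in steady-state release rate (pC/s) is divided
    by the standing quantity vacated by the jump.  The upper bound deconvolves
    that quantity assuming maximal bulk recruitment from the jump
    (back-extrapolation); the lower bound assumes none until exhaustion.
    """
    from .estimate import (estimate_rrp0, jump_onset_index, post_jump_excess,
                           steady_state_stats)
    j = jump_onset_index(jump_series)
    seg = jump_series.segment_length
    pre_rate = jump_series.charges[max(j - 30, 0):j].mean() / seg
    post_rate = jump_series.charges[-10:].mean() / seg
    increase = post_rate - pre_rate
    if increase <= 0:
        return 0.0, 0.0
    excess = post_jump_excess(jump_series)
    st = steady_state_stats(excess, protocol) if protocol is not None else None
    if st is None:
        from .protocols import StimulusProtocol
        raise EstimationError("protocol required to analyse the excess series")
    green = estimate_rrp0(excess, protocol, "back_extrapolation", stats=st).rrp0_pC
    brown = estimate_rrp0(excess, protocol, "none_until_ss", stats=st).rrp0_pC
    if rrp_ss100 is not None:
        if rrp_ss100 <= 0:
            raise EstimationError("rrp_ss100 must be positive")
        scale = rrp_ss100 / (0.5 * (green + brown))
        green, brown = green * scale, brown * scale
    return float(increase / brown), float(increase / green)


def pv_hi_range(pv_total: float, pv_low_upper: float, f_lpd: float) -> tuple:
    """Mean p_v of the intrinsically fast sites implied by the mixture:

    pv_hi = (pv_total - pv_low * f_lpd) / (1 - f_lpd),  f_lpd = LpD0/RRP0.

    The lower bound uses pv_low = pv_low_upper (the standing-supply value,
    itself likely facilitated above the resting value); the upper bound
    assumes pv_low = 0 at the start of stimulation.
    """
    if not 0.0 <= f_lpd < 1.0:
        raise EstimationError("f_lpd must be in [0, 1)")
    hi = pv_total / (1.0 - f_lpd)
    lo = (pv_total - pv_low_upper * f_lpd) / (1.0 - f_lpd)
    if lo < 0:
        raise InfeasibleModelError(
            f"pv_low = {pv_low_upper} with f_lpd = {f_lpd} implies a negative "
            "high-class p_v; the mixture is infeasible")
    return float(lo), float(hi)


def aposteriori_check(beta_ss: float, pv_ss: float, nu: float,
                      threshold: float = 1.5) -> dict:
    """Test for simultaneous p_v heterogeneity within the pool.

    ``beta_ss / nu`` is the mean p_v implied for *all* pool vesicles at steady
    state; if it exceeds the measured standing-supply p_v by more than
    ``threshold``-fold, vesicles with distinct p_v coexist at the same moment,
    ruling out a-posteriori (global fatigue) explanations.
    """
    if beta_ss <= 0 or pv_ss <= 0 or nu <= 0:
        raise EstimationError("inputs must be positive")
    implied = beta_ss / nu
    ratio = implied / pv_ss
    return {"implied_pv": float(implied), "measured_pv_ss": float(pv_ss),
            "ratio": float(ratio), "threshold": threshold,
            "verdict": "heterogeneous" if ratio > threshold else "homogeneous"}


def plasticity_correlations(per_trial) -> dict:
    """OLS of short-term-plasticity readouts on the pool-partition predictor.

    ``per_trial`` is a sequence of ``(predictor, ppr, half_decay)`` triples
    (predictor = steady-state unreleased fraction or LpD0/RRP0).  Returns per
    panel slope, intercept and R^2.
    """
    arr = np.asarray(list(per_trial), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 3:
        raise EstimationError("need >= 3 (predictor, ppr, half_decay) trials")
    x = arr[:, 0]
    if np.allclose(x, x[0]):
        raise EstimationError("degenerate (constant) predictor")
    out = {}
    for name, y in (("ppr", arr[:, 1]), ("half_decay", arr[:, 2])):
        res = sps.linregress(x, y)
        out[name] = {"slope": float(res.slope), "intercept": float(res.intercept),
                     "r_squared": float(res.rvalue ** 2), "p_value": float(res.pvalue)}
    return out
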