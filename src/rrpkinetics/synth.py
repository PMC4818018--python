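"""Synthetic release-site simulation and EPSC rendering.

The generator realises the two-state release-site picture directly: the pool
is ``n_sites`` autonomous sites, each Full (holding one releasable vesicle) or
Empty.  At each AP an occupied site releases with its class release
probability p_v; between events an empty site refills with probability
``1 - exp(-integral of alpha)`` under the configured recruitment-rate
schedule.  Sites come in classes (e.g. a low-p_v and a high-p_v class in
near-equal proportions, the parallel model), or a single pool whose occupants
mature from low to high p_v (the sequential model).

Released quanta are rendered into a current trace by convolving with a
miniature-EPSC kernel (difference of exponentials whose integral is the
quantal charge scaled by the kynurenate factor), with Gaussian sample noise
and optional biphasic stimulus artifacts, so that the full processing chain
(baseline, blanking, segmentation, estimation) can be exercised end to end
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import AlphaSchedule, accelerating_schedule, integrated_alpha
from .errors import ParameterError, ProtocolError
from .protocols import StimulusProtocol
from .traces import Trace


@dataclass(frozen=True)
class SiteClassSpec:
    """One class of release sites.

    ``fraction`` of all sites; ``pv_baseline`` per-AP release probability;
    optional multiplicative facilitation (per-AP increment on p_v, decaying
    exponentially between APs with ``facilitation_decay``); in sequential
    priming mode ``maturation_rate`` (/s) promotes this class's occupants to
    the next class.
    """

    fraction: float
    pv_baseline: float
    facilitation_increment: float = 0.0
    facilitation_decay: float = 0.1
    maturation_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ParameterError("class fraction must be in [0, 1]")
        if not 0.0 <= self.pv_baseline <= 1.0:
            raise ParameterError("pv_baseline must be in [0, 1]")
        if self.facilitation_increment < 0 or self.facilitation_decay <= 0:
            raise ParameterError("facilitation parameters must be positive")


def default_site_classes() -> tuple:
    """Two parallel classes: 49% low-p_v (4.7%) and 51% high-p_v (20%)."""
    return (SiteClassSpec(fraction=0.49, pv_baseline=0.047),
            SiteClassSpec(fraction=0.51, pv_baseline=0.20))


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration (defaults are the calyx study conditions)."""

    n_sites: int = 2553
    alpha_schedule: AlphaSchedule = field(default_factory=accelerating_schedule)
    site_classes: tuple = field(default_factory=default_site_classes)
    quantal_charge_fC: float = 31.4
    kyn_scale: float = 0.13
    mepsc_rise_s: float = 8.0e-5
    mepsc_decay_s: float = 2.5e-4
    mepsc_charge_cv: float = 0.0
    response_latency_s: float = 1.0e-3
    noise_sd_nA: float = 0.005
    async_rate: float = 0.0
    priming_mode: str = "parallel"
    sample_rate_hz: float = 50_000.0
    artifact_amp_nA: float = 5.0
    artifact_width_s: float = 3.0e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")
        if self.quantal_charge_fC <= 0:
            raise ParameterError("quantal_charge_fC must be > 0")
        if not 0.0 < self.kyn_scale <= 1.0:
            raise ParameterError("kyn_scale must be in (0, 1]")
        if self.priming_mode not in ("parallel", "sequential"):
            raise ParameterError("priming_mode must be 'parallel' or 'sequential'")
        fr = sum(c.fraction for c in self.site_classes)
        if abs(fr - 1.0) > 1e-9:
            raise ParameterError(f"class fractions must sum to 1, got {fr}")
        if self.mepsc_rise_s <= 0 or self.mepsc_decay_s <= 0:
            raise ParameterError("mEPSC kernel time constants must be > 0")
        if self.mepsc_rise_s >= self.mepsc_decay_s:
            raise ParameterError("mEPSC rise must be faster than decay")
        if self.response_latency_s < 0:
            raise ParameterError("response_latency_s must be >= 0")
        if self.async_rate < 0:
            raise ParameterError("async_rate must be >= 0")

    @property
    def quantal_charge_pC(self) -> float:
        """Measured charge per quantum after KYN scaling, pC."""
        return self.quantal_charge_fC * self.kyn_scale * 1.0e-3

    def class_capacities(self) -> np.ndarray:
        caps = np.floor(np.array([c.fraction for c in self.site_classes])
                        * self.n_sites).astype(int)
        caps[-1] += self.n_sites - caps.sum()
        return caps


@dataclass
class ReleaseRecord:
    """Bookkeeping of one simulated (or mean-field) train.

    Arrays are indexed ``[ap, class]``; ``occupancy`` holds the pool content
    immediately before each AP's release.  Conservation holds exactly:
    total releases (sync + async) + final occupancy = n_sites + total recruits.
    """

    protocol: StimulusProtocol
    n_sites: int
    releases: np.ndarray
    recruits: np.ndarray
    occupancy: np.ndarray
    async_counts: np.ndarray
    async_times: np.ndarray | None
    matured: np.ndarray
    final_occupancy: np.ndarray
    stochastic: bool

    @property
    def releases_per_ap(self) -> np.ndarray:
        return self.releases.sum(axis=1)

    @property
    def total_released(self) -> float:
        return float(self.releases.sum() + self.async_counts.sum())

    @property
    def total_recruited(self) -> float:
        return float(self.recruits.sum())

    def conservation_error(self) -> float:
        return float(self.total_released + self.final_occupancy.sum()
                     - self.n_sites - self.total_recruited)

    def segment_charges(self, params: SynthParams,
                        n_segments: int | None = None) -> np.ndarray:
        """Ground-truth released charge per grid segment, pC (KYN-scaled)."""
        p = self.protocol
        n = p.n_segments if n_segments is None else n_segments
        out = np.zeros(n)
        idx = p.segment_index(p.ap_times)
        np.add.at(out, idx, self.releases_per_ap * params.quantal_charge_pC)
        if self.async_times is not None and self.async_times.size:
            a_idx = np.floor((self.async_times - p.train_start)
                             / p.segment_length).astype(int)
            ok = (a_idx >= 0) & (a_idx < n)
            np.add.at(out, a_idx[ok], params.quantal_charge_pC)
        elif not self.stochastic and self.async_counts.any():
            # expected asynchronous charge spread over each inter-AP interval
            ivals = p.intervals()
            for k, t_ap in enumerate(p.ap_times):
                q = self.async_counts[k].sum() * params.quantal_charge_pC
                if q == 0:
                    continue
                s0 = p.segment_index(t_ap)
                s1 = min(p.segment_index(t_ap + ivals[k] - 1e-12), n - 1)
                span = np.arange(s0, s1 + 1)
                out[span] += q / span.size
        return out


def _interval_context(params: SynthParams, protocol: StimulusProtocol):
    """Per-interval (dt, refill probability context) shared by both simulators."""
    sched = params.alpha_schedule
    t0 = protocol.train_start
    intervals = protocol.intervals()
    stim_elapsed = 0.0
    ctx = []
    for k, (t_ap, dt) in enumerate(zip(protocol.ap_times, intervals)):
        if sched.mode == "rest_decay":
            # acceleration state resets its clock at each AP; during trains
            # (short intervals) alpha stays near alpha_max, during long rests
            # it disengages along the double exponential
            integ = integrated_alpha(sched, 0.0, dt)
        else:
            integ = integrated_alpha(sched, t_ap - t0, t_ap - t0 + dt,
                                     ap_count=k + 1, stim_elapsed=stim_elapsed)
        stim_elapsed += min(dt, 0.05)
        ctx.append((dt, 1.0 - np.exp(-integ)))
    return ctx


def _facilitated_pv(cls: SiteClassSpec, fac_state: float) -> float:
    pv = cls.pv_baseline * (1.0 + fac_state)
    if pv > 1.0 + 1e-12:
        raise ParameterError(
            f"facilitated p_v = {pv:.3f} exceeds 1; clamping is not performed")
    return min(pv, 1.0)


def simulate_sites(params: SynthParams, protocol: StimulusProtocol,
                   seed: int | None = None) -> ReleaseRecord:
    """Stochastic two-state Markov simulation of all release sites.

    At each AP, occupied sites release binomially with their class p_v (after
    facilitation / maturation updates); over the following inter-stimulus
    interval empty sites refill with probability ``1 - exp(-integral alpha)``,
    optional asynchronous release drains occupied sites as a Poisson process,
    and (sequential mode) occupants mature from the low- to the high-p_v class.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    classes = params.site_classes
    nc = len(classes)
    caps = params.class_capacities()
    occ = caps.copy()
    n_aps = protocol.ap_times.size
    rel = np.zeros((n_aps, nc), dtype=int)
    rec = np.zeros((n_aps, nc), dtype=int)
    occ_hist = np.zeros((n_aps, nc), dtype=int)
    asy = np.zeros((n_aps, nc), dtype=int)
    matured = np.zeros(n_aps, dtype=int)
    asy_times = []
    fac = np.zeros(nc)
    sequential = params.priming_mode == "sequential"

    for k, ((dt, p_fill), t_ap) in enumerate(zip(_interval_context(params, protocol),
                                                 protocol.ap_times)):
        occ_hist[k] = occ
        for c, cls in enumerate(classes):
            pv = _facilitated_pv(cls, fac[c])
            rel[k, c] = rng.binomial(occ[c], pv) if occ[c] > 0 else 0
            occ[c] -= rel[k, c]
            fac[c] = (fac[c] + cls.facilitation_increment) * np.exp(-dt / cls.facilitation_decay)
        if params.async_rate > 0:
            p_asy = 1.0 - np.exp(-params.async_rate * dt)
            for c in range(nc):
                asy[k, c] = rng.binomial(occ[c], p_asy) if occ[c] > 0 else 0
                occ[c] -= asy[k, c]
            n_asy = int(asy[k].sum())
            if n_asy:
                asy_times.append(t_ap + rng.uniform(0.0, dt, n_asy))
        if sequential and nc > 1:
            for c in range(nc - 1):
                m = classes[c].maturation_rate
                if m > 0 and occ[c] > 0:
                    mv = rng.binomial(occ[c], 1.0 - np.exp(-m * dt))
                    occ[c] -= mv
                    occ[c + 1] += mv
                    matured[k] += mv
        if sequential:
            vac = params.n_sites - int(occ.sum())
            rec[k, 0] = rng.binomial(vac, p_fill) if vac > 0 else 0
            occ[0] += rec[k, 0]
        else:
            for c in range(nc):
                vac = caps[c] - occ[c]
                rec[k, c] = rng.binomial(vac, p_fill) if vac > 0 else 0
                occ[c] += rec[k, c]

    times = np.sort(np.concatenate(asy_times)) if asy_times else np.empty(0)
    return ReleaseRecord(protocol=protocol, n_sites=params.n_sites,
                         releases=rel, recruits=rec, occupancy=occ_hist,
                         async_counts=asy, async_times=times, matured=matured,
                         final_occupancy=occ.astype(float), stochastic=True)


def mean_field(params: SynthParams, protocol: StimulusProtocol) -> ReleaseRecord:
    """Deterministic expected-value train: the large-N limit of simulate_sites."""
    classes = params.site_classes
    nc = len(classes)
    caps = params.class_capacities().astype(float)
    occ = caps.copy()
    n_aps = protocol.ap_times.size
    rel = np.zeros((n_aps, nc))
    rec = np.zeros((n_aps, nc))
    occ_hist = np.zeros((n_aps, nc))
    asy = np.zeros((n_aps, nc))
    matured = np.zeros(n_aps)
    fac = np.zeros(nc)
    sequential = params.priming_mode == "sequential"

    for k, (dt, p_fill) in enumerate(_interval_context(params, protocol)):
        occ_hist[k] = occ
        for c, cls in enumerate(classes):
            pv = _facilitated_pv(cls, fac[c])
            rel[k, c] = occ[c] * pv
            occ[c] -= rel[k, c]
            fac[c] = (fac[c] + cls.facilitation_increment) * np.exp(-dt / cls.facilitation_decay)
        if params.async_rate > 0:
            p_asy = 1.0 - np.exp(-params.async_rate * dt)
            asy[k] = occ * p_asy
            occ -= asy[k]
        if sequential and nc > 1:
            for c in range(nc - 1):
                m = classes[c].maturation_rate
                if m > 0:
                    mv = occ[c] * (1.0 - np.exp(-m * dt))
                    occ[c] -= mv
                    occ[c + 1] += mv
                    matured[k] += mv
        if sequential:
            g = (params.n_sites - occ.sum()) * p_fill
            occ[0] += g
            rec[k, 0] = g
        else:
            rec[k] = (caps - occ) * p_fill
            occ += rec[k]

    return ReleaseRecord(protocol=protocol, n_sites=params.n_sites,
                         releases=rel, recruits=rec, occupancy=occ_hist,
                         async_counts=asy, async_times=None, matured=matured,
                         final_occupancy=occ, stochastic=False)


# ---------------------------------------------------------------------------
# rendering


def _mepsc_kernel(params: SynthParams) -> np.ndarray:
    """Unit-integral difference-of-exponentials kernel, units 1/s."""
    dt = 1.0 / params.sample_rate_hz
    t = np.arange(0.0, 10.0 * params.mepsc_decay_s, dt)
    h = np.exp(-t / params.mepsc_decay_s) - np.exp(-t / params.mepsc_rise_s)
    area = h.sum() * dt
    if area <= 0:
        raise ParameterError("degenerate mEPSC kernel")
    return h / area


def render_trace(record: ReleaseRecord, params: SynthParams,
                 protocol: StimulusProtocol | None = None, *,
                 with_artifacts: bool = False, pre_train_s: float = 0.12,
                 post_train_s: float = 0.02, noise_sd: float | None = None,
                 seed: int | None = None) -> Trace:
    """Render released quanta into a current trace (nA, inward negative).

    Each quantum contributes a kernel whose integral is
    ``quantal_charge * kyn_scale``; the synchronous response begins
    ``response_latency_s`` after its AP (so that artifact blanking windows do
    not clip it); Gaussian sample noise is added, plus an optional biphasic
    stimulus artifact at each AP time.
    """
    protocol = record.protocol if protocol is None else protocol
    fs = params.sample_rate_hz
    dt = 1.0 / fs
    t0 = protocol.train_start - pre_train_s
    n = int(round((protocol.train_end + post_train_s - t0) * fs))
    imp = np.zeros(n)  # nC deposited per sample
    q_nC = params.quantal_charge_pC * 1.0e-3
    lat = params.response_latency_s

    ap_idx = np.round((protocol.ap_times - t0) * fs).astype(int)
    sync_idx = np.round((protocol.ap_times + lat - t0) * fs).astype(int)
    np.add.at(imp, sync_idx, record.releases_per_ap * q_nC)
    if record.async_times is not None and record.async_times.size:
        a_idx = np.round((record.async_times + lat - t0) * fs).astype(int)
        np.add.at(imp, a_idx[(a_idx >= 0) & (a_idx < n)], q_nC)
    elif not record.stochastic and record.async_counts.any():
        ivals = protocol.intervals()
        for k, t_ap in enumerate(protocol.ap_times):
            q = record.async_counts[k].sum() * q_nC
            if q == 0:
                continue
            i0 = int(round((t_ap + lat - t0) * fs))
            i1 = min(int(round((t_ap + lat + ivals[k] - t0) * fs)), n)
            imp[i0:i1] += q / max(i1 - i0, 1)

    current = -np.convolve(imp, _mepsc_kernel(params))[:n]

    if with_artifacts and params.artifact_amp_nA > 0:
        half = max(int(round(0.5 * params.artifact_width_s * fs)), 1)
        for i in ap_idx:
            current[i:i + half] += params.artifact_amp_nA
            current[i + half:i + 2 * half] -= params.artifact_amp_nA

    sd = params.noise_sd_nA if noise_sd is None else noise_sd
    if sd > 0:
        rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
        current = current + rng.normal(0.0, sd, n)

    return Trace(sample_period=dt, samples=current, t0=t0,
                 metadata={"kyn_scale": params.kyn_scale,
                           "quantal_charge_fC": params.quantal_charge_fC})


def generate_mepscs(rate: float, duration: float, params: SynthParams,
                    seed: int | None = None) -> Trace:
    """Continuous recording of spontaneous miniature EPSCs.

    Poisson event times at ``rate`` /s over ``duration`` s; per-event charge
    drawn around ``quantal_charge_fC`` with coefficient of variation
    ``mepsc_charge_cv`` (default 0, a delta distribution).  No KYN scaling:
    minis are recorded before the antagonist is added.  Event times and
    charges are kept in the trace metadata for calibration tests.
    """
    if rate < 0:
        raise ParameterError("rate must be >= 0")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    fs = params.sample_rate_hz
    n = int(round(duration * fs))
    n_ev = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n_ev))
    charges = np.full(n_ev, params.quantal_charge_fC)
    if params.mepsc_charge_cv > 0 and n_ev:
        charges = rng.normal(params.quantal_charge_fC,
                             params.mepsc_charge_cv * params.quantal_charge_fC,
                             n_ev).clip(min=0.0)
    imp = np.zeros(n)
    idx = np.minimum(np.round(times * fs).astype(int), n - 1)
    np.add.at(imp, idx, charges * 1.0e-6)  # fC -> nC
    current = -np.convolve(imp, _mepsc_kernel(params))[:n]
    if params.noise_sd_nA > 0:
        current = current + rng.normal(0.0, params.noise_sd_nA, n)
    return Trace(sample_period=1.0 / fs, samples=current, t0=0.0,
                 metadata={"event_times": times, "event_charges_fC": charges})
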