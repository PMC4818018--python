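"""Raw-trace processing: baseline, artifact blanking, segmentation, metrics.

Everything downstream works on the per-segment integrated charge series: the
record is divided into contiguous segments (default 3.33 ms, the 300 Hz
inter-stimulus interval) on one grid anchored at train onset, and each
segment's inward charge is reported as positive pC.  Blanked stimulus
artifacts are bridged by linear interpolation rather than zeroed so that
segment integrals stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TraceError
from .protocols import StimulusProtocol

#: default artifact blanking window, s (1 ms, as used for recordings in KYN)
DEFAULT_BLANK_S = 1.0e-3
#: post-pulse window used to measure the asynchronous release level, s
ASYNC_WINDOW_S = (2.8e-3, 3.3e-3)


@dataclass
class Trace:
    """Uniformly sampled current recording (nA; inward currents negative)."""

    sample_period: float
    samples: np.ndarray
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_period <= 0:
            raise TraceError("sample_period must be positive")
        if self.samples.ndim != 1:
            raise TraceError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise TraceError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) * self.sample_period

    @property
    def t_end(self) -> float:
        return self.t0 + self.samples.size * self.sample_period

    def index_of(self, t: float) -> int:
        return int(round((t - self.t0) / self.sample_period))

    def copy(self, samples=None) -> "Trace":
        return Trace(self.sample_period,
                     self.samples.copy() if samples is None else samples,
                     self.t0, dict(self.metadata))


@dataclass
class SegmentSeries:
    """Per-segment integrated charge aligned to the protocol grid.

    ``charges`` in pC (inward charge positive); ``ap_counts[i]`` is the number
    of APs in segment i (0 marks asynchronous-only segments, which are flagged
    but never dropped).
    """

    segment_length: float
    charges: np.ndarray
    t_start: np.ndarray
    ap_counts: np.ndarray

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.ap_counts = np.asarray(self.ap_counts, dtype=int)
        if not (self.charges.size == self.t_start.size == self.ap_counts.size):
            raise TraceError("segment arrays must have matching lengths")
        if not np.all(np.isfinite(self.charges)):
            raise TraceError("charges must be finite")

    @property
    def n_segments(self) -> int:
        return self.charges.size

    @property
    def has_ap(self) -> np.ndarray:
        return self.ap_counts > 0

    @property
    def ap_charges(self) -> np.ndarray:
        return self.charges[self.has_ap]

    @property
    def midpoints(self) -> np.ndarray:
        return self.t_start + 0.5 * self.segment_length

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.charges)

    @property
    def total(self) -> float:
        return float(self.charges.sum())

    def copy(self, charges=None) -> "SegmentSeries":
        return SegmentSeries(self.segment_length,
                             self.charges.copy() if charges is None else charges,
                             self.t_start.copy(), self.ap_counts.copy())


@dataclass
class PlasticityMetrics:
    paired_pulse_ratio: float
    half_decay_time: float | None
    sync_fraction: float | None


# ---------------------------------------------------------------------------
# trace operations


def baseline_subtract(trace: Trace, protocol: StimulusProtocol,
                      window: float = 0.100) -> Trace:
    """Subtract the mean of the ``window`` s immediately preceding the train."""
    start = protocol.train_start - window
    if start < trace.t0 - 0.5 * trace.sample_period:
        raise TraceError(
            f"need {window * 1e3:.0f} ms of pre-train record, trace starts at "
            f"{trace.t0:.4f} s but train starts at {protocol.train_start:.4f} s")
    i0 = max(trace.index_of(start), 0)
    i1 = trace.index_of(protocol.train_start)
    if i1 <= i0:
        raise TraceError("empty baseline window")
    return trace.copy(trace.samples - trace.samples[i0:i1].mean())


def blank_artifacts(trace: Trace, protocol: StimulusProtocol,
                    window: float = DEFAULT_BLANK_S) -> Trace:
    """Replace ``[t_ap, t_ap + window)`` with a linear bridge at every AP.

    Interpolation (not zeroing) keeps segment integrals unbiased; blanking is
    applied at every protocol AP, including during low-frequency epochs.
    """
    if window == 0:
        return trace.copy()
    if window < 0:
        raise TraceError("blank window must be >= 0")
    min_ival = np.diff(protocol.ap_times).min() if protocol.ap_times.size > 1 else np.inf
    if window >= min_ival:
        raise TraceError("blank window must be shorter than the inter-stimulus interval")
    out = trace.samples.copy()
    n = out.size
    w = max(int(round(window / trace.sample_period)), 1)
    for t_ap in protocol.ap_times:
        i0 = trace.index_of(t_ap)
        i1 = min(i0 + w, n - 1)
        if i0 < 0 or i0 >= n - 1:
            continue
        left = out[i0 - 1] if i0 > 0 else out[i1]
        out[i0:i1] = np.linspace(left, out[i1], i1 - i0, endpoint=False)
    return trace.copy(out)


def subtract_reference(trace_a: Trace, trace_b: Trace) -> Trace:
    """Pointwise difference (e.g. KYN recording minus CNQX reference)."""
    if trace_a.samples.shape != trace_b.samples.shape:
        raise TraceError("traces must have identical lengths")
    if not np.isclose(trace_a.sample_period, trace_b.sample_period):
        raise TraceError("traces must share a sampling period")
    if abs(trace_a.t0 - trace_b.t0) > 0.5 * trace_a.sample_period:
        raise TraceError("traces must be aligned in time")
    return trace_a.copy(trace_a.samples - trace_b.samples)


def average_traces(traces_: list) -> Trace:
    """Average digitized replicate trials before further analysis."""
    first = traces_[0]
    for t in traces_[1:]:
        if t.samples.shape != first.samples.shape:
            raise TraceError("replicates must have identical shapes")
    return first.copy(np.mean([t.samples for t in traces_], axis=0))


def integrate_segments(trace: Trace, protocol: StimulusProtocol,
                       segment_length: float | None = None,
                       n_segments: int | None = None) -> SegmentSeries:
    """Per-segment inward charge, pC, on the grid anchored at train onset.

    charge = -(integral of current over the segment) so that inward (negative)
    current yields positive charge; 1 nA over 1 ms = 1 pC.
    """
    seg = protocol.segment_length if segment_length is None else segment_length
    t_first = protocol.train_start
    if n_segments is None:
        n_full = int(np.floor((trace.t_end - t_first) / seg + 1e-9))
        n_min = int(np.floor((protocol.ap_times[-1] - t_first) / seg + 1e-9)) + 1
        n_segments = max(n_full, 0)
        if n_segments < n_min:
            raise TraceError("segment grid exceeds the recorded trace")
    starts = t_first + np.arange(n_segments) * seg
    if starts[-1] + seg > trace.t_end + 0.5 * trace.sample_period:
        raise TraceError("segment grid exceeds the recorded trace")
    # rectangle-rule integral via cumulative sums at grid boundaries
    csum = np.concatenate([[0.0], np.cumsum(trace.samples)]) * trace.sample_period
    edges = np.round((np.append(starts, starts[-1] + seg) - trace.t0)
                     / trace.sample_period).astype(int)
    edges = np.clip(edges, 0, trace.samples.size)
    charges = -(csum[edges[1:]] - csum[edges[:-1]]) * 1.0e3  # nA*s -> pC
    idx = np.floor((protocol.ap_times - t_first) / seg + 1e-9).astype(int)
    ap_counts = np.bincount(idx[(idx >= 0) & (idx < n_segments)], minlength=n_segments)
    return SegmentSeries(seg, charges, starts, ap_counts)


def sync_async_split(trace: Trace, protocol: StimulusProtocol,
                     segment_length: float | None = None,
                     async_window: tuple = ASYNC_WINDOW_S,
                     blank_window: float = DEFAULT_BLANK_S):
    """Split each AP segment into synchronous and asynchronous components.

    The asynchronous level is the mean current in the ``async_window`` after
    each pulse (default 2.8-3.3 ms); the synchronous charge is the segment
    charge minus that level times the segment duration.  Returns
    ``(metrics, components)`` where components maps ``sync``/``async`` to
    per-segment pC arrays that sum exactly to the unsplit segment charges.
    """
    if async_window[0] < blank_window:
        raise TraceError("asynchronous window collides with the blanking window")
    series = integrate_segments(trace, protocol, segment_length)
    seg = series.segment_length
    sync = np.zeros(series.n_segments)
    async_ = series.charges.copy()
    level = 0.0
    for i in range(series.n_segments):
        if series.ap_counts[i]:
            t_ap = series.t_start[i]
            j0 = trace.index_of(t_ap + async_window[0])
            j1 = trace.index_of(t_ap + async_window[1])
            level = float(trace.samples[j0:j1].mean())
            a = -level * seg * 1.0e3
            sync[i] = series.charges[i] - a
            async_[i] = a
    ap = series.has_ap
    tot_sync = sync[ap].sum()
    tot = tot_sync + async_[ap].sum()
    frac = tot_sync / tot if tot != 0 else 0.0
    metrics = PlasticityMetrics(
        paired_pulse_ratio=paired_pulse_ratio(series) if ap.sum() >= 2 else np.nan,
        half_decay_time=None,
        sync_fraction=float(np.clip(frac, 0.0, 1.0)))
    return metrics, {"sync": sync, "async": async_, "series": series}


# ---------------------------------------------------------------------------
# series-level metrics


def paired_pulse_ratio(series: SegmentSeries) -> float:
    """Second AP-segment charge over the first."""
    ap = series.ap_charges
    if ap.size < 2:
        raise TraceError("need at least two AP-containing segments")
    if ap[0] == 0:
        raise TraceError("zero first response")
    return float(ap[1] / ap[0])


def half_decay_time(series: SegmentSeries, steady_rate: float) -> float:
    """Time to release half of the steady-state-subtracted cumulative charge.

    ``steady_rate`` is the steady response per AP segment (pC); the crossing
    is interpolated linearly between segment midpoints and reported relative
    to train onset.
    """
    ap = series.has_ap
    y = series.charges[ap] - steady_rate
    t = series.midpoints[ap] - series.t_start[0]
    if np.all(y <= 0):
        raise TraceError("steady rate exceeds every response; nothing decays")
    cum = np.cumsum(y)
    target = 0.5 * cum[-1]
    j = int(np.searchsorted(cum, target))
    if j == 0:
        return float(t[0])
    frac = (target - cum[j - 1]) / (cum[j] - cum[j - 1])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))
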