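"""Stimulus protocols and the segment grid.

A protocol is an ordered list of action-potential (AP) times plus the
segmentation convention used throughout the analysis: the record is divided
into contiguous segments of fixed length (default 1/300 s = 3.33 ms),
anchored at the first AP and continuing through frequency changes and rest
intervals on one uninterrupted grid.  Per-segment integrated charge on this
grid is the universal currency of every downstream estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError

#: default segment length, s (the inter-stimulus interval at 300 Hz)
DEFAULT_SEGMENT_S = 1.0 / 300.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered AP times (s) with epoch labels and the segment grid length.

    Parameters
    ----------
    ap_times:
        Strictly increasing AP times in seconds.
    epochs:
        ``(label, start_time)`` pairs, e.g. ``(("100Hz", 0.15), ("300Hz", 0.65))``.
        Purely descriptive; frequencies are always derived from the AP times.
    segment_length:
        Grid length in seconds.
    """

    ap_times: np.ndarray
    epochs: tuple = ()
    segment_length: float = DEFAULT_SEGMENT_S

    def __post_init__(self):
        ap = np.asarray(self.ap_times, dtype=float)
        object.__setattr__(self, "ap_times", ap)
        if ap.ndim != 1 or ap.size == 0:
            raise ProtocolError("protocol needs at least one AP time")
        if ap.size > 1 and not np.all(np.diff(ap) > 0):
            raise ProtocolError("ap_times must be strictly increasing")
        if self.segment_length <= 0:
            raise ProtocolError("segment_length must be positive")

    # -- grid ------------------------------------------------------------
    @property
    def train_start(self) -> float:
        return float(self.ap_times[0])

    @property
    def train_end(self) -> float:
        """End of the segment containing the last AP."""
        last = self.segment_index(self.ap_times[-1])
        return self.train_start + (last + 1) * self.segment_length

    @property
    def n_segments(self) -> int:
        return self.segment_index(self.ap_times[-1]) + 1

    def segment_index(self, t) -> int:
        """Index of the grid segment containing time ``t``."""
        idx = np.floor((np.asarray(t) - self.train_start) / self.segment_length + 1e-9)
        return int(idx) if np.isscalar(t) or np.asarray(t).ndim == 0 else idx.astype(int)

    def segment_starts(self, n_segments: int | None = None) -> np.ndarray:
        n = self.n_segments if n_segments is None else n_segments
        return self.train_start + np.arange(n) * self.segment_length

    def ap_counts_per_segment(self, n_segments: int | None = None) -> np.ndarray:
        """Number of APs falling in each grid segment."""
        n = self.n_segments if n_segments is None else n_segments
        idx = np.floor((self.ap_times - self.train_start) / self.segment_length + 1e-9).astype(int)
        counts = np.bincount(idx[(idx >= 0) & (idx < n)], minlength=n)
        return counts

    # -- frequencies -----------------------------------------------------
    def frequency_at_end(self) -> float:
        """Stimulation frequency of the final epoch, from the last AP intervals."""
        if self.ap_times.size < 2:
            raise ProtocolError("need >=2 APs to derive a frequency")
        tail = np.diff(self.ap_times)[-min(5, self.ap_times.size - 1):]
        return 1.0 / float(np.median(tail))

    def intervals(self) -> np.ndarray:
        """Inter-AP intervals; the interval after the final AP is one segment."""
        if self.ap_times.size == 1:
            return np.array([self.segment_length])
        return np.append(np.diff(self.ap_times), self.segment_length)


def _train(start: float, freq: float, n: int) -> np.ndarray:
    return start + np.arange(n) / freq


def make_protocol(name: str, *, delta: float = 1.0, start: float = 0.15,
                  segment_length: float = DEFAULT_SEGMENT_S) -> StimulusProtocol:
    """Build one of the canonical stimulation protocols.

    ``rest300``      45 APs at 300 Hz (150 ms) from rest.
    ``jump500``      500 ms at 100 Hz, then 200 ms at 300 Hz.
    ``jump750``      750 ms at 100 Hz, then 200 ms at 300 Hz.
    ``hz100_long``   950 ms at 100 Hz.
    ``pairs``        two 150 ms 300 Hz trains separated by ``delta`` seconds of rest.
    ``conditioning`` 5 s of 100 Hz, then a 150 ms 300 Hz train, ``delta`` s rest,
                     and a second 150 ms 300 Hz train.
    """
    if name == "rest300":
        return StimulusProtocol(_train(start, 300.0, 45), (("300Hz", start),),
                                segment_length)
    if name in ("jump500", "jump750"):
        t100 = 0.5 if name == "jump500" else 0.75
        n100 = int(round(t100 * 100))
        aps = np.concatenate([_train(start, 100.0, n100),
                              _train(start + t100, 300.0, 60)])
        return StimulusProtocol(aps, (("100Hz", start), ("300Hz", start + t100)),
                                segment_length)
    if name == "hz100_long":
        return StimulusProtocol(_train(start, 100.0, 95), (("100Hz", start),),
                                segment_length)
    if name == "pairs":
        first = _train(start, 300.0, 45)
        t2 = start + 0.15 + delta
        aps = np.concatenate([first, _train(t2, 300.0, 45)])
        return StimulusProtocol(aps, (("300Hz", start), ("rest", start + 0.15),
                                      ("300Hz", t2)), segment_length)
    if name == "conditioning":
        cond = _train(start, 100.0, 500)
        t1 = start + 5.0
        t2 = t1 + 0.15 + delta
        aps = np.concatenate([cond, _train(t1, 300.0, 45), _train(t2, 300.0, 45)])
        return StimulusProtocol(aps, (("100Hz", start), ("300Hz", t1),
                                      ("rest", t1 + 0.15), ("300Hz", t2)),
                                segment_length)
    raise ProtocolError(f"unknown protocol name: {name!r}")


PROTOCOL_NAMES = ("rest300", "jump500", "jump750", "hz100_long", "pairs", "conditioning")
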