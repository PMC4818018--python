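"""Delimited-text and YAML interchange for traces, segment series and configs."""

from __future__ import annotations

import numpy as np
import yaml

from .engine import AlphaSchedule
from .errors import RRPKineticsError
from .protocols import StimulusProtocol, make_protocol
from .synth import SiteClassSpec, SynthParams
from .traces import SegmentSeries, Trace


def write_trace(path, trace: Trace) -> None:
    """Two-column text: time_s, current_nA."""
    header = (f"time_s\tcurrent_nA\n# sample_period_s={trace.sample_period!r} "
              f"t0={trace.t0!r}")
    np.savetxt(path, np.column_stack([trace.times, trace.samples]),
               fmt="%.9g", delimiter="\t", header=header)


def read_trace(path) -> Trace:
    data = np.loadtxt(path, delimiter="\t")
    if data.ndim != 2 or data.shape[1] != 2:
        raise RRPKineticsError(f"{path}: expected two columns (time_s, current_nA)")
    t, i = data[:, 0], data[:, 1]
    dt = float(np.median(np.diff(t)))
    return Trace(sample_period=dt, samples=i, t0=float(t[0]))


def write_segments(path, series: SegmentSeries) -> None:
    np.savetxt(path,
               np.column_stack([np.arange(series.n_segments), series.t_start,
                                series.charges, series.ap_counts]),
               fmt=("%d", "%.9g", "%.9g", "%d"), delimiter="\t",
               header=f"segment_index\tt_start_s\tcharge_pC\tn_aps\n"
                      f"# segment_length_s={series.segment_length!r}")


def read_segments(path) -> SegmentSeries:
    seg_len = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "segment_length_s=" in line:
                seg_len = float(line.split("segment_length_s=")[1])
            if not line.startswith("#"):
                break
    data = np.loadtxt(path, delimiter="\t")
    if seg_len is None:
        seg_len = float(np.median(np.diff(data[:, 1])))
    return SegmentSeries(segment_length=seg_len, charges=data[:, 2],
                         t_start=data[:, 1], ap_counts=data[:, 3].astype(int))


# ---------------------------------------------------------------------------
# configuration


def schedule_to_dict(s: AlphaSchedule) -> dict:
    d = {"mode": s.mode}
    if s.mode == "fixed":
        d["alpha_fixed"] = s.alpha_fixed
    elif s.mode == "accelerating":
        d.update(alpha_max=s.alpha_max, tau_ap=s.tau_ap, fatigue_rate=s.fatigue_rate)
    elif s.mode == "rest_decay":
        d.update(alpha_max=s.alpha_max, w=s.w, tau_f=s.tau_f, tau_s=s.tau_s,
                 alpha_inf=s.alpha_inf)
    else:
        d["table"] = np.asarray(s.table).tolist()
    return d


def schedule_from_dict(d: dict) -> AlphaSchedule:
    d = dict(d)
    if "table" in d:
        d["table"] = np.asarray(d["table"], dtype=float)
    return AlphaSchedule(**d)


def params_to_dict(p: SynthParams) -> dict:
    return {
        "n_sites": p.n_sites,
        "alpha_schedule": schedule_to_dict(p.alpha_schedule),
        "site_classes": [
            {"fraction": c.fraction, "pv_baseline": c.pv_baseline,
             "facilitation_increment": c.facilitation_increment,
             "facilitation_decay": c.facilitation_decay,
             "maturation_rate": c.maturation_rate}
            for c in p.site_classes],
        "quantal_charge_fC": p.quantal_charge_fC,
        "kyn_scale": p.kyn_scale,
        "mepsc_rise_s": p.mepsc_rise_s,
        "mepsc_decay_s": p.mepsc_decay_s,
        "mepsc_charge_cv": p.mepsc_charge_cv,
        "noise_sd_nA": p.noise_sd_nA,
        "async_rate": p.async_rate,
        "priming_mode": p.priming_mode,
        "sample_rate_hz": p.sample_rate_hz,
        "artifact_amp_nA": p.artifact_amp_nA,
        "artifact_width_s": p.artifact_width_s,
        "seed": p.seed,
    }


def params_from_dict(d: dict) -> SynthParams:
    d = dict(d)
    if "alpha_schedule" in d:
        d["alpha_schedule"] = schedule_from_dict(d["alpha_schedule"])
    if "site_classes" in d:
        d["site_classes"] = tuple(SiteClassSpec(**c) for c in d["site_classes"])
    return SynthParams(**d)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = dict(cfg)
    if "params" in cfg:
        out["params"] = params_from_dict(cfg["params"])
    if "protocol" in cfg:
        pr = cfg["protocol"]
        if isinstance(pr, str):
            out["protocol"] = make_protocol(pr)
        elif "name" in pr:
            kw = {k: v for k, v in pr.items() if k != "name"}
            out["protocol"] = make_protocol(pr["name"], **kw)
        else:
            out["protocol"] = StimulusProtocol(
                np.asarray(pr["ap_times"], dtype=float),
                tuple(tuple(e) for e in pr.get("epochs", ())),
                pr.get("segment_length", 1.0 / 300.0))
    return out


def save_config(path, params: SynthParams, protocol_name: str, **analysis) -> None:
    cfg = {"params": params_to_dict(params), "protocol": protocol_name}
    cfg.update(analysis)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_report(path, report: dict) -> None:
    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v
    with open(path, "w") as fh:
        yaml.safe_dump(clean(report), fh, sort_keys=False)
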