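import numpy as np
import pytest

import rrpkinetics as rk


@pytest.fixture(scope="session")
def rest300():
    return rk.make_protocol("rest300")


@pytest.fixture(scope="session")
def jump500():
    return rk.make_protocol("jump500")


@pytest.fixture(scope="session")
def hz100():
    return rk.make_protocol("hz100_long")


def single_class_params(alpha, pv=0.12, n_sites=2553, **kw):
    """One-class generator with a fixed (or given) recruitment schedule."""
    schedule = alpha if isinstance(alpha, rk.AlphaSchedule) else rk.fixed_schedule(alpha)
    return rk.SynthParams(n_sites=n_sites, alpha_schedule=schedule,
                          site_classes=(rk.SiteClassSpec(1.0, pv),), **kw)


def series_from_record(rec, params, protocol):
    """Ground-truth segment series straight from a release record (no rendering)."""
    return rk.SegmentSeries(protocol.segment_length, rec.segment_charges(params),
                            protocol.segment_starts(), protocol.ap_counts_per_segment())


def mean_field_series(params, protocol):
    return series_from_record(rk.mean_field(params, protocol), params, protocol)


@pytest.fixture(scope="session")
def geometric_series(rest300):
    """Pure depletion (alpha = 0, p_v = 0.2): exhausts within the train."""
    params = single_class_params(0.0, pv=0.2)
    return mean_field_series(params, rest300), params
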