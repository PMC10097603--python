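"""Shared fixtures: one modest synthetic night reused across the unit suite.

The 600-s night is long enough to contain several sleep cycles, a few
dominance switches and ~10,000 SNs, while keeping the default test run fast;
module-specific micro-fixtures (analytic signals, constructed traces) live
in the test files that use them.
"""
from __future__ import annotations

import numpy as np
import pytest

import clasp
from clasp import preprocess as pre

NIGHT_SEED = 7
NIGHT_DURATION_S = 600.0


@pytest.fixture(scope="session")
def night():
    """(recording, truth) for the default 600-s synthetic night."""
    cfg = clasp.GeneratorConfig(duration_s=NIGHT_DURATION_S, seed=NIGHT_SEED)
    rec, truth = clasp.generate_night(cfg)
    clasp.generate_spikes(truth, cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def conditioned(night):
    """Conditioned left/right claustrum signals of the shared night."""
    _, rec, _ = night
    return (pre.condition(rec, clasp.CLA_L), pre.condition(rec, clasp.CLA_R))


@pytest.fixture(scope="session")
def detection(night, conditioned):
    """(events, candidates) per side for the shared night."""
    sig_l, sig_r = conditioned
    ev_l, cand_l = clasp.detect_sns(sig_l, channel=clasp.CLA_L)
    ev_r, cand_r = clasp.detect_sns(sig_r, channel=clasp.CLA_R)
    return {"L": (ev_l, cand_l), "R": (ev_r, cand_r)}


@pytest.fixture(scope="session")
def episodes(night, conditioned):
    """Sleep segmentation of the shared night (adaptive threshold)."""
    cfg, _, _ = night
    sig_l, _ = conditioned
    beta = pre.band_power(sig_l)
    return clasp.segment_sleep(beta, pct="otsu", span=(0.0, cfg.duration_s))


def flat_signal(n=20000, rate=1000.0):
    v = np.zeros(n)
    return pre.ConditionedSignal(v=v, c=np.zeros(n), c2=np.zeros(n),
                                 rate_hz=rate)


def signal_from_trace(v, rate=1000.0, scale_uv=1.0):
    """Build a ConditionedSignal directly from a voltage trace (no filter)."""
    dt_ms = 1000.0 / rate
    c = np.gradient(v, dt_ms)
    return pre.ConditionedSignal(v=v, c=c, c2=np.gradient(c, dt_ms),
                                 rate_hz=rate, scale_uv=scale_uv)
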