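"""Sliding lagged cross-correlation, peak-lag distributions and the
instantaneous-leadership score.

The leadership score at lag L (here +-20 ms by default) is

    s_L(t) = log10[ sum_{tau=-w/2}^{+w/2} [c0(t+tau)]^- x [c1(t+tau+L)]^- ]

where c0 and c1 are the first derivatives of the two conditioned channels,
[x]^- clips to the non-positive part, and w is a 10-s window.  Products of
clipped derivatives are non-negative, so the sum is non-negative and the
base-10 logarithm (floored at a tiny epsilon for empty windows) is well
defined.  s_plus (c1 delayed) is large when channel 0 leads; s_minus when
channel 1 leads.  Dominance states are linear thresholds on the two scores
with short detours (< 3 s) defragmented away.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import ConditionedSignal
from .runs import defragment, runs_from_labels


@dataclass
class LaggedXCorr:
    """Cross-correlation matrix over (window center time, lag)."""

    t: np.ndarray           # window-center times, s
    lags_ms: np.ndarray     # symmetric lag grid
    m: np.ndarray           # (n_t, n_lags), normalized
    norm_value: float       # the 99.9th-percentile normalizer

    def peak_lags(self) -> tuple[np.ndarray, np.ndarray]:
        """(argmax lag per window, peak correlation value per window)."""
        k = np.argmax(self.m, axis=1)
        return self.lags_ms[k], self.m[np.arange(len(k)), k]


@dataclass
class PeakLagDistribution:
    """Histogram of per-window peak-correlation lags after filtering."""

    lags_kept_ms: np.ndarray
    bin_centers_ms: np.ndarray
    hist: np.ndarray
    modes_ms: list          # mode lags, strongest first
    median_lag_ms: float
    median_abs_lag_ms: float


@dataclass
class LeadershipTrace:
    """The s+ / s- score traces and (optionally) dominance labels."""

    t: np.ndarray
    s_plus: np.ndarray
    s_minus: np.ndarray
    state: np.ndarray | None = None   # SW | L | R | unsettled per time point
    params: dict = field(default_factory=dict)


def lagged_xcorr(sig0: ConditionedSignal, sig1: ConditionedSignal,
                 window_s: float = 10.0, step_s: float = 0.1,
                 lag_window_ms: float = 51.0,
                 norm_pct: float = 99.9) -> LaggedXCorr:
    """Sliding lagged cross-correlation of the first derivatives.

    Positive lag means channel 0 leads (its activity occurs earlier).  The
    matrix is normalized to its ``norm_pct`` percentile, so re-normalizing is
    idempotent.
    """
    if len(sig0) != len(sig1):
        raise ValueError("signals must have equal length")
    n = len(sig0)
    rate = sig0.rate_hz
    win = int(round(window_s * rate))
    if n < win:
        raise ValueError("signals shorter than the correlation window")
    step = int(round(step_s * rate))
    max_lag = int(round(lag_window_ms * rate / 1000.0))
    lags = np.arange(-max_lag, max_lag + 1)
    half = win // 2
    c_lo = half + max_lag
    c_hi = n - half - max_lag
    if c_hi <= c_lo:
        raise ValueError("signals too short for the lag window")
    centers = np.arange(c_lo, c_hi, step)
    c0, c1 = sig0.c, sig1.c
    m = np.empty((centers.size, lags.size), dtype=np.float32)
    prod = np.empty(n)
    for k, lag in enumerate(lags):
        prod[:] = 0.0
        if lag >= 0:
            prod[: n - lag] = c0[: n - lag] * c1[lag:]
        else:
            prod[-lag:] = c0[-lag:] * c1[: n + lag]
        cs = np.concatenate([[0.0], np.cumsum(prod)])
        m[:, k] = (cs[centers + half] - cs[centers - half]) / win
    norm = float(np.percentile(m, norm_pct))
    if norm > 0:
        m /= norm
    t = sig0.t0 + centers / rate
    return LaggedXCorr(t=t, lags_ms=lags * 1000.0 / rate, m=m,
                       norm_value=norm)


def peak_lag_distribution(xc: LaggedXCorr, keep_quantile: float = 0.75,
                          bin_ms: float = 1.0) -> PeakLagDistribution:
    """Distribution of per-window argmax lags over high-correlation windows.

    Windows whose peak correlation falls below the ``keep_quantile`` quantile
    of peak values are dropped (isolating periods of high correlation), as
    are windows peaking at the extreme lags of the grid (finite-exploration
    boundary artifacts).
    """
    peak_lag, peak_val = xc.peak_lags()
    thr = np.quantile(peak_val, keep_quantile)
    lag_max = np.max(np.abs(xc.lags_ms))
    keep = (peak_val >= thr) & (np.abs(peak_lag) < lag_max)
    kept = peak_lag[keep]
    if kept.size == 0:
        warnings.warn("all windows filtered out of the peak-lag distribution",
                      stacklevel=2)
        return PeakLagDistribution(kept, np.empty(0), np.empty(0, dtype=int),
                                   [], np.nan, np.nan)
    edges = np.arange(-lag_max + bin_ms / 2, lag_max + bin_ms / 2, bin_ms)
    hist, _ = np.histogram(kept, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    pk, props = sps.find_peaks(smooth, prominence=0.05 * smooth.max())
    if pk.size == 0:
        pk = np.array([int(np.argmax(smooth))])
        heights = smooth[pk]
    else:
        heights = smooth[pk]
    order = np.argsort(heights)[::-1]
    modes = [float(centers[pk[i]]) for i in order]
    return PeakLagDistribution(
        lags_kept_ms=kept, bin_centers_ms=centers, hist=hist, modes_ms=modes,
        median_lag_ms=float(np.median(kept)),
        median_abs_lag_ms=float(np.median(np.abs(kept))),
    )


def bimodal_modes(dist: PeakLagDistribution) -> tuple[float, float] | None:
    """The strongest negative-lag and positive-lag modes, if both exist."""
    neg = [m for m in dist.modes_ms if m < 0]
    pos = [m for m in dist.modes_ms if m > 0]
    if not neg or not pos:
        return None
    return neg[0], pos[0]


def leadership_score(sig0: ConditionedSignal, sig1: ConditionedSignal,
                     lag_ms: float = 20.0, window_s: float = 10.0,
                     step_s: float = 0.1,
                     floor_eps: float = 1e-12) -> LeadershipTrace:
    """The s+-lag instantaneous-leadership score traces.

    Implements the windowed sum of products of negative-clipped first
    derivatives at +lag (``s_plus``, channel 0 leads) and -lag (``s_minus``),
    floored at ``floor_eps`` before taking log10.
    """
    if len(sig0) != len(sig1):
        raise ValueError("signals must have equal length")
    n = len(sig0)
    rate = sig0.rate_hz
    win = int(round(window_s * rate))
    if n < win:
        raise ValueError("signals shorter than the score window")
    step = int(round(step_s * rate))
    lag = int(round(lag_ms * rate / 1000.0))
    half = win // 2
    c0 = np.minimum(sig0.c, 0.0)
    c1 = np.minimum(sig1.c, 0.0)

    def windowed(lag_signed: int) -> np.ndarray:
        prod = np.zeros(n)
        if lag_signed >= 0:
            prod[: n - lag_signed] = c0[: n - lag_signed] * c1[lag_signed:]
        else:
            prod[-lag_signed:] = c0[-lag_signed:] * c1[: n + lag_signed]
        cs = np.concatenate([[0.0], np.cumsum(prod)])
        return cs[centers + half] - cs[centers - half]

    c_lo = half + lag
    c_hi = n - half - lag
    if c_hi <= c_lo:
        raise ValueError("signals too short for the lag")
    centers = np.arange(c_lo, c_hi, step)
    s_plus = np.log10(np.maximum(windowed(lag), floor_eps))
    s_minus = np.log10(np.maximum(windowed(-lag), floor_eps))
    t = sig0.t0 + centers / rate
    return LeadershipTrace(
        t=t, s_plus=s_plus, s_minus=s_minus, state=None,
        params={"lag_ms": lag_ms, "window_s": window_s, "step_s": step_s,
                "floor_eps": floor_eps},
    )


def calibrate_thresholds(trace: LeadershipTrace, episodes: pd.DataFrame,
                         depth: float = 0.3) -> tuple[float, float]:
    """Per-side dominance thresholds from the night's own score clusters.

    Each side's threshold is placed ``depth`` of the way (in log10 units)
    from that side's dominant-score cluster (REM_P windows where it beats
    the other side) down toward its non-dominant cluster (windows where it
    loses).  Two points matter: (1) the non-dominant score sits well above
    the SW floor - event trains are quasi-periodic near twice the bilateral
    lag, so the "wrong" lag still picks up partial alignment - so thresholds
    must be referenced to the two REM_P clusters, not to SW; (2) at a
    dominance switch the two scores cross smoothly over one window length,
    so a threshold exactly at the crossing level would leave no interval in
    which neither side is established; placing it closer to the dominant
    cluster recovers the unsettled interlude around each switch.  If one
    side never dominates (unilateral lesion), its clusters are taken from
    the other side by mirror symmetry of the score definition.
    """
    in_rem = _in_state_mask(trace.t, episodes, "REM_P")
    if in_rem.sum() == 0 or (~in_rem).sum() == 0:
        raise ValueError("need both SW and REM_P time to calibrate thresholds")
    pairs = []
    for s_own, s_other in ((trace.s_plus, trace.s_minus),
                           (trace.s_minus, trace.s_plus)):
        dom = in_rem & (s_own > s_other)
        sub = in_rem & ~dom
        if dom.sum() < max(1, 0.01 * in_rem.sum()):
            pairs.append(None)  # this side never dominates (lesion)
            continue
        dom_c = float(np.median(s_own[dom]))
        # when one side dominates throughout, its own non-dominant sample is
        # empty; the losing channel's score in the same windows is the
        # mirror-symmetric estimate of that cluster
        sub_c = (float(np.median(s_own[sub])) if sub.sum() >= 1
                 else float(np.median(s_other[dom])))
        pairs.append((dom_c, sub_c))
    if pairs[0] is None and pairs[1] is None:
        raise ValueError("no dominant cluster on either side")
    out = []
    for i in range(2):
        dom_c, sub_c = pairs[i] if pairs[i] is not None else pairs[1 - i]
        out.append(dom_c - depth * (dom_c - sub_c))
    return out[0], out[1]


def _in_state_mask(t: np.ndarray, episodes: pd.DataFrame,
                   state: str) -> np.ndarray:
    mask = np.zeros(t.size, dtype=bool)
    for ep in episodes[episodes.state == state].itertuples():
        mask |= (t >= ep.start_s) & (t < ep.end_s)
    return mask


def segment_dominance(trace: LeadershipTrace, thr_plus: float,
                      thr_minus: float, min_dur_s: float = 3.0,
                      episodes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Label dominance states and cut them into segments.

    A time point is ``L`` when only s_plus exceeds its threshold, ``R`` when
    only s_minus does, and ``unsettled`` when both or neither do.  Outside
    REM_P episodes (when an episode table is given) the label is ``SW``.
    Detours shorter than ``min_dur_s`` are merged into their surroundings,
    independently inside each REM_P episode.  Returns segments
    (state, start_s, end_s) tiling each REM_P episode; the per-point labels
    are stored on ``trace.state``.
    """
    if not np.isfinite(thr_plus) or not np.isfinite(thr_minus):
        raise ValueError("dominance thresholds must be finite")
    t = trace.t
    above_p = trace.s_plus > thr_plus
    above_m = trace.s_minus > thr_minus
    raw = np.where(above_p & ~above_m, "L",
                   np.where(above_m & ~above_p, "R", "unsettled"))
    step = float(np.median(np.diff(t))) if t.size > 1 else min_dur_s
    min_run = max(int(round(min_dur_s / step)), 1)
    state = np.full(t.size, "SW", dtype=object)
    segments = []
    if episodes is None:
        episodes = pd.DataFrame(
            [{"state": "REM_P", "start_s": t[0], "end_s": t[-1] + step}]
        )
    for ep in episodes[episodes.state == "REM_P"].itertuples():
        sel = np.flatnonzero((t >= ep.start_s) & (t < ep.end_s))
        if sel.size == 0:
            continue
        lab = defragment(raw[sel].copy(), min_run)
        state[sel] = lab
        for a, b, lbl in runs_from_labels(lab):
            lo = ep.start_s if a == 0 else 0.5 * (t[sel[a - 1]] + t[sel[a]])
            hi = ep.end_s if b == sel.size else 0.5 * (t[sel[b - 1]] + t[sel[b]])
            segments.append({"side": lbl, "start_s": lo, "end_s": hi})
    trace.state = state
    return pd.DataFrame(segments, columns=["side", "start_s", "end_s"])
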