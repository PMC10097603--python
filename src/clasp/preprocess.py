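"""Clock synchronization, conditioning, band power and event-rate traces.

The conditioning chain is shared by every downstream stage: resample to a
1-kHz working rate, zero-phase low-pass at 40 Hz, z-score, and take first and
second derivatives by central differences.  Zero-phase filtering matters
because event *times* feed a +-20 ms lag analysis; a causal filter's group
delay would bias every lag estimate.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .recording import SYNC, Recording


class SyncError(RuntimeError):
    """Raised when the common square-wave reference cannot align recordings."""


@dataclass
class ConditionedSignal:
    """Low-passed, (optionally) z-scored voltage with its derivatives.

    ``v`` is the conditioned trace; ``c`` and ``c2`` its first and second
    central-difference derivatives, per millisecond.  ``scale_uv`` is the
    standard deviation (microvolts) removed by z-scoring, so event amplitudes
    can be reported back in physical units.
    """

    v: np.ndarray
    c: np.ndarray
    c2: np.ndarray
    rate_hz: float
    t0: float = 0.0
    scale_uv: float = 1.0
    filter_desc: str = ""

    def __len__(self) -> int:
        return len(self.v)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.v)) / self.rate_hz

    def index_of(self, t: float) -> int:
        return int(round((t - self.t0) * self.rate_hz))

    def slice(self, i0: int, i1: int) -> "ConditionedSignal":
        """View of samples [i0, i1) with an adjusted time origin."""
        return ConditionedSignal(
            v=self.v[i0:i1], c=self.c[i0:i1], c2=self.c2[i0:i1],
            rate_hz=self.rate_hz, t0=self.t0 + i0 / self.rate_hz,
            scale_uv=self.scale_uv, filter_desc=self.filter_desc,
        )

    def inverted(self) -> "ConditionedSignal":
        return ConditionedSignal(
            v=-self.v, c=-self.c, c2=-self.c2, rate_hz=self.rate_hz,
            t0=self.t0, scale_uv=self.scale_uv, filter_desc=self.filter_desc,
        )


@dataclass
class BandPowerTrace:
    """Sliding-window band power: window centers ``t`` (s) and power ``p``."""

    t: np.ndarray
    p: np.ndarray
    band_hz: tuple = (12.0, 30.0)
    window_s: float = 10.0
    step_s: float = 1.0


# --------------------------------------------------------------------- sync

def sync_edges(rec: Recording, sync_role: str = SYNC) -> np.ndarray:
    """Rising-edge times (s) of the synchronization square wave.

    Edges are located by half-amplitude threshold crossings with linear
    sub-sample interpolation.
    """
    x = rec.channel(sync_role)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise SyncError("sync channel is constant")
    thr = 0.5 * (lo + hi)
    above = x > thr
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size < 2:
        raise SyncError(f"need >=2 sync edges, found {idx.size}")
    frac = (thr - x[idx]) / (x[idx + 1] - x[idx])
    return rec.t0 + (idx + frac) / rec.rate_hz


def synchronize(recordings: list[Recording], sync_role: str = SYNC
                ) -> tuple[list[Recording], list[dict]]:
    """Resample all recordings onto the first recording's clock.

    Each recording's time axis is warped by piecewise-linear interpolation so
    that its sync edges coincide with the reference's, then all channels are
    re-sampled on the reference sample grid.  Returns the aligned recordings
    and per-recording diagnostics (edge count, drift estimate, residual edge
    misalignment after mapping, which is zero by construction at the edges).
    """
    ref = recordings[0]
    ref_edges = sync_edges(ref, sync_role)
    ref_times = ref.times()
    out = [ref]
    diags = [{"n_edges": len(ref_edges), "drift_ppm": 0.0, "residual_s": 0.0}]
    for rec in recordings[1:]:
        edges = sync_edges(rec, sync_role)
        n = min(len(edges), len(ref_edges))
        e, re_ = edges[:n], ref_edges[:n]
        if np.any(np.diff(e) <= 0) or np.any(np.diff(re_) <= 0):
            raise SyncError("non-monotonic sync edge sequence")
        # map this recording's clock onto the reference clock
        t_own = rec.times()
        t_mapped = np.interp(t_own, e, re_)
        # linear extrapolation outside the edge span
        rate0 = (re_[-1] - re_[0]) / (e[-1] - e[0])
        head = t_own < e[0]
        tail = t_own > e[-1]
        t_mapped[head] = re_[0] + (t_own[head] - e[0]) * rate0
        t_mapped[tail] = re_[-1] + (t_own[tail] - e[-1]) * rate0
        data = np.vstack([
            np.interp(ref_times, t_mapped, ch) for ch in rec.data
        ])
        out.append(Recording(data=data, rate_hz=ref.rate_hz,
                             channel_roles=list(rec.channel_roles),
                             t0=ref.t0))
        drift = (rate0 - 1.0) * 1e6
        resid = float(np.max(np.abs(np.interp(e, e, re_) - re_)))
        diags.append({"n_edges": n, "drift_ppm": drift, "residual_s": resid})
    return out, diags


# -------------------------------------------------------------- condition

def condition(rec: Recording, channel: str, working_rate_hz: float = 1000.0,
              lp_hz: float = 40.0, zscore: bool = True) -> ConditionedSignal:
    """Downsample, zero-phase low-pass and z-score one channel.

    The filter is an order-4 Butterworth applied forward-backward
    (zero net phase), so extremum times survive conditioning.
    """
    if rec.rate_hz < 2.0 * lp_hz:
        raise ValueError(
            f"rate {rec.rate_hz} Hz too low for a {lp_hz} Hz low-pass"
        )
    x = np.asarray(rec.channel(channel), dtype=np.float64)
    if rec.rate_hz != working_rate_hz:
        frac = Fraction(working_rate_hz / rec.rate_hz).limit_denominator(10000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    sos = sps.butter(4, lp_hz, btype="low", fs=working_rate_hz, output="sos")
    v = sps.sosfiltfilt(sos, x)
    scale = float(np.std(v))
    if zscore:
        if scale == 0:
            v = v - np.mean(v)
        else:
            v = (v - np.mean(v)) / scale
    dt_ms = 1000.0 / working_rate_hz
    c = np.gradient(v, dt_ms)
    c2 = np.gradient(c, dt_ms)
    return ConditionedSignal(
        v=v, c=c, c2=c2, rate_hz=working_rate_hz, t0=rec.t0,
        scale_uv=scale if zscore else 1.0,
        filter_desc=f"butter4 low-pass {lp_hz} Hz, zero-phase, "
                    f"{'z-scored' if zscore else 'raw'}",
    )


# -------------------------------------------------------------- band power

def _windowed_mean(x: np.ndarray, win: int, step: int) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(x)])
    starts = np.arange(0, len(x) - win + 1, step)
    return (cs[starts + win] - cs[starts]) / win


def band_power(sig: ConditionedSignal, band_hz: tuple = (12.0, 30.0),
               window_s: float = 10.0, step_s: float = 1.0) -> BandPowerTrace:
    """Sliding mean-square amplitude of the band-passed signal.

    Band-pass is a zero-phase order-4 Butterworth; power is the windowed mean
    of the squared band signal, reported at window centers.
    """
    n = len(sig.v)
    win = int(round(window_s * sig.rate_hz))
    step = int(round(step_s * sig.rate_hz))
    if n < win:
        raise ValueError("signal shorter than the analysis window")
    sos = sps.butter(4, band_hz, btype="bandpass", fs=sig.rate_hz,
                     output="sos")
    y = sps.sosfiltfilt(sos, sig.v)
    p = _windowed_mean(y * y, win, step)
    centers = sig.t0 + (np.arange(len(p)) * step + win / 2.0) / sig.rate_hz
    return BandPowerTrace(t=centers, p=p, band_hz=tuple(band_hz),
                          window_s=window_s, step_s=step_s)


def sn_rate(event_times: np.ndarray, span: tuple[float, float],
            window_s: float = 10.0, step_s: float = 1.0) -> BandPowerTrace:
    """Scrolling event rate (events/s) on the band-power grid.

    ``span`` is the (start, end) of the analyzed record in seconds so that the
    trace aligns with :func:`band_power` output for the same record.
    """
    t0, t1 = span
    ts = np.sort(np.asarray(event_times, dtype=float))
    centers = np.arange(t0 + window_s / 2.0, t1 - window_s / 2.0 + 1e-9,
                        step_s)
    lo = np.searchsorted(ts, centers - window_s / 2.0)
    hi = np.searchsorted(ts, centers + window_s / 2.0)
    rate = (hi - lo) / window_s
    return BandPowerTrace(t=centers, p=rate, band_hz=(np.nan, np.nan),
                          window_s=window_s, step_s=step_s)
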