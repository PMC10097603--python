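"""Sharp-negative (SN) event detection by derivative triplet peaks.

A candidate SN is a triplet of peaks on the conditioned signal: a negative
second-derivative peak (start of the downward phase), a negative
first-derivative peak (steepest descent) and a positive second-derivative
peak (end of the downward phase).  False positives are controlled by a
sign-flip null: running the same detector on the inverted signal, where true
SNs cannot exist, yields the joint (amplitude, duration) noise sample from
which minimum acceptance thresholds are drawn.

Detection is deterministic and scale-covariant: multiplying the signal by a
positive constant scales amplitudes and leaves times and durations unchanged
(the peak-prominence floor is relative to the derivative's standard
deviation).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import ConditionedSignal

EVENT_COLUMNS = ["t_start", "t_steep", "t_end", "amplitude_uv",
                 "amplitude", "duration_ms", "p_null", "channel"]


_MIN_EVENTS_PER_BIN = 50


@dataclass
class NoiseModel:
    """Empirical joint (amplitude, duration) sample of inverted detections.

    The null probability of a candidate is the tail probability of its
    amplitude on the noise amplitude CDF *conditioned on its duration*
    (duration-binned CDFs): noise "events" on slow ramps grow in amplitude
    with their span, so a fixed-duration slice is the fair comparison - a
    true sharp event is extreme for its duration.  This realizes
    duration-dependent minimum amplitude thresholds.
    """

    amplitudes: np.ndarray    # sorted marginal, conditioned units
    durations_ms: np.ndarray  # sorted marginal
    n_noise_events: int
    dur_bin_edges: np.ndarray = None  # interior edges between duration bins
    bin_amps: list = None             # sorted amplitude sample per bin

    def sf_amplitude(self, a: np.ndarray) -> np.ndarray:
        """Marginal survival P(noise amplitude >= a)."""
        if self.n_noise_events == 0:
            return np.zeros_like(np.asarray(a, dtype=float))
        k = np.searchsorted(self.amplitudes, a, side="left")
        return (self.n_noise_events - k) / self.n_noise_events

    def sf_duration(self, d: np.ndarray) -> np.ndarray:
        """Marginal survival P(noise duration >= d)."""
        if self.n_noise_events == 0:
            return np.zeros_like(np.asarray(d, dtype=float))
        k = np.searchsorted(self.durations_ms, d, side="left")
        return (self.n_noise_events - k) / self.n_noise_events

    def p_null(self, amplitude: np.ndarray, duration_ms: np.ndarray
               ) -> np.ndarray:
        """Conditional amplitude tail probability given duration."""
        a = np.asarray(amplitude, dtype=float)
        d = np.asarray(duration_ms, dtype=float)
        if self.n_noise_events == 0:
            return np.zeros_like(a)
        if self.dur_bin_edges is None or not len(self.bin_amps):
            return self.sf_amplitude(a)
        which = np.searchsorted(self.dur_bin_edges, d, side="right")
        out = np.empty_like(a)
        for b, amps in enumerate(self.bin_amps):
            sel = which == b
            if sel.any():
                k = np.searchsorted(amps, a[sel], side="left")
                out[sel] = (len(amps) - k) / len(amps)
        return out

    @classmethod
    def from_sample(cls, amplitudes: np.ndarray, durations_ms: np.ndarray
                    ) -> "NoiseModel":
        amps = np.asarray(amplitudes, dtype=float)
        durs = np.asarray(durations_ms, dtype=float)
        n = len(amps)
        model = cls(amplitudes=np.sort(amps), durations_ms=np.sort(durs),
                    n_noise_events=n)
        n_bins = max(1, min(10, n // _MIN_EVENTS_PER_BIN))
        if n and n_bins > 1:
            qs = np.linspace(0, 1, n_bins + 1)[1:-1]
            edges = np.unique(np.quantile(durs, qs))
            which = np.searchsorted(edges, durs, side="right")
            model.dur_bin_edges = edges
            model.bin_amps = [np.sort(amps[which == b])
                              for b in range(len(edges) + 1)]
        else:
            model.dur_bin_edges = None
            model.bin_amps = []
        return model


def detect_triplets(sig: ConditionedSignal, prominence_floor: float = 0.5,
                    max_gap_ms: float = 100.0, channel: str = "",
                    steepness_floor: float = 1.0,
                    c2_prominence_floor: float | None = None) -> pd.DataFrame:
    """Find candidate SNs as ordered derivative-peak triplets.

    ``prominence_floor`` scales the minimal peak prominence on the first and
    second derivatives relative to their standard deviations, suppressing
    numerical micro-peaks.  ``steepness_floor`` additionally requires the
    steepest-descent peak to reach that many standard deviations of the first
    derivative: a genuinely sharp event descends faster than the slow
    recovery ramps and baseline wander that surround it, so the height of
    the descent peak - not just its prominence - is part of what "sharp"
    means.  Both criteria are relative, keeping detection covariant under
    signal rescaling.  Each negative first-derivative peak is paired with
    the nearest preceding negative and nearest following positive
    second-derivative peak within ``max_gap_ms``; when two steepest-descent
    peaks resolve to the same outer pair, the steeper one wins.

    Returns a time-sorted DataFrame with columns ``t_start``, ``t_steep``,
    ``t_end`` (s), ``amplitude`` (conditioned units), ``amplitude_uv``,
    ``duration_ms`` and ``channel``; ``p_null`` is NaN until a noise model is
    applied.
    """
    c, c2, v = sig.c, sig.c2, sig.v
    sd_c = float(np.std(c))
    sd_c2 = float(np.std(c2))
    empty = pd.DataFrame(columns=EVENT_COLUMNS)
    if sd_c == 0 or sd_c2 == 0:
        return empty
    steep_idx, _ = sps.find_peaks(
        -c, prominence=prominence_floor * sd_c,
        height=steepness_floor * sd_c)
    c2_floor = (prominence_floor if c2_prominence_floor is None
                else c2_prominence_floor) * sd_c2
    neg2_idx, _ = sps.find_peaks(-c2, prominence=c2_floor)
    pos2_idx, _ = sps.find_peaks(c2, prominence=c2_floor)
    if steep_idx.size == 0 or neg2_idx.size == 0 or pos2_idx.size == 0:
        return empty

    max_gap = int(round(max_gap_ms * sig.rate_hz / 1000.0))
    # nearest preceding negative-c2 peak
    k_prev = np.searchsorted(neg2_idx, steep_idx, side="right") - 1
    # nearest following positive-c2 peak
    k_next = np.searchsorted(pos2_idx, steep_idx, side="left")
    ok = (k_prev >= 0) & (k_next < pos2_idx.size)
    steep = steep_idx[ok]
    start = neg2_idx[k_prev[ok]]
    end = pos2_idx[k_next[ok]]
    ok2 = ((steep - start) <= max_gap) & ((end - steep) <= max_gap) \
        & (start < steep) & (steep < end)
    steep, start, end = steep[ok2], start[ok2], end[ok2]
    if steep.size == 0:
        return empty

    df = pd.DataFrame({
        "start": start, "steep": steep, "end": end,
        "steepness": -c[steep],
    })
    # unresolvable overlaps (same outer pair) keep the steeper candidate
    df = (df.sort_values("steepness", ascending=False)
            .drop_duplicates(["start", "end"])
            .sort_values("steep"))
    start = df["start"].to_numpy()
    steep = df["steep"].to_numpy()
    end = df["end"].to_numpy()
    amp = v[start] - v[end]
    keep = amp > 0
    start, steep, end, amp = start[keep], steep[keep], end[keep], amp[keep]
    rate = sig.rate_hz
    # sub-sample refinement of the steepest-descent time by parabolic
    # interpolation around the derivative peak (standard peak interpolation;
    # sharpens inter-event intervals and bilateral lag estimates)
    frac = np.zeros_like(amp)
    inner = (steep > 0) & (steep < len(c) - 1)
    y0, y1, y2 = -c[steep - 1], -c[steep], -c[steep + 1]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 0.5 * (y0 - y2) / denom
    frac[inner] = np.clip(np.nan_to_num(f[inner]), -0.5, 0.5)
    out = pd.DataFrame({
        "t_start": sig.t0 + start / rate,
        "t_steep": sig.t0 + (steep + frac) / rate,
        "t_end": sig.t0 + end / rate,
        "amplitude_uv": amp * sig.scale_uv,
        "amplitude": amp,
        "duration_ms": (end - start) * 1000.0 / rate,
        "p_null": np.nan,
        "channel": channel,
    })
    return out.reset_index(drop=True)


def estimate_noise(sig: ConditionedSignal, prominence_floor: float = 0.5,
                   max_gap_ms: float = 100.0,
                   steepness_floor: float = 1.0) -> NoiseModel:
    """Sign-flip null: detect "events" on the inverted signal.

    Sharp positive deflections do not exist in claustrum sleep LFP, so
    anything the triplet detector finds on ``-v`` is noise; its (amplitude,
    duration) sample calibrates the acceptance thresholds.
    """
    cands = detect_triplets(sig.inverted(), prominence_floor, max_gap_ms,
                            steepness_floor=steepness_floor)
    if len(cands) == 0:
        warnings.warn("no noise events detected; degenerate noise model "
                      "keeps all candidates", stacklevel=2)
    return NoiseModel.from_sample(cands["amplitude"].to_numpy(),
                                  cands["duration_ms"].to_numpy())


def filter_candidates(candidates: pd.DataFrame, noise: NoiseModel,
                      alpha: float = 0.025) -> pd.DataFrame:
    """Keep candidates in the extreme tail of the noise CDF.

    A candidate passes when its amplitude lies beyond the (1 - alpha) tail of
    the noise amplitude CDF *at its duration* (duration-binned noise CDFs:
    minimum amplitude thresholds that rise with duration, because slow noise
    ramps accumulate amplitude over their span).  ``p_null`` records the
    conditional tail probability, so acceptance is exactly
    ``p_null < alpha``.

    The input frame is returned in full with ``p_null`` populated plus a
    boolean ``kept`` column; downstream stages that want only accepted events
    filter on it (see :func:`detect_sns`).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    out = candidates.copy()
    if len(out) == 0:
        out["kept"] = pd.Series(dtype=bool)
        return out
    if noise.n_noise_events == 0:
        out["p_null"] = 0.0
        out["kept"] = True
        return out
    out["p_null"] = noise.p_null(out["amplitude"].to_numpy(),
                                 out["duration_ms"].to_numpy())
    out["kept"] = out["p_null"] < alpha
    return out


def detect_sns(sig: ConditionedSignal, alpha: float = 0.025,
               prominence_floor: float = 0.5, chunk_s: float = 3600.0,
               channel: str = "",
               steepness_floor: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full detection pass in consecutive sections (default 1 h).

    The noise model is estimated per section, so slow drifts in noise
    statistics do not leak across the night.  Returns ``(events,
    candidates)``: the accepted SN set (p_null < alpha) and the complete
    candidate pool with p_null populated, which the bilateral matching stage
    consumes.
    """
    n = len(sig)
    chunk = int(round(chunk_s * sig.rate_hz))
    pieces = []
    for i0 in range(0, n, chunk):
        part = sig.slice(i0, min(i0 + chunk, n))
        if len(part) < 10:
            continue
        cands = detect_triplets(part, prominence_floor, channel=channel,
                                steepness_floor=steepness_floor)
        noise = estimate_noise(part, prominence_floor,
                               steepness_floor=steepness_floor)
        pieces.append(filter_candidates(cands, noise, alpha))
    if not pieces:
        cols = EVENT_COLUMNS + ["kept"]
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=cols)
    candidates = pd.concat(pieces, ignore_index=True)
    events = candidates[candidates.kept].reset_index(drop=True)
    return events, candidates


# ----------------------------------------------------------------- statistics

def iei_stats(event_times: np.ndarray, episodes: pd.DataFrame | None = None,
              bin_ms: float = 5.0, max_ms: float = 150.0) -> dict:
    """Inter-event-interval summary for one channel.

    When an episode table is given, only events inside REM_P episodes count,
    and intervals never span an episode boundary.  The histogram is truncated
    at ``max_ms`` (display parity with how IEI distributions are usually
    shown); the median and quartiles use all intervals.  Histogram bins are
    centered on multiples of ``bin_ms``, and the mode is the center of the
    argmax bin after a three-bin moving average - a plateau-robust estimator
    (the IEI density is flat-topped near its mode, so the raw argmax bin is a
    coin flip among adjacent bins).
    """
    ts = np.sort(np.asarray(event_times, dtype=float))
    if episodes is not None:
        rem = episodes[episodes.state == "REM_P"]
        ieis = []
        for _, ep in rem.iterrows():
            seg = ts[(ts >= ep.start_s) & (ts < ep.end_s)]
            if len(seg) >= 2:
                ieis.append(np.diff(seg))
        ieis = np.concatenate(ieis) * 1000.0 if ieis else np.empty(0)
    else:
        if len(ts) < 2:
            raise ValueError("need at least two events")
        ieis = np.diff(ts) * 1000.0
    if len(ieis) == 0:
        raise ValueError("no inter-event intervals in REM_P episodes")
    edges = np.arange(-bin_ms / 2.0, max_ms + bin_ms, bin_ms)
    hist, _ = np.histogram(ieis, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if hist.sum():
        smooth = np.convolve(hist, np.array([0.25, 0.5, 0.25]), mode="same")
        mode_ms = float(centers[np.argmax(smooth)])
    else:
        mode_ms = np.nan
    return {
        "n": int(len(ieis)),
        "median_ms": float(np.median(ieis)),
        "mode_ms": mode_ms,
        "q25_ms": float(np.percentile(ieis, 25)),
        "q75_ms": float(np.percentile(ieis, 75)),
        "hist": hist,
        "bin_centers_ms": centers,
        "ieis_ms": ieis,
    }


def spike_sn_alignment(spike_trains: dict, t_steep: np.ndarray,
                       window_ms: float = 50.0,
                       count_window_ms: float = 10.0) -> dict:
    """Per-unit spike-time histograms around SN steepest descent.

    For every SN, spikes within +-``window_ms`` of ``t_steep`` enter the lag
    histogram; per-SN firing probabilities P(>=1 spike) and P(>1 spike) count
    spikes within +-``count_window_ms``.
    """
    ts = np.sort(np.asarray(t_steep, dtype=float))
    out = {}
    w = window_ms / 1000.0
    cw = count_window_ms / 1000.0
    edges = np.arange(-window_ms, window_ms + 2.0, 2.0)
    for unit, spikes in spike_trains.items():
        sp = np.sort(np.asarray(spikes, dtype=float))
        if ts.size == 0:
            out[unit] = {"hist": np.zeros(len(edges) - 1, dtype=int),
                         "bin_centers_ms": 0.5 * (edges[:-1] + edges[1:]),
                         "p_ge1": 0.0, "p_gt1": 0.0}
            continue
        lags = []
        lo = np.searchsorted(sp, ts - w)
        hi = np.searchsorted(sp, ts + w)
        for t, a, b in zip(ts, lo, hi):
            if b > a:
                lags.append((sp[a:b] - t) * 1000.0)
        lags = np.concatenate(lags) if lags else np.empty(0)
        hist, _ = np.histogram(lags, bins=edges)
        n1 = np.searchsorted(sp, ts + cw) - np.searchsorted(sp, ts - cw)
        out[unit] = {
            "hist": hist,
            "bin_centers_ms": 0.5 * (edges[:-1] + edges[1:]),
            "p_ge1": float(np.mean(n1 >= 1)),
            "p_gt1": float(np.mean(n1 > 1)),
        }
    return out
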