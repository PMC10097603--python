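"""Sleep-state segmentation and episode-level statistics.

REM_P/SW segmentation thresholds the beta-band (12-30 Hz) power trace:
windows above threshold are REM_P, below are SW, and state detours shorter
than 15 s are merged away.  The threshold is either a fixed percentile of the
trace (the classical rule) or, by default in the pipeline, chosen per night
by two-class variance maximization (Otsu) on the log-power histogram - which
amounts to picking the percentile that matches the night's actual SW
fraction (see docs/methods.md for why a fixed percentile cannot).

Episode statistics count dominance switches (left<->right transitions,
ignoring unsettled interludes), per-state time fractions, and the night-level
aggregates used to compare control and lesioned nights.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage.filters import threshold_otsu

from .preprocess import BandPowerTrace
from .runs import defragment, runs_from_labels

EPISODE_COLUMNS = ["state", "start_s", "end_s", "n_switches", "time_left_s",
                   "time_right_s", "time_unsettled_s",
                   "leading_side_majority"]


def segment_sleep(beta: BandPowerTrace, pct: float | str = 15.0,
                  min_dur_s: float = 15.0,
                  span: tuple[float, float] | None = None) -> pd.DataFrame:
    """Cut the night into SW / REM_P episodes from the beta-power trace.

    ``pct`` is the percentile of the trace used as threshold (beta power
    above it is REM_P); the string ``"otsu"`` selects the threshold by Otsu's
    method on log10 power instead.  Runs shorter than ``min_dur_s`` are
    merged into their surroundings.  ``span`` optionally extends the outer
    episodes to the full analyzed interval (the trace itself starts and ends
    half a window in).
    """
    p = np.asarray(beta.p, dtype=float)
    t = np.asarray(beta.t, dtype=float)
    if p.size < 2:
        raise ValueError("beta trace too short to segment")
    if float(np.max(p)) == float(np.min(p)):
        raise ValueError("constant beta-power trace: threshold is degenerate")
    if isinstance(pct, str):
        if pct != "otsu":
            raise ValueError(f"unknown threshold rule {pct!r}")
        logp = np.log10(p + 1e-30)
        thr = 10.0 ** float(threshold_otsu(logp, nbins=256))
        # refine to the midpoint of the two class medians: windowed power is
        # linear in episode overlap, so the arithmetic midpoint crosses at
        # the center of each boundary ramp (unbiased episode edges)
        lo_med = float(np.median(p[p <= thr]))
        hi_med = float(np.median(p[p > thr]))
        thr = 0.5 * (lo_med + hi_med)
    else:
        thr = float(np.percentile(p, pct))
    labels = np.where(p > thr, "REM_P", "SW").astype(object)
    step = float(np.median(np.diff(t)))
    min_run = max(int(round(min_dur_s / step)), 1)
    labels = defragment(labels, min_run)
    lo_span, hi_span = span if span is not None else (
        t[0] - beta.window_s / 2.0, t[-1] + beta.window_s / 2.0
    )
    rows = []
    for a, b, lbl in runs_from_labels(labels):
        lo = lo_span if a == 0 else 0.5 * (t[a - 1] + t[a])
        hi = hi_span if b == labels.size else 0.5 * (t[b - 1] + t[b])
        rows.append({"state": lbl, "start_s": lo, "end_s": hi})
    return pd.DataFrame(rows, columns=["state", "start_s", "end_s"])


def count_switches(sides: list[str]) -> int:
    """Left<->right transitions in a dominance-segment sequence.

    Unsettled interludes are ignored: L, unsettled, L is zero switches;
    L, unsettled, R is one.
    """
    lr = [s for s in sides if s in ("L", "R")]
    return int(sum(a != b for a, b in zip(lr[:-1], lr[1:])))


def episode_stats(episodes: pd.DataFrame, dominance: pd.DataFrame
                  ) -> tuple[pd.DataFrame, dict]:
    """Per-episode dominance accounting and night-level summaries.

    For every REM_P episode: the time spent left-dominant, right-dominant and
    unsettled, the switch count, and the majority side.  Night summaries
    report the mean duration of 0-switch and 1-switch episodes (excluding
    episodes cut off by the edges of the analyzed span), the mean unsettled
    time per switching episode, per-cycle leading fractions, and total times.
    """
    eps = episodes.sort_values("start_s").reset_index(drop=True).copy()
    for col in ("n_switches", "time_left_s", "time_right_s",
                "time_unsettled_s"):
        eps[col] = 0.0
    eps["leading_side_majority"] = ""
    span_lo = float(eps.start_s.min())
    span_hi = float(eps.end_s.max())
    for i, ep in eps.iterrows():
        if ep.state != "REM_P":
            continue
        inside = dominance[
            (dominance.end_s > ep.start_s) & (dominance.start_s < ep.end_s)
        ].sort_values("start_s")
        if len(inside) == 0:
            raise ValueError(
                f"no dominance segments for REM_P episode at {ep.start_s:.1f} s"
            )
        overlap = (np.minimum(inside.end_s, ep.end_s)
                   - np.maximum(inside.start_s, ep.start_s))
        for side, key in (("L", "time_left_s"), ("R", "time_right_s"),
                          ("unsettled", "time_unsettled_s")):
            eps.at[i, key] = float(overlap[inside.side == side].sum())
        eps.at[i, "n_switches"] = count_switches(list(inside.side))
        tl, tr = eps.at[i, "time_left_s"], eps.at[i, "time_right_s"]
        eps.at[i, "leading_side_majority"] = "L" if tl >= tr else "R"
    eps["n_switches"] = eps["n_switches"].astype(int)

    rem = eps[eps.state == "REM_P"].copy()
    rem["duration_s"] = rem.end_s - rem.start_s
    interior = rem[(rem.start_s > span_lo + 1e-9)
                   & (rem.end_s < span_hi - 1e-9)]
    d0 = interior.loc[interior.n_switches == 0, "duration_s"]
    d1 = interior.loc[interior.n_switches == 1, "duration_s"]
    switching = rem[rem.n_switches >= 1]
    summary = {
        "n_remp_episodes": int(len(rem)),
        "mean_duration_0switch_s": float(d0.mean()) if len(d0) else np.nan,
        "mean_duration_1switch_s": float(d1.mean()) if len(d1) else np.nan,
        "n_0switch": int(len(d0)),
        "n_1switch": int(len(d1)),
        "mean_remp_duration_s": float(interior.duration_s.mean())
        if len(interior) else np.nan,
        "mean_unsettled_per_switching_episode_s":
            float(switching.time_unsettled_s.mean()) if len(switching)
            else np.nan,
        "switch_count_distribution":
            rem.n_switches.value_counts().sort_index().to_dict(),
        "total_remp_s": float(rem.duration_s.sum()),
        "total_sw_s": float(
            (eps.loc[eps.state == "SW", "end_s"]
             - eps.loc[eps.state == "SW", "start_s"]).sum()
        ),
        "fraction_left_per_episode": (
            rem.time_left_s / rem.duration_s).round(6).tolist(),
        "fraction_right_per_episode": (
            rem.time_right_s / rem.duration_s).round(6).tolist(),
    }
    return eps[EPISODE_COLUMNS], summary


def amplitude_lag_stats(pairs: pd.DataFrame, how: str = "median"
                        ) -> dict:
    """Side-normalized amplitude difference versus lag sign, with rank test.

    Each side's amplitudes are normalized by that side's night median (or
    z-scored when ``how="zscore"``); delta = normalized left - normalized
    right.  The two groups (left-leads: lag > 0; right-leads: lag < 0) are
    compared with a two-sided Mann-Whitney U test.
    """
    acc = pairs[pairs.accepted] if "accepted" in pairs else pairs
    if len(acc) == 0:
        raise ValueError("no accepted pairs")
    al = acc["amp_left"].to_numpy(dtype=float)
    ar = acc["amp_right"].to_numpy(dtype=float)
    if how == "median":
        nl = al / np.median(al)
        nr = ar / np.median(ar)
    elif how == "zscore":
        nl = (al - al.mean()) / al.std()
        nr = (ar - ar.mean()) / ar.std()
    else:
        raise ValueError("how must be 'median' or 'zscore'")
    delta = nl - nr
    lag = acc["lag_ms"].to_numpy(dtype=float)
    left_leads = delta[lag > 0]
    right_leads = delta[lag < 0]
    if len(left_leads) < 2 or len(right_leads) < 2:
        raise ValueError("need >=2 pairs in each lag-sign group")
    u, p = sstats.mannwhitneyu(left_leads, right_leads,
                               alternative="two-sided")
    return {
        "delta": delta, "lag_ms": lag,
        "mean_delta_left_leads": float(np.mean(left_leads)),
        "mean_delta_right_leads": float(np.mean(right_leads)),
        "mannwhitney_u": float(u), "p_value": float(p),
        "n_left_leads": int(len(left_leads)),
        "n_right_leads": int(len(right_leads)),
    }


def welch_ttest(durations_a: np.ndarray, durations_b: np.ndarray
                ) -> tuple[float, float]:
    """Welch's two-sided t-test; t < 0 when group b has the larger mean."""
    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 samples per group")
    res = sstats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def signed_rank(values: np.ndarray, alternative: str = "greater"
                ) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test on per-night values."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >=2 samples")
    res = sstats.wilcoxon(v, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
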