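"""Scoring of analysis output against generator ground truth.

These helpers close the loop between the synthetic-night generator and the
analysis stages: event-level recall/precision, recovery of bilateral pairs,
and dominance-segmentation agreement.  They are used by the test suite and
the acceptance script, and are handy when tuning detector settings on
simulated data.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import GroundTruth


def _nearest(sorted_arr: np.ndarray, t: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Index of and distance to the nearest element of ``sorted_arr``."""
    t = np.atleast_1d(t)
    if sorted_arr.size == 0:
        return np.full(t.shape, -1), np.full(t.shape, np.inf)
    i = np.searchsorted(sorted_arr, t)
    lo = np.clip(i - 1, 0, sorted_arr.size - 1)
    hi = np.clip(i, 0, sorted_arr.size - 1)
    pick_hi = np.abs(sorted_arr[hi] - t) < np.abs(sorted_arr[lo] - t)
    j = np.where(pick_hi, hi, lo)
    return j, np.abs(sorted_arr[j] - t)


def detection_scores(events: pd.DataFrame, truth: GroundTruth, side: str,
                     tol_ms: float = 5.0) -> dict:
    """Recall and precision of detected SNs against the truth registry."""
    tol = tol_ms / 1000.0
    det_t = np.sort(events["t_steep"].to_numpy())
    tru_t = np.sort(truth.sn.loc[truth.sn.side == side, "t_steep"].to_numpy())
    _, d_rec = _nearest(det_t, tru_t)
    _, d_pre = _nearest(tru_t, det_t)
    return {
        "recall": float(np.mean(d_rec < tol)) if tru_t.size else np.nan,
        "precision": float(np.mean(d_pre < tol)) if det_t.size else np.nan,
        "n_detected": int(det_t.size),
        "n_truth": int(tru_t.size),
    }


def pair_recovery_rate(events_l: pd.DataFrame, events_r: pd.DataFrame,
                       pairs: pd.DataFrame, truth: GroundTruth,
                       top_quantile: float = 0.95,
                       tol_ms: float = 5.0) -> dict:
    """Fraction of clearly detectable SNs recovered in correct-lag pairs.

    Units are detected SNs in the top ``1 - top_quantile`` of the pooled
    amplitude distribution whose truth event belongs to a bilateral pair;
    each is scored as recovered when it appears in an accepted pair whose
    lag matches the truth lag within ``tol_ms``.
    """
    tol = tol_ms / 1000.0
    amp_pool = np.concatenate([events_l["amplitude_uv"].to_numpy(),
                               events_r["amplitude_uv"].to_numpy()])
    thr = np.quantile(amp_pool, top_quantile)
    acc = pairs[pairs["accepted"]] if "accepted" in pairs else pairs
    acc_l = acc["t_left"].to_numpy()
    acc_r = acc["t_right"].to_numpy()
    order = np.argsort(acc_l)
    acc_l, acc_r = acc_l[order], acc_r[order]
    order_r = np.argsort(acc_r)
    acc_r_sorted = acc_r[order_r]
    acc_l_by_r = acc_l[order_r]

    n_units = 0
    n_recovered = 0
    for side, events, own_times, partner_times in (
        ("L", events_l, acc_l, acc_r),
        ("R", events_r, acc_r_sorted, acc_l_by_r),
    ):
        tru = truth.sn[truth.sn.side == side]
        paired = tru[tru.pair_id >= 0]
        tru_t = paired["t_steep"].to_numpy()
        pair_ids = paired["pair_id"].to_numpy()
        lag_by_pair = truth.pairs.set_index("pair_id")["lag_ms"]
        big = events[events["amplitude_uv"] >= thr]
        det_t = big["t_steep"].to_numpy()
        if det_t.size == 0:
            continue
        j, d = _nearest(np.sort(tru_t), det_t)
        tru_sorted = np.sort(tru_t)
        sort_idx = np.argsort(tru_t)
        for k in range(det_t.size):
            if d[k] >= tol:
                continue  # detected event has no paired truth partner
            n_units += 1
            pid = pair_ids[sort_idx[j[k]]]
            true_lag_s = lag_by_pair.loc[pid] / 1000.0
            jj, dd = _nearest(own_times, det_t[k])
            if jj < 0 or dd >= tol:
                continue
            got_lag = partner_times[jj] - own_times[jj]
            if side == "R":
                got_lag = -got_lag
            # lag convention: t_right - t_left, seen from the left event
            if side == "L" and abs(got_lag - true_lag_s) < tol:
                n_recovered += 1
            elif side == "R" and abs(-got_lag - -true_lag_s) < tol:
                n_recovered += 1
    return {
        "rate": n_recovered / n_units if n_units else np.nan,
        "n_units": n_units,
        "n_recovered": n_recovered,
        "amplitude_threshold_uv": float(thr),
    }


def switch_recovery(dominance_detected: pd.DataFrame, truth: GroundTruth,
                    tol_s: float = 2.0) -> dict:
    """Fraction of true dominance-switch boundaries recovered within tol.

    A truth switch is the midpoint of each unsettled interlude (or the
    boundary between two opposite dominance segments); it counts as
    recovered when the detected segmentation changes sides within ``tol_s``.
    """
    tru_switches = _switch_times(truth.dominance)
    det_switches = _switch_times(dominance_detected)
    if len(tru_switches) == 0:
        return {"rate": np.nan, "n_switches": 0, "n_recovered": 0}
    det_sorted = np.sort(det_switches)
    _, d = _nearest(det_sorted, np.asarray(tru_switches))
    hits = int(np.sum(d < tol_s)) if det_sorted.size else 0
    return {"rate": hits / len(tru_switches),
            "n_switches": len(tru_switches), "n_recovered": hits}


def _switch_times(dominance: pd.DataFrame) -> list[float]:
    """Midpoints of within-episode left<->right transitions.

    A jump across an episode gap (consecutive dominance segments separated
    by slow-wave time) is not a switch.
    """
    out = []
    segs = dominance[dominance.side.isin(["L", "R", "unsettled"])] \
        .sort_values("start_s")
    prev_side = None       # side of the last L/R segment in this episode
    last_lr_end = None     # its end time
    prev_end = None        # end of the last segment of any kind
    for seg in segs.itertuples():
        if prev_end is not None and seg.start_s - prev_end > 1.0:
            prev_side = None  # episode boundary: reset
            last_lr_end = None
        if seg.side in ("L", "R"):
            if prev_side is not None and seg.side != prev_side:
                out.append(0.5 * (last_lr_end + seg.start_s))
            prev_side = seg.side
            last_lr_end = float(seg.end_s)
        prev_end = float(seg.end_s)
    return out
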