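"""Optimal one-to-one bilateral matching of candidate SNs.

Each feasible left/right pair (|lag| within the lag window) is scored by the
local cross-correlation of the negative-clipped first derivatives in a 100-ms
window centered between the two events, evaluated at the pair's lag and
weighted by an exponential lag kernel exp(-|lag|/tau).  The globally optimal
one-to-one combination (events may stay unmatched) is then found by solving a
linear assignment problem on each connected component of the candidate graph;
since scores are non-negative and unmatched events contribute zero, solving
the dense rectangular assignment per component and discarding zero-score
assignments is exactly the constrained optimum.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import MatchParams
from .preprocess import ConditionedSignal

PAIR_COLUMNS = ["left_idx", "right_idx", "t_left", "t_right", "lag_ms",
                "score", "p_null_left", "p_null_right", "accepted"]


def score_pairs(left_t: np.ndarray, right_t: np.ndarray,
                sig_left: ConditionedSignal, sig_right: ConditionedSignal,
                params: MatchParams | None = None) -> pd.DataFrame:
    """Score every (left, right) candidate pair within the lag window.

    ``left_t``/``right_t`` are steepest-descent times in seconds.  Lag is
    ``t_right - t_left`` in ms (positive = left leads).  Scores are
    non-negative by construction (products of negative-clipped derivatives).
    """
    params = params or MatchParams()
    lt = np.asarray(left_t, dtype=float)
    rt = np.asarray(right_t, dtype=float)
    if lt.size == 0 or rt.size == 0:
        return pd.DataFrame(columns=["li", "rj", "lag_ms", "score"])
    rate = sig_left.rate_hz
    lag_win_s = params.lag_window_ms / 1000.0
    # feasible pairs via sorted search
    lo = np.searchsorted(rt, lt - lag_win_s)
    hi = np.searchsorted(rt, lt + lag_win_s)
    li = np.repeat(np.arange(lt.size), hi - lo)
    rj = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) \
        if li.size else np.empty(0, dtype=int)
    if li.size == 0:
        return pd.DataFrame(columns=["li", "rj", "lag_ms", "score"])
    tl, tr = lt[li], rt[rj]
    lag_ms = (tr - tl) * 1000.0
    lag_smp = np.round((tr - tl) * rate).astype(int)
    center = np.round(((tl + tr) / 2.0 - sig_left.t0) * rate).astype(int)

    cl = np.minimum(sig_left.c, 0.0)
    cr = np.minimum(sig_right.c, 0.0)
    half = int(round(params.xcorr_window_ms / 2.0 * rate / 1000.0))
    n = len(cl)
    offsets = np.arange(-half, half + 1)
    scores = np.empty(li.size)
    batch = 4096
    for b0 in range(0, li.size, batch):
        b1 = min(b0 + batch, li.size)
        idx0 = center[b0:b1, None] + offsets[None, :]
        idx1 = idx0 + lag_smp[b0:b1, None]
        valid = (idx0 >= 0) & (idx0 < n) & (idx1 >= 0) & (idx1 < n)
        i0 = np.clip(idx0, 0, n - 1)
        i1 = np.clip(idx1, 0, n - 1)
        prod = cl[i0] * cr[i1] * valid
        scores[b0:b1] = prod.sum(axis=1) / (2 * half + 1)
    scores *= np.exp(-np.abs(lag_ms) / params.kernel_tau_ms)
    return pd.DataFrame({"li": li, "rj": rj, "lag_ms": lag_ms,
                         "score": scores})


def match_pairs(scored: pd.DataFrame) -> pd.DataFrame:
    """Globally optimal one-to-one assignment maximizing the total score.

    Operates on the output of :func:`score_pairs`.  Pairs with non-positive
    score never match; events may remain unmatched.  The candidate graph is
    split into connected components and each component is solved exactly as a
    rectangular linear assignment problem.
    """
    pos = scored[scored.score > 0]
    if len(pos) == 0:
        return pd.DataFrame(columns=["li", "rj", "lag_ms", "score"])
    left_ids = pos.li.to_numpy()
    right_ids = pos.rj.to_numpy()
    # union-find over left (even keys) and right (odd keys) nodes
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for li, rj in zip(left_ids, right_ids):
        union(2 * int(li), 2 * int(rj) + 1)
    comp_of_edge = np.fromiter(
        (find(2 * int(li)) for li in left_ids), dtype=int, count=len(left_ids)
    )
    rows = []
    pos = pos.assign(_comp=comp_of_edge)
    for _, grp in pos.groupby("_comp", sort=False):
        ls = np.unique(grp.li.to_numpy())
        rs = np.unique(grp.rj.to_numpy())
        mat = np.zeros((ls.size, rs.size))
        lpos = {v: i for i, v in enumerate(ls)}
        rpos = {v: i for i, v in enumerate(rs)}
        for e in grp.itertuples():
            mat[lpos[e.li], rpos[e.rj]] = max(
                mat[lpos[e.li], rpos[e.rj]], e.score
            )
        ri, ci = linear_sum_assignment(mat, maximize=True)
        for i, j in zip(ri, ci):
            if mat[i, j] > 0:
                sel = grp[(grp.li == ls[i]) & (grp.rj == rs[j])]
                best = sel.loc[sel.score.idxmax()]
                rows.append({"li": int(ls[i]), "rj": int(rs[j]),
                             "lag_ms": float(best.lag_ms),
                             "score": float(best.score)})
    out = pd.DataFrame(rows, columns=["li", "rj", "lag_ms", "score"])
    return out.sort_values(["li", "rj"]).reset_index(drop=True)


def accept_pairs(pairs: pd.DataFrame, p_null_left: np.ndarray,
                 p_null_right: np.ndarray, alpha: float = 0.05
                 ) -> pd.DataFrame:
    """Flag pairs whose better partner beats the noise null at ``alpha``.

    A pair is accepted when at least one of its two events has null
    probability below ``alpha``.  Rejected pairs are retained (flagged
    ``accepted=False``) for audit.
    """
    out = pairs.copy()
    if len(out) == 0:
        out["p_null_left"] = out["p_null_right"] = pd.Series(dtype=float)
        out["accepted"] = pd.Series(dtype=bool)
        return out
    pl = np.asarray(p_null_left, dtype=float)[out.li.to_numpy()]
    pr = np.asarray(p_null_right, dtype=float)[out.rj.to_numpy()]
    if np.any(np.isnan(pl)) or np.any(np.isnan(pr)):
        raise ValueError("p_null missing on events; run filter_candidates first")
    out["p_null_left"] = pl
    out["p_null_right"] = pr
    out["accepted"] = np.minimum(pl, pr) < alpha
    return out


def match_bilateral(cand_left: pd.DataFrame, cand_right: pd.DataFrame,
                    sig_left: ConditionedSignal, sig_right: ConditionedSignal,
                    params: MatchParams | None = None,
                    alpha_pair: float = 0.05) -> pd.DataFrame:
    """Score, match and accept bilateral SN pairs in 1-h sections.

    ``cand_left``/``cand_right`` are candidate tables from the detection
    stage (p_null populated).  Sections are cut on the midpoint time of each
    pair, mirroring the chunked detection.  Returns a pair table with event
    row indices into the candidate tables, lag (ms, positive = left leads),
    score, per-side null probabilities and the ``accepted`` flag.
    """
    params = params or MatchParams()
    lt = cand_left["t_steep"].to_numpy()
    rt = cand_right["t_steep"].to_numpy()
    scored = score_pairs(lt, rt, sig_left, sig_right, params)
    if len(scored) == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    chunk_s = params.chunk_hours * 3600.0
    mid = (lt[scored.li.to_numpy()] + rt[scored.rj.to_numpy()]) / 2.0
    section = np.floor((mid - sig_left.t0) / chunk_s).astype(int)
    matched = []
    for _, grp in scored.assign(_sec=section).groupby("_sec", sort=True):
        matched.append(match_pairs(grp.drop(columns="_sec")))
    pairs = pd.concat(matched, ignore_index=True)
    # an event matched in two sections (possible at a boundary) keeps its
    # higher-score pair
    pairs = (pairs.sort_values("score", ascending=False)
             .drop_duplicates("li").drop_duplicates("rj")
             .sort_values("li").reset_index(drop=True))
    pairs = accept_pairs(pairs, cand_left["p_null"].to_numpy(),
                         cand_right["p_null"].to_numpy(), alpha_pair)
    pairs = pairs.rename(columns={"li": "left_idx", "rj": "right_idx"})
    pairs["t_left"] = lt[pairs.left_idx.to_numpy()]
    pairs["t_right"] = rt[pairs.right_idx.to_numpy()]
    return pairs[PAIR_COLUMNS]
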