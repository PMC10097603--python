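"""Run-length utilities shared by the state-segmentation stages."""
from __future__ import annotations

import numpy as np


def runs_from_labels(labels: np.ndarray) -> list[tuple[int, int, object]]:
    """Contiguous runs as (start, stop, label) with stop exclusive."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.size]])
    return [(int(a), int(b), labels[a]) for a, b in zip(starts, stops)]


def defragment(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Merge runs shorter than ``min_run`` samples into their surroundings.

    Short detours that leave and re-enter a state are absorbed by it; a short
    run between two different states joins the longer neighbor.  Runs are
    merged shortest-first until every remaining run reaches ``min_run`` (a
    single surviving run is always legal).
    """
    labels = np.asarray(labels).copy()
    while True:
        runs = runs_from_labels(labels)
        if len(runs) <= 1:
            return labels
        short = [(b - a, i) for i, (a, b, _) in enumerate(runs)
                 if (b - a) < min_run]
        if not short:
            return labels
        _, i = min(short)
        a, b, _ = runs[i]
        if i == 0:
            labels[a:b] = runs[1][2]
        elif i == len(runs) - 1:
            labels[a:b] = runs[i - 1][2]
        else:
            prev_run, next_run = runs[i - 1], runs[i + 1]
            if prev_run[2] == next_run[2]:
                labels[a:b] = prev_run[2]
            else:
                longer = prev_run if (prev_run[1] - prev_run[0]) >= (
                    next_run[1] - next_run[0]) else next_run
                labels[a:b] = longer[2]
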