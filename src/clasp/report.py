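"""Summary figures for a finished run (SVG, headless backend)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def make_figures(prod: dict, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    iei = prod["iei"]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(iei["bin_centers_ms"], iei["hist"], width=4.5, color="0.3")
    ax.axvline(iei["median_ms"], color="r", lw=1,
               label=f"median {iei['median_ms']:.1f} ms")
    ax.set_xlabel("inter-event interval (ms)")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    fig.tight_layout()
    p = outdir / "iei_hist.svg"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    dist = prod["peak_lags"]
    if dist.bin_centers_ms.size:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(dist.bin_centers_ms, dist.hist, color="0.2")
        for m in dist.modes_ms[:2]:
            ax.axvline(m, color="r", ls="--", lw=1)
        ax.set_xlabel("peak-correlation lag (ms; + = left leads)")
        ax.set_ylabel("windows")
        fig.tight_layout()
        p = outdir / "peak_lag_hist.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    trace = prod["trace"]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.hist2d(trace.s_plus, trace.s_minus, bins=80, cmap="viridis")
    ax.set_xlabel("s$_{+}$ (left leads)")
    ax.set_ylabel("s$_{-}$ (right leads)")
    fig.tight_layout()
    p = outdir / "leadership_density.svg"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    ep = prod["episode_table"]
    rem = ep[ep.state == "REM_P"]
    if len(rem):
        dur = (rem.end_s - rem.start_s).to_numpy()
        fl = rem.time_left_s.to_numpy() / dur
        fr = rem.time_right_s.to_numpy() / dur
        fu = rem.time_unsettled_s.to_numpy() / dur
        x = np.arange(len(rem))
        fig, ax = plt.subplots(figsize=(6, 2.5))
        ax.bar(x, fl, color="tab:blue", label="left")
        ax.bar(x, fu, bottom=fl, color="gold", label="unsettled")
        ax.bar(x, fr, bottom=fl + fu, color="tab:red", label="right")
        ax.set_xlabel("REM$_P$ episode")
        ax.set_ylabel("fraction of time")
        ax.legend(frameon=False, fontsize=7)
        fig.tight_layout()
        p = outdir / "dominance_fractions.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    return written
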