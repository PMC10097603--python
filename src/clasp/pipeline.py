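"""End-to-end orchestration: simulate -> condition -> detect -> match ->
leadership -> segment -> statistics, under one config and one seed.

``run_all`` is deterministic: identical configurations (including the seed)
reproduce identical event tables.  Every table written to a run directory
carries the configuration hash so that outputs can always be traced to the
exact settings that produced them.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as det
from . import leadership as lead
from . import match as mat
from . import preprocess as pre
from . import sleep as slp
from . import synth
from .config import RunConfig
from .recording import CLA_L, CLA_R, IMC_L, IMC_R, Recording

log = logging.getLogger("clasp")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def analyze_recording(rec: Recording, cfg: RunConfig) -> dict:
    """Run every analysis stage on an existing recording.

    Returns a dict of intermediate and final products keyed by stage name;
    see :func:`run_all` for the full list.
    """
    out: dict = {"config": cfg}
    gen = cfg.generator
    try:
        sig_l = pre.condition(rec, CLA_L)
        sig_r = pre.condition(rec, CLA_R)
        out["sig_l"], out["sig_r"] = sig_l, sig_r
    except Exception as e:  # noqa: BLE001
        raise StageError("condition", str(e)) from e

    try:
        beta = pre.band_power(sig_l, band_hz=cfg.beta_band_hz,
                              window_s=cfg.window_s, step_s=1.0)
        episodes = slp.segment_sleep(beta, pct=cfg.beta_pct,
                                     min_dur_s=cfg.min_episode_s,
                                     span=(rec.t0, rec.t0 + rec.duration_s))
        out["beta"], out["episodes"] = beta, episodes
    except Exception as e:  # noqa: BLE001
        raise StageError("segment_sleep", str(e)) from e

    try:
        events_l, cand_l = det.detect_sns(
            sig_l, alpha=cfg.alpha_detect,
            prominence_floor=cfg.prominence_floor, channel=CLA_L)
        events_r, cand_r = det.detect_sns(
            sig_r, alpha=cfg.alpha_detect,
            prominence_floor=cfg.prominence_floor, channel=CLA_R)
        out.update(events_l=events_l, events_r=events_r,
                   cand_l=cand_l, cand_r=cand_r)
        out["iei"] = det.iei_stats(events_l["t_steep"].to_numpy(),
                                   episodes=episodes)
    except Exception as e:  # noqa: BLE001
        raise StageError("detect", str(e)) from e

    try:
        pairs = mat.match_bilateral(cand_l, cand_r, sig_l, sig_r,
                                    params=cfg.match,
                                    alpha_pair=cfg.alpha_pair)
        pairs["amp_left"] = cand_l["amplitude_uv"].to_numpy()[
            pairs.left_idx.to_numpy()] if len(pairs) else []
        pairs["amp_right"] = cand_r["amplitude_uv"].to_numpy()[
            pairs.right_idx.to_numpy()] if len(pairs) else []
        out["pairs"] = pairs
    except Exception as e:  # noqa: BLE001
        raise StageError("match", str(e)) from e

    try:
        xc = lead.lagged_xcorr(sig_l, sig_r, window_s=cfg.window_s,
                               step_s=cfg.xcorr_step_s,
                               lag_window_ms=cfg.match.lag_window_ms,
                               norm_pct=cfg.xcorr_norm_pct)
        dist = lead.peak_lag_distribution(xc, keep_quantile=cfg.keep_quantile)
        out["xcorr"], out["peak_lags"] = xc, dist
    except Exception as e:  # noqa: BLE001
        raise StageError("lagged_xcorr", str(e)) from e

    try:
        trace = lead.leadership_score(sig_l, sig_r, lag_ms=cfg.lag_ms,
                                      window_s=cfg.window_s,
                                      step_s=cfg.xcorr_step_s)
        if cfg.dominance_threshold_l is None or cfg.dominance_threshold_r is None:
            thr_l, thr_r = lead.calibrate_thresholds(trace, episodes)
        else:
            thr_l, thr_r = cfg.dominance_threshold_l, cfg.dominance_threshold_r
        dominance = lead.segment_dominance(trace, thr_l, thr_r,
                                           min_dur_s=cfg.min_dominance_s,
                                           episodes=episodes)
        out.update(trace=trace, thresholds=(thr_l, thr_r),
                   dominance=dominance)
    except Exception as e:  # noqa: BLE001
        raise StageError("leadership", str(e)) from e

    try:
        ep_full, summary = slp.episode_stats(episodes, dominance)
        out["episode_table"], out["episode_summary"] = ep_full, summary
    except Exception as e:  # noqa: BLE001
        raise StageError("episode_stats", str(e)) from e

    try:
        if len(pairs) and pairs.accepted.sum() >= 4:
            out["amp_lag"] = slp.amplitude_lag_stats(pairs)
        else:
            out["amp_lag"] = None
    except ValueError:
        out["amp_lag"] = None

    modes = lead.bimodal_modes(dist)
    out["unimodal_lag_distribution"] = modes is None
    out["summary"] = _night_summary(out, gen)
    return out


def _night_summary(prod: dict, gen) -> dict:
    iei = prod["iei"]
    dist = prod["peak_lags"]
    s = {
        "iei_median_ms": iei["median_ms"],
        "iei_mode_ms": iei["mode_ms"],
        "iei_q25_ms": iei["q25_ms"],
        "iei_q75_ms": iei["q75_ms"],
        "n_sn_left": int(len(prod["events_l"])),
        "n_sn_right": int(len(prod["events_r"])),
        "n_pairs_accepted": int(prod["pairs"].accepted.sum())
        if len(prod["pairs"]) else 0,
        "peak_lag_modes_ms": [float(m) for m in dist.modes_ms[:4]],
        "median_abs_peak_lag_ms": dist.median_abs_lag_ms,
        "unimodal_lag_distribution": bool(prod["unimodal_lag_distribution"]),
        "dominance_thresholds": [float(x) for x in prod["thresholds"]],
        "lesion_side": gen.lesion_side,
        **{k: v for k, v in prod["episode_summary"].items()
           if not isinstance(v, list)},
    }
    if prod["amp_lag"] is not None:
        s["amp_delta_left_leads"] = prod["amp_lag"]["mean_delta_left_leads"]
        s["amp_delta_right_leads"] = prod["amp_lag"]["mean_delta_right_leads"]
        s["amp_lag_mannwhitney_p"] = prod["amp_lag"]["p_value"]
    return s


def run_all(cfg: RunConfig, outdir: str | Path | None = None,
            write_figures: bool = False) -> dict:
    """Simulate one night and run the full analysis on it.

    The generator's seed is taken from the run seed so that one number
    reproduces the whole run.  When ``outdir`` is given, all artifacts
    (recording, truth, event tables, pair table, leadership trace, episode
    tables, summary JSON and the resolved config) are written there.
    """
    gen = cfg.generator
    gen.seed = cfg.seed
    log.info("simulating night: %.0f s, seed %d, lesion=%s",
             gen.duration_s, gen.seed, gen.lesion_side)
    rec, truth = synth.generate_night(gen)
    synth.generate_spikes(truth, gen)
    prod = analyze_recording(rec, cfg)
    prod.update(recording=rec, truth=truth)
    if outdir is not None:
        _write_run(Path(outdir), cfg, prod, write_figures)
    return prod


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_run(outdir: Path, cfg: RunConfig, prod: dict,
               write_figures: bool) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    cfg.to_yaml(outdir / "resolved_config.yaml")
    if "recording" in prod:
        prod["recording"].to_dir(outdir / "recording")
    if "truth" in prod:
        prod["truth"].to_dir(outdir / "truth")

    def save(df: pd.DataFrame, name: str) -> None:
        df = df.copy()
        df.attrs["config_hash"] = h
        with open(outdir / name, "w") as f:
            f.write(f"# config_hash={h}\n")
            df.round(6).to_csv(f, index=False)

    save(prod["events_l"], "sn_events_L.csv")
    save(prod["events_r"], "sn_events_R.csv")
    save(prod["cand_l"], "sn_candidates_L.csv")
    save(prod["cand_r"], "sn_candidates_R.csv")
    save(prod["pairs"], "sn_pairs.csv")
    save(prod["dominance"], "dominance_segments.csv")
    save(prod["episode_table"], "episodes.csv")
    trace = prod["trace"]
    save(pd.DataFrame({"t": trace.t, "s_plus": trace.s_plus,
                       "s_minus": trace.s_minus,
                       "state": trace.state}), "leadership.csv")
    xc = prod["xcorr"]
    try:
        import h5py
        with h5py.File(outdir / "xcorr.h5", "w") as f:
            f.create_dataset("t", data=xc.t)
            f.create_dataset("lags_ms", data=xc.lags_ms)
            f.create_dataset("m", data=xc.m, compression="gzip")
            f.attrs["norm_value"] = xc.norm_value
            f.attrs["config_hash"] = h
    except ImportError:
        np.savez_compressed(outdir / "xcorr.npz", t=xc.t, lags_ms=xc.lags_ms,
                            m=xc.m, norm_value=xc.norm_value)
    summary = dict(prod["summary"])
    summary["config_hash"] = h
    (outdir / "night_summary.json").write_text(
        json.dumps(summary, indent=1, default=_json_default)
    )
    if write_figures:
        from . import report
        report.make_figures(prod, outdir / "figures")


def conditioned_imc(rec: Recording, side: str) -> "pre.ConditionedSignal":
    """Condition an Imc channel (convenience for the three-site lag analysis)."""
    role = IMC_L if side == "L" else IMC_R
    return pre.condition(rec, role)
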