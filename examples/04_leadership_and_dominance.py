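"""Lag structure, instantaneous leadership and dominance segmentation.

The sliding lagged cross-correlation of the two claustrum derivatives peaks
at +-20 ms (whichever side currently leads); the s+-20 leadership scores
turn that into a per-instant left/right/unsettled state, and episode
statistics count how often dominance switches within an episode.
"""
import clasp
from clasp import leadership as lead
from clasp import preprocess as pre

cfg = clasp.GeneratorConfig(duration_s=1800.0, seed=2)
rec, truth = clasp.generate_night(cfg)

sig_l = pre.condition(rec, clasp.CLA_L)
sig_r = pre.condition(rec, clasp.CLA_R)
beta = pre.band_power(sig_l)
episodes = clasp.segment_sleep(beta, pct="otsu", span=(0.0, cfg.duration_s))

xc = lead.lagged_xcorr(sig_l, sig_r)
dist = lead.peak_lag_distribution(xc)
print(f"peak-correlation lag modes: "
      f"{[round(m, 1) for m in dist.modes_ms[:2]]} ms "
      f"(positive = left leads)")

trace = lead.leadership_score(sig_l, sig_r, lag_ms=20.0)
thr_l, thr_r = lead.calibrate_thresholds(trace, episodes)
dominance = lead.segment_dominance(trace, thr_l, thr_r, episodes=episodes)
table, summary = clasp.episode_stats(episodes, dominance)

print(f"dominance thresholds: ({thr_l:.2f}, {thr_r:.2f}) log10 units")
print(f"REM_P episodes: {summary['n_remp_episodes']}, switch counts "
      f"{summary['switch_count_distribution']}")
print(f"mean duration: {summary['mean_duration_0switch_s']:.1f} s without "
      f"a switch vs {summary['mean_duration_1switch_s']:.1f} s with one")
print(f"unsettled time per switching episode: "
      f"{summary['mean_unsettled_per_switching_episode_s']:.1f} s")
# Episodes containing a dominance switch run markedly longer (~90 s vs
# ~60 s), and only a few seconds around each switch lack a settled leader.
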