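"""Detect sharp negative events and recover their interval statistics.

Conditioning (1 kHz, zero-phase 40-Hz low-pass, z-score) is followed by
derivative-triplet detection with a sign-flip noise null: the same detector
runs on the inverted signal, where sharp positive events do not exist, and
candidates must beat the resulting noise CDF at their duration (P < 0.025).
"""
import clasp
from clasp import preprocess as pre

cfg = clasp.GeneratorConfig(duration_s=600.0, seed=1)
rec, truth = clasp.generate_night(cfg)

sig = pre.condition(rec, clasp.CLA_L)
beta = pre.band_power(sig)
episodes = clasp.segment_sleep(beta, pct="otsu", span=(0.0, cfg.duration_s))
events, candidates = clasp.detect_sns(sig, channel=clasp.CLA_L)

print(f"candidates: {len(candidates)}, accepted SNs: {len(events)} "
      f"(p_null < 0.025)")

from clasp.validation import detection_scores
scores = detection_scores(events, truth, "L")
print(f"against truth: recall {scores['recall']:.3f}, "
      f"precision {scores['precision']:.3f}")

iei = clasp.iei_stats(events.t_steep.to_numpy(), episodes=episodes)
print(f"IEI during REM_P: median {iei['median_ms']:.1f} ms, "
      f"mode {iei['mode_ms']:.0f} ms, IQR "
      f"[{iei['q25_ms']:.1f}, {iei['q75_ms']:.1f}] ms over {iei['n']} "
      f"intervals")
# The generative law has median 60.2 ms and mode 40 ms; the recovered
# median runs a few percent high because the 40-Hz conditioning merges the
# rare near-coincident event pairs.
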