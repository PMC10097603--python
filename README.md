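# clasp — bilateral claustrum sleep-LFP analysis

During sleep, the lizard *Pogona vitticeps* alternates every 1.5–2.5 minutes
between a slow-wave-like state (SW), in which each claustrum produces
sharp-wave ripples independently, and a REM-like state (REM_P), in which
both claustra emit trains of **sharp negative field potentials (SNs)** that
are precisely mirrored across hemispheres — but not simultaneously: one
side leads the other by about 20 ms, the leading side carries the larger
events, and leadership switches at most once or twice per episode.  This
lead–lag structure is the readout of a winner-take-all competition between
the two sides of the midbrain (the nucleus isthmi pars magnocellularis,
Imc, leads its ipsilateral claustrum by ~30 ms and the contralateral one by
~50 ms; a unilateral Imc lesion freezes dominance on the intact side and
shortens REM_P).

`clasp` is a Python package for this analysis, aimed at electrophysiologists
working with bilateral event-train LFP data:

* **synthetic nights** — a generator that emulates the full statistical
  structure (episode alternation, log-normal SN intervals with median
  60.2 ms and mode 40 ms, ±20 ms bilateral pairs with leader-amplitude
  dominance, Imc leads, dominance switching, unilateral-lesion mode) and
  records complete ground truth for validation;
* **detection** — SNs as derivative triplets (negative d²V/dt² peak,
  negative dV/dt peak, positive d²V/dt² peak) on the conditioned signal
  (1 kHz, zero-phase 40-Hz low-pass, z-scored), filtered against a
  sign-flip noise null at *P* < 0.025;
* **matching** — globally optimal one-to-one bilateral pairing by linear
  assignment on local cross-correlation scores weighted by
  exp(−|lag|/10 ms), pairs accepted when either member has *P* < 0.05;
* **leadership** — sliding lagged cross-correlation (10-s windows, 100-ms
  steps, ±51-ms lags, 99.9th-percentile normalization), peak-lag
  distributions, and the instantaneous-leadership score
  `s±20(t) = log10 Σ [c0(t+τ)]⁻ [c1(t+τ±20)]⁻` with dominance segmentation
  (left / right / unsettled, 3-s defragmentation);
* **episode statistics** — REM_P/SW segmentation from 12–30 Hz band power,
  switch counting, per-state time fractions, amplitude–lag statistics
  (Mann–Whitney), and lesion/control comparisons (Welch, Wilcoxon).

## Worked example

```python
import clasp
from clasp import preprocess as pre, leadership as lead

cfg = clasp.GeneratorConfig(duration_s=1800.0, seed=2)
rec, truth = clasp.generate_night(cfg)

sig_l = pre.condition(rec, clasp.CLA_L)
sig_r = pre.condition(rec, clasp.CLA_R)
beta = pre.band_power(sig_l)
episodes = clasp.segment_sleep(beta, pct="otsu", span=(0, cfg.duration_s))

dist = lead.peak_lag_distribution(lead.lagged_xcorr(sig_l, sig_r))
trace = lead.leadership_score(sig_l, sig_r, lag_ms=20.0)
thr_l, thr_r = lead.calibrate_thresholds(trace, episodes)
dominance = lead.segment_dominance(trace, thr_l, thr_r, episodes=episodes)
table, summary = clasp.episode_stats(episodes, dominance)
```

Printed by `examples/04_leadership_and_dominance.py`, which runs exactly
this analysis:

```
peak-correlation lag modes: [-20.0, 20.0] ms (positive = left leads)
dominance thresholds: (-0.59, -0.59) log10 units
REM_P episodes: 15, switch counts {0: 6, 1: 8, 2: 1}
mean duration: 72.2 s without a switch vs 86.3 s with one
unsettled time per switching episode: 4.5 s
```

The bimodal ±20 ms lag distribution is the signature of alternating
side-leadership; episodes that contain a dominance switch last longer
(~90 s vs ~60 s on average over many nights), and only a few seconds around
each switch lack a settled leader.  The other scripts in `examples/` cover
simulation (`01`), detection and interval statistics (`02`), bilateral
matching and amplitude–leadership coupling (`03`), and the unilateral-lesion
phenotype with its unimodal lag distribution (`05`).

A thin CLI mirrors the library for shell use:

```
clasp run-all --seed 7 --out runs/night7        # simulate + full analysis
clasp simulate --seed 7 --out data/night7       # generator only
clasp detect --in data/night7 --out out/night7  # stage by stage
```

Every run directory contains the resolved configuration (YAML) and a
`night_summary.json` with the recovered statistics; event tables are CSV.

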