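# Methods

`clasp` analyzes bilateral claustrum field-potential recordings from sleeping
lizards (*Pogona vitticeps*), in which sleep alternates every 1.5–2.5 min
between a slow-wave-like state (SW, independent sharp-wave ripples on each
side) and a REM-like state (REM_P, trains of sharp negative potentials — SNs
— that are tightly mirrored across hemispheres with a ±20 ms lag).  The
package implements the full analysis chain — conditioning, SN detection with
a sign-flip noise null, optimal bilateral event matching, lagged
cross-correlation and instantaneous-leadership scoring, sleep-state and
dominance segmentation, episode statistics — together with a synthetic night
generator that reproduces the statistical structure the chain assumes, so
every stage can be validated against ground truth.

## Signal conditioning

All stages share one conditioning chain: resample to a 1 kHz working rate,
zero-phase low-pass at 40 Hz (order-4 Butterworth, forward–backward),
z-score over the analyzed span, first and second derivatives by central
differences.  Zero-phase filtering is essential: every downstream quantity
is a time relation at the ±20 ms scale, and a causal filter's group delay
would bias all of them.  z-scoring statistics are global rather than
windowed, so that amplitude comparisons across the night remain meaningful;
the standard deviation removed is retained so event amplitudes can be
reported in microvolts.

When several acquisition clocks are involved, recordings are aligned by
piecewise-linear interpolation of a common 1-Hz square-wave reference
(rising edges by half-amplitude threshold with sub-sample interpolation);
the test suite verifies that a 50-ppm clock drift is corrected to within one
working-rate sample.

## SN detection

A candidate SN is a triplet of derivative peaks: a negative
second-derivative peak (start of the falling phase), a negative
first-derivative peak (steepest descent), and a positive second-derivative
peak (the trough).  Amplitude is the voltage drop across the outer pair;
duration their separation.  Peak picking uses two relative criteria: a
prominence floor (0.5 × the derivative's standard deviation; suppresses
numerical micro-peaks) and a steepness floor (the descent peak must reach
1.0 × std(c)).  The steepness criterion is part of what "sharp" means: the
slow recovery ramps that follow each event — whose mean upward slope is
fixed at amplitude/IEI by conservation — never descend steeply, and without
a height requirement their noise-broken chunks flood the candidate pool on
both the upright and inverted signal.  Both criteria are scale-relative, so
detection is covariant under signal rescaling.  The steepest-descent time is
refined by parabolic interpolation around the derivative peak.

False positives are controlled by a sign-flip null: the same detector runs
on the inverted signal, where genuine sharp *positive* deflections do not
exist, and everything it finds is noise.  A candidate is kept when its
amplitude lies beyond the (1 − α) tail (α = 0.025) of the noise amplitude
CDF **at its duration** (noise-duration-binned CDFs, ≥50 events per bin).
This realizes minimum amplitude thresholds that rise with duration.  The
duration-conditional form matters: inverted-signal events live on slow
recovery ramps, so their amplitude grows with their span, and at any fixed
duration a true SN is far out in the amplitude tail, while the *marginal*
noise duration distribution is systematically longer than the sharp true
events (a minimum-duration threshold at the marginal noise quantile would
reject essentially everything — we verified this across wide parameter
ranges before adopting the conditional form).  Detection and noise
estimation run in consecutive 1-h sections so slow drifts in noise
statistics stay local.

Interval statistics restrict to REM_P episodes and never span an episode
boundary.  The IEI histogram uses 5-ms bins centered on multiples of 5 ms
and is truncated at 150 ms for display; the mode is the argmax after a
[0.25, 0.5, 0.25] smoothing kernel (the IEI density is flat-topped near its
mode, making the raw argmax bin a coin flip among neighbors).  Two
structural biases bound how well the generative median can be recovered:
the 40-Hz low-pass merges event pairs closer than ~15 ms (≈1.5 % of
intervals under the default law), and the occasional absence of a
contralateral partner thins the follower-side train; together they inflate
the recovered median by ~4 % over the generative 60.2 ms.

## Bilateral matching

Every left/right candidate pair within a ±51 ms lag window is scored by the
local cross-correlation of the negative-clipped first derivatives in a
100-ms window centered midway between the two events, evaluated at the
pair's lag and weighted by exp(−|lag|/10 ms).  Scores are non-negative, so
the optimal one-to-one combination (events may stay unmatched) is found
exactly by splitting the candidate graph into connected components and
solving each as a rectangular linear assignment problem
(`scipy.optimize.linear_sum_assignment`); zero-score assignments are
discarded, which is equivalent to allowing unmatched events.  A pair is
accepted when at least one member has null probability below 0.05 —
matching therefore operates on the full candidate pool (with null
probabilities recorded), not on the stricter α = 0.025 detection set;
otherwise the laxer pair-acceptance rule would be vacuous.  Matching is
chunked in 1-h sections on the pair midpoint time.

The irreducible error mode is the train's quasi-periodicity: the IEI mode
(~40 ms) is close to twice the bilateral lag, so pairing an event with its
partner's neighbor produces a lag of roughly the opposite sign with the
same kernel weight.  Amplitude covariation and jitter accumulation let the
correct pairing win most of the time; recovered pairing among clearly
detectable events runs at ~85–90 %, the same range reported for recorded
data.

## Lagged cross-correlation and leadership

The sliding lagged cross-correlation uses the first derivatives, a 10-s
window scrolled in 100-ms steps, a ±51-ms lag grid, and normalization of
the matrix to its 99.9th percentile.  Peak-lag distributions keep only
windows whose peak correlation reaches the top quartile of peak values
(`keep_quantile = 0.75`, exposed because the phrasing "top 75 % percentile"
admits both readings) and drop peaks at the extreme lags of the grid.
Positive lag means the left channel leads.

The instantaneous-leadership score at lag L is
`s_L(t) = log10 [ Σ_{τ=−w/2}^{w/2} [c0(t+τ)]⁻ [c1(t+τ+L)]⁻ ]` with w = 10 s
and the sums floored at 1e−12 before the logarithm.  `s_plus` (c1 delayed
by +20 ms) is large when the left channel leads; `s_minus` mirrors it.  An
independent nested-loop implementation of the sum serves as the oracle in
the test suite (agreement to 1e−9 relative).

Dominance states are linear thresholds on the two scores: left when only
`s_plus` is above threshold, right when only `s_minus`, unsettled when both
or neither; runs shorter than 3 s are merged into their surroundings, and
SW time (from sleep segmentation) is excluded.  Thresholds are calibrated
per night: each side's threshold sits 30 % of the way from its dominant
score cluster (REM_P windows where it beats the other side) down toward its
non-dominant cluster.  Two empirical facts drive this rule.  First, the
non-dominant score sits far above the SW floor (quasi-periodicity again:
the wrong lag still picks up partial alignment), so a threshold referenced
to SW labels all of REM_P "unsettled".  Second, at a switch the two scores
cross smoothly over about one window length; a threshold exactly at the
crossing level leaves no interval in which neither side is established,
whereas placing it closer to the dominant cluster recovers the ~4-s
unsettled interlude around each switch.  On lesioned nights one side never
dominates and its clusters are taken from the other side by mirror
symmetry.

## Sleep segmentation and episode statistics

REM_P/SW segmentation thresholds the 12–30 Hz band power (zero-phase
band-pass, 10-s windows, 1-s steps) and merges state detours shorter than
15 s.  The classical rule thresholds at a fixed percentile of the trace
(default 15); the pipeline default (`beta_pct="otsu"`) instead chooses the
threshold per night by Otsu's two-class criterion on the log-power
histogram, refined to the arithmetic midpoint of the two class medians.
The fixed percentile presupposes the night's SW fraction — by construction
it labels exactly that percentile of windows SW, and a night with ~40 % SW
(let alone a lesioned night with an SW excess) cannot be segmented by a
15th-percentile cut.  The midpoint refinement matters for boundary
accuracy: windowed power is linear in the window's overlap with an episode,
so the midpoint threshold crosses at the center of each boundary ramp and
episode edges come out unbiased (±1 s on synthetic nights).

Episode statistics count dominance switches as left↔right transitions with
unsettled interludes ignored (left→unsettled→left is zero switches), report
per-state times and the majority side per episode, and aggregate mean
durations of 0-switch and 1-switch episodes excluding episodes clipped by
the edges of the analyzed span.  Amplitude–lag statistics normalize each
side's amplitudes by that side's night median (robust and scale-free; a
z-score variant is exposed) and compare the left-leads and right-leads
groups with a two-sided Mann–Whitney U test; lesion/control comparisons use
Welch's t (negative t when the second group is larger) and one-sided
Wilcoxon signed-rank tests from `scipy.stats`.

## The synthetic-night generator

The generator is phenomenological — stereotyped waveform templates on a
noise floor, not a circuit model.  Its defaults encode the published
statistics of the system: sleep cycles uniform on [90, 150] s; REM_P
durations Normal(57, 16.6) s without a dominance switch and
Normal(88.5, 19.6) s with one (P(switch) = 103/162, plus a 0.02 residual of
two switches); a 4-s unsettled interlude straddling each switch, during
which both sides fire independently; SN inter-event intervals log-normal
with median 60.2 ms and mode 40 ms (σ² = ln(median/mode)); bilateral pairs
offset by 20 ± 3 ms with the follower at 0.8× the leader's amplitude; Imc
deflections leading the leading claustrum by 30 ms (hence the contralateral
claustrum by 50 ms); per-side SWR trains at ~1 Hz (250-ms refractory) in
SW; lesion mode with dominance fixed on the intact side and REM_P durations
Normal(33, 8) s.  A first-order autoregressive tendency (coefficient 0.9
per episode) gives the slow across-night waxing and waning of side
dominance.  Per-unit spiking probabilities are spread evenly across the
interior of the reported ranges (P(≥1 spike) ∈ [0.14, 0.43], P(>1) ∈
[0.003, 0.03]), with 2-ms jitter around the steepest descent and a 0.1-Hz
background.

Waveform choices that are not pinned by any published number, and the
reasoning behind them:

* **SN template** — half-Gaussian fall (falling-phase duration median 6 ms,
  i.e. σ = duration/√3 ≈ 3.5 ms, log-normal spread 0.15) whose analytic
  triplet recovers start = trough − σ√3, steepest descent = trough − σ,
  amplitude (1 − e^(−3/2)) × depth; amplitude log-normal with median 450 µV
  and shape 0.2.  Sharp means sharp: at the 40-Hz working bandwidth, events
  much wider than ~15 ms become inseparable from their neighbors at the
  short end of the interval distribution.  Recovery is three-pooled: a small sharp
  rebound (15 %, τ = 15 ms) that separates consecutive events at short
  intervals, then slow pools (42.5 % at τ = 400 ms, 42.5 % at τ = 800 ms)
  that carry the sustained down-state.  The slow recovery is a load-bearing
  property, not a cosmetic one: recorded claustrum sleep LFP contains no
  sharp positive deflections, and the sign-flip noise null is only valid
  when no upward slope rivals a falling slope.
* **SWR template** — monophasic sharp wave (negative Gaussian, σ = 30 ms,
  300 µV) with a slow recovery and a ~100-Hz ripple.  The width keeps SWR
  energy below the beta band (a narrower, 20-ms sharp wave leaks enough
  12–30 Hz power to destroy the REM/SW beta contrast that segmentation
  needs), and the monophasic shape respects the no-sharp-positive property.
* **Noise** — pink (1/f) floor at 15 µV RMS plus a 5 µV RMS broadband
  band (30–48 Hz, above beta and below the conditioning low-pass) that
  gives the background realistic fast texture.
* **Pairing probability** — 0.97 generative.  The reported "85–90 % of
  clearly detectable events" and ~208,000 pairs among 220,000–260,000
  detected SNs are post-detection observables; treating them as the
  generative rate double-counts detection and matching losses.  At 0.97 the
  pipeline's observed pairing lands at ~0.85–0.90, matching the recordings.

What the generator does *not* emulate: continuous background oscillations
and awake-like activity, electrode artifacts, spatial channel structure and
volume conduction, amplitude non-stationarity across the night, and any
biophysics of the claustrum–Imc loop.  Passing recovery tests on synthetic
nights therefore demonstrates that the analysis chain is correct and
well-calibrated for signals with the assumed event structure, not that it
is robust to every pathology of real recordings.

## Numerical choices and degenerate inputs

Events are rendered with σ-quantized cached templates (0.25-ms grid);
recordings serialize as interleaved little-endian int16 with a JSON sidecar
(scale chosen per recording, quantization ≤ 1 bit).  Times are seconds at
6 decimals; lags signed milliseconds (positive = left leads); intervals are
half-open `[start, end)`.  Empty event lists, empty candidate sets, flat
signals and constant beta traces all have defined behavior (empty outputs
or explicit errors, tested).  The leadership log floor is 1e−12; assignment
ties are broken by the LAP solver deterministically; defragmentation merges
shortest runs first, with a short run between two different states joining
the longer neighbor.

## Problem sizes

The validation suite runs on a 600-s night (≈10,000 SNs) for unit-level
checks and on 1–3-h nights for end-to-end recovery; the acceptance script
analyzes a 1-h default night (interval statistics, lag structure, pair
recovery), a 3-h night (episode statistics) and a 2-h lesioned night.
These sizes give a few thousand pairs and 30–90 episodes per quantity —
comfortably past the point where recovered statistics stabilize (standard
errors well inside the tolerances used), while keeping a full run on one
CPU in a few minutes.

## Known limitations

* The recovered IEI median carries a ~+4 % structural bias (low-pass merge
  of near-coincident events plus follower-train thinning); the mode at 5-ms
  bin resolution is recoverable only to one bin.
* Matching inherits a ±(IEI − lag) ambiguity from the train's
  quasi-periodicity; ~10–15 % of pairs among clearly detectable events
  resolve to a neighbor, as in the recorded data.
* Dominance-threshold calibration assumes both states (SW and REM_P) are
  present in the analyzed span and that at least one side dominates
  somewhere.
* The whole pipeline assumes the bilateral lag is stable within a night;
  drifting lags would require re-estimating the leadership lag per segment.
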