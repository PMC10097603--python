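"""Synthetic bilateral sleep-night generator.

Produces multi-channel recordings (left/right claustrum LFP, left/right Imc
LFP, and a shared 1-Hz synchronization square wave) whose statistical
structure mirrors what the analysis stages assume about *Pogona* sleep:

* alternating slow-wave (SW) and REM_P episodes, each full cycle 1.5-2.5 min;
* SW episodes carry independent sharp-wave-ripple (SWR) trains on each side;
* REM_P episodes carry trains of sharp negative events (SNs) drawn from a
  right-skewed log-normal inter-event-interval law; one side ("leader")
  emits the train, the other mirrors it ~20 ms later at reduced amplitude;
* the leading side switches 0-1 (rarely 2) times per episode, with a short
  unsettled interlude around each switch during which both sides fire
  independently;
* Imc channels carry negative deflections leading the leader-side claustrum
  SNs by 30 ms (hence the contralateral claustrum by 50 ms);
* an optional unilateral-lesion mode removes switching entirely, fixes
  dominance on the intact side and shortens REM_P episodes.

The generator is phenomenological: waveforms are stereotyped templates on a
pink-noise floor, not the output of a circuit model.  Everything it draws is
written into a :class:`GroundTruth` registry so that recovery by the analysis
stages can be scored exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .recording import CLA_L, CLA_R, IMC_L, IMC_R, SYNC, Recording

SIDES = ("L", "R")
# three-pool recovery after each SN trough: a small sharp rebound (which
# separates consecutive events at short inter-event intervals, as in real
# traces where the potential bounces part-way back immediately), then a slow
# pool and a slower "down state" pool.  The two slow time constants are long
# relative to the falling phase, so no sustained upward slope ever rivals a
# falling slope - recorded sleep LFP shows no sharp positive deflections,
# and the sign-flip noise null relies on it; the rebound is small enough
# that its inverted image stays inside the small-noise population.
_REC_REBOUND_FRACTION = 0.15
_REC_TAU_REBOUND_MS = 15.0
_REC_FAST_FRACTION = 0.425
_REC_TAU_FAST_MS = 400.0
_REC_TAU_SLOW_MS = 800.0
_SIGMA_CACHE_STEP_MS = 0.25


@dataclass
class GroundTruth:
    """Generator-side truth registry for recovery scoring.

    ``episodes``  : state (SW|REM_P), start_s, end_s, n_switches, truncated
    ``dominance`` : side (L|R|unsettled), start_s, end_s  (REM_P time only)
    ``sn``        : id, side, t_trough, t_steep, amp_uv, sigma_ms, leader, pair_id
    ``pairs``     : pair_id, leader_side, left_id, right_id, t_left, t_right,
                    lag_ms (= t_right - t_left, positive when left leads),
                    leader_amp_uv, follower_amp_uv
    ``imc``       : side, t (burst trough time, s)
    ``spikes``    : {(side, unit): spike time array}, filled by generate_spikes
    """

    episodes: pd.DataFrame
    dominance: pd.DataFrame
    sn: pd.DataFrame
    pairs: pd.DataFrame
    imc: pd.DataFrame
    spikes: dict = field(default_factory=dict)

    def sn_times(self, side: str) -> np.ndarray:
        return self.sn.loc[self.sn.side == side, "t_trough"].to_numpy()

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        fmt = lambda df: df.round(6)
        fmt(self.episodes).to_csv(path / "episodes.csv", index=False)
        fmt(self.dominance).to_csv(path / "dominance.csv", index=False)
        fmt(self.sn).to_csv(path / "sn_truth.csv", index=False)
        fmt(self.pairs).to_csv(path / "pairs_truth.csv", index=False)
        fmt(self.imc).to_csv(path / "imc_truth.csv", index=False)
        rows = [
            {"side": side, "unit": unit, "t": round(float(t), 6)}
            for (side, unit), ts in sorted(self.spikes.items())
            for t in ts
        ]
        pd.DataFrame(rows, columns=["side", "unit", "t"]).to_csv(
            path / "spikes.csv", index=False
        )
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "GroundTruth":
        path = Path(path)
        spikes: dict = {}
        sp = pd.read_csv(path / "spikes.csv")
        for (side, unit), grp in sp.groupby(["side", "unit"]):
            spikes[(side, int(unit))] = grp["t"].to_numpy()
        return cls(
            episodes=pd.read_csv(path / "episodes.csv"),
            dominance=pd.read_csv(path / "dominance.csv"),
            sn=pd.read_csv(path / "sn_truth.csv"),
            pairs=pd.read_csv(path / "pairs_truth.csv"),
            imc=pd.read_csv(path / "imc_truth.csv"),
            spikes=spikes,
        )


# --------------------------------------------------------------------------
# episode and dominance scaffolding
# --------------------------------------------------------------------------

def _iei_params(cfg: GeneratorConfig) -> tuple[float, float]:
    """Log-normal (mu, sigma) from the configured IEI median and mode.

    For a log-normal law, median = exp(mu) and mode = exp(mu - sigma^2), so
    sigma^2 = ln(median / mode).
    """
    sigma = np.sqrt(np.log(cfg.sn_iei_median_ms / cfg.sn_iei_mode_ms))
    return np.log(cfg.sn_iei_median_ms), sigma


def _draw_episodes(cfg: GeneratorConfig, rng: np.random.Generator):
    """Alternating SW / REM_P episodes tiling [0, duration_s) exactly."""
    lesioned = cfg.lesion_side != "none"
    if lesioned and cfg.p_switch > 0:
        warnings.warn(
            "lesion_side is set: dominance switches are suppressed "
            "(p_switch ignored)",
            stacklevel=3,
        )
    rows = []
    t = 0.0
    while t < cfg.duration_s:
        cycle = rng.uniform(*cfg.sleep_cycle_s)
        if lesioned:
            n_sw = 0
            rem = rng.normal(cfg.lesioned_remp_mean_s, cfg.lesioned_remp_sd_s)
        else:
            u = rng.random()
            if u < cfg.p_switch:
                n_sw = 1
                rem = rng.normal(cfg.remp_onesw_mean_s, cfg.remp_onesw_sd_s)
            elif u < cfg.p_switch + cfg.p_two_switches:
                n_sw = 2
                rem = rng.normal(
                    cfg.remp_onesw_mean_s + 30.0, cfg.remp_onesw_sd_s
                )
            else:
                n_sw = 0
                rem = rng.normal(cfg.remp_nosw_mean_s, cfg.remp_nosw_sd_s)
        rem = max(rem, cfg.min_remp_s)
        sw = max(cycle - rem, cfg.min_sw_s)
        rows.append({"state": "SW", "start_s": t, "end_s": t + sw,
                     "n_switches": 0})
        rows.append({"state": "REM_P", "start_s": t + sw,
                     "end_s": t + sw + rem, "n_switches": n_sw})
        t += sw + rem
    ep = pd.DataFrame(rows)
    truncated = ep["end_s"] > cfg.duration_s
    ep.loc[truncated, "end_s"] = cfg.duration_s
    ep["truncated"] = truncated
    ep = ep[ep.end_s > ep.start_s].reset_index(drop=True)
    return ep


def _draw_dominance(cfg: GeneratorConfig, rng: np.random.Generator,
                    episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-REM_P-episode dominance segments with an AR(1) side tendency."""
    lesioned = cfg.lesion_side != "none"
    intact = {"left": "R", "right": "L"}.get(cfg.lesion_side)
    ar = cfg.side_bias_ar
    bias = rng.normal()
    half_u = cfg.unsettled_s / 2.0
    rows = []
    for _, ep in episodes[episodes.state == "REM_P"].iterrows():
        a, b = float(ep.start_s), float(ep.end_s)
        bias = ar * bias + np.sqrt(max(1.0 - ar**2, 0.0)) * rng.normal()
        if lesioned:
            rows.append({"side": intact, "start_s": a, "end_s": b})
            continue
        start_side = "L" if bias > 0 else "R"
        n_sw = int(ep.n_switches)
        if n_sw == 0:
            cuts = []
        elif n_sw == 1:
            cuts = [a + rng.uniform(0.3, 0.7) * (b - a)]
        else:
            cuts = [a + rng.uniform(0.25, 0.40) * (b - a),
                    a + rng.uniform(0.60, 0.75) * (b - a)]
        side = start_side
        prev = a
        for cut in cuts:
            lo, hi = max(cut - half_u, a), min(cut + half_u, b)
            if lo > prev:
                rows.append({"side": side, "start_s": prev, "end_s": lo})
            rows.append({"side": "unsettled", "start_s": lo, "end_s": hi})
            side = "L" if side == "R" else "R"
            prev = hi
        if b > prev:
            rows.append({"side": side, "start_s": prev, "end_s": b})
        if n_sw % 2 == 1:  # carry the end side into the AR tendency
            bias = -bias
    return pd.DataFrame(rows, columns=["side", "start_s", "end_s"])


def _renewal_train(rng: np.random.Generator, start: float, end: float,
                   mu: float, sigma: float) -> np.ndarray:
    """Event times of a log-normal renewal process on [start, end) (seconds).

    mu/sigma parameterize the IEI law in log-milliseconds.
    """
    if end <= start:
        return np.empty(0)
    mean_iei_s = np.exp(mu + sigma**2 / 2.0) / 1000.0
    out = []
    t = start
    n_guess = max(int((end - start) / mean_iei_s * 1.3) + 16, 16)
    while t < end:
        ieis = rng.lognormal(mu, sigma, n_guess) / 1000.0
        ts = t + np.cumsum(ieis)
        out.append(ts[ts < end])
        t = ts[-1]
    return np.concatenate(out) if out else np.empty(0)


# --------------------------------------------------------------------------
# event drawing
# --------------------------------------------------------------------------

def _draw_events(cfg: GeneratorConfig, rng: np.random.Generator,
                 dominance: pd.DataFrame):
    """Draw SN trains, bilateral pairs and Imc bursts from the dominance plan."""
    mu, sigma = _iei_params(cfg)
    sig_med_ms = cfg.sn_duration_median_ms / np.sqrt(3.0)  # falling sigma
    ev: dict[str, dict[str, list]] = {
        s: {"t": [], "amp": [], "sigma_ms": [], "leader": [], "pair": []}
        for s in SIDES
    }
    imc_rows: list[tuple[str, float]] = []
    pair_info: list[dict] = []  # indices into per-side append order

    def add_event(side, t, amp, sig_ms, leader, pair_id):
        ev[side]["t"].append(t)
        ev[side]["amp"].append(amp)
        ev[side]["sigma_ms"].append(sig_ms)
        ev[side]["leader"].append(leader)
        ev[side]["pair"].append(pair_id)
        return len(ev[side]["t"]) - 1

    next_pair = 0
    for _, seg in dominance.iterrows():
        a, b = float(seg.start_s), float(seg.end_s)
        if seg.side == "unsettled":
            # both sides free-run independently; no pairs, own-side Imc drive
            for side in SIDES:
                for t in _renewal_train(rng, a, b, mu, sigma):
                    amp = cfg.sn_amp_median_uv * rng.lognormal(0, cfg.sn_amp_spread)
                    sg = sig_med_ms * rng.lognormal(0, cfg.sn_duration_spread)
                    add_event(side, t, amp, sg, False, -1)
                    imc_rows.append((side, t - cfg.imc_ipsi_lead_ms / 1000.0))
            continue
        leader = str(seg.side)
        follower = "R" if leader == "L" else "L"
        for t in _renewal_train(rng, a, b, mu, sigma):
            amp = cfg.sn_amp_median_uv * rng.lognormal(0, cfg.sn_amp_spread)
            sg = sig_med_ms * rng.lognormal(0, cfg.sn_duration_spread)
            imc_rows.append((leader, t - cfg.imc_ipsi_lead_ms / 1000.0))
            if rng.random() < cfg.p_bilateral:
                lag_s = (cfg.interclaustral_lag_ms
                         + rng.normal(0, cfg.lag_jitter_sd_ms)) / 1000.0
                tf = t + lag_s
                if tf >= cfg.duration_s:
                    add_event(leader, t, amp, sg, True, -1)
                    continue
                pid = next_pair
                next_pair += 1
                i_lead = add_event(leader, t, amp, sg, True, pid)
                i_fol = add_event(
                    follower, tf, amp * cfg.follower_amp_factor, sg, False, pid
                )
                pair_info.append({
                    "pair_id": pid, "leader_side": leader,
                    "lead_idx": i_lead, "fol_idx": i_fol,
                    "leader_amp_uv": amp,
                    "follower_amp_uv": amp * cfg.follower_amp_factor,
                })
            else:
                add_event(leader, t, amp, sg, True, -1)

    # assemble per-side tables sorted by time, with stable global ids
    frames = []
    id_maps = {}
    offset = 0
    for side in SIDES:
        d = ev[side]
        df = pd.DataFrame({
            "side": side,
            "t_trough": np.asarray(d["t"]),
            "amp_uv": np.asarray(d["amp"]),
            "sigma_ms": np.asarray(d["sigma_ms"]),
            "leader": np.asarray(d["leader"], dtype=bool),
            "pair_id": np.asarray(d["pair"], dtype=int),
        })
        order = np.argsort(df.t_trough.to_numpy(), kind="stable")
        df = df.iloc[order].reset_index(drop=True)
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        id_maps[side] = inv + offset
        df["id"] = np.arange(len(df)) + offset
        offset += len(df)
        frames.append(df)
    sn = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    sn["t_steep"] = sn["t_trough"] - sn["sigma_ms"] / 1000.0
    sn = sn[["id", "side", "t_trough", "t_steep", "amp_uv", "sigma_ms",
             "leader", "pair_id"]]

    pair_rows = []
    for p in pair_info:
        lead_side = p["leader_side"]
        fol_side = "R" if lead_side == "L" else "L"
        lid = int(id_maps[lead_side][p["lead_idx"]])
        fid = int(id_maps[fol_side][p["fol_idx"]])
        left_id, right_id = (lid, fid) if lead_side == "L" else (fid, lid)
        t_left = float(sn.loc[sn.id == left_id, "t_steep"].iloc[0])
        t_right = float(sn.loc[sn.id == right_id, "t_steep"].iloc[0])
        pair_rows.append({
            "pair_id": p["pair_id"], "leader_side": lead_side,
            "left_id": left_id, "right_id": right_id,
            "t_left": t_left, "t_right": t_right,
            "lag_ms": (t_right - t_left) * 1000.0,
            "leader_amp_uv": p["leader_amp_uv"],
            "follower_amp_uv": p["follower_amp_uv"],
        })
    pairs = pd.DataFrame(
        pair_rows,
        columns=["pair_id", "leader_side", "left_id", "right_id",
                 "t_left", "t_right", "lag_ms", "leader_amp_uv",
                 "follower_amp_uv"],
    )
    imc = pd.DataFrame(imc_rows, columns=["side", "t"])
    imc = imc[(imc.t >= 0) & (imc.t < cfg.duration_s)]
    imc = imc.sort_values(["side", "t"]).reset_index(drop=True)
    return sn, pairs, imc


def _draw_swr_times(cfg: GeneratorConfig, rng: np.random.Generator,
                    episodes: pd.DataFrame) -> dict[str, np.ndarray]:
    """Independent per-side SWR trains in SW episodes.

    Homogeneous renewal with a 250-ms refractory period, scaled so the mean
    rate equals ``swr_rate_hz`` ("irregularly every 0.5-2 s").
    """
    refractory = 0.25
    mean_iei = 1.0 / cfg.swr_rate_hz
    exp_mean = max(mean_iei - refractory, 0.05)
    out = {s: [] for s in SIDES}
    for _, ep in episodes[episodes.state == "SW"].iterrows():
        for side in SIDES:
            t = float(ep.start_s)
            while True:
                t += refractory + rng.exponential(exp_mean)
                if t >= ep.end_s:
                    break
                out[side].append(t)
    return {s: np.asarray(v) for s, v in out.items()}


# --------------------------------------------------------------------------
# waveform rendering
# --------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    """1/f ("pink") noise with the requested RMS amplitude."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x *= rms / np.std(x)
    return x


def _band_noise(rng: np.random.Generator, n: int, rms: float,
                band_hz: tuple, rate_hz: float) -> np.ndarray:
    """Band-limited Gaussian noise: broadband fast LFP activity.

    Placed above the beta band and below the conditioning low-pass, this is
    what keeps slow inter-event recovery ramps from being read as single
    smooth "events" by the sign-flip null - as in recorded LFP, where the
    background is never ramp-smooth.
    """
    if rms == 0 or n == 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    spec[(f < band_hz[0]) | (f > band_hz[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    if sd > 0:
        x *= rms / sd
    return x


def _sn_template(sigma_ms: float, rate_hz: float):
    """Sharp-negative template: half-Gaussian fall, slow biphasic recovery.

    Returns (waveform of unit depth, index of the trough).  The triplet
    detector applied to the analytic fall recovers t_start = trough - sigma*
    sqrt(3), t_steep = trough - sigma and amplitude (1 - e^(-3/2)) x depth.
    """
    dt_ms = 1000.0 / rate_hz
    sig = max(sigma_ms, dt_ms)
    t_fall = np.arange(-4.0 * sig, 0, dt_ms)
    t_rec = np.arange(0, 5.0 * _REC_TAU_SLOW_MS, dt_ms)
    fall = -np.exp(-0.5 * (t_fall / sig) ** 2)
    slow_frac = 1.0 - _REC_REBOUND_FRACTION - _REC_FAST_FRACTION
    rec = -(_REC_REBOUND_FRACTION * np.exp(-t_rec / _REC_TAU_REBOUND_MS)
            + _REC_FAST_FRACTION * np.exp(-t_rec / _REC_TAU_FAST_MS)
            + slow_frac * np.exp(-t_rec / _REC_TAU_SLOW_MS))
    w = np.concatenate([fall, rec])
    w -= w[-1]  # land exactly on baseline to avoid steps
    return w, len(t_fall)


def _swr_template(rate_hz: float, amp_uv: float):
    """Biphasic sharp wave (~100 ms) with a superimposed fast ripple.

    The sharp-wave width keeps SWR energy below the beta band (12-30 Hz), so
    SW episodes show the low beta power that sleep segmentation relies on;
    the ripple rides near 100 Hz and is removed by the 40-Hz conditioning
    low-pass.
    """
    dt = 1.0 / rate_hz
    sig = 0.030
    tau = 0.120
    t_fall = np.arange(-4 * sig, 0, dt)
    t_rec = np.arange(0, 5 * tau, dt)
    # predominantly negative deflection: sharp-ish fall, slow recovery
    sharp = np.concatenate([
        -np.exp(-0.5 * (t_fall / sig) ** 2), -np.exp(-t_rec / tau)
    ])
    sharp -= sharp[-1]
    sharp *= amp_uv
    t = np.concatenate([t_fall, t_rec])
    ripple = 0.2 * amp_uv * np.exp(-0.5 * (t / 0.012) ** 2) * np.sin(
        2 * np.pi * 100.0 * t
    )
    w = sharp + ripple
    return w, int(np.argmin(w))


def _add_at(signal: np.ndarray, center_idx: int, template: np.ndarray,
            anchor: int) -> None:
    """Add ``template`` so its ``anchor`` sample lands on ``center_idx``."""
    lo = center_idx - anchor
    hi = lo + len(template)
    a, b = max(lo, 0), min(hi, len(signal))
    if a >= b:
        return
    signal[a:b] += template[a - lo: b - lo]


def _render(cfg: GeneratorConfig, rng: np.random.Generator,
            episodes: pd.DataFrame, sn: pd.DataFrame, imc: pd.DataFrame,
            swr: dict[str, np.ndarray]) -> Recording:
    n = int(round(cfg.duration_s * cfg.rate_hz))
    rate = cfg.rate_hz
    chans = {role: _pink_noise(rng, n, cfg.noise_rms_uv)
             + _band_noise(rng, n, cfg.fast_noise_rms_uv,
                           cfg.fast_noise_band_hz, rate)
             for role in (CLA_L, CLA_R, IMC_L, IMC_R)}

    cache: dict[float, tuple[np.ndarray, int]] = {}

    def sn_tmpl(sig_ms: float):
        key = round(sig_ms / _SIGMA_CACHE_STEP_MS) * _SIGMA_CACHE_STEP_MS
        if key not in cache:
            cache[key] = _sn_template(key, rate)
        return cache[key]

    cla_role = {"L": CLA_L, "R": CLA_R}
    for row in sn.itertuples():
        w, anchor = sn_tmpl(row.sigma_ms)
        idx = int(round(row.t_trough * rate))
        _add_at(chans[cla_role[row.side]], idx, row.amp_uv * w, anchor)

    imc_role = {"L": IMC_L, "R": IMC_R}
    imc_sig_ms = 4.0
    w_imc, anchor_imc = _sn_template(imc_sig_ms, rate)
    for row in imc.itertuples():
        idx = int(round(row.t * rate))
        amp = cfg.imc_amp_uv * rng.lognormal(0, 0.2)
        _add_at(chans[imc_role[row.side]], idx, amp * w_imc, anchor_imc)

    w_swr, anchor_swr = _swr_template(rate, cfg.swr_amp_uv)
    for side, times in swr.items():
        for t in times:
            idx = int(round(t * rate))
            scale = rng.lognormal(0, 0.25)
            _add_at(chans[cla_role[side]], idx, scale * w_swr, anchor_swr)

    tsec = np.arange(n) / rate
    sync = np.where((tsec % 1.0) < 0.5, 500.0, -500.0)

    data = np.vstack([chans[CLA_L], chans[CLA_R], chans[IMC_L],
                      chans[IMC_R], sync])
    return Recording(data=data, rate_hz=rate,
                     channel_roles=[CLA_L, CLA_R, IMC_L, IMC_R, SYNC], t0=0.0)


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def generate_night(cfg: GeneratorConfig) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic night and its full ground truth.

    Identical configurations (including the seed) give identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    episodes = _draw_episodes(cfg, rng)
    dominance = _draw_dominance(cfg, rng, episodes)
    sn, pairs, imc = _draw_events(cfg, rng, dominance)
    swr = _draw_swr_times(cfg, rng, episodes)
    rec = _render(cfg, rng, episodes, sn, imc, swr)
    truth = GroundTruth(episodes=episodes, dominance=dominance, sn=sn,
                        pairs=pairs, imc=imc)
    return rec, truth


def unit_spike_probs(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit P(>=1 spike per SN) and P(>1 spike), spread evenly across the
    interior of the configured ranges so every unit stays strictly inside the
    reported envelope."""
    lo, hi = cfg.p_spike_range
    p1 = np.linspace(lo, hi, cfg.n_units + 2)[1:-1]
    lo2, hi2 = cfg.p_multispike_range
    p2 = np.linspace(lo2, hi2, cfg.n_units + 2)[1:-1]
    return p1, p2


def generate_spikes(truth: GroundTruth, cfg: GeneratorConfig) -> dict:
    """Draw per-unit spike trains aligned to ipsilateral SN steepest descent.

    Each of ``n_units`` units per claustrum fires >=1 spike per ipsilateral SN
    with its assigned probability, jittered by ``spike_jitter_sd_ms``; a
    second spike follows ~3 ms later with the unit's multi-spike probability.
    A sparse Poisson background covers the rest of the night.  The spike dict
    is also stored on ``truth.spikes``.
    """
    rng = np.random.default_rng([int(cfg.seed), 7])
    p1, p2 = unit_spike_probs(cfg)
    jit = cfg.spike_jitter_sd_ms / 1000.0
    spikes: dict = {}
    for side in SIDES:
        steep = truth.sn.loc[truth.sn.side == side, "t_steep"].to_numpy()
        for u in range(cfg.n_units):
            ts = []
            if steep.size:
                fire = rng.random(steep.size) < p1[u]
                t_first = steep[fire] + rng.normal(0, jit, fire.sum())
                ts.append(t_first)
                multi = rng.random(fire.sum()) < (p2[u] / max(p1[u], 1e-12))
                ts.append(t_first[multi] + 0.003
                          + np.abs(rng.normal(0, 0.001, multi.sum())))
            n_bg = rng.poisson(cfg.spike_background_hz * cfg.duration_s)
            ts.append(rng.uniform(0, cfg.duration_s, n_bg))
            train = np.sort(np.concatenate(ts)) if ts else np.empty(0)
            spikes[(side, u)] = train[(train >= 0) & (train < cfg.duration_s)]
    truth.spikes = spikes
    return spikes
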