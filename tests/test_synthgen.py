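"""Generator contracts: determinism, episode tiling, pair geometry, lesion
mode and spike statistics."""
import numpy as np
import pytest

import clasp
from clasp import GeneratorConfig, generate_night, generate_spikes
from clasp.detect import spike_sn_alignment
from clasp.synth import unit_spike_probs


def test_identical_seeds_give_identical_nights():
    cfg_a = GeneratorConfig(duration_s=60.0, seed=3)
    cfg_b = GeneratorConfig(duration_s=60.0, seed=3)
    rec_a, truth_a = generate_night(cfg_a)
    rec_b, truth_b = generate_night(cfg_b)
    assert np.array_equal(rec_a.data, rec_b.data)
    assert truth_a.sn.equals(truth_b.sn)
    assert truth_a.pairs.equals(truth_b.pairs)
    assert truth_a.episodes.equals(truth_b.episodes)


def test_episodes_tile_night_exactly(night):
    cfg, _, truth = night
    ep = truth.episodes
    assert ep.start_s.iloc[0] == 0.0
    assert ep.end_s.iloc[-1] == cfg.duration_s
    np.testing.assert_allclose(ep.start_s.values[1:], ep.end_s.values[:-1])
    states = ep.state.values
    assert all(a != b for a, b in zip(states[:-1], states[1:]))


def test_cycle_lengths_within_configured_range(night):
    cfg, _, truth = night
    ep = truth.episodes[~truth.episodes.truncated]
    sw = ep[ep.state == "SW"].reset_index(drop=True)
    rem = ep[ep.state == "REM_P"].reset_index(drop=True)
    n = min(len(sw), len(rem)) - 1  # drop possibly-clipped last cycle
    cycles = (sw.end_s - sw.start_s).values[:n] \
        + (rem.end_s - rem.start_s).values[:n]
    lo, hi = cfg.sleep_cycle_s
    # REM_P draws may exceed the cycle draw (a floor keeps SW >= min_sw_s)
    assert np.all(cycles >= lo - 1e-9)
    assert np.all(cycles <= hi + cfg.min_sw_s)


def test_pair_lag_mean_matches_configured_delay(night):
    cfg, _, truth = night
    pairs = truth.pairs
    assert len(pairs) > 1000
    signed = np.where(pairs.leader_side == "L", pairs.lag_ms, -pairs.lag_ms)
    se = signed.std() / np.sqrt(len(signed))
    assert abs(signed.mean() - cfg.interclaustral_lag_ms) < 3 * se


def test_leader_amplitude_exceeds_follower(night):
    _, _, truth = night
    pairs = truth.pairs
    assert (pairs.leader_amp_uv > pairs.follower_amp_uv).all()
    assert pairs.leader_amp_uv.mean() > pairs.follower_amp_uv.mean()


def test_dominance_segments_confined_to_remp(night):
    _, _, truth = night
    rem = truth.episodes[truth.episodes.state == "REM_P"]
    for seg in truth.dominance.itertuples():
        inside = ((rem.start_s <= seg.start_s + 1e-9)
                  & (rem.end_s >= seg.end_s - 1e-9)).any()
        assert inside, f"dominance segment {seg} outside REM_P"


def test_no_partner_probability_zero_gives_empty_pair_registry():
    cfg = GeneratorConfig(duration_s=120.0, seed=5, p_bilateral=0.0)
    _, truth = generate_night(cfg)
    assert len(truth.pairs) == 0
    assert (truth.sn.pair_id == -1).all()


def test_lesion_mode_fixes_dominance_and_shortens_episodes():
    cfg = GeneratorConfig(duration_s=1800.0, seed=9, lesion_side="left")
    with pytest.warns(UserWarning, match="switches are suppressed"):
        _, truth = generate_night(cfg)
    assert set(truth.dominance.side) == {"R"}  # intact side only
    rem = truth.episodes.query("state == 'REM_P' and not truncated")
    durs = (rem.end_s - rem.start_s).values
    se = durs.std() / np.sqrt(len(durs))
    assert abs(durs.mean() - cfg.lesioned_remp_mean_s) < 3 * se


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="duration"):
        GeneratorConfig(duration_s=-1.0)
    with pytest.raises(ValueError, match="mode"):
        GeneratorConfig(sn_iei_mode_ms=80.0)  # above the median
    with pytest.raises(ValueError, match="imc_contra"):
        GeneratorConfig(imc_contra_lead_ms=45.0)  # breaks delay consistency
    with pytest.raises(ValueError, match="lesion_side"):
        GeneratorConfig(lesion_side="both")


def test_imc_bursts_lead_leader_sns(night):
    cfg, _, truth = night
    lead_l = truth.sn[(truth.sn.side == "L") & truth.sn.leader]
    imc_l = np.sort(truth.imc.loc[truth.imc.side == "L", "t"].to_numpy())
    expect = lead_l.t_trough.to_numpy() - cfg.imc_ipsi_lead_ms / 1000.0
    j = np.searchsorted(imc_l, expect)
    j = np.clip(j, 0, len(imc_l) - 1)
    d = np.minimum(np.abs(imc_l[j] - expect),
                   np.abs(imc_l[np.maximum(j - 1, 0)] - expect))
    assert np.median(d) < 1e-6


def test_iei_law_median_and_mode():
    """The drawn IEI law reproduces its configured median, and its density
    peaks near the configured mode."""
    from clasp.synth import _iei_params, _renewal_train
    cfg = GeneratorConfig()
    mu, sigma = _iei_params(cfg)
    rng = np.random.default_rng(0)
    draws = rng.lognormal(mu, sigma, 200000)
    assert abs(np.median(draws) - cfg.sn_iei_median_ms) < 0.5
    hist, edges = np.histogram(draws, bins=np.arange(0, 150, 2.0))
    peak = 0.5 * (edges[:-1] + edges[1:])[np.argmax(hist)]
    assert abs(peak - cfg.sn_iei_mode_ms) < 5.0
    train = _renewal_train(np.random.default_rng(1), 10.0, 40.0, mu, sigma)
    assert np.all((train >= 10.0) & (train < 40.0))
    assert np.all(np.diff(train) > 0)


class TestSpikes:
    def test_certain_firing_no_jitter_hits_steepest_descent(self, night):
        cfg, _, truth = night
        cfg2 = GeneratorConfig(
            duration_s=cfg.duration_s, seed=cfg.seed,
            p_spike_range=(1.0, 1.0), p_multispike_range=(0.0, 0.0),
            spike_jitter_sd_ms=0.0, spike_background_hz=0.0)
        spikes = generate_spikes(truth, cfg2)
        steep_l = np.sort(truth.sn.loc[truth.sn.side == "L", "t_steep"])
        got = spikes[("L", 0)]
        assert len(got) == len(steep_l)
        np.testing.assert_allclose(got, steep_l, atol=1e-9)

    def test_zero_probability_gives_background_only(self, night):
        cfg, _, truth = night
        cfg2 = GeneratorConfig(
            duration_s=cfg.duration_s, seed=cfg.seed,
            p_spike_range=(0.0, 0.0), p_multispike_range=(0.0, 0.0))
        spikes = generate_spikes(truth, cfg2)
        n_bg_expected = cfg2.spike_background_hz * cfg2.duration_s
        for train in spikes.values():
            assert len(train) < 5 * n_bg_expected + 10

    def test_default_firing_probabilities_inside_reported_range(self, night):
        cfg, _, truth = night
        spikes = generate_spikes(truth, cfg)
        steep = truth.sn.loc[truth.sn.side == "L", "t_steep"].to_numpy()
        assert len(steep) > 4000
        trains = {u: spikes[("L", u)] for u in range(cfg.n_units)}
        stats = spike_sn_alignment(trains, steep)
        lo, hi = cfg.p_spike_range
        lo2, hi2 = cfg.p_multispike_range
        for u in range(cfg.n_units):
            assert lo <= stats[u]["p_ge1"] <= hi
            assert lo2 <= stats[u]["p_gt1"] <= hi2

    def test_unit_probabilities_span_range_interior(self):
        cfg = GeneratorConfig()
        p1, p2 = unit_spike_probs(cfg)
        lo, hi = cfg.p_spike_range
        assert np.all((p1 > lo) & (p1 < hi))
        assert len(np.unique(p1)) == cfg.n_units


def test_recording_roundtrip(tmp_path, night):
    _, rec, _ = night
    sub = clasp.Recording(data=rec.data[:, :20000], rate_hz=rec.rate_hz,
                          channel_roles=list(rec.channel_roles))
    sub.to_dir(tmp_path / "rec")
    back = clasp.Recording.from_dir(tmp_path / "rec")
    assert back.channel_roles == sub.channel_roles
    assert back.rate_hz == sub.rate_hz
    # int16 quantization: agreement to one bit
    step = np.max(np.abs(sub.data)) / 32000.0
    assert np.max(np.abs(back.data - sub.data)) <= step


def test_groundtruth_roundtrip(tmp_path, night):
    _, _, truth = night
    truth.to_dir(tmp_path / "truth")
    back = clasp.GroundTruth.from_dir(tmp_path / "truth")
    assert len(back.sn) == len(truth.sn)
    assert len(back.pairs) == len(truth.pairs)
    np.testing.assert_allclose(back.episodes.end_s, truth.episodes.end_s,
                               atol=1e-5)
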