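"""SN detection: analytic triplet geometry, the sign-flip noise null,
candidate filtering, determinism/covariance and interval statistics."""
import numpy as np
import pytest

import clasp
from clasp import detect as det
from clasp import preprocess as pre
from clasp.validation import detection_scores

from conftest import flat_signal, signal_from_trace

RATE = 1000.0


class TestTriplets:
    def test_flat_signal_yields_no_candidates(self):
        assert len(det.detect_triplets(flat_signal())) == 0
        assert len(det.detect_triplets(signal_from_trace(
            np.full(20000, 7.0)))) == 0

    def test_gaussian_trough_geometry(self):
        # v(t) = -A exp(-(t-t0)^2 / (2 sigma^2)): the triplet brackets the
        # falling phase: start at t0 - sigma*sqrt(3) (second-derivative
        # minimum), steepest descent at t0 - sigma, end at the trough t0;
        # duration sigma*sqrt(3), amplitude A(1 - e^(-3/2)).
        A, sigma, t0 = 300.0, 0.005, 10.0
        t = np.arange(0, 20, 1 / RATE)
        v = -A * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        sig = signal_from_trace(v)
        cands = det.detect_triplets(sig)
        assert len(cands) == 1
        ev = cands.iloc[0]
        sq3 = sigma * np.sqrt(3.0)
        assert ev.t_start == pytest.approx(t0 - sq3, abs=1.5e-3)
        assert ev.t_steep == pytest.approx(t0 - sigma, abs=1.5e-3)
        assert ev.t_end == pytest.approx(t0, abs=1.5e-3)
        assert ev.duration_ms == pytest.approx(sq3 * 1000, abs=1.5)
        # sample-grid quantization of t_start (8 vs 8.66 ms before the
        # trough) moves the measured amplitude by up to ~8 uV
        assert ev.amplitude_uv == pytest.approx(A * (1 - np.exp(-1.5)),
                                                abs=9.0)

    def test_detection_is_deterministic(self, conditioned):
        sig_l, _ = conditioned
        a = det.detect_triplets(sig_l)
        b = det.detect_triplets(sig_l)
        assert a.equals(b)

    def test_scaling_covariance(self, conditioned):
        sig_l, _ = conditioned
        part = sig_l.slice(0, 120000)
        k = 3.7
        scaled = pre.ConditionedSignal(
            v=k * part.v, c=k * part.c, c2=k * part.c2,
            rate_hz=part.rate_hz, t0=part.t0, scale_uv=part.scale_uv)
        a = det.detect_triplets(part)
        b = det.detect_triplets(scaled)
        assert len(a) == len(b)
        np.testing.assert_allclose(b.t_steep, a.t_steep)
        np.testing.assert_allclose(b.duration_ms, a.duration_ms)
        np.testing.assert_allclose(b.amplitude, k * a.amplitude, rtol=1e-9)


@pytest.fixture(scope="module")
def noise_sig():
    rng = np.random.default_rng(42)
    rec = clasp.Recording(
        data=20.0 * rng.standard_normal((1, 600000)), rate_hz=RATE,
        channel_roles=["claustrum-L"])
    return pre.condition(rec, "claustrum-L")


class TestNoiseNull:
    def test_sign_flip_counts_symmetric_for_symmetric_noise(self, noise_sig):
        up = det.detect_triplets(noise_sig)
        down = det.detect_triplets(noise_sig.inverted())
        n = max(len(up), 1)
        assert abs(len(up) - len(down)) < 3 * np.sqrt(n) + 5

    def test_pure_noise_acceptance_near_alpha(self, noise_sig):
        events, cands = det.detect_sns(noise_sig, alpha=0.025)
        assert len(cands) > 200
        assert len(events) / len(cands) < 0.05

    def test_noiseless_negative_template_has_no_inverted_events(self):
        # sharp-negative templates with slow recoveries: inversion turns
        # them into slow positive ramps, which never form steep triplets
        from clasp.synth import _sn_template
        w, anchor = _sn_template(4.0, RATE)
        v = np.zeros(30000 + len(w))
        for t0 in np.arange(1.0, 29.0, 0.5):
            i = int(t0 * RATE) - anchor
            v[i:i + len(w)] += 300.0 * w
        v = v[:30000]
        model = det.estimate_noise(signal_from_trace(v))
        assert model.n_noise_events == 0


class TestFilter:
    @staticmethod
    def _model(rng, n=2000):
        # independent amplitude and duration noise sample
        return det.NoiseModel.from_sample(
            rng.lognormal(np.log(50), 0.4, n), rng.uniform(8, 30, n))

    def test_everything_beyond_noise_kept_with_zero_p(self):
        rng = np.random.default_rng(1)
        model = self._model(rng)
        import pandas as pd
        cand = pd.DataFrame({"amplitude": [1e4], "duration_ms": [100.0]})
        out = det.filter_candidates(cand, model, alpha=0.025)
        assert bool(out.kept.iloc[0])
        assert out.p_null.iloc[0] == 0.0

    def test_candidate_at_noise_median_rejected(self):
        rng = np.random.default_rng(2)
        model = self._model(rng)
        import pandas as pd
        cand = pd.DataFrame({"amplitude": [50.0], "duration_ms": [19.0]})
        out = det.filter_candidates(cand, model, alpha=0.025)
        assert not bool(out.kept.iloc[0])
        assert out.p_null.iloc[0] > 0.3

    def test_bad_alpha_rejected(self):
        import pandas as pd
        model = det.NoiseModel.from_sample(np.ones(10), np.ones(10))
        with pytest.raises(ValueError, match="alpha"):
            det.filter_candidates(pd.DataFrame(), model, alpha=1.5)

    def test_degenerate_noise_model_keeps_all(self):
        import pandas as pd
        model = det.NoiseModel.from_sample(np.empty(0), np.empty(0))
        cand = pd.DataFrame({"amplitude": [1.0], "duration_ms": [5.0]})
        out = det.filter_candidates(cand, model)
        assert bool(out.kept.iloc[0])


class TestAgainstTruth:
    def test_recall_and_precision_on_synthetic_night(self, night, detection):
        _, _, truth = night
        for side in ("L", "R"):
            events, _ = detection[side]
            scores = detection_scores(events, truth, side)
            assert scores["recall"] >= 0.9, scores
            assert scores["precision"] >= 0.9, scores

    def test_bright_truth_events_all_kept(self, night, detection):
        """Every truth SN well above the noise floor is recovered."""
        _, _, truth = night
        events, _ = detection["L"]
        big = truth.sn[(truth.sn.side == "L")
                       & (truth.sn.amp_uv > truth.sn.amp_uv.quantile(0.5))]
        det_t = np.sort(events.t_steep.to_numpy())
        j = np.searchsorted(det_t, big.t_steep.to_numpy())
        j = np.clip(j, 1, len(det_t) - 1)
        d = np.minimum(np.abs(det_t[j] - big.t_steep.to_numpy()),
                       np.abs(det_t[j - 1] - big.t_steep.to_numpy()))
        assert np.mean(d < 0.005) > 0.97

    def test_chunked_detection_stable_away_from_boundary(self, conditioned):
        sig_l, _ = conditioned
        _, whole = det.detect_sns(sig_l, chunk_s=1e9)
        _, halves = det.detect_sns(sig_l, chunk_s=300.0)
        boundary = 300.0
        w = whole[np.abs(whole.t_steep - boundary) > 1.0].t_steep.to_numpy()
        h = halves[np.abs(halves.t_steep - boundary) > 1.0].t_steep.to_numpy()
        j = np.searchsorted(h, w)
        j = np.clip(j, 1, len(h) - 1)
        d = np.minimum(np.abs(h[j] - w), np.abs(h[j - 1] - w))
        assert np.mean(d < 1e-3) > 0.98


class TestIeiStats:
    def test_regular_train(self):
        events = np.arange(0, 10, 0.05)
        s = det.iei_stats(events)
        assert s["median_ms"] == pytest.approx(50.0)
        assert s["mode_ms"] == pytest.approx(50.0)
        assert s["q75_ms"] - s["q25_ms"] == pytest.approx(0.0)

    def test_two_events_single_interval(self):
        s = det.iei_stats(np.array([1.0, 1.08]))
        assert s["n"] == 1
        assert s["median_ms"] == pytest.approx(80.0)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            det.iei_stats(np.array([1.0]))

    def test_intervals_do_not_cross_episodes(self):
        import pandas as pd
        episodes = pd.DataFrame([
            {"state": "REM_P", "start_s": 0.0, "end_s": 10.0},
            {"state": "SW", "start_s": 10.0, "end_s": 20.0},
            {"state": "REM_P", "start_s": 20.0, "end_s": 30.0},
        ])
        events = np.array([9.0, 9.95, 20.05, 21.0])
        s = det.iei_stats(events, episodes=episodes)
        assert s["n"] == 2  # the 10-s gap across SW never counts


class TestSpikeAlignment:
    def test_spikes_at_steepest_descent(self):
        steep = np.arange(1.0, 50.0, 0.5)
        out = det.spike_sn_alignment({0: steep.copy()}, steep)
        assert out[0]["p_ge1"] == 1.0
        assert out[0]["p_gt1"] == 0.0
        hist = out[0]["hist"]
        centers = out[0]["bin_centers_ms"]
        assert centers[np.argmax(hist)] == pytest.approx(1.0, abs=1.01)

    def test_no_spikes(self):
        out = det.spike_sn_alignment({0: np.array([])},
                                     np.arange(1.0, 10.0, 0.5))
        assert out[0]["p_ge1"] == 0.0
        assert out[0]["hist"].sum() == 0
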