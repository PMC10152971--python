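"""Feature extraction: EMG level, peak detection, replicability, threshold."""

import dataclasses
import math

import numpy as np
import pytest

from cvemp.features import (AveragedTrace, amplitude_ratio,
                            detect_pn, emg_level, extract_ear_features,
                            find_threshold, is_replicable)
from cvemp.simulate import (CohortConfig, WaveformConfig, _band_noise,
                            sample_cohort, synth_average, synth_session)

FS = 10_000.0
QUIET = WaveformConfig(noise_rms_uv=0.0)


def make_trace(samples, **kw):
    return AveragedTrace(np.asarray(samples, dtype=float), FS, **kw)


class TestEmgLevel:
    def test_constant_trace_gives_its_value(self):
        t = make_trace(np.full(1500, 7.5))
        assert emg_level(t) == pytest.approx(7.5)

    def test_rectification_symmetric(self):
        t = make_trace(np.sin(np.arange(1500) / 10.0) * 50)
        neg = make_trace(-t.samples)
        assert emg_level(t) == pytest.approx(emg_level(neg))

    def test_gaussian_noise_folded_mean(self, rng):
        x = _band_noise(rng, 150_000, FS, (20.0, 450.0), 200.0)
        t = make_trace(x[:15_000])
        # folded-Gaussian identity: E|X| = RMS * sqrt(2/pi) ~ 159.6 uV
        assert emg_level(t, (0.0, 1500.0)) == pytest.approx(
            200.0 * math.sqrt(2 / math.pi), rel=0.05)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            emg_level(make_trace(np.ones(1500)), (140.0, 130.0))


class TestDetectPn:
    def test_noiseless_round_trip(self, small_cohort):
        dt = 1000.0 / FS
        for subj in small_cohort[:10]:
            truth = subj.truth("L", "BC")
            trace = synth_average(subj, "L", "BC", 86.0, 2, QUIET, rng=0)
            f = detect_pn(trace)
            assert f.response_present
            assert abs(f.p_latency_ms - truth.t_p_ms) <= dt
            assert abs(f.n_latency_ms - truth.t_n_ms) <= dt
            assert f.pn_uv == pytest.approx(truth.ratio * subj.emg_uv, rel=1e-9)

    def test_flat_trace_has_no_response(self):
        f = detect_pn(make_trace(np.zeros(1500)))
        assert not f.response_present and f.pn_uv == 0.0

    def test_scale_equivariance(self, child, rng):
        trace = synth_average(child, "R", "AC", 88.0, 25, rng=rng)
        scaled = make_trace(3.0 * trace.samples, emg_uv=trace.emg_uv)
        fa, fb = detect_pn(trace), detect_pn(scaled)
        assert fb.p_latency_ms == fa.p_latency_ms
        assert fb.n_latency_ms == fa.n_latency_ms
        assert fb.pn_uv == pytest.approx(3.0 * fa.pn_uv)
        assert fb.response_present == fa.response_present

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="ms"):
            detect_pn(make_trace(np.zeros(200)))


class TestAmplitudeRatio:
    def test_arithmetic(self):
        assert amplitude_ratio(300.0, 150.0) == 2.0
        assert amplitude_ratio(0.0, 200.0) == 0.0

    def test_nonpositive_emg_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            amplitude_ratio(100.0, 0.0)

    def test_noiseless_generator_round_trip(self, small_cohort):
        for subj in small_cohort[:6]:
            truth = subj.truth("R", "AC")
            trace = synth_average(subj, "R", "AC", 88.0, 2, QUIET, rng=0)
            f = detect_pn(trace)
            assert amplitude_ratio(f.pn_uv, subj.emg_uv) == pytest.approx(
                truth.ratio, rel=1e-9)

    def test_invariant_to_session_gain(self, child, rng):
        # rescaling the whole recording chain leaves PN/EMG unchanged
        trace = synth_average(child, "R", "AC", 88.0, 25, rng=rng)
        f = detect_pn(trace)
        scaled = make_trace(5.0 * trace.samples, emg_uv=5.0 * trace.emg_uv)
        g = detect_pn(scaled)
        assert amplitude_ratio(g.pn_uv, scaled.emg_uv) == pytest.approx(
            amplitude_ratio(f.pn_uv, trace.emg_uv))


class TestReplicability:
    def test_identical_responses_replicable(self, child):
        a = synth_average(child, "R", "AC", 88.0, 25, rng=5)
        b = synth_average(child, "R", "AC", 88.0, 25, rng=6)
        assert is_replicable(a, a)
        assert is_replicable(a, b)

    def test_negated_trace_not_replicable(self, child):
        a = synth_average(child, "R", "AC", 88.0, 25, rng=5)
        b = make_trace(-a.samples, level_dbnhl=a.level_dbnhl, emg_uv=a.emg_uv)
        assert not is_replicable(a, b)

    def test_pure_noise_rarely_replicable(self, child, rng):
        hits = sum(
            is_replicable(
                synth_average(child, "R", "AC", 48.0, 50, rng=rng),
                synth_average(child, "R", "AC", 48.0, 50, rng=rng))
            for _ in range(40))
        assert hits <= 2  # false-positive rate well under 5%

    def test_mismatched_levels_rejected(self, child):
        a = synth_average(child, "R", "AC", 88.0, 25, rng=5)
        b = synth_average(child, "R", "AC", 83.0, 25, rng=5)
        with pytest.raises(ValueError, match="levels"):
            is_replicable(a, b)


class TestThreshold:
    def test_lowest_replicable_level_wins(self, child, protocol):
        session = synth_session(child, modes=("AC",), ears=("R",))
        res = find_threshold(session[("R", "AC")], protocol)
        assert res.threshold_dbnhl is not None
        assert res.threshold_dbnhl == min(res.replicable_at)
        assert abs(res.threshold_dbnhl
                   - child.truth("R", "AC").threshold_dbnhl) <= 5.0

    def test_replicable_to_floor_returns_floor(self, child, protocol):
        # strong noiseless responses at every level down to the floor
        levels = {lvl: [synth_average(child, "R", "AC", 88.0, 2, QUIET, rng=k)
                        for k in range(2)]
                  for lvl in (88.0, 83.0, 78.0)}
        relabeled = {
            lvl: [dataclasses.replace(t, level_dbnhl=lvl) for t in traces]
            for lvl, traces in levels.items()}
        res = find_threshold(relabeled, protocol)
        assert res.threshold_dbnhl == 78.0

    def test_never_replicable_flagged_absent(self, protocol, rng):
        cfg = CohortConfig(n_children=0, n_adults=3, absent_bc_prob_adult=1.0)
        adult = sample_cohort(cfg, seed=3)[0]
        rec = synth_session(adult, modes=("BC",), ears=("R",))[("R", "BC")]
        res = find_threshold(rec, protocol)
        assert res.threshold_dbnhl is None and res.replicable_at == ()

    def test_estimate_monotone_in_true_threshold(self, protocol):
        # raising the true threshold by 10 dB never lowers the estimate
        subjects = sample_cohort(CohortConfig(n_children=6, n_adults=0), seed=21)
        for subj in subjects:
            truth = subj.truth("R", "AC")
            raised = dataclasses.replace(
                subj, ears={**subj.ears,
                            ("R", "AC"): dataclasses.replace(
                                truth, threshold_dbnhl=truth.threshold_dbnhl + 10)})
            lo = find_threshold(
                synth_session(subj, modes=("AC",), ears=("R",))[("R", "AC")],
                protocol)
            hi = find_threshold(
                synth_session(raised, modes=("AC",), ears=("R",))[("R", "AC")],
                protocol)
            if lo.threshold_dbnhl is not None and hi.threshold_dbnhl is not None:
                assert hi.threshold_dbnhl >= lo.threshold_dbnhl

    def test_too_few_replicates_rejected(self, child):
        a = synth_average(child, "R", "AC", 88.0, 25, rng=5)
        with pytest.raises(ValueError, match="replicate"):
            find_threshold({88.0: [a]})
        with pytest.raises(ValueError, match="empty"):
            find_threshold({})


class TestEarFeatures:
    def test_reference_features_average_the_validation_pair(self, child, protocol):
        session = synth_session(child, modes=("AC",), ears=("R",))
        feats, thr = extract_ear_features(session[("R", "AC")], protocol)
        truth = child.truth("R", "AC")
        assert feats.response_present
        assert feats.amplitude_ratio == pytest.approx(feats.pn_uv / feats.emg_uv)
        # rectified-mean EMG normalisation: measured ratio sits near
        # true_ratio / sqrt(2/pi)
        assert feats.amplitude_ratio == pytest.approx(
            truth.ratio / math.sqrt(2 / math.pi), rel=0.35)
        assert thr.threshold_dbnhl is not None

    def test_absent_ear_reported_missing(self, protocol):
        cfg = CohortConfig(n_children=0, n_adults=3, absent_bc_prob_adult=1.0)
        adult = sample_cohort(cfg, seed=3)[0]
        session = synth_session(adult, modes=("BC",), ears=("L",))
        feats, thr = extract_ear_features(session[("L", "BC")], protocol)
        assert thr.threshold_dbnhl is None
        assert not feats.response_present
        assert feats.amplitude_ratio is None and feats.p_latency_ms is None
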