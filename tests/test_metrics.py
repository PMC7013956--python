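"""PRD, local PRD, CR, diagnostic features, WDD, stream estimate, density."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adaptecg as a
from adaptecg.metrics import WDD_WEIGHTS, _region_masks


class TestPRD:
    def test_identical_series_is_zero(self):
        x = np.sin(np.linspace(0, 10, 500))
        assert a.prd(x, x) == 0.0

    def test_ten_percent_scaling_is_ten_percent(self):
        x = np.sin(np.linspace(0, 10, 500)) + 2.0
        assert a.prd(x, 1.1 * x) == pytest.approx(10.0)

    def test_total_loss_is_hundred_percent(self):
        assert a.prd(np.array([3.0, 4.0]), np.zeros(2)) == pytest.approx(100.0)

    def test_scales_linearly_with_error_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000) + 5
        e = rng.normal(size=1000)
        assert a.prd(x, x + 2 * e) == pytest.approx(2 * a.prd(x, x + e))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            a.prd(np.zeros(5), np.ones(5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            a.prd(np.ones(5), np.ones(6))


class TestLocalPRD:
    def test_error_between_beats_only_hits_out_region(self, record):
        ecg, annotations = record
        x2 = ecg.data.copy()
        masks = _region_masks(annotations, ecg.n_samples)
        x2[masks["out"]] += 50.0
        prds, _ = a.local_prd(ecg.data, x2, annotations)
        assert prds["P"] == 0.0 and prds["QRS"] == 0.0 and prds["T"] == 0.0
        assert prds["out"] > 0.0

    def test_regions_partition_the_record(self, record):
        ecg, annotations = record
        masks = _region_masks(annotations, ecg.n_samples)
        total = sum(m.sum() for m in masks.values())
        assert total == ecg.n_samples

    def test_regional_numerators_recombine_to_global(self, encoded):
        ecg, annotations, _, dec = encoded
        prds, _ = a.local_prd(ecg.data, dec.data, annotations)
        masks = _region_masks(annotations, ecg.n_samples)
        num = sum(
            (prds[r] / 100.0) ** 2 * np.sum(ecg.data[masks[r]] ** 2)
            for r in prds
        )
        global_prd = a.prd(ecg.data, dec.data)
        assert np.sqrt(num / np.sum(ecg.data**2)) * 100 == pytest.approx(
            global_prd, rel=1e-9
        )

    def test_empty_region_reported_absent(self):
        x = np.random.default_rng(0).normal(size=(1000, 1)) + 3
        prds, ptps = a.local_prd(x, x + 0.1, [])
        assert prds["P"] is None and ptps["P"] is None
        assert prds["out"] is not None

    def test_adc_lsb_is_2_44_microvolt(self):
        assert a.DEFAULT_RESOLUTION_UV == pytest.approx(2.44, abs=0.005)


class TestCompressionRatio:
    def test_uniform_stream_is_72kbps(self):
        assert a.uniform_stream_bps(12, 500.0, 12) == 72_000

    def _nu(self, policy, m, leads=12):
        return a.NonUniformECG(
            policy=policy,
            codes=np.full(m, 63),
            values_int=np.zeros((m, leads), dtype=int),
            lead_labels=[f"L{i}" for i in range(leads)],
            bit_depth=12,
            n_uniform=500 * 10,
        )

    def test_uniform_100hz_output_gives_4_8(self, policy):
        original = a.UniformECG(np.ones((5000, 12)), fs=500.0)
        nu = self._nu(policy, m=1000)  # 100 Hz for 10 s
        assert a.compression_ratio(original, nu) == pytest.approx(4.8)

    def test_identity_sampling_pays_side_channel(self, policy):
        original = a.UniformECG(np.ones((5000, 12)), fs=500.0)
        nu = self._nu(policy, m=5000)
        assert a.compression_ratio(original, nu) == pytest.approx(0.96)

    def test_file_payload_matches_formula(self, encoded, tmp_path):
        ecg, _, nu, _ = encoded
        cr_mem = a.compression_ratio(ecg, nu)
        n, m, L = ecg.n_samples, nu.n_points, ecg.n_leads
        cr_formula = (n * L * 12) / (m * L * 12 + m * 6)
        assert cr_mem == pytest.approx(cr_formula)

    def test_span_mismatch_rejected(self, policy):
        original = a.UniformECG(np.ones((100, 12)), fs=500.0)
        with pytest.raises(ValueError, match="span"):
            a.compression_ratio(original, self._nu(policy, m=50))


class TestFeatures:
    def test_rr_interval_matches_generator_period(self, record):
        ecg, annotations = record
        feats = a.extract_features_all(ecg, annotations)
        rr = np.array([f.rr_int_ms for f in feats])
        assert rr == pytest.approx(1000.0, abs=1.0)

    def test_qrs_duration_is_border_difference(self, record):
        ecg, annotations = record
        f = a.extract_features(ecg, annotations[0], rr_ms=1000.0)
        want = (annotations[0].qrs_end - annotations[0].qrs_on) / ecg.fs * 1000
        assert f.qrs_dur_ms == pytest.approx(want)

    def test_identical_beats_give_identical_features(self, record):
        ecg, annotations = record
        f1 = a.extract_features(ecg, annotations[3], rr_ms=1000.0)
        f2 = a.extract_features(ecg, annotations[3], rr_ms=1000.0)
        assert f1 == f2

    def test_morphology_classes_on_default_beat(self, record):
        ecg, annotations = record
        f = a.extract_features(ecg, annotations[0], rr_ms=1000.0)
        assert f.t_shape == "positive"
        assert f.p_shape == "positive"
        assert f.qrsp_amp_uv > 0 > f.qrsn_amp_uv
        assert f.qrs_peaks_no >= 1

    def test_annotation_outside_record_rejected(self, record):
        ecg, annotations = record
        bad = annotations[0].shifted(ecg.n_samples)
        with pytest.raises(ValueError, match="outside"):
            a.extract_features(ecg, bad, rr_ms=1000.0)


class TestWDD:
    def test_identical_features_give_zero(self, record):
        ecg, annotations = record
        f = a.extract_features(ecg, annotations[0], rr_ms=1000.0)
        assert a.wdd(f, f) == 0.0

    def test_single_categorical_mismatch(self, record):
        ecg, annotations = record
        f = a.extract_features(ecg, annotations[0], rr_ms=1000.0)
        other = "downsloping" if f.st_shape != "downsloping" else "horizontal"
        g = dataclasses.replace(f, st_shape=other)
        assert a.wdd(f, g) == pytest.approx(100 * 3 / 29.1)

    def test_all_unit_mismatches_reach_ceiling(self):
        lo = a.DiagnosticFeatures(*(0.0,) * 6, 0, False, False,
                                  "a", "a", "a", *(0.0,) * 6)
        hi = a.DiagnosticFeatures(*(10_000.0,) * 6, 9, True, True,
                                  "b", "b", "b", *(10_000.0,) * 6)
        assert a.wdd(lo, hi) == pytest.approx(100.0)

    def test_trace_of_printed_weights(self):
        # independent oracle: sum the published diagonal by hand
        printed = [2.5, 2.5, 1, 1, 2, 2, 1, 0.5, 0.1,
                   1.5, 1, 3, 1.5, 1.5, 1, 1, 3, 3]
        assert sum(printed) == pytest.approx(29.1)
        assert WDD_WEIGHTS.sum() == pytest.approx(29.1)

    def test_symmetric_in_arguments(self, record):
        ecg, annotations = record
        f = a.extract_features(ecg, annotations[0], rr_ms=1000.0)
        g = dataclasses.replace(f, t_amp_uv=f.t_amp_uv * 1.4,
                                qrs_dur_ms=f.qrs_dur_ms + 12)
        assert a.wdd(f, g) == pytest.approx(a.wdd(g, f))

    def test_bounded_between_zero_and_hundred(self, record):
        ecg, annotations = record
        feats = a.extract_features_all(ecg, annotations)
        for f, g in zip(feats[:-1], feats[1:]):
            assert 0.0 <= a.wdd(f, g) <= 100.0


class TestEstimateStream:
    def test_zero_relevance_floor(self, policy):
        tpl = a.MRFTemplate(values=np.array([1e-12] * 10),
                            landmarks=(1, 2, 3, 4, 5))
        assert a.estimate_stream(tpl, policy, sr=12) == pytest.approx(1200.0)

    def test_unit_mass_ceiling(self, policy):
        # bl * sum(values) == 1  ->  d = fs * sr = 6000 bps per lead
        vals = np.full(125, 0.25)  # 125 bins x 0.25 x 0.032 s = 1
        tpl = a.MRFTemplate(values=vals, landmarks=(1, 2, 3, 4, 5))
        assert tpl.bin_length_s * tpl.values.sum() == pytest.approx(1.0)
        assert a.estimate_stream(tpl, policy, sr=12) == pytest.approx(6000.0)

    def test_monotone_in_relevance_mass(self, policy):
        lo = a.MRFTemplate(values=np.full(20, 0.2), landmarks=(1, 2, 3, 4, 5))
        hi = a.MRFTemplate(values=np.full(20, 0.8), landmarks=(1, 2, 3, 4, 5))
        assert a.estimate_stream(hi, policy) > a.estimate_stream(lo, policy)


class TestBeurlingDensity:
    def test_uniform_2ms_grid_is_500_per_second(self):
        t = np.arange(0, 10, 0.002)
        assert a.beurling_density(t, 1.0) == pytest.approx(500.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.sets(st.integers(min_value=0, max_value=4999),
                   min_size=100, max_size=500))
    def test_removing_samples_never_increases_density(self, idx):
        t = np.arange(0, 10, 0.002)
        keep = np.ones(t.size, dtype=bool)
        keep[list(idx)] = False
        thinned = t[keep]
        assert a.beurling_density(thinned, 1.0) <= a.beurling_density(t, 1.0)

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValueError, match="window"):
            a.beurling_density(np.array([0.0, 0.5, 1.0]), 2.0)


class TestEvaluateRecord:
    def test_report_is_complete_and_serializable(self, encoded, tmp_path):
        ecg, annotations, nu, dec = encoded
        report = a.evaluate_record(ecg, dec, annotations, nu)
        assert report.prd_global > 0
        assert report.cr > 1
        assert report.wdd is not None and 0 <= report.wdd <= 100
        report.to_json(tmp_path / "r.json")
        text = report.summary()
        assert "compression ratio" in text and "WDD" in text
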