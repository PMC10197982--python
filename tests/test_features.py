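"""Beat detection, fiducial localisation and the 48-feature vector."""

import numpy as np
import pytest

from conftest import gaussian_beat
from ecgkalemia.errors import DelineationError, ValidationError
from ecgkalemia.features import (
    FEATURE_VECTOR_NAMES,
    BeatFiducials,
    compute_lead_features,
    delineate_beat,
    detect_r_peaks,
    extract_feature_vector,
)
from ecgkalemia.synthetic import (
    BeatTemplateParams,
    NoiseModel,
    WaveParams,
    default_template,
    generate_record,
    k_to_template,
)

FS = 500.0


def _beat_train_signal(template, fs=FS, duration=10.0, first_r=0.5, rr=1.0):
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros_like(t)
    r_times = np.arange(first_r, duration - 0.2, rr)
    for r in r_times:
        x += gaussian_beat(t, r, template)
    return t, x, r_times


class TestRPeakDetection:
    def test_60bpm_peaks_within_10ms(self, base_template):
        _, x, r_times = _beat_train_signal(base_template)
        peaks = detect_r_peaks(x, FS)
        assert peaks.size == r_times.size == 10
        np.testing.assert_allclose(peaks / FS, r_times, atol=0.010)

    def test_flat_signal_raises(self):
        with pytest.raises(DelineationError):
            detect_r_peaks(np.zeros(int(10 * FS)), FS)

    @pytest.mark.parametrize("scale", [0.5, 2.0])
    def test_amplitude_scaling_invariance(self, base_template, scale):
        _, x, _ = _beat_train_signal(base_template)
        np.testing.assert_array_equal(detect_r_peaks(x, FS),
                                      detect_r_peaks(scale * x, FS))

    def test_refractory_period_enforced(self, base_template):
        _, x, _ = _beat_train_signal(base_template)
        peaks = detect_r_peaks(x, FS)
        assert np.all(np.diff(peaks) >= int(0.2 * FS))


class TestDelineation:
    def test_fiducials_within_15ms_of_analytic_truth(self, base_template):
        _, x, r_times = _beat_train_signal(base_template)
        r_idx = int(round(r_times[3] * FS))
        fid = delineate_beat(x, FS, r_idx, rr_prev_s=1.0)
        tw = base_template.waves["T"]
        truth = {
            "t_peak": r_times[3] + tw.center_s,
            # tangent method on a Gaussian: onset/offset land at center -+ 2*width
            "t_onset": r_times[3] + tw.center_s - 2 * tw.width_s,
            "t_offset": r_times[3] + tw.center_s + 2 * tw.width_s,
            "s_trough": r_times[3] + base_template.waves["S"].center_s,
        }
        for name, true_t in truth.items():
            assert getattr(fid, name) / FS == pytest.approx(true_t, abs=0.015), name
        # QRS onset precedes the Q trough, QRS offset follows the S trough
        assert fid.q_onset / FS < r_times[3] + base_template.waves["Q"].center_s
        assert fid.s_offset >= fid.s_trough
        assert abs(fid.iso_level_mv) < 0.01

    def test_absent_t_wave_reported(self, base_template):
        waves = dict(base_template.waves)
        waves["T"] = WaveParams(1e-6, waves["T"].center_s, waves["T"].width_s)
        flat_t = BeatTemplateParams(waves=waves)
        _, x, r_times = _beat_train_signal(flat_t)
        with pytest.raises(DelineationError, match="T wave absent"):
            delineate_beat(x, FS, int(round(r_times[3] * FS)), 1.0)

    def test_edge_beat_rejected(self, base_template):
        _, x, r_times = _beat_train_signal(base_template)
        with pytest.raises(DelineationError):
            delineate_beat(x, FS, 10, rr_prev_s=1.0)

    def test_ordering_invariant_on_random_beats(self):
        rng = np.random.default_rng(42)
        base = default_template()
        for _ in range(100):
            waves = {
                name: WaveParams(
                    w.amp_mv * float(np.exp(rng.normal(0, 0.2))),
                    w.center_s, w.width_s * float(np.exp(rng.normal(0, 0.1))),
                )
                for name, w in base.waves.items()
            }
            tpl = BeatTemplateParams(waves=waves)
            _, x, r_times = _beat_train_signal(tpl, duration=3.0)
            fid = delineate_beat(x, FS, int(round(r_times[1] * FS)), 1.0)
            assert (fid.q_onset < fid.r_peak < fid.s_trough <= fid.s_offset
                    < fid.t_onset < fid.t_peak < fid.t_offset)


class TestLeadFeatures:
    def _triangle_fiducials(self, fs=1000.0):
        """Isoceles triangular T: peak 0.5 mV, base 0.2 s, on a flat beat."""
        n = int(2.0 * fs)
        x = np.zeros(n)
        t_on, t_pk, t_off = int(1.0 * fs), int(1.1 * fs), int(1.2 * fs)
        rise = np.linspace(0, 0.5, t_pk - t_on + 1)
        x[t_on:t_pk + 1] = rise
        x[t_pk:t_off + 1] = rise[::-1]
        # minimal synthetic QRS so the fiducial ordering holds
        q_on, r_pk, s_tr, s_off = int(0.5 * fs), int(0.52 * fs), int(0.54 * fs), int(0.56 * fs)
        x[r_pk] = 1.0
        x[s_tr] = -0.2
        fid = BeatFiducials(
            r_peak=r_pk, q_onset=q_on, s_offset=s_off, s_trough=s_tr,
            t_onset=t_on, t_peak=t_pk, t_offset=t_off,
            rr_prev_s=1.0, iso_level_mv=0.0,
        )
        return x, fs, fid

    def test_triangular_t_geometry(self):
        x, fs, fid = self._triangle_fiducials()
        lf = compute_lead_features(x, fs, fid)
        assert lf.t_left_slope == pytest.approx(5.0, rel=1e-6)
        assert lf.t_right_slope == pytest.approx(-5.0, rel=1e-6)
        assert lf.t_area == pytest.approx(0.05, rel=1e-3)
        assert lf.t_amp == pytest.approx(0.5)

    def test_unit_rr_makes_area_per_s_equal_area(self):
        x, fs, fid = self._triangle_fiducials()
        lf = compute_lead_features(x, fs, fid)
        assert lf.t_area_per_s == lf.t_area
        assert lf.r_area_per_s == lf.r_area
        assert lf.s_area_per_s == lf.s_area

    def test_gaussian_t_area_matches_fine_grid_integral(self, base_template):
        _, x, r_times = _beat_train_signal(base_template)
        r_idx = int(round(r_times[3] * FS))
        fid = delineate_beat(x, FS, r_idx, 1.0)
        lf = compute_lead_features(x, FS, fid)
        tw = base_template.waves["T"]
        analytic = tw.amp_mv * tw.width_s * np.sqrt(2 * np.pi)
        # the tangent bounds truncate the Gaussian at about +-2 sigma (~95%)
        assert lf.t_area == pytest.approx(analytic, rel=0.08)
        assert lf.t_amp == pytest.approx(tw.amp_mv, rel=0.02)


class TestFeatureVector:
    def test_48_finite_named_values(self, clean_record):
        fv = extract_feature_vector(clean_record)
        assert len(fv) == 48
        assert fv.names == FEATURE_VECTOR_NAMES
        assert np.all(np.isfinite(fv.values))

    def test_identical_beats_aggregate_to_per_beat_values(self, base_template):
        # a strictly periodic noise-free train: the median across beats
        # equals any single beat's features
        _, x, r_times = _beat_train_signal(base_template)
        r_idx = int(round(r_times[4] * FS))
        fid = delineate_beat(x, FS, r_idx, 1.0)
        single = compute_lead_features(x, FS, fid).as_array()
        per_beat = []
        for i in range(1, r_times.size):
            f = delineate_beat(x, FS, int(round(r_times[i] * FS)), 1.0)
            per_beat.append(compute_lead_features(x, FS, f).as_array())
        agg = np.median(np.vstack(per_beat), axis=0)
        np.testing.assert_allclose(agg, single, rtol=0.02, atol=5e-4)

    def test_amplitude_homogeneity(self, clean_record):
        fv1 = extract_feature_vector(clean_record)
        doubled = type(clean_record)(
            record_id="x2", fs=clean_record.fs,
            lead_names=clean_record.lead_names,
            signal=2.0 * clean_record.signal,
        )
        fv2 = extract_feature_vector(doubled)
        np.testing.assert_allclose(fv2.values, 2.0 * fv1.values,
                                   rtol=0.01, atol=1e-4)

    def test_missing_lead_rejected(self, clean_record):
        sub = type(clean_record)(
            record_id="sub", fs=clean_record.fs,
            lead_names=("V2", "V3"),
            signal=np.column_stack([clean_record.lead("V2"),
                                    clean_record.lead("V3")]),
        )
        with pytest.raises(ValidationError, match="V4"):
            extract_feature_vector(sub)

    def test_t_amp_monotone_in_true_amplitude(self):
        """Extracted T amplitude preserves the rank order of the generator's
        true T amplitude over >= 5 levels (Spearman rho = 1)."""
        t_amps = []
        trues = np.linspace(0.2, 0.7, 6)
        base = default_template()
        for a in trues:
            waves = dict(base.waves)
            waves["T"] = WaveParams(float(a), waves["T"].center_s,
                                    waves["T"].width_s)
            rec = generate_record(
                4.0, BeatTemplateParams(waves=waves),
                noise=NoiseModel.silent(), seed=5, duration_s=12.0, fs=FS,
            )
            t_amps.append(extract_feature_vector(rec).as_dict()["V2_t_amp"])
        assert np.all(np.diff(t_amps) > 0)

    def test_tented_t_at_high_potassium(self):
        """At high potassium the extracted T is taller and its base narrower
        than at the reference potassium (paired, noise-free)."""
        feats = {}
        for k in (4.0, 6.5):
            rec = generate_record(k, noise=NoiseModel.silent(), seed=6,
                                  duration_s=12.0, fs=FS)
            from ecgkalemia.features import detect_r_peaks as _det
            x = rec.lead("V2")
            peaks = _det(x, rec.fs)
            rr = float(np.diff(peaks).mean() / rec.fs)
            fid = delineate_beat(x, rec.fs, int(peaks[peaks.size // 2]), rr)
            feats[k] = (x[fid.t_peak] - fid.iso_level_mv,
                        (fid.t_offset - fid.t_onset) / rec.fs)
        assert feats[6.5][0] > feats[4.0][0]      # taller
        assert feats[6.5][1] < feats[4.0][1]      # narrower base
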