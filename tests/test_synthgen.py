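"""Simulator contracts: protocol constants, determinism, envelope consistency,
artifact locality."""

import numpy as np
import pytest

from oscibp.preprocess import lowpass_cuff_baseline
from oscibp.synthgen import (
    ARTIFACT_KINDS,
    ConfigurationError,
    RatioLink,
    SynthConfig,
    envelope_amplitude,
    generate_cohort,
    generate_recording,
    inject_artifact,
)


class TestProtocolConstants:
    def test_deflation_endpoints(self, clean_recording):
        rec, _ = clean_recording
        assert abs(rec.cp[0] - 180.0) < 2.0
        assert abs(rec.cp[-1] - 40.0) < 2.0

    def test_deflation_rate_in_band(self, clean_recording):
        """Least-squares slope of the low-passed pressure is 2-3 mmHg/s down."""
        rec, _ = clean_recording
        base = lowpass_cuff_baseline(rec.cp, rec.fs)
        trim = int(2 * rec.fs)
        t = rec.time[trim:-trim]
        slope = np.polyfit(t, base[trim:-trim], 1)[0]
        assert -3.0 <= slope <= -2.0

    def test_cohort_pressures_within_ranges(self):
        cfg = SynthConfig(n_recordings=200, seed=3, fs=100.0)
        sbps, dbps = [], []
        for i in range(cfg.n_recordings):
            rec, gt = generate_recording(cfg, i)
            sbps.append(gt.sbp)
            dbps.append(gt.dbp)
        assert min(sbps) >= 70.0 and max(sbps) <= 133.0
        assert min(dbps) >= 42.0 and max(dbps) <= 88.0

    def test_r_peaks_mark_beat_onsets(self, clean_recording):
        rec, gt = clean_recording
        rr = np.diff(rec.r_peaks) / rec.fs
        assert np.allclose(rr, 60.0 / gt.hr, atol=2.0 / rec.fs)


class TestDeterminismAndGroundTruth:
    def test_identical_seed_identical_output(self):
        cfg = SynthConfig(n_recordings=3, seed=11, fs=250.0)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for (ra, ga), (rb, gb) in zip(a, b):
            np.testing.assert_array_equal(ra.cp, rb.cp)
            np.testing.assert_array_equal(ra.r_peaks, rb.r_peaks)
            assert ga.sbp == gb.sbp and ga.sbpr == gb.sbpr

    def test_distinct_draws_differ(self):
        cfg = SynthConfig(seed=11, fs=250.0)
        _, g0 = generate_recording(cfg, 0)
        _, g1 = generate_recording(cfg, 1)
        assert g0.sbp != g1.sbp

    def test_envelope_consistency_at_reference_pressures(self):
        """env(SBP) = SBPR*MA and env(DBP) = DBPR*MA to 1e-9 relative."""
        cfg = SynthConfig(seed=5, sensor_noise_sd=0.0, fs=250.0)
        for i in range(10):
            _, gt = generate_recording(cfg, i)
            assert gt.envelope(gt.sbp) == pytest.approx(gt.sbpr * gt.ma, rel=1e-9)
            assert gt.envelope(gt.dbp) == pytest.approx(gt.dbpr * gt.ma, rel=1e-9)
            assert gt.dbp < gt.map < gt.sbp

    def test_zero_link_noise_gives_exact_linear_ratio(self):
        """With no link noise both ratios are exact affine functions of the
        same latent asymmetry, so they are perfectly collinear."""
        link = RatioLink(noise_sd=0.0)
        cfg = SynthConfig(seed=5, ratio_link=link, fs=250.0)
        for i in range(8):
            _, gt = generate_recording(cfg, i)
            a_from_sbpr = (gt.sbpr - link.sbpr_intercept) / link.sbpr_slope
            a_from_dbpr = (gt.dbpr - link.dbpr_intercept) / link.dbpr_slope
            assert a_from_sbpr == pytest.approx(a_from_dbpr, abs=1e-9)
            assert -1.0 - 1e-9 <= a_from_sbpr <= 1.0 + 1e-9

    def test_envelope_peak_is_at_map(self):
        _, gt = generate_recording(SynthConfig(seed=7, fs=250.0), 0)
        grid = np.linspace(gt.dbp - 20, gt.sbp + 20, 2001)
        assert grid[np.argmax(gt.envelope(grid))] == pytest.approx(gt.map, abs=0.05)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_recordings": 0},
            {"cp_start": 120.0},          # below SBP range maximum
            {"cp_end": 60.0},             # above DBP range minimum
            {"fs": 1.0},                  # under twice max heart rate
            {"sbp_range": (133.0, 70.0)},
            {"artifact_spec": (("wobble", 10.0, 1.0),)},
        ],
    )
    def test_infeasible_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SynthConfig(**kwargs)


class TestArtifacts:
    @pytest.mark.parametrize("kind", ARTIFACT_KINDS)
    def test_zero_magnitude_is_identity(self, clean_recording, kind):
        rec, _ = clean_recording
        out = inject_artifact(rec, kind, at=20.0, magnitude=0.0)
        np.testing.assert_array_equal(out.cp, rec.cp)

    @pytest.mark.parametrize("kind", ARTIFACT_KINDS)
    def test_locality_outside_interval(self, clean_recording, kind):
        rec, _ = clean_recording
        out = inject_artifact(rec, kind, at=20.0, magnitude=2.0, seed=3)
        (prov,) = out.meta["artifacts"]
        i0 = int(np.floor(prov["t0"] * rec.fs))
        i1 = int(np.ceil(prov["t1"] * rec.fs))
        np.testing.assert_array_equal(out.cp[:i0], rec.cp[:i0])
        np.testing.assert_array_equal(out.cp[i1 + 1 :], rec.cp[i1 + 1 :])
        assert np.any(out.cp[i0 : i1 + 1] != rec.cp[i0 : i1 + 1])

    def test_pressure_bump_rises_during_deflation(self, clean_recording):
        rec, _ = clean_recording
        out = inject_artifact(rec, "pressure-bump", at=20.0, magnitude=8.0, duration=0.5)
        i0, i1 = int(20.0 * rec.fs), int(20.5 * rec.fs)
        assert np.max(np.diff(out.cp[i0:i1])) > 0

    def test_amplitude_spike_multiplies_pulse_height(self, clean_recording):
        """A x1.8 spike leaves the pulse more than 1.5x its neighbours."""
        from oscibp.preprocess import detrend_oscillometric, segment_pulses

        rec, _ = clean_recording
        at = rec.duration / 2
        out = inject_artifact(rec, "amplitude-spike", at=at, magnitude=0.8)
        omw = detrend_oscillometric(out.cp, out.fs)
        pulses = segment_pulses(omw, out)
        k = next(i for i, p in enumerate(pulses) if p.start / rec.fs <= at < p.end / rec.fs)
        height = pulses[k].peak_value - pulses[k].bottom_value
        neigh = [pulses[i].peak_value - pulses[i].bottom_value
                 for i in (k - 2, k - 1, k + 1, k + 2)]
        assert height > 1.5 * np.median(neigh)

    def test_unknown_kind_rejected(self, clean_recording):
        rec, _ = clean_recording
        with pytest.raises(ValueError, match="unknown artifact kind"):
            inject_artifact(rec, "teleport", at=10.0, magnitude=1.0)


def test_envelope_amplitude_two_sided():
    amp = envelope_amplitude(np.array([80.0, 100.0, 120.0]), 2.0, 100.0, 10.0, 20.0)
    assert amp[1] == pytest.approx(2.0)
    assert amp[0] == pytest.approx(2.0 * np.exp(-4.0))   # left width 10
    assert amp[2] == pytest.approx(2.0 * np.exp(-1.0))   # right width 20
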