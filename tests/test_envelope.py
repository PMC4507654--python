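"""Envelope construction and spline fit, checked against an independently
coded tridiagonal natural-spline oracle."""

import numpy as np
import pytest

from oscibp.envelope import OWE, EnvelopeTruncatedWarning, build_owe, fit_envelope, fit_spline
from oscibp.preprocess import Pulse


def natural_spline_oracle(x, y, xq):
    """Independent natural cubic spline: solve the tridiagonal system for the
    second derivatives, then evaluate piecewise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    h = np.diff(x)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2.0 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    m = np.linalg.solve(A, rhs)  # second derivatives at the knots
    out = []
    for q in np.atleast_1d(xq):
        i = min(np.searchsorted(x, q, side="right") - 1, n - 2)
        i = max(i, 0)
        hi = h[i]
        a, b = x[i + 1] - q, q - x[i]
        out.append(
            (m[i] * a**3 + m[i + 1] * b**3) / (6 * hi)
            + (y[i] / hi - m[i] * hi / 6) * a
            + (y[i + 1] / hi - m[i + 1] * hi / 6) * b
        )
    return np.array(out)


def pulses_from_knots(cps, amps, rr=0.8):
    """Pulse list whose knots reproduce (cps, amps) in deflation order."""
    out = []
    for i, (cp, amp) in enumerate(zip(cps, amps)):
        s = int(i * rr * 1000)
        out.append(
            Pulse(
                start=s, end=int((i + 1) * rr * 1000), peak_value=amp / 2,
                bottom_value=-amp / 2, pk2bt_prev=amp, pk2bt_next=amp,
                cp_at_peak=cp, t_peak=(i + 0.5) * rr,
            )
        )
    return out


class TestBuildOwe:
    def test_one_knot_per_pulse_sorted_by_pressure(self):
        cps = np.array([150.0, 140, 130, 120, 110, 100, 90, 80, 70, 60])
        amps = np.linspace(0.5, 2.5, 10)
        owe = build_owe(pulses_from_knots(cps, amps))
        assert owe.cp_knots.size == 10
        np.testing.assert_array_equal(owe.cp_knots, np.sort(cps))
        np.testing.assert_allclose(owe.amp_knots, amps[::-1])

    def test_duplicate_pressures_merged_by_mean(self):
        cps = [150.0, 140, 130, 130, 120, 110]
        amps = [1.0, 2.0, 3.0, 5.0, 2.0, 1.0]
        pulses = pulses_from_knots(cps, amps)
        # same cp, different time: rebuild times strictly increasing
        owe = build_owe(pulses)
        assert owe.cp_knots.size == 5
        i = int(np.flatnonzero(owe.cp_knots == 130.0)[0])
        assert owe.amp_knots[i] == pytest.approx(4.0)

    def test_knot_amplitudes_track_ground_truth_envelope(self):
        """With heart rate at the filter centre and no noise, knot heights
        match the generator envelope (gain-matched, relative to MA) to 2%."""
        from oscibp.preprocess import detrend_oscillometric, segment_pulses
        from oscibp.synthgen import SynthConfig, generate_recording

        cfg = SynthConfig(seed=9, sensor_noise_sd=0.0, hr_range=(95.0, 95.0))
        rec, gt = generate_recording(cfg, 0)
        omw = detrend_oscillometric(rec.cp, rec.fs)
        pulses = segment_pulses(omw, rec)[3:-3]
        owe = build_owe(pulses)
        truth = gt.envelope(owe.cp_knots)
        scale = owe.amp_knots.max() / truth.max()
        assert np.max(np.abs(owe.amp_knots - scale * truth)) / (scale * truth.max()) <= 0.02

    def test_too_few_or_unordered_pulses_rejected(self):
        with pytest.raises(ValueError, match="at least four"):
            build_owe(pulses_from_knots([150.0, 140, 130], [1, 2, 1]))
        pulses = pulses_from_knots([150.0, 140, 130, 120], [1, 2, 2, 1])
        shuffled = [pulses[1], pulses[0], pulses[2], pulses[3]]
        with pytest.raises(ValueError, match="increasing"):
            build_owe(shuffled)


class TestSpline:
    def test_interpolates_knots_exactly(self):
        rng = np.random.default_rng(4)
        cps = np.sort(rng.uniform(50, 160, 12))
        amps = rng.uniform(0.5, 3.0, 12)
        owe = fit_spline(OWE(cp_knots=cps, amp_knots=amps, t_knots=(160 - cps) / 2.5))
        np.testing.assert_allclose(owe(cps), amps, atol=1e-9)

    def test_matches_tridiagonal_oracle(self):
        rng = np.random.default_rng(5)
        cps = np.sort(rng.uniform(50, 160, 9))
        amps = rng.uniform(0.5, 3.0, 9)
        owe = fit_spline(OWE(cp_knots=cps, amp_knots=amps, t_knots=(160 - cps) / 2.5))
        xq = rng.uniform(cps[0], cps[-1], 10)
        np.testing.assert_allclose(owe(xq), natural_spline_oracle(cps, amps, xq), rtol=1e-8)

    def test_symmetric_triangle_apex_found(self, triangular_owe):
        assert triangular_owe.map == pytest.approx(100.0, abs=0.1)
        assert triangular_owe.ma == pytest.approx(3.0, abs=0.05)

    def test_map_recovered_from_clean_recording(self, processed_clean, clean_recording):
        _, gt = clean_recording
        assert processed_clean.owe.map == pytest.approx(gt.map, abs=2.0)

    def test_equal_maxima_tie_breaks_to_higher_pressure(self):
        cp = np.array([60.0, 80, 100, 120, 140])
        amp = np.array([1.0, 3.0, 2.0, 3.0, 1.0])
        owe = fit_spline(OWE(cp_knots=cp, amp_knots=amp, t_knots=(140 - cp) / 2.5))
        assert owe.map > 100.0

    def test_apex_at_first_knot_sets_truncation_warning(self):
        cp = np.array([100.0, 110, 120, 130, 140])
        amp = np.array([3.0, 2.5, 1.8, 1.0, 0.4])
        with pytest.warns(EnvelopeTruncatedWarning):
            owe = fit_spline(OWE(cp_knots=cp, amp_knots=amp, t_knots=(140 - cp) / 2.5))
        assert owe.truncated

    def test_evaluation_outside_domain_rejected(self, triangular_owe):
        with pytest.raises(ValueError, match="domain"):
            triangular_owe(150.0)


class TestOutlierRemovalEffect:
    def test_removal_tightens_envelope_fit(self):
        """Spline error against the true envelope shrinks once spiked pulses
        are removed."""
        from oscibp.artifacts import flag_outlier_pulses, remove_outliers
        from oscibp.experiments import inject_cohort_artifacts
        from oscibp.preprocess import detrend_oscillometric, segment_pulses
        from oscibp.synthgen import SynthConfig, generate_recording

        cfg = SynthConfig(seed=13, sensor_noise_sd=0.0)
        rec, gt = generate_recording(cfg, 0)
        (spiked,) = inject_cohort_artifacts([rec], seed=13, n_bumps=0)
        omw = detrend_oscillometric(spiked.cp, spiked.fs)
        pulses = segment_pulses(omw, spiked)

        with_removal = fit_envelope(
            remove_outliers(pulses, flag_outlier_pulses(pulses), [])
        )
        without_removal = fit_envelope(pulses)
        lo = max(with_removal.cp_min, without_removal.cp_min)
        hi = min(with_removal.cp_max, without_removal.cp_max)
        grid = np.linspace(lo, hi, 400)
        scale = gt.envelope(grid).max()

        def err(owe):
            return np.max(np.abs(owe(grid) / owe.ma - gt.envelope(grid) / scale))

        assert err(with_removal) < err(without_removal)
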