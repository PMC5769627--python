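"""Fourier periodicity pipeline: thresholding, ray sampling, dominant periods."""

import numpy as np
import pytest

from rdpi.periodicity import (
    PeriodSet,
    RadialSignal,
    compare_period_sets,
    detrend_smooth,
    dominant_period,
    field_periods,
    null_aperiodic_fraction,
    sample_radii,
    threshold_field,
)
from rdpi.synthetic import PeriodicFieldSpec, generate_periodic_field
from conftest import disk_snapshot


class TestThresholdField:
    def test_constant_field_unchanged(self):
        # SD = 0, so no pixel is strictly lower than mean + SD
        snap = disk_snapshot(lambda r, th: np.full_like(r, 2.0))
        out = threshold_field(snap)
        assert np.allclose(out.a[out.mask], 2.0)

    def test_two_valued_field_arithmetic(self):
        # 90% zeros / 10% tens: mean 1, sd 3, cutoff 4: both values survive
        # (zeros are already zero, tens stay)
        rng = np.random.default_rng(0)
        snap = disk_snapshot(lambda r, th: np.zeros_like(r), grid=201, radius_px=95)
        vals = np.where(rng.random(snap.a.shape) < 0.1, 10.0, 0.0)
        snap.a[snap.mask] = vals[snap.mask]
        inside = snap.a[snap.mask]
        cut = inside.mean() + inside.std()
        out = threshold_field(snap)
        expect = np.where(inside < cut, 0.0, inside)
        assert np.array_equal(out.a[out.mask], expect)

    def test_statistics_over_mask_only(self):
        # identical in-mask values but different grid size must give same cut
        s1 = disk_snapshot(lambda r, th: r, grid=101, radius_px=45)
        s2 = disk_snapshot(lambda r, th: r, grid=151, radius_px=45)
        f1, f2 = threshold_field(s1), threshold_field(s2)
        assert np.isclose(np.nanmax(f1.a), np.nanmax(f2.a))


class TestSampleRadii:
    def test_thirty_degree_step_gives_twelve_signals(self):
        snap = disk_snapshot(lambda r, th: r)
        assert len(sample_radii(snap, angle_step_deg=30.0)) == 12

    def test_rotationally_symmetric_field_identical_signals(self):
        snap = disk_snapshot(lambda r, th: np.sin(r / 6.0) + 1.5, grid=201, radius_px=95)
        sigs = sample_radii(snap, angle_step_deg=30.0)
        ref = sigs[0].samples
        for s in sigs[1:]:
            # bilinear interpolation error differs between axis-aligned and
            # oblique rays; agreement is to interpolation accuracy only
            assert np.max(np.abs(s.samples - ref)) < 3e-2 * np.max(np.abs(ref))

    def test_ray_values_match_manual_bilinear_interpolation(self):
        snap = disk_snapshot(lambda r, th: r * np.cos(th) ** 2 + 1.0,
                             grid=101, radius_px=45)
        sig = sample_radii(snap, angle_step_deg=90.0, n_samples=64)[1]  # 90 degrees
        a = np.where(snap.mask, snap.a, 0.0)
        c = (101 - 1) / 2.0
        rows, cols = np.nonzero(snap.mask)
        radius = np.hypot(rows - rows.mean(), cols - cols.mean()).max()
        tt = np.linspace(0, radius, 64)
        manual = np.empty(64)
        for k, t in enumerate(tt):  # ray along +y: row varies, col fixed
            rr, cc = c + t, c
            r0, c0 = int(np.floor(rr)), int(np.floor(cc))
            fr, fc = rr - r0, cc - c0
            manual[k] = ((1 - fr) * (1 - fc) * a[r0, c0]
                         + fr * (1 - fc) * a[min(r0 + 1, 100), c0]
                         + (1 - fr) * fc * a[r0, min(c0 + 1, 100)]
                         + fr * fc * a[min(r0 + 1, 100), min(c0 + 1, 100)])
        assert np.max(np.abs(sig.samples - manual)) < 1e-6

    def test_edge_exclusion_shortens_and_renormalizes(self):
        snap = disk_snapshot(lambda r, th: r)
        full = sample_radii(snap, exclude_edge_frac=0.0)[0]
        cut = sample_radii(snap, exclude_edge_frac=0.2)[0]
        assert len(cut.samples) == len(full.samples)
        assert cut.samples.max() < full.samples.max()

    def test_angle_step_must_divide_360(self):
        snap = disk_snapshot(lambda r, th: r)
        with pytest.raises(ValueError, match="divide 360"):
            sample_radii(snap, angle_step_deg=50.0)


class TestDetrendSmooth:
    def test_constant_signal_becomes_zero(self):
        sig = RadialSignal(0.0, np.full(64, 3.3), "model")
        out = detrend_smooth(sig, sigma=3.0)
        assert np.allclose(out.samples, 0.0)

    def test_output_mean_is_zero(self):
        rng = np.random.default_rng(1)
        for order in ("detrend_first", "smooth_first"):
            sig = RadialSignal(0.0, rng.random(128) * 7, "experiment")
            out = detrend_smooth(sig, order=order)
            assert abs(out.samples.mean()) < 1e-10 * np.abs(sig.samples).max()

    def test_delta_response_matches_analytic_gaussian_kernel(self):
        sigma = 3.0
        n = 129
        x = np.zeros(n)
        x[n // 2] = 1.0
        out = detrend_smooth(RadialSignal(0.0, x, "experiment"), sigma=sigma)
        radius = int(4 * sigma + 0.5)
        j = np.arange(-radius, radius + 1)
        kernel = np.exp(-j * j / (2 * sigma * sigma))
        kernel /= kernel.sum()
        got = out.samples[n // 2 - radius:n // 2 + radius + 1] + 1.0 / n  # undo detrend
        assert np.max(np.abs(got - kernel)) < 1e-8

    def test_oversized_sigma_rejected(self):
        with pytest.raises(ValueError):
            detrend_smooth(RadialSignal(0.0, np.ones(32), "model"), sigma=40.0)


class TestDominantPeriod:
    @staticmethod
    def sig(vals):
        return RadialSignal(0.0, np.asarray(vals, float), "model")

    def test_four_cycle_sinusoid(self):
        r = np.linspace(0, 1, 256, endpoint=False)
        p = dominant_period(self.sig(np.sin(2 * np.pi * 4 * r)))
        assert abs(p - 0.25) <= 1 / (4 - 0.25) - 0.25  # one frequency-bin width

    def test_constant_gives_no_period_sentinel(self):
        assert dominant_period(self.sig(np.full(64, 1.7))) == np.inf

    def test_linear_ramp_classified_aperiodic(self):
        r = np.linspace(0, 1, 256, endpoint=False)
        assert dominant_period(self.sig(r)) >= 1.0

    def test_affine_intensity_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.random(128)
        s = detrend_smooth(self.sig(base), sigma=3.0)
        s2 = detrend_smooth(self.sig(2.5 * base + 7.0), sigma=3.0)
        assert dominant_period(s) == dominant_period(s2)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            dominant_period(self.sig(np.arange(5)))


class TestFieldPeriods:
    def test_noise_free_four_cycle_disk(self):
        snap = generate_periodic_field(PeriodicFieldSpec(n_cycles=4, noise_sd=0.0))
        ps = field_periods(snap, source="experiment")
        bin_width_period = 1 / (4 - 0.25) - 0.25
        assert np.all(np.abs(ps.periods - 0.25) <= bin_width_period)

    def test_rotation_by_angle_step_preserves_period_multiset(self):
        def fn(offset):
            return lambda r, th: 1.0 + 0.5 * np.sin(2 * np.pi * 3 * r / 95.0) * (
                1 + 0.3 * np.cos(2 * (th - offset)))

        a = field_periods(disk_snapshot(fn(0.0), grid=201, radius_px=95), "experiment")
        b = field_periods(disk_snapshot(fn(np.deg2rad(30)), grid=201, radius_px=95),
                          "experiment")
        assert np.allclose(np.sort(a.periods), np.sort(b.periods))

    def test_recovered_period_converges_with_sampling(self):
        # finer angular check: recovered period approaches 1/k within one bin
        for k in (2, 6):
            snap = generate_periodic_field(PeriodicFieldSpec(n_cycles=k, noise_sd=0.0))
            ps = field_periods(snap, source="experiment")
            assert np.median(np.abs(ps.periods - 1 / k)) <= 1 / (k - 0.25) - 1 / k

    def test_null_fraction_consistent_with_simulated_null(self):
        # the detector's false-periodicity rate on structureless noise is
        # calibrated by its own null simulation; two independent batches
        # must agree within sampling error
        ref = null_aperiodic_fraction(n_fields=25, source="model", seed=100)
        new = null_aperiodic_fraction(n_fields=25, source="model", seed=200)
        se = np.sqrt(ref.var() / 25 + new.var() / 25)
        assert abs(ref.mean() - new.mean()) < 4 * se + 0.05


class TestComparePeriodSets:
    def test_identical_sets_ks_zero(self):
        a = np.array([0.2, 0.25, 0.3, 0.4])
        out = compare_period_sets(a, a.copy())
        assert out["ks_D"] == 0.0

    def test_disjoint_supports_significant(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 0.3, 20)
        b = rng.uniform(0.6, 0.9, 20)
        out = compare_period_sets(a, b)
        assert out["mwu_p"] < 0.01 and out["ks_p"] < 0.01

    def test_mwu_statistic_matches_pairwise_count(self):
        a = np.array([0.2, 0.5, 0.5, 0.9])
        b = np.array([0.1, 0.5, 0.6])
        out = compare_period_sets(a, b)
        wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert out["mwu_U"] == wins

    def test_insufficient_periods_rejected(self):
        with pytest.raises(ValueError):
            compare_period_sets(np.array([0.1, 0.2]), np.array([0.1, 0.2, 0.3]))

    def test_infinite_periods_excluded(self):
        ps = PeriodSet(periods=np.array([0.2, 0.3, 0.4, np.inf]),
                       angles_deg=np.arange(4) * 90.0)
        assert len(ps.finite) == 3
        assert ps.aperiodic_fraction() == 0.25
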