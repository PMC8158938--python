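"""OBRIR assembly, configuration transforms, loudness equalization, levels."""

import numpy as np
import pytest

from echowall import auralize, fdtd
from echowall.synthetic_data import make_fixture_filters


def _toy_bundle(rate=48_000.0, n=256, d_dir=10, d_ref=60, a_ref=0.3):
    direct = np.zeros(n)
    direct[d_dir] = 1.0
    reflected = np.zeros(n)
    reflected[d_ref] = a_ref
    return fdtd.RIRBundle(
        total=direct + reflected, direct=direct, reflected=reflected,
        rate=rate, window_length=n / rate, first_reflection_time=d_ref / rate,
        texture="toy", distance=0.81,
    )


class TestAssemble:
    def test_identity_filters_pass_through(self):
        bundle = _toy_bundle(a_ref=0.0)
        obrir = auralize.assemble_obrir(bundle, auralize.HeadFilters.identity())
        np.testing.assert_allclose(obrir.left[: len(bundle.direct)], bundle.direct)
        np.testing.assert_allclose(obrir.left, obrir.right)

    def test_delay_filter_convolution_oracle(self):
        """Impulse components through pure-delay filters: two impulses at the
        summed delays, by direct summation of the convolution."""
        bundle = _toy_bundle(d_dir=10, d_ref=60, a_ref=0.5)
        d1, d2 = 7, 13
        obtf = np.zeros(32); obtf[d1] = 1.0
        hrtf = np.zeros(32); hrtf[d2] = 1.0
        filters = auralize.HeadFilters(obtf=obtf, hrtf_left=hrtf, hrtf_right=hrtf)
        obrir = auralize.assemble_obrir(bundle, filters)
        expected_direct = 10 + d1
        expected_echo = 60 + d2
        assert obrir.direct[0, expected_direct] == pytest.approx(1.0)
        assert obrir.reflected[0, expected_echo] == pytest.approx(0.5)
        assert np.count_nonzero(obrir.left) == 2

    def test_linearity(self, flat_near, fixture_filters):
        *_, bundle = flat_near
        from dataclasses import replace
        one = auralize.assemble_obrir(bundle, fixture_filters)
        two = auralize.assemble_obrir(
            replace(bundle, total=2 * bundle.total, direct=2 * bundle.direct, reflected=2 * bundle.reflected),
            fixture_filters,
        )
        np.testing.assert_array_equal(two.direct, 2.0 * one.direct)
        np.testing.assert_array_equal(two.reflected, 2.0 * one.reflected)


class TestConfigurations:
    def test_rdld_plus6_is_exact(self, flat_near, fixture_filters):
        *_, bundle = flat_near
        obrir = auralize.assemble_obrir(bundle, fixture_filters)
        boosted = auralize.apply_configuration(obrir, "rdld_plus6")
        assert auralize.rdld_db(boosted) - auralize.rdld_db(obrir) == pytest.approx(6.0, abs=1e-9)
        np.testing.assert_array_equal(boosted.direct, obrir.direct)

    def test_normal_is_identity(self):
        obrir = auralize.assemble_obrir(_toy_bundle(), auralize.HeadFilters.identity())
        same = auralize.apply_configuration(obrir, "normal")
        np.testing.assert_array_equal(same.direct, obrir.direct)
        np.testing.assert_array_equal(same.reflected, obrir.reflected)

    def test_reflections_only_zeroes_direct(self):
        obrir = auralize.assemble_obrir(_toy_bundle(), auralize.HeadFilters.identity())
        echo = auralize.apply_configuration(obrir, "reflections_only")
        assert not echo.direct.any()
        assert echo.reflected.any()

    def test_reflections_only_of_silent_echo_is_degenerate(self):
        obrir = auralize.assemble_obrir(_toy_bundle(a_ref=0.0), auralize.HeadFilters.identity())
        echo = auralize.apply_configuration(obrir, "reflections_only")
        assert echo.is_degenerate

    def test_unknown_mode_raises(self):
        obrir = auralize.assemble_obrir(_toy_bundle(), auralize.HeadFilters.identity())
        with pytest.raises(ValueError, match="unknown"):
            auralize.apply_configuration(obrir, "louder")

    def test_fixture_filters_give_negative_rdld(self, flat_near, fixture_filters):
        """Mouth-to-ear direct path louder than the wall echo: RDLD < 0 dB."""
        *_, bundle = flat_near
        obrir = auralize.assemble_obrir(bundle, fixture_filters)
        assert auralize.rdld_db(obrir) < 0.0


class TestEqualize:
    def test_bisection_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2048)
        metric = auralize.AWeightedExposure()
        gains = auralize.equalize_set([x, 0.5 * x], 48_000.0, metric=metric, tol=1e-6)
        # energy metric is gain-quadratic, so the closed-form gain is 2
        assert gains[0] == pytest.approx(1.0)
        assert gains[1] == pytest.approx(2.0, rel=1e-4)

    def test_identical_inputs_unit_gains(self):
        x = np.sin(np.linspace(0, 100, 4096))
        gains = auralize.equalize_set([x, x.copy(), x.copy()], 48_000.0)
        np.testing.assert_allclose(gains, 1.0)

    def test_spread_below_tolerance_and_order_invariance(self):
        rng = np.random.default_rng(2)
        sigs = [a * rng.standard_normal(4096) for a in (1.0, 0.3, 0.7)]
        metric = auralize.StevensLoudness()
        tol = 1e-5
        gains = auralize.equalize_set(sigs, 48_000.0, metric=metric, tol=tol)
        vals = [metric(g * s, 48_000.0) for g, s in zip(gains, sigs)]
        assert (max(vals) - min(vals)) / max(vals) < 2 * tol
        perm = [2, 0, 1]
        gains_perm = auralize.equalize_set([sigs[i] for i in perm], 48_000.0, metric=metric, tol=tol)
        np.testing.assert_allclose(gains_perm, gains[perm], rtol=1e-6)

    def test_silent_input_raises(self):
        with pytest.raises(ValueError, match="silent"):
            auralize.equalize_set([np.ones(64), np.zeros(64)], 48_000.0)


class TestLevels:
    def test_a_weighted_sel_against_iir_oracle(self):
        """Frequency-domain A-weighting agrees with an independent
        time-domain IIR A-filter (bilinear transform of the analog poles,
        run oversampled to dodge warping) within 0.1 dB on 1 s of noise."""
        from scipy import signal as sps

        rng = np.random.default_rng(3)
        rate = 48_000.0
        x = rng.standard_normal(int(rate))
        cal = auralize.Calibration()
        sel = auralize.sound_exposure_level(x, rate, cal)
        up = 4
        b, a = auralize.a_weighting_coefficients(rate * up)
        x_up = sps.resample_poly(x * cal.pascal_per_unit, up, 1)
        pa = sps.lfilter(b, a, x_up)
        energy = np.sum(pa**2) / (rate * up)
        oracle = 10 * np.log10(energy / auralize.REFERENCE_PRESSURE**2)
        assert sel == pytest.approx(oracle, abs=0.1)

    def test_session_calibration_hits_51_dba(self, default_click, fixture_filters, flat_near):
        *_, bundle = flat_near
        cal = auralize.Calibration()
        obrir = auralize.assemble_obrir(bundle, fixture_filters)
        reference = np.convolve(obrir.direct[0], default_click.samples)
        gain = auralize.session_gain(reference, default_click.rate, cal)
        assert auralize.sound_exposure_level(gain * reference, default_click.rate, cal) == pytest.approx(51.0, abs=1e-6)

    def test_zero_obrir_gives_zero_stimulus(self, default_click):
        obrir = auralize.assemble_obrir(_toy_bundle(a_ref=0.0), auralize.HeadFilters.identity())
        silent = auralize.apply_configuration(obrir, "reflections_only")
        stim = auralize.auralize_stimulus(silent, default_click, auralize.Calibration(), gain=0.01)
        assert not stim.left.any() and not stim.right.any()

    def test_stimulus_linearity_in_click(self, default_click):
        obrir = auralize.assemble_obrir(_toy_bundle(), auralize.HeadFilters.identity())
        cal = auralize.Calibration()
        a = auralize.auralize_stimulus(obrir, default_click, cal, gain=0.01)
        half = type(default_click)(
            samples=default_click.samples * 0.5, rate=default_click.rate,
            peak_frequency=default_click.peak_frequency,
            duration_26db=default_click.duration_26db, tail_32db=default_click.tail_32db,
        )
        b = auralize.auralize_stimulus(obrir, half, cal, gain=0.01)
        np.testing.assert_allclose(b.left, 0.5 * a.left, atol=1e-15)

    def test_clipping_raises(self, default_click):
        obrir = auralize.assemble_obrir(_toy_bundle(), auralize.HeadFilters.identity())
        with pytest.raises(ValueError, match="clips"):
            auralize.auralize_stimulus(obrir, default_click, auralize.Calibration(), gain=1e3)


class TestHeadFilters:
    def test_fixture_determinism(self):
        a = make_fixture_filters(seed=4)
        b = make_fixture_filters(seed=4)
        np.testing.assert_array_equal(a.obtf, b.obtf)
        np.testing.assert_array_equal(a.hrtf_left, b.hrtf_left)

    def test_save_load_roundtrip(self, fixture_filters, tmp_path):
        fixture_filters.save(tmp_path)
        again = auralize.HeadFilters.load(tmp_path)
        np.testing.assert_allclose(again.obtf, fixture_filters.obtf, atol=1e-7)
        assert again.rate == fixture_filters.rate
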