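"""Freezing-spectrum derivation, binning, knee detection and T_char,50."""

import math

import numpy as np
import pytest

from inproice.spectra import (
    AssayConditions,
    BinnedSpectrum,
    FreezingAssay,
    KneeConfig,
    NucleationSpectrum,
    detect_activity_classes,
    find_knee,
    frozen_fraction_curve,
    merge_and_bin,
    nn_per_molecule,
    spectrum_from_assay,
    t_char_50,
)

COND = AssayConditions(c_m=1e-3, droplet_volume_l=5.24e-10, molar_mass=6.0e4)


def _assay(temps, n_unfrozen=0, cond=COND):
    return FreezingAssay(cond, np.asarray(temps, dtype=float), n_unfrozen)


class TestFrozenFraction:
    def test_simple_counting(self):
        temps = np.concatenate([np.linspace(-5, -10, 45), np.linspace(-20, -25, 45)])
        assay = _assay(temps)
        assert frozen_fraction_curve(assay, [-15.0])[0] == pytest.approx(0.5)
        assert frozen_fraction_curve(assay, [-1.0])[0] == 0.0
        assert frozen_fraction_curve(assay, [-30.0])[0] == 1.0

    def test_matches_indicator_sum_oracle(self):
        rng = np.random.default_rng(42)
        temps = rng.uniform(-30, -5, size=200)
        assay = _assay(temps, n_unfrozen=17)
        grid = rng.uniform(-35, -2, size=25)
        expected = np.array([np.sum(temps >= t) / 217 for t in grid])
        np.testing.assert_allclose(frozen_fraction_curve(assay, grid), expected)

    def test_unfrozen_droplets_dilute_fraction(self):
        a1 = _assay([-10.0] * 10)
        a2 = _assay([-10.0] * 10, n_unfrozen=10)
        assert frozen_fraction_curve(a1, [-10.0])[0] == 1.0
        assert frozen_fraction_curve(a2, [-10.0])[0] == 0.5


class TestNnPerMolecule:
    def test_zero_at_zero_fraction(self):
        assert nn_per_molecule(0.0, COND) == 0.0

    def test_hand_value(self):
        # molecules per droplet = 1e-3 * 5.24e-10 * 6.02214076e23 / 6e4 ~ 5.26e6
        lam = 1e-3 * 5.24e-10 * 6.02214076e23 / 6.0e4
        assert COND.molecules_per_droplet == pytest.approx(lam)
        assert nn_per_molecule(0.5, COND) == pytest.approx(math.log(2) / lam)
        assert nn_per_molecule(0.5, COND) == pytest.approx(1.32e-7, rel=0.01)

    def test_linear_in_inverse_concentration(self):
        double = AssayConditions(c_m=2e-3, droplet_volume_l=5.24e-10, molar_mass=6.0e4)
        assert nn_per_molecule(0.3, double) == pytest.approx(nn_per_molecule(0.3, COND) / 2)

    def test_dilution_factor_raises_nn(self):
        diluted = AssayConditions(
            c_m=1e-3, droplet_volume_l=5.24e-10, molar_mass=6.0e4, dilution_factor=10.0
        )
        assert nn_per_molecule(0.3, diluted) == pytest.approx(10 * nn_per_molecule(0.3, COND))

    def test_saturated_fraction_rejected(self):
        with pytest.raises(ValueError):
            nn_per_molecule(1.0, COND)
        with pytest.raises(ValueError):
            nn_per_molecule(-0.1, COND)


class TestSpectrumFromAssay:
    def test_monotone_nonincreasing_with_warming(self):
        rng = np.random.default_rng(7)
        assay = _assay(rng.uniform(-25, -5, 100), n_unfrozen=20)
        spec = spectrum_from_assay(assay)
        assert np.all(np.diff(spec.temperature_c) < 0)
        assert np.all(np.diff(spec.nn) >= 0)  # Nn grows toward colder

    def test_fully_frozen_point_dropped(self):
        spec = spectrum_from_assay(_assay([-5.0, -10.0, -15.0]))
        # f=1 at -15 is dropped; remaining fractions 1/3 and 2/3
        assert spec.temperature_c.tolist() == [-5.0, -10.0]
        np.testing.assert_allclose(
            spec.nn, nn_per_molecule(np.array([1 / 3, 2 / 3]), COND)
        )


class TestMergeAndBin:
    def test_single_wide_bin_averages_everything(self):
        spec = NucleationSpectrum([-10.0, -10.4], [1e-8, 1e-6])
        binned = merge_and_bin([spec], KneeConfig(bin_width_k=5.0))
        assert binned.temperature_c.size == 1
        assert binned.log10_nn[0] == pytest.approx(-7.0)

    def test_identical_dilutions_merge_to_same_value(self):
        s1 = NucleationSpectrum([-10.0, -11.0], [1e-7, 2e-7], (1.0,))
        s2 = NucleationSpectrum([-10.2, -11.2], [1e-7, 2e-7], (10.0,))
        binned = merge_and_bin([s1, s2], KneeConfig(bin_width_k=0.5))
        assert np.allclose(binned.nn[binned.n_points == 2], [1e-7, 2e-7])

    def test_matches_groupby_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(5, 60)
            t = -rng.uniform(2, 30, n)
            nn = 10.0 ** rng.uniform(-10, -5, n)
            order = np.argsort(-t)
            t, nn = t[order], nn[order]
            t = t - np.arange(n) * 1e-9  # enforce strictly decreasing
            w = float(rng.choice([0.25, 0.5, 1.0]))
            binned = merge_and_bin([NucleationSpectrum(t, nn)], KneeConfig(bin_width_k=w))
            # brute-force: group points by floor(-T/w) and average log10
            groups = {}
            for ti, ni in zip(t, nn):
                groups.setdefault(math.floor(-ti / w), []).append(math.log10(ni))
            expect = {k: np.mean(v) for k, v in groups.items()}
            assert binned.temperature_c.size == len(expect)
            for centre, mean in zip(binned.temperature_c, binned.log10_nn):
                k = math.floor(-centre / w)
                assert mean == pytest.approx(expect[k])

    def test_warm_to_cold_ordering(self):
        s = NucleationSpectrum([-5.0, -12.0, -20.0], [1e-9, 1e-8, 1e-7])
        binned = merge_and_bin([s])
        assert np.all(np.diff(binned.temperature_c) < 0)


def _concave_fixture(rng):
    """Random concave-increasing curve (log-spectrum shaped) with >= 8 bins."""
    n = int(rng.integers(12, 40))
    x = np.sort(rng.uniform(0, 1, n))
    x[0], x[-1] = 0.0, 1.0
    k = rng.uniform(3, 25)
    y = 1.0 - np.exp(-k * x)
    t = -2.0 - 20.0 * x  # map to a temperature axis, warm -> cold
    return BinnedSpectrum(t, y, np.ones(n, dtype=int))


def _bruteforce_knee(binned):
    """Independent difference-curve maximizer (normalize, subtract, argmax)."""
    x = -binned.temperature_c
    y = binned.log10_nn
    xn = (x - x.min()) / (x.max() - x.min())
    yn = (y - y.min()) / (y.max() - y.min())
    i = int(np.argmax(yn - xn))
    return float(binned.temperature_c[i]), float(binned.nn[i])


class TestFindKnee:
    def test_piecewise_linear_breakpoint(self):
        # steep rise over 5 bins then flat: knee exactly at the breakpoint
        t = -np.arange(10, dtype=float)
        y = np.concatenate([np.linspace(-10, -6, 5), np.full(5, -6.0)])
        binned = BinnedSpectrum(t, y, np.ones(10, dtype=int))
        knee = find_knee(binned, KneeConfig(homog_cutoff_c=-99))
        assert knee[0] == t[4]
        assert knee[1] == pytest.approx(10.0**-6.0)

    def test_matches_bruteforce_oracle_on_random_concave_curves(self):
        rng = np.random.default_rng(2024)
        cfg = KneeConfig(homog_cutoff_c=-99)
        for _ in range(100):
            binned = _concave_fixture(rng)
            knee = find_knee(binned, cfg)
            assert knee is not None
            assert knee == _bruteforce_knee(binned)

    def test_no_knee_on_straight_line(self):
        t = -np.arange(8, dtype=float)
        y = np.linspace(-9, -5, 8)
        assert find_knee(BinnedSpectrum(t, y, np.ones(8, int)), KneeConfig(homog_cutoff_c=-99)) is None


class TestTChar50:
    def test_step_spectrum_onset(self):
        spec = NucleationSpectrum([-12.0, -13.0, -14.0], [1e-7, 1e-7, 1e-7])
        assert t_char_50(spec, (-14.0, 1e-7)) == -12.0

    def test_linear_log_spectrum_interpolation(self):
        # log10 Nn linear from (-10, -8) to (-20, -6); knee (-20, 1e-6)
        t = np.linspace(-10, -20, 11)
        y = np.interp(t, [-20, -10], [-6.0, -8.0])
        spec = BinnedSpectrum(t, y, np.ones(11, int))
        t50 = t_char_50(spec, (-20.0, 1e-6))
        # level = log10(5e-7); dense-grid brute force of the same interpolation
        dense_t = np.linspace(-10, -20, 100001)
        dense_y = np.interp(dense_t, [-20, -10], [-6.0, -8.0])
        expected = dense_t[np.argmin(np.abs(dense_y - math.log10(5e-7)))]
        assert t50 == pytest.approx(expected, abs=1e-3)
        assert t50 == pytest.approx(-18.495, abs=0.01)

    def test_always_at_or_warmer_than_knee(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            binned = _concave_fixture(rng)
            knee = find_knee(binned, KneeConfig(homog_cutoff_c=-99))
            if knee is None:
                continue
            assert t_char_50(binned, knee) >= knee[0]

    def test_interpolated_value_is_half_knee(self):
        t = np.linspace(-10, -20, 21)
        y = np.interp(t, [-20, -10], [-6.0, -9.0])
        spec = BinnedSpectrum(t, y, np.ones(21, int))
        knee = (-20.0, 1e-6)
        t50 = t_char_50(spec, knee)
        level = np.interp(t50, t[::-1], y[::-1])
        assert 10.0**level == pytest.approx(0.5e-6, rel=1e-6)

    def test_unreachable_level_raises(self):
        spec = NucleationSpectrum([-12.0, -13.0], [1e-9, 1e-9])
        with pytest.raises(ValueError, match="not bracketed"):
            t_char_50(spec, (-13.0, 1e-3))


class TestDetectActivityClasses:
    def _two_mode_curve(self):
        # steep rise to a -10 plateau (mode A), second rise to -7.3 (mode C)
        t = -np.arange(2, 10.5, 0.5)
        y = np.interp(t, [-10, -8.5, -7, -4.5, -2], [-7.3, -7.3, -10, -10, -12.5])
        return BinnedSpectrum(t, y, np.ones(t.size, int))

    def test_two_modes_detected_and_labelled(self):
        binned = self._two_mode_curve()
        results = detect_activity_classes(binned, KneeConfig(homog_cutoff_c=-99))
        assert len(results) == 2
        assert [r.class_label for r in results] == ["A", "C"]
        assert results[0].t_knee_c > results[1].t_knee_c
        # plateau levels recovered within half a decade
        assert abs(math.log10(results[0].nn_knee) - (-10.0)) < 0.5
        assert abs(math.log10(results[1].nn_knee) - (-7.3)) < 0.5

    def test_single_mode_returns_one_result(self):
        t = -np.arange(2, 8, 0.5)
        y = np.where(t > -4.5, -11 + 2.0 * -(t + 2), -6.0)
        binned = BinnedSpectrum(t, y, np.ones(t.size, int))
        results = detect_activity_classes(binned, KneeConfig(homog_cutoff_c=-99))
        assert len(results) == 1
        assert results[0].class_label is None

    def test_all_flat_uses_global_knee_path(self):
        t = -np.arange(2, 8, 0.5)
        y = np.where(t > -4.0, -8 + 1.5 * -(t + 2), -5.0)
        binned = BinnedSpectrum(t, y, np.ones(t.size, int))
        # plateau_slope high enough that nothing is steep -> global knee result
        results = detect_activity_classes(
            binned, KneeConfig(plateau_slope=99.0, homog_cutoff_c=-99)
        )
        assert len(results) == 1

    def test_too_few_bins_rejected(self):
        binned = BinnedSpectrum(
            np.array([-2.0, -3.0, -4.0]), np.array([-9.0, -7.0, -6.0]), np.ones(3, int)
        )
        with pytest.raises(ValueError, match="bins"):
            detect_activity_classes(binned, KneeConfig(homog_cutoff_c=-99))
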