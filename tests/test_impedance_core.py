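import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sckinetics import (
    DataError,
    FrequencySelectionError,
    ImpedanceSpectrum,
    MixSpec,
    ResponseSeries,
    UndefinedPhaseError,
    build_response_series,
    conductance_at,
    derive_spectrum,
    mix_index,
    normalize_series,
)
from sckinetics.core import magnitude_at, select_frequency


def spectrum_from(z_re, z_im, freqs=None):
    z_re = np.atleast_1d(np.asarray(z_re, dtype=float))
    if freqs is None:
        freqs = np.geomspace(1e3, 1e6, len(z_re))
    return ImpedanceSpectrum(freqs, z_re, np.atleast_1d(np.asarray(z_im, dtype=float)))


class TestDeriveSpectrum:
    def test_three_four_five_triangle(self):
        derived = derive_spectrum(spectrum_from([3.0], [4.0]))
        assert derived.magnitude_ohm[0] == pytest.approx(5.0)
        assert derived.phase_deg[0] == pytest.approx(53.130, abs=1e-3)

    def test_pure_resistance_and_pure_reactance(self):
        derived = derive_spectrum(spectrum_from([250.0, 0.0], [0.0, -80.0]))
        assert derived.magnitude_ohm == pytest.approx([250.0, 80.0])
        assert derived.phase_deg == pytest.approx([0.0, -90.0])

    def test_zero_impedance_names_frequency(self):
        spec = spectrum_from([10.0, 0.0], [5.0, 0.0], freqs=np.array([1e3, 2e3]))
        with pytest.raises(UndefinedPhaseError, match="2000"):
            derive_spectrum(spec)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-1e6, 1e6, allow_nan=False),
                st.floats(-1e6, 1e6, allow_nan=False),
            ).filter(lambda p: abs(p[0]) + abs(p[1]) > 1e-9),
            min_size=1,
            max_size=20,
        )
    )
    def test_magnitude_identity_pointwise(self, pairs):
        z_re = np.array([p[0] for p in pairs])
        z_im = np.array([p[1] for p in pairs])
        derived = derive_spectrum(spectrum_from(z_re, z_im))
        np.testing.assert_allclose(derived.magnitude_ohm**2, z_re**2 + z_im**2, rtol=1e-12)
        assert np.all(derived.magnitude_ohm >= np.abs(z_re) - 1e-9)
        assert np.all(derived.magnitude_ohm >= np.abs(z_im) - 1e-9)
        assert np.all(derived.phase_deg > -90 - 1e-9)
        assert np.all(derived.phase_deg <= 90 + 1e-9)


class TestFrequencySelection:
    def test_flat_spectrum_conductance(self, flat_spectrum):
        value, f_sel = conductance_at(flat_spectrum, 1e4)
        assert value == pytest.approx(100.0)  # 1 / 10 kOhm in µS

    def test_ne_grid_resolves_300khz_to_log_nearest(self, flat_spectrum):
        # independent oracle: enumerate the 35-point grid in log space
        grid = np.geomspace(1e3, 2.5e6, 35)
        dists = [abs(math.log(f) - math.log(300e3)) for f in grid]
        expected = grid[dists.index(min(dists))]
        _, f_sel = conductance_at(flat_spectrum, 300e3)
        assert f_sel == pytest.approx(expected)
        # the paper's substitution frequency for this instrument
        assert f_sel == pytest.approx(315e3, rel=2e-3)

    def test_target_outside_grid_is_range_error(self, flat_spectrum):
        with pytest.raises(FrequencySelectionError, match="outside"):
            conductance_at(flat_spectrum, 5e6)

    def test_too_far_from_any_grid_point_is_selection_error(self):
        spec = spectrum_from([1.0, 1.0], [0.0, 0.0], freqs=np.array([1e3, 1e6]))
        with pytest.raises(FrequencySelectionError, match="deviates"):
            conductance_at(spec, 50e3, rel_tolerance=0.05)

    def test_log_tie_breaks_toward_lower_frequency(self):
        freqs = np.array([1e3, 4e3])
        idx = select_frequency(freqs, 2e3, rel_tolerance=1.0)  # 2 kHz is the log midpoint
        assert idx == 0


class TestMixIndex:
    def test_flat_spectrum_gives_unity(self, flat_spectrum):
        assert mix_index(flat_spectrum, MixSpec(20e3, 500e3)) == pytest.approx(1.0)

    def test_inverted_frequency_pair_rejected(self):
        with pytest.raises(DataError, match="f_low < f_high"):
            MixSpec(10e3, 1e3)

    def test_matches_closed_form_circuit_ratio(self):
        # series 1 kΩ + parallel RC (99 kΩ, ideal capacitor): oracle evaluated
        # by hand-written complex arithmetic at the two MIX frequencies
        r_sol, r_sc, c_sc = 1e3, 99e3, 5.36e-10

        def oracle_magnitude(f):
            omega = 2 * math.pi * f
            denom = complex(1.0, omega * r_sc * c_sc)
            z = r_sol + r_sc / denom
            return abs(z)

        freqs = 10.0 ** (1 + np.arange(21) / 4.0)
        omega = 2 * np.pi * freqs
        z = r_sol + r_sc / (1 + 1j * omega * r_sc * c_sc)
        spec = ImpedanceSpectrum(freqs, z.real, z.imag)
        expected = oracle_magnitude(1e3) / oracle_magnitude(10e3)
        assert mix_index(spec, MixSpec(1e3, 10e3)) == pytest.approx(expected, rel=1e-12)
        assert expected > 1

    def test_invariant_under_row_reordering(self, flat_spectrum):
        rng = np.random.default_rng(7)
        freqs = np.geomspace(1e3, 2.5e6, 35)
        z_re = rng.uniform(1e3, 1e5, 35)
        z_im = -rng.uniform(1e2, 1e4, 35)
        perm = rng.permutation(35)
        spec_sorted = ImpedanceSpectrum(freqs, z_re, z_im)
        spec_shuffled = ImpedanceSpectrum(freqs[perm], z_re[perm], z_im[perm])
        assert mix_index(spec_shuffled, MixSpec(20e3, 500e3)) == pytest.approx(
            mix_index(spec_sorted, MixSpec(20e3, 500e3))
        )
        assert conductance_at(spec_shuffled, 300e3).value == pytest.approx(
            conductance_at(spec_sorted, 300e3).value
        )

    def test_simulated_spectra_have_mix_above_one(self, franz_zero_noise):
        for spec in franz_zero_noise.spectra:
            assert mix_index(spec, MixSpec(1e3, 10e3)) > 1.0


class TestBuildResponseSeries:
    def test_twelve_ne_sweeps_make_twelve_point_mix_series(self, ne_zero_noise):
        sweeps = ne_zero_noise.replicate_spectra("rep01")
        series = build_response_series(sweeps, "mix", MixSpec(20e3, 500e3))
        assert len(series) == 12
        assert series.parameter_kind == "mix"
        assert series.usable_for_fitting

    def test_single_sweep_is_flagged_unusable(self, flat_spectrum):
        with pytest.warns(UserWarning, match="single-point"):
            series = build_response_series([flat_spectrum], "conductance", 300e3)
        assert not series.usable_for_fitting

    def test_out_of_time_order_rejected(self, ne_zero_noise):
        sweeps = ne_zero_noise.replicate_spectra("rep01")
        with pytest.raises(DataError, match="time order"):
            build_response_series([sweeps[3], sweeps[1]], "conductance", 300e3)

    def test_mixed_replicates_rejected(self, flat_spectrum):
        import dataclasses

        other = ImpedanceSpectrum(
            flat_spectrum.frequencies_hz,
            flat_spectrum.z_re_ohm,
            flat_spectrum.z_im_ohm,
            time_s=30.0,
            method_tag="NE",
            replicate_id="r2",
            site_id="s1",
        )
        with pytest.raises(DataError, match="mix"):
            build_response_series([flat_spectrum, other], "conductance", 300e3)


class TestNormalizeSeries:
    def make_series(self, times, values):
        return ResponseSeries(np.asarray(times, float), np.asarray(values, float), "conductance")

    def test_reference_point_becomes_one(self):
        series = self.make_series([0, 30, 60, 120], [10, 20, 30, 40])
        normalized = normalize_series(series, 30.0)
        assert normalized.values[0] == pytest.approx(1.0)
        assert normalized.time_s[0] == 30.0
        assert normalized.normalized

    def test_constant_series_maps_to_all_ones(self):
        series = self.make_series([0, 30, 60], [5.0, 5.0, 5.0])
        normalized = normalize_series(series, 30.0)
        np.testing.assert_allclose(normalized.values, 1.0)

    def test_reference_before_series_start_is_range_error(self):
        series = self.make_series([60, 90, 120], [1, 2, 3])
        with pytest.raises(DataError, match="outside"):
            normalize_series(series, 30.0)

    def test_idempotent_after_first_application(self):
        series = self.make_series([0, 30, 60, 120], [10, 20, 30, 40])
        once = normalize_series(series, 30.0)
        twice = normalize_series(once, 30.0)
        np.testing.assert_allclose(once.values, twice.values)
        np.testing.assert_allclose(once.time_s, twice.time_s)
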