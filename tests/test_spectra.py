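"""Tube-spectrum model: Kramers law, filtration, sampling, beam quality."""
import numpy as np
import pytest
from scipy import stats

from nanodose import materials, spectra
from nanodose.errors import InvalidConfigurationError, InvalidStateError
from nanodose.spectra import (BeamSpectrum, FilterLayer, apply_filtration,
                              half_value_layer, kramers_unfiltered,
                              read_spectrum, sample_energy, write_spectrum)


def mono(energy, kvp=None):
    return BeamSpectrum(kvp=float(kvp or energy),
                        energy_bins=np.array([float(energy)]),
                        weights=np.array([1.0]))


class TestKramers:
    def test_weights_follow_the_stated_law(self):
        s = kramers_unfiltered(100)
        c = s.energy_bins
        i, j = np.argmin(np.abs(c - 50)), np.argmin(np.abs(c - 75))
        expected = ((100 - c[i]) / c[i]) / ((100 - c[j]) / c[j])
        assert s.weights[i] / s.weights[j] == pytest.approx(expected, rel=1e-12)
        # the quoted closed-form instance at exactly 50 and 75 keV
        assert ((100 - 50) / 50) / ((100 - 75) / 75) == pytest.approx(3.0)

    def test_highest_bin_weight_vanishes_near_kvp(self):
        s = kramers_unfiltered(105)
        assert s.weights[-1] == min(s.weights)
        # (Emax - E) factor: the last bin weight is tiny vs the modal one
        assert s.weights[-1] < 0.01 * s.weights.max()

    def test_anode_z_cancels_after_normalization(self):
        a = kramers_unfiltered(105, anode_z=74)
        b = kramers_unfiltered(105, anode_z=148)
        np.testing.assert_allclose(a.weights, b.weights, rtol=1e-12)

    def test_bins_respect_cutoff_and_kvp(self):
        s = kramers_unfiltered(105)
        assert s.energy_bins[0] >= spectra.PHOTON_CUTOFF_KEV
        assert s.energy_bins[-1] <= 105

    def test_invalid_kvp_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            kramers_unfiltered(5)
        with pytest.raises(InvalidConfigurationError):
            kramers_unfiltered(105, n_bins=3)

    def test_k_lines_add_intensity_near_59_kev(self):
        plain = kramers_unfiltered(105)
        lines = kramers_unfiltered(105, k_lines=True)
        i = np.argmin(np.abs(plain.energy_bins - 59.32))
        assert lines.weights[i] > 2 * plain.weights[i]


class TestFiltration:
    def test_zero_layer_list_is_identity(self):
        s = kramers_unfiltered(105)
        assert apply_filtration(s, []) is s

    def test_aluminium_annihilates_10_kev(self):
        # survival through 2.4 mm Al at 10 keV from the element table
        mu_rho = materials.cross_section_table("Al").coefficient(10.0, "total")
        survival = np.exp(-mu_rho * 2.70 * 0.24)
        assert survival < 1e-7
        two_bin = BeamSpectrum(kvp=105.0,
                               energy_bins=np.array([10.0, 80.0]),
                               weights=np.array([0.5, 0.5]))
        filtered = apply_filtration(two_bin, [FilterLayer("Al", 2.4)])
        assert filtered.weights[0] < 1e-6

    def test_beam_hardening_strictly_increases_mean_energy(self):
        s = kramers_unfiltered(105)
        f1 = apply_filtration(s, [FilterLayer("Al", 2.4)])
        f2 = apply_filtration(f1, [FilterLayer("Al", 1.0)])
        assert f1.mean_energy > s.mean_energy
        assert f2.mean_energy > f1.mean_energy

    def test_negative_thickness_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            FilterLayer("Al", -1.0)

    def test_normalization_invariant(self, beam105, beam220):
        for s in (beam105, beam220, kramers_unfiltered(150)):
            assert abs(s.weights.sum() - 1.0) < 1e-12


class TestSampling:
    def test_single_bin_returns_that_energy(self, rng):
        s = mono(59.0)
        assert np.all(sample_energy(s, rng, 100) == 59.0)

    def test_two_bin_frequencies_within_binomial_error(self, rng):
        s = BeamSpectrum(kvp=100.0, energy_bins=np.array([30.0, 60.0]),
                         weights=np.array([0.25, 0.75]))
        n = 100_000
        draws = sample_energy(s, rng, n)
        p_hat = np.mean(draws == 30.0)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(p_hat - 0.25) < 4 * se

    def test_sample_mean_matches_spectrum_mean(self, beam105, rng):
        n = 1_000_000
        draws = sample_energy(beam105, rng, n)
        var = np.sum(beam105.weights
                     * (beam105.energy_bins - beam105.mean_energy) ** 2)
        assert abs(draws.mean() - beam105.mean_energy) < 3 * np.sqrt(var / n)
        assert draws.max() <= beam105.kvp

    def test_chi_square_against_weights(self, beam105, rng):
        n = 1_000_000
        draws = sample_energy(beam105, rng, n)
        counts = np.array([(draws == e).sum() for e in beam105.energy_bins])
        expected = beam105.weights * n
        sel = expected >= 10
        # merge the negligible-weight bins into one bucket
        obs = np.append(counts[sel], counts[~sel].sum())
        exp = np.append(expected[sel], expected[~sel].sum())
        if exp[-1] == 0:
            obs, exp = obs[:-1], exp[:-1]
        _, p = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.001

    def test_unnormalized_spectrum_rejected(self, rng):
        s = mono(50.0)
        object.__setattr__(s, "weights", np.array([0.5]))
        with pytest.raises(InvalidStateError):
            sample_energy(s, rng, 10)


class TestHalfValueLayer:
    def test_monoenergetic_closed_form(self):
        e = 60.0
        mu_mm = (materials.cross_section_table("Cu").coefficient(e, "total")
                 * 8.96 / 10.0)
        assert half_value_layer(mono(e), "Cu") == pytest.approx(
            np.log(2) / mu_mm, abs=2e-4)

    def test_harder_beam_has_larger_hvl(self, beam105, beam220):
        assert (half_value_layer(beam220, "Cu")
                > half_value_layer(beam105, "Cu"))

    def test_filtration_never_decreases_hvl(self, beam105):
        harder = apply_filtration(beam105, [FilterLayer("Al", 1.0)])
        assert (half_value_layer(harder, "Al")
                >= half_value_layer(beam105, "Al"))


def test_spectrum_text_roundtrip(tmp_path, beam105):
    path = tmp_path / "beam.txt"
    write_spectrum(beam105, path)
    back = read_spectrum(path)
    assert back.kvp == beam105.kvp
    np.testing.assert_allclose(back.energy_bins, beam105.energy_bins)
    np.testing.assert_allclose(back.weights, beam105.weights, atol=1e-12)
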