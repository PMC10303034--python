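"""Monte Carlo transport physics against closed-form and numeric oracles."""
import numpy as np
import pytest
from scipy import stats

import nanodose as nd
from nanodose.errors import InvalidConfigurationError, InvalidStateError
from nanodose.scoring import DoseGrid, depth_dose
from nanodose.spectra import BeamSpectrum
from nanodose.transport import (MEC2_KEV, MaterialLookup, PhantomGeometry,
                                PhotonState, SourceConfig, TransportConfig,
                                _emit_batch, distance_to_interaction,
                                emit_photon, klein_nishina_scatter,
                                rayleigh_scatter, run_simulation,
                                select_interaction, transport_history)


def mono_beam(energy):
    return BeamSpectrum(kvp=float(energy), energy_bins=np.array([energy]),
                        weights=np.array([1.0]))


class TestFreePath:
    def test_mean_free_path(self, rng):
        mu = 0.2
        s = distance_to_interaction(np.full(1_000_000, mu), rng)
        se = (1 / mu) / np.sqrt(s.size)
        assert abs(s.mean() - 1 / mu) < 4 * se

    def test_exponential_tail(self, rng):
        mu = 0.7
        s = distance_to_interaction(np.full(200_000, mu), rng)
        p = np.mean(s > 1 / mu)
        assert abs(p - np.exp(-1)) < 4 * np.sqrt(np.exp(-1) * (1 - np.exp(-1))
                                                 / s.size)

    def test_nonpositive_mu_rejected(self, rng):
        with pytest.raises(InvalidStateError):
            distance_to_interaction(0.0, rng)


class TestEmission:
    def test_directions_hit_the_field_disk(self, rng, beam105):
        src = SourceConfig()
        pos, direction, _ = _emit_batch(src, beam105, rng, 10_000)
        t = -pos[:, 2] / direction[:, 2]  # to the z=0 entry plane
        lateral = pos[:, :2] + direction[:, :2] * t[:, None]
        r = np.hypot(lateral[:, 0], lateral[:, 1])
        assert r.max() <= src.field_diameter_cm / 2 + 1e-9

    def test_disk_moments(self, rng, beam105):
        src = SourceConfig()
        pos, direction, _ = _emit_batch(src, beam105, rng, 100_000)
        t = -pos[:, 2] / direction[:, 2]
        lateral = pos[:, :2] + direction[:, :2] * t[:, None]
        radius = src.field_diameter_cm / 2
        rms_ref = radius / np.sqrt(2)
        se_mean = rms_ref / np.sqrt(lateral.shape[0])
        assert abs(lateral[:, 0].mean()) < 4 * se_mean
        assert abs(lateral[:, 1].mean()) < 4 * se_mean
        rms = np.sqrt(np.mean(lateral[:, 0] ** 2 + lateral[:, 1] ** 2))
        assert rms == pytest.approx(rms_ref, rel=0.02)

    def test_single_photon_state(self, rng, beam105):
        p = emit_photon(SourceConfig(), beam105, rng)
        assert np.linalg.norm(p.direction) == pytest.approx(1.0, abs=1e-12)
        assert p.alive and p.energy >= 1.0

    def test_inverse_square_fluence(self, rng, beam105):
        """Geometric fluence through a fixed aperture falls as 1/d^2."""
        src = SourceConfig(ssd_cm=20.0)
        _, direction, _ = _emit_batch(src, beam105, rng, 400_000)
        a = 0.5  # cm, counting aperture radius
        hits = []
        for d in (20.0, 40.0):
            lateral = direction[:, :2] / direction[:, 2:3] * d
            hits.append(np.mean(np.hypot(lateral[:, 0], lateral[:, 1]) < a))
        ratio = hits[0] / hits[1]
        se = ratio * np.sqrt(sum(1 / (h * 400_000) for h in hits))
        assert abs(ratio - 4.0) < 4 * se


class TestChannelSelection:
    def test_modal_channels(self, rng):
        au40 = nd.nanoparticle_mixture("gold", 40)
        picks = [select_interaction(au40, 30.0, rng) for _ in range(400)]
        assert picks.count("photoelectric") > 200
        w = nd.water()
        picks = [select_interaction(w, 200.0, rng) for _ in range(400)]
        assert picks.count("incoherent") > 200

    def test_frequencies_match_partial_coefficients(self, rng):
        m = nd.nanoparticle_mixture("iodine", 18)
        e = 45.0
        probs = np.array([nd.mass_attenuation(m, e, p) for p in
                          ("photoelectric", "incoherent", "coherent")])
        probs /= probs.sum()
        lookup = MaterialLookup(m)
        n = 1_000_000
        u = rng.random(n)
        f_pe, f_inc = lookup.channel_cum(np.full(n, e))
        counts = np.array([(u < f_pe).sum(),
                           ((u >= f_pe) & (u < f_inc)).sum(),
                           (u >= f_inc).sum()])
        for k in range(3):
            se = np.sqrt(n * probs[k] * (1 - probs[k]))
            assert abs(counts[k] - n * probs[k]) < 4 * se


class TestComptonKinematics:
    def test_forward_scatter_keeps_energy(self):
        e = 80.0
        e_sc = e / (1 + (e / MEC2_KEV) * (1 - np.cos(0.0)))
        assert e_sc == e

    def test_backscatter_at_511_kev(self):
        e_sc = 511.0 / (1 + (511.0 / MEC2_KEV) * (1 - np.cos(np.pi)))
        assert e_sc == pytest.approx(511.0 / 3.0, rel=1e-3)

    def test_sampled_energies_within_compton_bounds(self, rng):
        e = 150.0
        e_sc, theta = klein_nishina_scatter(np.full(50_000, e), rng)
        e_min = e / (1 + 2 * e / MEC2_KEV)
        assert np.all(e_sc >= e_min - 1e-9) and np.all(e_sc <= e + 1e-9)
        assert np.all((theta >= 0) & (theta <= np.pi))

    def test_angle_distribution_chi_square_at_100_kev(self, rng):
        """Sampled cos(theta) histogram vs the numerically integrated
        Klein-Nishina density."""
        e = 100.0
        n = 1_000_000
        _, theta = klein_nishina_scatter(np.full(n, e), rng)
        cost = np.cos(theta)
        edges = np.linspace(-1, 1, 41)
        counts, _ = np.histogram(cost, edges)
        # numeric oracle: integrate the differential cross section per bin
        alpha = e / MEC2_KEV
        fine = np.linspace(-1, 1, 40_001)
        ratio = 1 / (1 + alpha * (1 - fine))
        dens = ratio**2 * (ratio + 1 / ratio - (1 - fine**2))
        cdf = np.concatenate([[0], np.cumsum((dens[1:] + dens[:-1]) / 2
                                             * np.diff(fine))])
        cdf /= cdf[-1]
        expected = np.diff(np.interp(edges, fine, cdf)) * n
        _, p = stats.chisquare(counts, expected * counts.sum() / expected.sum())
        assert p > 0.001


class TestRayleigh:
    def test_elastic_no_energy_change(self, rng):
        theta = rayleigh_scatter(np.full(1000, 75.0), rng)
        assert theta.shape == (1000,)  # energy untouched by design

    def test_thomson_symmetry(self, rng):
        theta = rayleigh_scatter(np.full(1_000_000, 60.0), rng)
        cost = np.cos(theta)
        assert abs(cost.mean()) < 4 * cost.std() / np.sqrt(cost.size)
        p_forward = np.mean(theta < np.pi / 2)
        assert abs(p_forward - 0.5) < 4 * np.sqrt(0.25 / cost.size)


class TestTransport:
    def test_energy_conservation_per_batch(self, water_run_105):
        assert np.all(np.abs(water_run_105.energy_balance()) < 1e-6)

    def test_determinism_bit_identical(self, beam105):
        cfg = TransportConfig(n_histories=20_000, rng_seed=7)
        g1 = run_simulation(beam105, nd.water(), config=cfg)
        g2 = run_simulation(beam105, nd.water(), config=cfg)
        assert np.array_equal(g1.batch_deposits, g2.batch_deposits)
        assert np.array_equal(g1.escaped_kev, g2.escaped_kev)

    def test_beer_lambert_in_photoelectric_only_medium(self):
        """Narrow parallel beam, scatter channels disabled: the depth
        profile of deposited energy must follow exp(-mu_pe * d)."""
        e = 30.0
        w = nd.water()
        lookup = MaterialLookup(w, channel_override={"incoherent": 0.0,
                                                     "coherent": 0.0})
        mu_ref = nd.mass_attenuation(w, e, "photoelectric") * w.density
        geometry = PhantomGeometry()
        source = SourceConfig(ssd_cm=1000.0, field_diameter_cm=0.2)
        cfg = TransportConfig(n_histories=400_000, rng_seed=3)
        grid = run_simulation(mono_beam(e), w, geometry=geometry,
                              source=source, config=cfg, lookup=lookup)
        profile = grid.pooled.sum(axis=(0, 1))
        z = 0.5 * (geometry.edges(2)[:-1] + geometry.edges(2)[1:])
        slope = np.polyfit(z, np.log(profile), 1)[0]
        assert -slope == pytest.approx(mu_ref, rel=0.02)

    def test_photon_aimed_outside_box_deposits_nothing(self, rng):
        geometry = PhantomGeometry()
        grid = DoseGrid.empty((geometry.edges(0), geometry.edges(1),
                               geometry.edges(2)), n_batches=2,
                              n_histories=1, material_name="water",
                              density=1.0)
        photon = PhotonState(position=np.array([0.0, 0.0, -20.0]),
                             direction=np.array([0.0, 1.0, 0.0]),
                             energy=50.0)
        transport_history(photon, geometry, nd.water(), TransportConfig(),
                          grid, rng)
        assert grid.pooled.sum() == 0.0
        assert grid.escaped_kev.sum() == pytest.approx(50.0)

    def test_single_history_conserves_energy(self, rng, beam105):
        geometry = PhantomGeometry()
        grid = DoseGrid.empty((geometry.edges(0), geometry.edges(1),
                               geometry.edges(2)), n_batches=2,
                              n_histories=10, material_name="water",
                              density=1.0)
        total_emitted = 0.0
        for _ in range(10):
            photon = emit_photon(SourceConfig(), beam105, rng)
            total_emitted += photon.energy
            transport_history(photon, geometry, nd.water(),
                              TransportConfig(), grid, rng)
            assert not photon.alive
        assert grid.pooled.sum() + grid.escaped_kev.sum() == pytest.approx(
            total_emitted, rel=1e-12)

    def test_fluorescence_moves_energy_out_of_the_first_bin(self, beam220):
        """Disabling K-fluorescence transport must increase the local dose
        from a gold mixture under the 220 kVp beam (K photons above the
        edge carry energy away)."""
        au = nd.nanoparticle_mixture("gold", 40)
        doses = {}
        for flag in (True, False):
            cfg = TransportConfig(n_histories=150_000, rng_seed=11,
                                  k_fluorescence=flag)
            doses[flag] = depth_dose(run_simulation(
                beam220, au, config=cfg)).dose_per_history[0]
        assert doses[False] > 1.1 * doses[True]


class TestValidation:
    def test_bad_geometry_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            PhantomGeometry(size_cm=(10, 10, 12), voxel_cm=(0.7, 0.5, 1.0))

    def test_bad_transport_config_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            TransportConfig(photon_cutoff_kev=0.5)
        with pytest.raises(InvalidConfigurationError):
            TransportConfig(n_histories=11, n_batches=2)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(InvalidStateError):
            PhotonState(position=np.zeros(3),
                        direction=np.array([0.0, 0.0, 2.0]), energy=10.0)
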