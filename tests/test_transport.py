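"""Step sampling, continuous/discrete EM physics, nuclear events, and
full-history transport."""

import math

import numpy as np
import pytest
from scipy import stats

from protonmc import materials as M
from protonmc import transport as T
from protonmc.constants import M_P
from protonmc.geometry import MagneticField, VoxelPhantom


class TestSampleNumMfp:
    def test_known_values(self):
        assert T.sample_num_mfp(eta=1 / math.e) == pytest.approx(1.0)
        assert T.sample_num_mfp(eta=1 - 1e-12) == pytest.approx(0.0, abs=1e-11)

    def test_invalid_eta(self):
        with pytest.raises(ValueError):
            T.sample_num_mfp(eta=0.0)

    def test_exponential_moments(self, rng):
        draws = np.array([T.sample_num_mfp(rng) for _ in range(100000)])
        assert draws.mean() == pytest.approx(1.0, abs=0.01)
        assert np.all(draws > 0)


class TestDiscreteDistances:
    def test_vacuum_density_gives_infinite_distances(self, tables, rng,
                                                     material_ids):
        d = T.distances_to_discrete(150.0, material_ids["water"], 0.0,
                                    tables, rng)
        assert d == (math.inf, math.inf, math.inf)

    def test_min_distance_is_exponential_with_total_rate(self, tables, rng,
                                                         material_ids):
        """Competing exponentials: the minimum of the per-channel
        distances is Exp(Sigma_tot)."""
        wid = material_ids["water"]
        T_p, rho = 150.0, 1.0
        sig_tot = (
            rho * tables.interp_logT(tables.sig_ion_mass[wid], T_p) * 0.1
            + M.macroscopic_nuclear_xs(wid, rho, T_p, "elastic", tables)
            + M.macroscopic_nuclear_xs(wid, rho, T_p, "inelastic", tables))
        mins = np.array([min(T.distances_to_discrete(T_p, wid, rho, tables, rng))
                         for _ in range(20000)])
        _, p = stats.kstest(mins, "expon", args=(0, 1.0 / sig_tot))
        assert p > 0.01


class TestChooseStep:
    def test_boundary_wins(self, tables, material_ids):
        cfg = T.TransportConfig()
        step, ev = T.choose_step(1.0, 5.0, 9.0, 30.0, 150.0,
                                 material_ids["water"], 1.0, tables, cfg)
        assert (step, ev) == (1.0, "BOUNDARY")

    def test_range_cap_is_20_percent_of_residual_range(self, tables,
                                                       material_ids):
        cfg = T.TransportConfig()
        wid = material_ids["water"]
        # pick the energy whose residual range is 40 mm
        t40 = float(np.interp(40.0 / 10.0, tables.range_mass[wid],
                              tables.energy_grid))
        step, ev = T.choose_step(1e9, 1e9, 1e9, 1e9, t40, wid, 1.0,
                                 tables, cfg)
        assert ev == "RANGE_CAP"
        assert step == pytest.approx(8.0, rel=1e-3)

    def test_shifter_cap_is_10mm(self, tables, material_ids):
        cfg = T.TransportConfig()
        step, ev = T.choose_step(1e9, 1e9, 1e9, 1e9, 150.0,
                                 material_ids["pmma"], 1.19, tables, cfg)
        assert (step, ev) == (10.0, "RANGE_CAP")

    def test_discrete_channel_selected(self, tables, material_ids):
        cfg = T.TransportConfig()
        step, ev = T.choose_step(9.0, 5.0, 7.0, 30.0, 150.0,
                                 material_ids["water"], 1.0, tables, cfg)
        assert (step, ev) == (5.0, "IONIZATION")


class TestContinuousLoss:
    def test_zero_step(self, tables, material_ids, rng):
        assert T.continuous_loss(100.0, material_ids["water"], 1.0, 0.0,
                                 tables, rng) == 0.0

    def test_mean_matches_range_inversion(self, tables, material_ids):
        wid = material_ids["water"]
        de = T.continuous_loss(100.0, wid, 1.0, 10.0, tables,
                               straggling=False)
        e_after, _ = M.energy_after_pathlength(wid, 100.0, 10.0, tables)
        assert de == pytest.approx(100.0 - e_after, rel=1e-12)

    def test_straggling_variance_matches_bohr(self, tables, material_ids,
                                              rng):
        wid = material_ids["water"]
        T_p, dx = 150.0, 1.0
        draws = np.array([T.continuous_loss(T_p, wid, 1.0, dx, tables, rng)
                          for _ in range(100000)])
        expected = M.bohr_variance(wid, T_p, dx, tables)
        assert draws.var() == pytest.approx(expected, rel=0.03)


class TestDeltaElectron:
    def test_kinematic_maximum_at_250mev(self):
        """Exact limit 2 m_e c^2 beta^2 gamma^2 / (1 + 2 gamma m_e/m_p +
        (m_e/m_p)^2), evaluated independently."""
        me, mp = 0.511, 938.272
        gamma = 1 + 250.0 / mp
        b2g2 = gamma**2 - 1
        expected = 2 * me * b2g2 / (1 + 2 * gamma * me / mp + (me / mp) ** 2)
        assert T.max_delta_energy(250.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.616, abs=0.002)

    def test_samples_within_bounds(self, rng):
        tmax = T.max_delta_energy(200.0)
        draws = [T.delta_electron_event(200.0, rng) for _ in range(2000)]
        assert all(0.1 <= d <= tmax for d in draws)

    def test_below_threshold_noop(self, rng):
        # at 2 MeV the kinematic maximum is ~4.4 keV < 0.1 MeV threshold
        assert T.delta_electron_event(2.0, rng) == 0.0

    def test_spectrum_matches_rutherford_shape(self, rng):
        """Chi-square GOF against bin probabilities integrated
        independently from the 1/T^2 (1 - beta^2 T/Tmax) density."""
        T_p = 200.0
        tmax = T.max_delta_energy(T_p)
        tecut = 0.1
        gamma = 1 + T_p / M_P
        beta2 = 1 - 1 / gamma**2
        grid = np.linspace(tecut, tmax, 2001)
        pdf = grid**-2 * (1 - beta2 * grid / tmax)
        cdf = np.concatenate([[0], np.cumsum((pdf[1:] + pdf[:-1]) / 2
                                             * np.diff(grid))])
        cdf /= cdf[-1]
        edges = np.linspace(tecut, tmax, 13)
        probs = np.diff(np.interp(edges, grid, cdf))
        n = 50000
        draws = np.array([T.delta_electron_event(T_p, rng) for _ in range(n)])
        counts, _ = np.histogram(draws, bins=edges)
        _, p = stats.chisquare(counts, probs / probs.sum() * counts.sum())
        assert p > 0.01


class TestMultipleScattering:
    def test_variance_matches_theta0(self, tables, material_ids, rng):
        wid = material_ids["water"]
        T_p, dx = 150.0, 1.0
        th0 = T.scattering_theta0(T_p, wid, 1.0, dx, tables)
        d0 = np.array([0.0, 0.0, 1.0])
        n = 100000
        polar = np.empty(n)
        for i in range(n):
            nd = T.multiple_scattering(d0, T_p, wid, 1.0, dx, tables, rng)
            polar[i] = math.acos(min(nd @ d0, 1.0))
        assert polar.var() + polar.mean() ** 2 == pytest.approx(th0**2,
                                                                rel=0.02)

    def test_variance_additivity_of_substeps(self, tables, material_ids, rng):
        """Two dx/2 sub-steps accumulate the angular variance of one dx
        step (Gaussian convolution), within a few percent."""
        wid = material_ids["water"]
        T_p, dx = 150.0, 2.0
        d0 = np.array([0.0, 0.0, 1.0])
        n = 30000
        one = np.empty(n)
        two = np.empty(n)
        for i in range(n):
            nd = T.multiple_scattering(d0, T_p, wid, 1.0, dx, tables, rng)
            one[i] = math.acos(min(nd @ d0, 1.0))
            nd = T.multiple_scattering(d0, T_p, wid, 1.0, dx / 2, tables, rng)
            nd = T.multiple_scattering(nd, T_p, wid, 1.0, dx / 2, tables, rng)
            two[i] = math.acos(min(nd @ d0, 1.0))
        v1 = np.mean(one**2)
        v2 = np.mean(two**2)
        assert v2 == pytest.approx(v1, rel=0.05)

    def test_unit_norm_preserved(self, tables, material_ids, rng):
        d = np.array([0.6, 0.0, 0.8])
        for _ in range(100):
            d = T.multiple_scattering(d, 100.0, material_ids["water"], 1.0,
                                      1.0, tables, rng)
            assert abs(np.linalg.norm(d) - 1.0) < 1e-9


class TestMagneticDeflection:
    def test_zero_field_identity(self):
        d = np.array([0.0, 0.0, 1.0])
        nd = T.magnetic_deflection(d, MagneticField((0, 0, 0)), 150.0, 1.0)
        assert np.array_equal(nd, d)

    def test_parallel_field_identity(self):
        d = np.array([0.0, 0.0, 1.0])
        nd = T.magnetic_deflection(d, MagneticField((0, 0, 1.5)), 150.0, 1.0)
        assert np.allclose(nd, d, atol=1e-15)

    def test_deflection_angle_matches_gyroradius(self):
        """One step of dx in B perpendicular turns the direction by
        dx / r with r = pc/(0.299792 B), to O((dx/r)^2)."""
        T_p, b, dx = 150.0, 1.0, 1.0
        r = T.gyroradius_mm(T_p, b)
        pc = math.sqrt((T_p + M_P) ** 2 - M_P**2)
        assert r == pytest.approx(pc / (0.299792 * b), rel=1e-12)
        d = np.array([0.0, 0.0, 1.0])
        nd = T.magnetic_deflection(d, MagneticField((0, b, 0)), T_p, dx)
        angle = math.acos(min(nd @ d, 1.0))
        assert angle == pytest.approx(dx / r, rel=1e-6)
        assert abs(np.linalg.norm(nd) - 1.0) < 1e-12


class TestElasticEvent:
    def test_pp_conserves_energy_exactly(self, nucdb, rng):
        for _ in range(200):
            kind, (t1, d1), (t2, d2) = T.elastic_event(
                120.0, [0, 0, 1.0], "H", nucdb, rng)
            assert kind == "pp"
            assert t1 + t2 == pytest.approx(120.0, rel=1e-12)

    def test_pp_mean_secondary_energy(self, nucdb, rng):
        t2s = [T.elastic_event(100.0, [0, 0, 1.0], "H", nucdb, rng)[2][0]
               for _ in range(100000)]
        assert np.mean(t2s) == pytest.approx(50.0, rel=0.01)

    def test_pp_opening_angle_nonrelativistic_limit(self, nucdb, rng):
        """As T -> 0 the two outgoing protons separate by 90 degrees."""
        angles = []
        for _ in range(500):
            _, (t1, d1), (t2, d2) = T.elastic_event(1.0, [0, 0, 1.0], "H",
                                                    nucdb, rng)
            angles.append(math.degrees(math.acos(np.clip(d1 @ d2, -1, 1))))
        assert np.mean(angles) == pytest.approx(90.0, abs=0.2)

    def test_px_recoil_balances(self, nucdb, rng):
        kind, (kept, d1), recoil = T.elastic_event(150.0, [0, 0, 1.0], "O",
                                                   nucdb, rng)
        assert kind == "pX"
        assert kept + recoil == pytest.approx(150.0, rel=1e-12)
        assert recoil >= 0


class TestInelasticEvent:
    def test_energy_conservation_each_event(self, nucdb, rng):
        for _ in range(500):
            protons, local, neutral = T.inelastic_event(
                180.0, [0, 0, 1.0], "O", nucdb, rng)
            total = sum(e for e, _ in protons) + local + neutral
            assert total == pytest.approx(180.0, rel=1e-12)
            assert sum(e for e, _ in protons) <= 180.0

    def test_secondary_spectrum_matches_table(self, nucdb, rng):
        """Marginal secondary-proton energy histogram against the DB's
        energy marginal (chi-square, coarse bins)."""
        T_p = 150.0  # exactly on a bin centre: single table in play
        ei = nucdb.element_bin("O", T_p)
        b = int((T_p - nucdb.ebins[0]) / (nucdb.ebins[1] - nucdb.ebins[0]))
        marg = nucdb.pjoint[ei, b].sum(axis=1)
        e_avail = T_p - nucdb.q_reaction
        edges = nucdb.efrac_edges * e_avail
        draws = []
        for _ in range(30000):
            ev = nucdb.sample_inelastic("O", T_p, rng)
            protons = [e for kind, e, mu, phi in ev if kind == 0]
            # single-proton events: the energy-conservation resampling
            # can never trigger, so the marginal is exact
            if len(protons) == 1:
                draws.append(protons[0])
        counts, _ = np.histogram(draws, bins=edges)
        probs = marg / marg.sum()
        exp = probs * len(draws)
        keep = exp > 5
        if np.all(keep):
            c, e = counts, exp
        else:
            c = np.append(counts[keep], counts[~keep].sum())
            e = np.append(exp[keep], exp[~keep].sum())
        _, p = stats.chisquare(c, e / e.sum() * c.sum())
        assert p > 0.01


class TestTransportHistory:
    def _kdata(self, tables, nucdb, **kw):
        return T.TransportKernelData(tables, nucdb, T.TransportConfig(**kw))

    def test_vacuum_flythrough(self, tables, nucdb, material_ids):
        kd = self._kdata(tables, nucdb)
        ph = VoxelPhantom.uniform((5, 5, 10), (2, 2, 2), material_ids["water"],
                                 0.0)
        dep = np.zeros(ph.dims)
        led, _ = T.transport_history(
            T.ProtonState([5.0, 5.0, 0.0], [0, 0, 1.0], 100.0), ph,
            MagneticField(), kd, dep, seed=1)
        assert led.escaped == pytest.approx(100.0)
        assert dep.sum() == 0.0

    def test_ledger_balances_with_all_physics(self, tables, nucdb,
                                              material_ids):
        kd = self._kdata(tables, nucdb)
        ph = VoxelPhantom.uniform((25, 25, 200), (2, 2, 1),
                                  material_ids["water"], 1.0)
        dep = np.zeros(ph.dims)
        for h in range(300):
            led, _ = T.transport_history(
                T.ProtonState([25.0, 25.0, 0.0], [0, 0, 1.0], 150.0), ph,
                MagneticField(), kd, dep, seed=9, history_index=h)
            assert led.balance_error(150.0) < 1e-6

    def test_deposit_plus_escape_matches_grid(self, tables, nucdb,
                                              material_ids):
        kd = self._kdata(tables, nucdb)
        ph = VoxelPhantom.uniform((25, 25, 120), (2, 2, 1),
                                  material_ids["water"], 1.0)
        dep = np.zeros(ph.dims)
        total_in_grid_buckets = 0.0
        for h in range(100):
            led, _ = T.transport_history(
                T.ProtonState([25.0, 25.0, 0.0], [0, 0, 1.0], 120.0), ph,
                MagneticField(), kd, dep, seed=4, history_index=h)
            total_in_grid_buckets += led.deposited + led.local_secondary
        assert dep.sum() == pytest.approx(total_in_grid_buckets, rel=1e-9)

    def test_determinism(self, tables, nucdb, material_ids):
        kd = self._kdata(tables, nucdb)
        ph = VoxelPhantom.uniform((11, 11, 60), (2, 2, 2),
                                  material_ids["water"], 1.0)
        out = []
        for _ in range(2):
            dep = np.zeros(ph.dims)
            for h in range(50):
                T.transport_history(
                    T.ProtonState([11.0, 11.0, 0.0], [0, 0, 1.0], 100.0), ph,
                    MagneticField((0, 1.0, 0)), kd, dep, seed=7,
                    history_index=h)
            out.append(dep.copy())
        assert np.array_equal(out[0], out[1])

    def test_csda_depth_dose_without_stochastics(self, tables, nucdb,
                                                 material_ids):
        """All stochastic channels off, B = 0: the depth-dose is the
        deterministic curve dose(z) ~ L(T(z))."""
        kd = self._kdata(tables, nucdb, straggling=False, ms=False,
                         delta=False, nuclear=False)
        wid = material_ids["water"]
        ph = VoxelPhantom.uniform((3, 3, 100), (10, 10, 1), wid, 1.0)
        dep = np.zeros(ph.dims)
        T.transport_history(T.ProtonState([15.0, 15.0, 0.0], [0, 0, 1.0],
                                          100.0), ph, MagneticField(), kd,
                            dep, seed=1)
        dd = dep.sum(axis=(0, 1))
        # compare against L(T(z)) from the range table, away from the peak
        for z in (10, 30, 50):
            e, _ = M.energy_after_pathlength(wid, 100.0, z + 0.5, tables)
            expected = M.restricted_stopping_power(wid, e, tables) * 0.1
            assert dd[z] == pytest.approx(expected, rel=0.02)
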