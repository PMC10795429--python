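"""Registry, HU conversion, and physics-table generation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from protonmc import materials as M
from protonmc.constants import K_BETHE, M_E, N_A, R_E_CM


def _material(tables, name):
    return next(m for m in tables.materials if m.name == name)


class TestRegistry:
    def test_counts(self, registry):
        elements, materials, _ = registry
        assert len(elements) == 13
        assert len(materials) == 24
        symbols = {e.symbol for e in elements}
        assert {"H", "C", "N", "O", "Ca"} <= symbols

    def test_weights_normalized_and_registered(self, registry):
        elements, materials, _ = registry
        symbols = {e.symbol for e in elements}
        for m in materials:
            assert abs(sum(m.weights.values()) - 1.0) < 1e-9
            assert set(m.weights) <= symbols

    def test_water_is_stoichiometric(self, registry):
        _, materials, _ = registry
        w = next(m for m in materials if m.name == "water").weights
        # H2O mass fractions from atomic masses
        assert w["H"] == pytest.approx(2 * 1.008 / (2 * 1.008 + 15.999), abs=1e-4)
        assert w["O"] == pytest.approx(15.999 / (2 * 1.008 + 15.999), abs=1e-4)

    def test_benchmark_materials_present(self, registry):
        _, materials, _ = registry
        by_name = {m.name: m for m in materials}
        assert by_name["cortical_bone"].default_density == pytest.approx(1.85)
        assert by_name["lung"].default_density == pytest.approx(0.40)
        assert by_name["soft_tissue"].default_density == pytest.approx(1.15)
        assert any(m.is_range_shifter for m in materials)


class TestHUConversion:
    def test_anchors(self, registry):
        _, materials, hu = registry
        rho, mid = M.hu_to_material(0.0, hu)
        assert rho == pytest.approx(1.00, abs=0.02)
        assert materials[mid].name == "water"
        rho_air, _ = M.hu_to_material(-1000.0, hu)
        assert rho_air < 0.01

    def test_monotone_within_ramp(self, registry):
        _, _, hu = registry
        grid = np.linspace(-1024, 3000, 500)
        rhos = [M.hu_to_material(h, hu)[0] for h in grid]
        assert np.all(np.diff(rhos) >= 0)

    def test_out_of_span_clamps(self, registry, caplog):
        _, _, hu = registry
        rho_hi, _ = M.hu_to_material(5000.0, hu)
        rho_edge, _ = M.hu_to_material(3000.0, hu)
        assert rho_hi == rho_edge
        assert "clamping" in caplog.text


class TestStoppingPower:
    def test_water_unrestricted_near_reference(self, tables):
        """Unrestricted mass stopping power of water at 150 MeV is within
        3% of the standard reference tabulation (~5.44 MeV cm^2/g)."""
        w = _material(tables, "water")
        L = M.mass_stopping_power(w.weights, tables._by_sym, 150.0)
        assert L == pytest.approx(5.44, rel=0.03)

    def test_density_scaling(self, tables, material_ids):
        lid = material_ids["lung"]
        L1 = M.restricted_stopping_power(lid, 100.0, tables, density=0.40)
        L2 = M.restricted_stopping_power(lid, 100.0, tables, density=0.80)
        assert L2 == pytest.approx(2 * L1, rel=1e-12)

    def test_monotone_decreasing_regime(self, tables, material_ids):
        wid = material_ids["water"]
        L100 = M.restricted_stopping_power(wid, 100.0, tables)
        L200 = M.restricted_stopping_power(wid, 200.0, tables)
        assert L100 > L200
        grid = tables.energy_grid
        row = tables.L_mass[wid]
        above = grid > 10.0
        assert np.all(np.diff(row[above]) < 0)

    def test_out_of_grid_raises(self, tables, material_ids):
        with pytest.raises(ValueError):
            M.restricted_stopping_power(material_ids["water"], 0.3, tables)

    def test_mass_tables_density_independent(self, tables):
        """Materials sharing a composition share bit-identical mass tables."""
        a = _material(tables, "lung")
        b = _material(tables, "lung_inflated")
        assert a.weights == b.weights
        assert np.array_equal(tables.L_mass[a.id], tables.L_mass[b.id])
        assert np.array_equal(tables.sig_ion_mass[a.id], tables.sig_ion_mass[b.id])
        assert np.array_equal(tables.range_mass[a.id], tables.range_mass[b.id])

    def test_range_consistent_with_stopping_power(self, tables, material_ids):
        """d(range)/dT recovers 1/L within 0.5% away from grid ends."""
        wid = material_ids["water"]
        g = tables.energy_grid
        drdt = np.gradient(tables.range_mass[wid], g)
        inv_l = 1.0 / tables.L_mass[wid]
        inner = slice(10, -10)
        assert np.allclose(drdt[inner], inv_l[inner], rtol=5e-3)

    def test_interpolation_bounded_by_nodes(self, tables, material_ids):
        wid = material_ids["water"]
        g = tables.energy_grid
        for i in (5, 100, 400):
            t = 0.5 * (g[i] + g[i + 1])
            val = tables.interp_linear(tables.L_mass[wid], t)
            lo, hi = sorted((tables.L_mass[wid][i], tables.L_mass[wid][i + 1]))
            assert lo <= val <= hi


class TestRange:
    def test_zero_path_identity(self, tables, material_ids):
        wid = material_ids["water"]
        e, exhausted = M.energy_after_pathlength(wid, 87.0, 0.0, tables)
        assert e == pytest.approx(87.0, rel=1e-9)
        assert not exhausted

    def test_roundtrip_consistency(self, tables, material_ids):
        wid = material_ids["water"]
        T = 100.0
        s = 10.0
        e, _ = M.energy_after_pathlength(wid, T, s, tables)
        r0 = M.residual_range(wid, T, tables)
        r1 = M.residual_range(wid, e, tables)
        assert r1 == pytest.approx(r0 - s, rel=1e-3)

    def test_against_ode_oracle(self, tables, material_ids):
        """Fine-step integration of dT/ds = -L as an independent oracle."""
        wid = material_ids["water"]

        def rhs(s, T):
            return [-0.1 * tables.interp_linear(tables.L_mass[wid], T[0])]

        sol = solve_ivp(rhs, [0.0, 10.0], [100.0], max_step=0.05, rtol=1e-10)
        expected = sol.y[0, -1]
        e, _ = M.energy_after_pathlength(wid, 100.0, 10.0, tables)
        assert e == pytest.approx(expected, rel=1e-3)

    def test_exhaustion_flag(self, tables, material_ids):
        wid = material_ids["water"]
        r = M.residual_range(wid, 50.0, tables)
        e, exhausted = M.energy_after_pathlength(wid, 50.0, 2 * r, tables)
        assert exhausted
        assert e == tables.energy_grid[0]

    def test_non_increasing_in_pathlength(self, tables, material_ids):
        wid = material_ids["water"]
        es = [M.energy_after_pathlength(wid, 150.0, s, tables)[0]
              for s in np.linspace(0, 120, 25)]
        assert np.all(np.diff(es) <= 0)


class TestBohrVariance:
    def test_linear_in_dx(self, tables, material_ids):
        wid = material_ids["water"]
        v1 = M.bohr_variance(wid, 150.0, 1.0, tables)
        v2 = M.bohr_variance(wid, 150.0, 2.0, tables)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)
        assert M.bohr_variance(wid, 150.0, 0.0, tables) == 0.0

    def test_matches_closed_form(self, tables, material_ids):
        """Independent evaluation of the restricted Bohr expression from
        the classical prefactor 4 pi r_e^2 (m_e c^2)^2 n_e."""
        wid = material_ids["water"]
        w = _material(tables, "water")
        T, dx = 150.0, 1.0
        beta2, _, tmax = M.kinematics(T)
        tup = min(tables.tecut, float(tmax))
        zoa = sum(wt * tables._by_sym[s].Z / tables._by_sym[s].A
                  for s, wt in w.weights.items())
        n_e = N_A * zoa * 1.0  # electrons per cm^3 at 1 g/cm^3
        prefactor = 4 * np.pi * R_E_CM**2 * M_E**2 * n_e  # MeV^2/cm
        expected = (prefactor * (tup / (2 * M_E * float(beta2)))
                    * (1.0 - float(beta2) * tup / (2 * float(tmax))) * dx * 0.1)
        got = M.bohr_variance(wid, T, dx, tables)
        # independent constants (r_e, N_A) agree with the tabulated
        # Bethe prefactor to ~1e-6 relative
        assert got == pytest.approx(expected, rel=1e-4)


class TestNuclearXS:
    def test_zero_density(self, tables, material_ids):
        assert M.macroscopic_nuclear_xs(material_ids["water"], 0.0, 100.0,
                                        "elastic", tables) == 0.0

    def test_unknown_channel(self, tables, material_ids):
        with pytest.raises(ValueError):
            M.macroscopic_nuclear_xs(material_ids["water"], 1.0, 100.0,
                                     "fission", tables)

    def test_single_element_hand_computed(self, tables):
        """One-term evaluation: Sigma = rho N_A (w/A) sigma."""
        # pmma has three elements; hydrogen's elastic term alone
        w = _material(tables, "water")
        el_h = tables._by_sym["H"]
        k = [e.symbol for e in tables.elements].index("H")
        T = 100.0
        sig_barn = tables.interp_logT(tables.sigma_el[k], T)
        expected_h = 1.0 * N_A * w.weights["H"] / el_h.A * sig_barn * 1e-24 * 0.1
        el_o = tables._by_sym["O"]
        ko = [e.symbol for e in tables.elements].index("O")
        sig_o = tables.interp_logT(tables.sigma_el[ko], T)
        expected = expected_h + 1.0 * N_A * w.weights["O"] / el_o.A * sig_o * 1e-24 * 0.1
        got = M.macroscopic_nuclear_xs(w.id, 1.0, T, "elastic", tables)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_linearity_over_elements(self, tables):
        """Sigma of a mixture equals the weight-sum of per-element terms."""
        got = M.macroscopic_nuclear_xs(_material(tables, "water").id, 1.3,
                                       80.0, "inelastic", tables)
        total = 0.0
        w = _material(tables, "water")
        for k, el in enumerate(tables.elements):
            wt = w.weights.get(el.symbol, 0.0)
            if wt:
                sig = tables.interp_logT(tables.sigma_inel[k], 80.0)
                total += 1.3 * N_A * wt / el.A * sig * 1e-24 * 0.1
        assert got == pytest.approx(total, rel=1e-12)

    def test_hydrogen_has_no_inelastic(self, tables):
        k = [e.symbol for e in tables.elements].index("H")
        assert np.all(tables.sigma_inel[k] == 0.0)


class TestPersistence:
    def test_roundtrip_bit_exact(self, tables, tmp_path):
        p = tmp_path / "tables.h5"
        M.save_tables(tables, p)
        loaded = M.load_tables(p)
        for name in ("energy_grid", "L_mass", "range_mass", "sig_ion_mass",
                     "sigma_el", "sigma_inel"):
            assert np.array_equal(getattr(tables, name), getattr(loaded, name))
        assert loaded.tecut == tables.tecut

    def test_version_rejected(self, tables, tmp_path):
        import h5py
        p = tmp_path / "tables.h5"
        M.save_tables(tables, p)
        with h5py.File(p, "a") as f:
            f.attrs["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            M.load_tables(p)
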