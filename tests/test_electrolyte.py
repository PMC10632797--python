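"""Primitive-model electrolyte: BMCSL, MSA, mixing curves and efficiency."""

import numpy as np
import pytest

from twistpore import electrolyte as el
from twistpore.constants import MOLAR_TO_PER_A3, bjerrum_length, thermal_energy
from twistpore.errors import ElectrolyteError

from conftest import random_neutral_state


class TestIdeal:
    def test_reference_concentration_gives_zero(self):
        st = el.SolutionState({"K": 1.0, "Cl": 1.0})
        assert el.ideal_mu(st, "K") == 0.0

    def test_e_molar_gives_kt(self):
        st = el.SolutionState({"K": np.e, "Cl": np.e})
        assert el.ideal_mu(st, "K") == pytest.approx(
            thermal_energy(300.0), rel=1e-12
        )

    def test_additivity(self):
        s1 = el.SolutionState({"K": 0.3, "Cl": 0.3})
        s2 = el.SolutionState({"K": 0.05, "Cl": 0.05})
        diff = el.ideal_mu(s1, "K") - el.ideal_mu(s2, "K")
        assert diff == pytest.approx(
            thermal_energy(300.0) * np.log(0.3 / 0.05), rel=1e-12
        )

    def test_zero_concentration_rejected(self):
        st = el.SolutionState({"K": 1.0, "Cl": 1.0})
        with pytest.raises(ElectrolyteError):
            el.ideal_mu(st, "Na")


class TestHardSphere:
    def test_dilute_limit_vanishes(self):
        st = el.SolutionState({"K": 1e-12, "Cl": 1e-12})
        assert el.hs_mu(st, "K") == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_equal_diameters_match_carnahan_starling(self, seed):
        """BMCSL collapses to the one-component CS excess chemical potential."""
        rng = np.random.default_rng(seed)
        st = random_neutral_state(rng, equal_diameter=rng.uniform(3.0, 6.0))
        eta = st.packing_fraction()
        mu_cs = eta * (8 - 9 * eta + 3 * eta**2) / (1 - eta) ** 3
        for name in st.concentrations:
            assert el.hs_mu(st, name) == pytest.approx(
                thermal_energy(300.0) * mu_cs, rel=1e-10
            )

    def test_strictly_increasing_in_total_concentration(self):
        values = []
        for c in np.linspace(0.1, 2.0, 8):
            st = el.SolutionState({"K": c, "Cl": c})
            values.append(el.hs_mu(st, "K"))
        assert all(a < b for a, b in zip(values, values[1:]))


class TestMSA:
    @pytest.mark.parametrize("seed", range(50))
    def test_gamma_matches_restricted_closed_form(self, seed):
        """Equal diameters: Γ = (sqrt(1 + 2κσ) − 1)/(2σ) to 1e-10."""
        rng = np.random.default_rng(100 + seed)
        sigma = rng.uniform(3.0, 6.5)
        st = random_neutral_state(rng, equal_diameter=sigma)
        lb = bjerrum_length(st.temperature, st.relative_permittivity)
        ionic = sum(
            c * MOLAR_TO_PER_A3 * st.species[n].valence ** 2
            for n, c in st.concentrations.items()
        )
        kappa = np.sqrt(4 * np.pi * lb * ionic)
        closed = (np.sqrt(1 + 2 * kappa * sigma) - 1) / (2 * sigma)
        assert el.solve_msa_gamma(st) == pytest.approx(closed, rel=1e-10)

    def test_gamma_solver_residual(self):
        st = el.SolutionState({"K": 0.5, "Na": 0.5, "Cl": 1.0})
        gamma = el.solve_msa_gamma(st)
        names = sorted(st.concentrations)
        dens = np.array([st.concentrations[n] * MOLAR_TO_PER_A3 for n in names])
        val = np.array([float(st.species[n].valence) for n in names])
        dia = np.array([st.species[n].hydrated_diameter for n in names])
        lb = bjerrum_length(300.0, 78.4)
        eta = el._msa_eta(gamma, dens, dia, val)
        x = (val - eta * dia**2) / (1 + gamma * dia)
        residual = gamma - 0.5 * np.sqrt(4 * np.pi * lb * np.sum(dens * x**2))
        assert abs(residual) < 1e-12 * gamma

    def test_neutral_species_no_electrostatics(self):
        species = {
            "A": el.IonSpecies("A", 0, 4.0),
            "B": el.IonSpecies("B", 0, 5.0),
        }
        st = el.SolutionState({"A": 0.5, "B": 0.5}, species=species)
        assert el.msa_mu(st, "A") == 0.0

    @pytest.mark.parametrize("c", [1e-4, 1e-5, 1e-6])
    def test_debye_hueckel_limiting_law(self, c):
        """ln γ± → −λ_B κ/2 for a dilute 1:1 electrolyte."""
        st = el.SolutionState({"K": c, "Cl": c})
        lb = bjerrum_length(300.0, 78.4)
        kappa = np.sqrt(4 * np.pi * lb * 2 * c * MOLAR_TO_PER_A3)
        ln_gamma = 0.5 * (
            el.msa_mu(st, "K") + el.msa_mu(st, "Cl")
        ) / thermal_energy(300.0)
        assert ln_gamma == pytest.approx(-lb * kappa / 2, rel=0.02 if c > 1e-5 else 0.05)

    def test_maxwell_symmetry_of_chemical_potentials(self):
        """∂μ_i/∂ρ_j = ∂μ_j/∂ρ_i: the numerical μ derive from one free energy."""
        st = el.SolutionState({"K": 0.4, "Na": 0.6, "Cl": 1.0})
        h = 1e-4

        def mu(name, conc):
            s = el._unchecked(st, conc)
            return el.msa_mu(s, name) + el.hs_mu(s, name)

        base = dict(st.concentrations)
        for i, j in (("K", "Cl"), ("Na", "Cl"), ("K", "Na")):
            up_j = dict(base); up_j[j] = base[j] + h
            dn_j = dict(base); dn_j[j] = base[j] - h
            dmui_dcj = (mu(i, up_j) - mu(i, dn_j)) / (2 * h)
            up_i = dict(base); up_i[i] = base[i] + h
            dn_i = dict(base); dn_i[i] = base[i] - h
            dmuj_dci = (mu(j, up_i) - mu(j, dn_i)) / (2 * h)
            assert dmui_dcj == pytest.approx(dmuj_dci, rel=1e-3, abs=1e-8)


class TestReservoir:
    def test_reference_state_zero_ideal_free_energy(self):
        st = el.SolutionState({"K": 1.0, "Cl": 1.0})
        assert el.reservoir_free_energy(st, 1.0, ("ideal",)) == 0.0

    def test_extensive_in_volume(self):
        st = el.SolutionState({"K": 0.5, "Na": 0.5, "Cl": 1.0})
        g1 = el.reservoir_free_energy(st, 1.0)
        g2 = el.reservoir_free_energy(st, 2.0)
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_mixing_lowers_ideal_free_energy(self):
        mixed = el.SolutionState({"K": 0.5, "Na": 0.5, "Cl": 1.0})
        pure = el.SolutionState({"K": 1.0, "Cl": 1.0})
        assert el.reservoir_free_energy(mixed, 1.0, ("ideal",)) < (
            el.reservoir_free_energy(pure, 1.0, ("ideal",))
        )


class TestMixingCurves:
    def test_zero_transfer_zero_free_energy(self):
        grid = np.array([0.0, 0.1, 0.2])
        for mode in ("KPM", "free_mix"):
            curve = el.mixing_curve(mode, grid, terms=("ideal",))
            assert curve.dg[0] == 0.0

    def test_ideal_kpm_argmin_one_third(self):
        grid = np.arange(0.0, 0.45, 0.002)
        curve = el.mixing_curve("KPM", grid, terms=("ideal",))
        assert el.spontaneous_terminus(curve) == pytest.approx(1 / 3, abs=2e-3)

    def test_ideal_free_mix_argmin_one_half(self):
        grid = np.arange(0.0, 0.8, 0.002)
        curve = el.mixing_curve("free_mix", grid, terms=("ideal",))
        assert el.spontaneous_terminus(curve) == pytest.approx(0.5, abs=2e-3)

    @pytest.mark.parametrize(
        "terms",
        [("ideal",), ("ideal", "hs"), ("ideal", "msa"), ("ideal", "hs", "msa")],
    )
    def test_kpm_curve_above_free_mix_everywhere(self, terms):
        grid = np.arange(0.0, 0.42, 0.02)
        kpm = el.mixing_curve("KPM", grid, terms=terms)
        free = el.mixing_curve("free_mix", grid, terms=terms)
        assert np.all(kpm.dg >= free.dg - 1e-9)

    def test_ideal_efficiency_at_0p16(self):
        """Closed-form ideal-only check: |f_KPM|/|f_free| ≈ 0.414/0.879."""
        x = 0.16
        f_kpm = 2 * (1 - x) * np.log(1 - x) + x * np.log(x) + (1 + x) * np.log(1 + x)
        f_free = 2 * ((1 - x) * np.log(1 - x) + x * np.log(x))
        grid = np.arange(0.0, 0.45, 0.002)
        kpm = el.mixing_curve("KPM", grid, terms=("ideal",))
        free = el.mixing_curve("free_mix", grid, terms=("ideal",))
        eff = el.efficiency(kpm, free, x)
        assert f_kpm / f_free == pytest.approx(0.414 / 0.879, rel=0.01)
        assert eff["eta"] == pytest.approx(f_kpm / f_free, rel=1e-3)

    def test_parabola_vertex_refined_exactly(self):
        grid = np.arange(0.0, 0.41, 0.05)
        curve = el.MixingCurve("KPM", grid, (grid - 0.17) ** 2, ("ideal",))
        assert el.spontaneous_terminus(curve) == pytest.approx(0.17, abs=1e-12)

    def test_monotone_curve_has_no_terminus(self):
        grid = np.linspace(0.0, 0.4, 20)
        curve = el.MixingCurve("free_mix", grid, -grid, ("ideal",))
        with pytest.raises(ElectrolyteError):
            el.spontaneous_terminus(curve)

    def test_identical_curves_unit_efficiency(self):
        grid = np.linspace(0.0, 0.4, 40)
        dg = (grid - 0.2) ** 2 - 0.04
        a = el.MixingCurve("KPM", grid, dg, ("ideal",))
        b = el.MixingCurve("free_mix", grid, dg, ("ideal",))
        assert el.efficiency(a, b, 0.1)["eta"] == pytest.approx(1.0)

    def test_efficiency_normalization_invariant(self):
        """η is a ratio of ΔG values: rescaling both curves leaves it fixed."""
        grid = np.arange(0.0, 0.45, 0.005)
        kpm = el.mixing_curve("KPM", grid, terms=("ideal",))
        free = el.mixing_curve("free_mix", grid, terms=("ideal",))
        eta = el.efficiency(kpm, free, 0.2)["eta"]
        kpm2 = el.MixingCurve("KPM", grid, 17.3 * kpm.dg, kpm.terms)
        free2 = el.MixingCurve("free_mix", grid, 17.3 * free.dg, free.terms)
        assert el.efficiency(kpm2, free2, 0.2)["eta"] == pytest.approx(eta, rel=1e-12)

    def test_beyond_spontaneous_branch_rejected(self):
        grid = np.arange(0.0, 0.45, 0.005)
        kpm = el.mixing_curve("KPM", grid, terms=("ideal",))
        free = el.mixing_curve("free_mix", grid, terms=("ideal",))
        with pytest.raises(ElectrolyteError):
            el.efficiency(kpm, free, 0.4)


class TestValidation:
    def test_charge_imbalance_rejected(self):
        with pytest.raises(ElectrolyteError):
            el.SolutionState({"K": 1.0, "Cl": 0.5})

    def test_negative_concentration_rejected(self):
        with pytest.raises(ElectrolyteError):
            el.SolutionState({"K": -0.1, "Cl": -0.1})

    def test_invalid_grid_rejected(self):
        with pytest.raises(ElectrolyteError):
            el.mixing_curve("KPM", np.array([0.0, 1.2]))
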