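"""Primitive-model electrolyte thermodynamics.

Aqueous KCl/NaCl solutions are treated as charged hard spheres in a
dielectric continuum.  The chemical potential of each species is a sum of

* an ideal term ``k_B T ln(c/c°)`` with ``c° = 1 mol/L``,
* a hard-sphere excess from the Boublík--Mansoori--Carnahan--Starling--Leland
  (BMCSL) mixture equation of state, and
* an electrostatic excess from the non-restricted mean spherical
  approximation (MSA) with its screening parameter Γ solved
  self-consistently.

The direct mean-field Coulomb term between homogeneous electroneutral
reservoirs vanishes and is therefore not represented.

On top of the chemical potentials the module builds the salinity-mixing
scenarios for osmotic power generation with a potassium-permselective
membrane (KPM): two 1 L reservoirs, initially 1 M KCl (left) and 1 M NaCl
(right), exchange δC mol of salt either non-selectively ("free mix") or
with only K⁺ allowed through (KPM, electroneutral KCl bookkeeping).  The
mixing free-energy curve ΔG_m(δC), its spontaneous terminus δC₀, and the
work ratio η = ON/OP follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    DEFAULT_PERMITTIVITY,
    DEFAULT_TEMPERATURE,
    KCAL_TO_KJ,
    MOLAR_TO_PER_A3,
    bjerrum_length,
    thermal_energy,
)
from .errors import ElectrolyteError

__all__ = [
    "IonSpecies",
    "SolutionState",
    "MixingCurve",
    "DEFAULT_SPECIES",
    "ideal_mu",
    "hs_mu",
    "msa_mu",
    "solve_msa_gamma",
    "chemical_potential",
    "reservoir_free_energy",
    "mixing_curve",
    "spontaneous_terminus",
    "efficiency",
]


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species of the primitive model."""

    name: str
    valence: int
    hydrated_diameter: float  # Å

    def __post_init__(self) -> None:
        if self.hydrated_diameter <= 0:
            raise ElectrolyteError(f"non-positive diameter for {self.name}")


#: Hydrated diameters of K+, Na+ and Cl- (Å).
DEFAULT_SPECIES = {
    "K": IonSpecies("K", +1, 5.6),
    "Na": IonSpecies("Na", +1, 4.7),
    "Cl": IonSpecies("Cl", -1, 6.4),
}

_NEUTRALITY_TOL = 1e-9
_MAX_PACKING = 0.74


@dataclass(frozen=True)
class SolutionState:
    """A homogeneous electrolyte solution.

    ``concentrations`` maps species names to molarities (mol/L); species
    not listed are absent.  The state must be electroneutral.
    """

    concentrations: dict[str, float]
    temperature: float = DEFAULT_TEMPERATURE
    relative_permittivity: float = DEFAULT_PERMITTIVITY
    species: dict[str, IonSpecies] = field(default_factory=lambda: dict(DEFAULT_SPECIES))

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if name not in self.species:
                raise ElectrolyteError(f"unknown species {name!r}")
            if c < 0:
                raise ElectrolyteError(f"negative concentration for {name}: {c}")
        charge = sum(
            self.species[n].valence * c for n, c in self.concentrations.items()
        )
        if abs(charge) > _NEUTRALITY_TOL:
            raise ElectrolyteError(f"state not electroneutral: net charge {charge} M")
        if self.packing_fraction() >= _MAX_PACKING:
            raise ElectrolyteError("hard-sphere packing fraction beyond close packing")

    # -- helpers -------------------------------------------------------
    def number_densities(self) -> dict[str, float]:
        """Number densities in 1/Å^3."""
        return {n: c * MOLAR_TO_PER_A3 for n, c in self.concentrations.items()}

    def packing_fraction(self) -> float:
        return sum(
            np.pi / 6.0 * rho * self.species[n].hydrated_diameter ** 3
            for n, rho in self.number_densities().items()
        )

    def with_concentrations(self, concentrations: dict[str, float]) -> "SolutionState":
        return replace(self, concentrations=dict(concentrations))


# ----------------------------------------------------------------------
# chemical potential terms
# ----------------------------------------------------------------------

def ideal_mu(state: SolutionState, name: str) -> float:
    """Ideal-solution chemical potential k_B T ln(c/c°), kcal/mol."""
    c = state.concentrations.get(name, 0.0)
    if c <= 0:
        raise ElectrolyteError(f"ideal_mu undefined at zero concentration ({name})")
    return thermal_energy(state.temperature) * float(np.log(c))


def _xi(densities: np.ndarray, diameters: np.ndarray) -> np.ndarray:
    """Moments ξ_n = (π/6) Σ ρ_i σ_i^n for n = 0..3."""
    return np.array(
        [np.pi / 6.0 * np.sum(densities * diameters**n) for n in range(4)]
    )


def _bmcsl_free_energy_density(densities: np.ndarray, diameters: np.ndarray) -> float:
    """BMCSL excess Helmholtz free energy per volume, in units of k_B T / Å^3."""
    xi0, xi1, xi2, xi3 = _xi(densities, diameters)
    if xi3 <= 0:
        return 0.0
    delta = 1.0 - xi3
    if delta <= 0:
        raise ElectrolyteError("packing fraction >= 1 in BMCSL")
    return (6.0 / np.pi) * (
        3.0 * xi1 * xi2 / delta
        + xi2**3 / (xi3 * delta**2)
        + (xi2**3 / xi3**2 - xi0) * np.log(delta)
    )


def _bmcsl_mu_excess(densities: np.ndarray, diameters: np.ndarray) -> np.ndarray:
    """BMCSL excess chemical potentials βμ_i^hs for every species (dimensionless).

    Obtained analytically as ∂(βA/V)/∂ρ_i through the moments ξ_n
    (∂ξ_n/∂ρ_i = (π/6) σ_i^n).
    """
    xi0, xi1, xi2, xi3 = _xi(densities, diameters)
    if xi3 <= 0:
        return np.zeros_like(densities)
    delta = 1.0 - xi3
    log_delta = np.log(delta)
    dF = np.empty(4)
    dF[0] = -log_delta
    dF[1] = 3.0 * xi2 / delta
    dF[2] = 3.0 * xi1 / delta + 3.0 * xi2**2 / (xi3 * delta**2) + (
        3.0 * xi2**2 / xi3**2
    ) * log_delta
    dF[3] = (
        3.0 * xi1 * xi2 / delta**2
        + xi2**3 * (2.0 / (xi3 * delta**3) - 1.0 / (xi3**2 * delta**2))
        - 2.0 * xi2**3 / xi3**3 * log_delta
        - (xi2**3 / xi3**2 - xi0) / delta
    )
    powers = np.stack([diameters**n for n in range(4)])  # (4, n_species)
    return dF @ powers


def hs_mu(state: SolutionState, name: str) -> float:
    """BMCSL hard-sphere excess chemical potential, kcal/mol."""
    names = sorted(state.concentrations)
    densities = np.array([state.concentrations[n] * MOLAR_TO_PER_A3 for n in names])
    diameters = np.array([state.species[n].hydrated_diameter for n in names])
    if name not in names:
        raise ElectrolyteError(f"species {name!r} absent from state")
    beta_mu = _bmcsl_mu_excess(densities, diameters)
    return thermal_energy(state.temperature) * float(beta_mu[names.index(name)])


# ----------------------------------------------------------------------
# MSA electrostatics
# ----------------------------------------------------------------------

def _msa_eta(gamma: float, densities, diameters, valences) -> float:
    """The P_n-coupling parameter η of the non-restricted MSA."""
    delta = 1.0 - np.pi / 6.0 * np.sum(densities * diameters**3)
    omega = 1.0 + (np.pi / (2.0 * delta)) * np.sum(
        densities * diameters**3 / (1.0 + gamma * diameters)
    )
    pn = np.sum(densities * diameters * valences / (1.0 + gamma * diameters))
    return (np.pi / (2.0 * delta)) * pn / omega


def solve_msa_gamma(
    state: SolutionState, tol: float = 1e-12, max_iter: int = 500
) -> float:
    """Solve the MSA screening parameter Γ (1/Å) self-consistently.

    Iterates 2Γ = sqrt(4 π λ_B Σ ρ_i X_i(Γ)^2) with
    X_i = (z_i - η σ_i^2)/(1 + Γ σ_i), starting from the Debye value
    Γ = κ/2.  Converges to a relative tolerance of ``tol``.
    """
    names = sorted(state.concentrations)
    densities = np.array([state.concentrations[n] * MOLAR_TO_PER_A3 for n in names])
    valences = np.array([float(state.species[n].valence) for n in names])
    diameters = np.array([state.species[n].hydrated_diameter for n in names])
    lb = bjerrum_length(state.temperature, state.relative_permittivity)
    ionic = np.sum(densities * valences**2)
    if ionic <= 0:
        return 0.0
    kappa = np.sqrt(4.0 * np.pi * lb * ionic)
    gamma = kappa / 2.0
    for _ in range(max_iter):
        eta = _msa_eta(gamma, densities, diameters, valences)
        x = (valences - eta * diameters**2) / (1.0 + gamma * diameters)
        new = 0.5 * np.sqrt(4.0 * np.pi * lb * np.sum(densities * x**2))
        if abs(new - gamma) <= tol * max(new, 1e-30):
            return float(new)
        gamma = new
    raise ElectrolyteError("MSA Γ iteration did not converge")


def _msa_free_energy_density(state: SolutionState) -> float:
    """MSA electrostatic Helmholtz free energy per volume, k_B T / Å^3.

    Energy route: βA_el/V = βE/V + Γ^3/(3π) with
    βE/V = -λ_B Σ ρ_i z_i (Γ z_i + η σ_i)/(1 + Γ σ_i).
    """
    names = sorted(state.concentrations)
    densities = np.array([state.concentrations[n] * MOLAR_TO_PER_A3 for n in names])
    if densities.sum() == 0:
        return 0.0
    valences = np.array([float(state.species[n].valence) for n in names])
    diameters = np.array([state.species[n].hydrated_diameter for n in names])
    lb = bjerrum_length(state.temperature, state.relative_permittivity)
    gamma = solve_msa_gamma(state)
    if gamma == 0.0:
        return 0.0
    eta = _msa_eta(gamma, densities, diameters, valences)
    energy = -lb * np.sum(
        densities * valences * (gamma * valences + eta * diameters)
        / (1.0 + gamma * diameters)
    )
    return float(energy + gamma**3 / (3.0 * np.pi))


def msa_mu(state: SolutionState, name: str, rel_step: float = 1e-5) -> float:
    """MSA electrostatic excess chemical potential, kcal/mol.

    Computed as the numerical composition derivative of the MSA free-energy
    density, re-solving Γ at the displaced compositions; this keeps the
    result exact for the non-restricted (unequal-diameter) theory without
    committing to a closed-form μ expression.  The equal-diameter closed
    form is used as an oracle in the test suite.
    """
    if name not in state.concentrations:
        raise ElectrolyteError(f"species {name!r} absent from state")
    c = state.concentrations[name]
    valences_present = any(
        state.species[n].valence != 0 for n in state.concentrations
    )
    if not valences_present:
        return 0.0
    h = max(c * rel_step, 1e-7)
    up = dict(state.concentrations)
    dn = dict(state.concentrations)
    up[name] = c + h
    dn[name] = max(c - h, 0.0)
    # bypass electroneutrality validation for the displaced states: the
    # free-energy density is an analytic function of the densities and the
    # physical μ is its derivative along a single-species displacement.
    a_up = _msa_free_energy_density(_unchecked(state, up))
    a_dn = _msa_free_energy_density(_unchecked(state, dn))
    dadrho = (a_up - a_dn) / ((up[name] - dn[name]) * MOLAR_TO_PER_A3)
    return thermal_energy(state.temperature) * float(dadrho)


def _unchecked(state: SolutionState, concentrations: dict[str, float]) -> SolutionState:
    new = object.__new__(SolutionState)
    object.__setattr__(new, "concentrations", concentrations)
    object.__setattr__(new, "temperature", state.temperature)
    object.__setattr__(new, "relative_permittivity", state.relative_permittivity)
    object.__setattr__(new, "species", state.species)
    return new


_TERMS = ("ideal", "hs", "msa")


def chemical_potential(
    state: SolutionState, name: str, terms: tuple[str, ...] = _TERMS
) -> float:
    """Total chemical potential (kcal/mol) with the requested terms."""
    mu = 0.0
    for term in terms:
        if term == "ideal":
            mu += ideal_mu(state, name)
        elif term == "hs":
            mu += hs_mu(state, name)
        elif term == "msa":
            mu += msa_mu(state, name)
        else:
            raise ElectrolyteError(f"unknown model term {term!r}")
    return mu


def reservoir_free_energy(
    state: SolutionState, volume_l: float = 1.0, terms: tuple[str, ...] = _TERMS
) -> float:
    """Free energy G = Σ n_i μ_i of a reservoir, in kcal (Euler convention).

    Species at zero concentration contribute nothing (the n ln n limit).
    """
    g = 0.0
    for name, c in state.concentrations.items():
        if c == 0.0:
            continue
        g += c * volume_l * chemical_potential(state, name, terms)
    return g


# ----------------------------------------------------------------------
# mixing scenarios
# ----------------------------------------------------------------------

@dataclass
class MixingCurve:
    """ΔG_m(δC) for one mixing mode.

    ``dg`` is in kJ per mole of initial salt per reservoir (1 mol for the
    default 1 L / 1 M setup) unless ``normalization`` says otherwise.
    """

    mode: str
    dc: np.ndarray
    dg: np.ndarray
    terms: tuple[str, ...]
    normalization: str = "kJ/mol-salt"

    def interpolate(self, dc: float) -> float:
        return float(np.interp(dc, self.dc, self.dg))


def _kpm_compositions(x: float, c0: float) -> tuple[dict, dict]:
    """Reservoir compositions after transferring x mol KCl through a KPM."""
    left = {"K": c0 - x, "Cl": c0 - x}
    right = {"Na": c0, "K": x, "Cl": c0 + x}
    return left, right


def _free_mix_compositions(x: float, c0: float) -> tuple[dict, dict]:
    """Compositions after a non-selective exchange of x mol K+ for x mol Na+."""
    left = {"K": c0 - x, "Na": x, "Cl": c0}
    right = {"Na": c0 - x, "K": x, "Cl": c0}
    return left, right


def mixing_curve(
    mode: str,
    dc_grid: np.ndarray | None = None,
    terms: tuple[str, ...] = _TERMS,
    c0: float = 1.0,
    volume_l: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
    relative_permittivity: float = DEFAULT_PERMITTIVITY,
    species: dict[str, IonSpecies] | None = None,
) -> MixingCurve:
    """Mixing free-energy curve ΔG_m(δC) for ``mode`` in {"free_mix", "KPM"}.

    δC is the amount of K⁺ (in mol, equal to mol/L at 1 L) moved from the
    KCl reservoir to the NaCl reservoir.  ΔG_m(0) = 0 by construction.
    """
    if dc_grid is None:
        dc_grid = np.arange(0.0, 0.5 + 1e-12, 0.001)
    dc_grid = np.asarray(dc_grid, dtype=float)
    if dc_grid.min() < 0 or dc_grid.max() >= c0:
        raise ElectrolyteError("δC grid must lie in [0, c0)")
    if mode not in ("free_mix", "KPM"):
        raise ElectrolyteError(f"unknown mixing mode {mode!r}")
    comp = _kpm_compositions if mode == "KPM" else _free_mix_compositions
    sp = dict(species) if species is not None else dict(DEFAULT_SPECIES)

    def g_total(x: float) -> float:
        left_c, right_c = comp(x, c0)
        g = 0.0
        for conc in (left_c, right_c):
            state = SolutionState(
                {k: v for k, v in conc.items() if v > 0},
                temperature=temperature,
                relative_permittivity=relative_permittivity,
                species=sp,
            )
            g += reservoir_free_energy(state, volume_l, terms)
        return g

    g0 = g_total(0.0)
    dg_kcal = np.array([g_total(float(x)) - g0 for x in dc_grid])
    moles_salt = c0 * volume_l  # initial salt per reservoir
    dg = dg_kcal * KCAL_TO_KJ / moles_salt
    return MixingCurve(mode=mode, dc=dc_grid, dg=dg, terms=terms)


def spontaneous_terminus(curve: MixingCurve) -> float:
    """δC₀: location of the interior minimum of the mixing curve.

    The grid argmin is refined by a local quadratic fit through the three
    surrounding points.  A curve that is monotone on its grid has no
    spontaneous terminus and raises.
    """
    i = int(np.argmin(curve.dg))
    if i == 0 or i == len(curve.dg) - 1:
        raise ElectrolyteError("mixing curve has no interior minimum on its grid")
    x = curve.dc[i - 1 : i + 2]
    y = curve.dg[i - 1 : i + 2]
    a, b, _ = np.polyfit(x, y, 2)
    if a <= 0:
        return float(curve.dc[i])
    return float(-b / (2.0 * a))


def efficiency(
    curve_kpm: MixingCurve,
    curve_free: MixingCurve,
    dc: float,
    enforce_spontaneous: bool = True,
) -> dict:
    """Extractable work ON, free-mix work loss OP and η = ON/OP at δC = ``dc``.

    With ``enforce_spontaneous`` (the default), ``dc`` must lie on the
    spontaneous branch of the KPM curve (δC ≤ δC₀); with the flag off
    the ratio is evaluated wherever both curves are defined.  η is a
    ratio of two ΔG_m values and is therefore independent of the curve
    normalization.
    """
    if enforce_spontaneous:
        dc0 = spontaneous_terminus(curve_kpm)
        if dc > dc0 * (1.0 + 1e-6):
            raise ElectrolyteError(
                f"δC = {dc} beyond the spontaneous branch (δC₀ = {dc0:.4f})"
            )
    on = abs(curve_kpm.interpolate(dc))
    op = abs(curve_free.interpolate(dc))
    if op == 0:
        raise ElectrolyteError("free-mix work loss vanishes at this δC")
    return {"ON": on, "OP": op, "eta": on / op}
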