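"""Osmotic power generation with a potassium-permselective membrane.

With 1 M KCl and 1 M NaCl on the two sides of the membrane, only K⁺
permeates: the current–voltage line has non-zero intercepts — a net
diffusive current I_diff at zero bias and a reversal potential U_diff.
This module fits those intercepts, provides a Goldman–Hodgkin–Katz
reversal-potential calculator, a dual-ion Coulomb repulsion utility, and
the scaling from single-pore power to membrane areal power density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .constants import COULOMB_KCAL_A, DEFAULT_TEMPERATURE, RT_OVER_F_PER_K
from .errors import AnalysisError, GeometryError

__all__ = [
    "IVData",
    "IVFit",
    "OsmoticOutput",
    "fit_iv",
    "ghk_reversal",
    "coulomb_energy",
    "pore_density_from_pitch",
    "power_density",
    "porosity",
    "max_transfer_power",
    "osmotic_output",
]


@dataclass(frozen=True)
class IVData:
    """Paired current–voltage samples (pA vs mV)."""

    applied_voltage: np.ndarray  # mV
    current: np.ndarray  # pA

    def __post_init__(self) -> None:
        v = np.asarray(self.applied_voltage, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if v.shape != i.shape or v.ndim != 1:
            raise AnalysisError("voltage and current must be 1-D and paired")
        if len(np.unique(v)) < 3:
            raise AnalysisError("need at least 3 distinct voltages")
        object.__setattr__(self, "applied_voltage", v)
        object.__setattr__(self, "current", i)


@dataclass(frozen=True)
class IVFit:
    conductance: float  # nS (pA/mV)
    i_diff: float  # pA, current at V = 0
    u_diff: float  # mV, voltage intercept (reversal potential)
    stderr_conductance: float
    stderr_i_diff: float


@dataclass(frozen=True)
class OsmoticOutput:
    i_diff: float  # pA
    u_diff: float  # mV
    single_pore_power: float  # W
    pore_density: float  # pores/m^2
    power_density: float  # W/m^2


def read_iv(path) -> IVData:
    """Read `voltage_mV,current_pA` CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    return IVData(df["voltage_mV"].to_numpy(), df["current_pA"].to_numpy())


def write_iv(data: IVData, path):
    import pandas as pd

    pd.DataFrame(
        {"voltage_mV": data.applied_voltage, "current_pA": data.current}
    ).to_csv(path, index=False)
    return path


def fit_iv(data: IVData) -> IVFit:
    """Least-squares line through the I–V samples.

    I_diff is the current intercept at V = 0; U_diff = −I_diff/G is the
    voltage at which the net current reverses.  Positive current is
    cation flux from the KCl to the NaCl reservoir.
    """
    design = sm.add_constant(data.applied_voltage)
    res = sm.OLS(data.current, design).fit()
    i0, slope = res.params
    if slope == 0:
        raise AnalysisError("zero conductance: U_diff undefined")
    return IVFit(
        conductance=float(slope),
        i_diff=float(i0),
        u_diff=float(-i0 / slope),
        stderr_conductance=float(res.bse[1]),
        stderr_i_diff=float(res.bse[0]),
    )


def ghk_reversal(
    permeabilities: dict[str, float],
    concentrations_left: dict[str, float],
    concentrations_right: dict[str, float],
    temperature: float = DEFAULT_TEMPERATURE,
    valences: dict[str, int] | None = None,
) -> float:
    """Goldman–Hodgkin–Katz reversal potential, mV.

    Monovalent ions only; ``valences`` defaults to +1 for K/Na and −1 for
    Cl.  Returns the potential of the left side relative to the right:

        U = (RT/F) ln [ (Σ_cat P c_right + Σ_an P c_left)
                      / (Σ_cat P c_left + Σ_an P c_right) ]

    With a single permeant cation this reduces to the Nernst potential
    (RT/F)·ln(c_right/c_left); swapping the two sides flips the sign.
    """
    if valences is None:
        valences = {"K": 1, "Na": 1, "Cl": -1}
    if not permeabilities or all(p == 0 for p in permeabilities.values()):
        raise AnalysisError("at least one nonzero permeability required")
    num = 0.0
    den = 0.0
    for name, p in permeabilities.items():
        z = valences.get(name)
        if z is None:
            raise AnalysisError(f"no valence for species {name!r}")
        if abs(z) != 1:
            raise AnalysisError("GHK form implemented for monovalent ions only")
        cl = concentrations_left.get(name, 0.0)
        cr = concentrations_right.get(name, 0.0)
        if z > 0:
            num += p * cr
            den += p * cl
        else:
            num += p * cl
            den += p * cr
    if num <= 0 or den <= 0:
        raise AnalysisError("GHK argument non-positive; check concentrations")
    return RT_OVER_F_PER_K * temperature * 1e3 * float(np.log(num / den))


def coulomb_energy(
    valence1: int, valence2: int, separation: float, relative_permittivity: float = 1.0
) -> float:
    """Direct electrostatic energy of two point charges, kcal/mol."""
    if separation <= 0:
        raise GeometryError("separation must be positive")
    return COULOMB_KCAL_A * valence1 * valence2 / (relative_permittivity * separation)


def pore_density_from_pitch(patch_edge_nm: float) -> float:
    """Pore density (pores/m²) for one pore per square patch of given edge."""
    if patch_edge_nm <= 0:
        raise GeometryError("patch edge must be positive")
    return 1.0 / (patch_edge_nm * 1e-9) ** 2


def power_density(single_pore_power: float, pore_density: float) -> float:
    """Areal power density, W/m²."""
    if single_pore_power < 0 or pore_density < 0:
        raise AnalysisError("power and density must be non-negative")
    return single_pore_power * pore_density


def porosity(pore_area_A2: float, pore_density: float) -> float:
    """Open-area fraction of the membrane (pore area in Å²)."""
    if pore_area_A2 < 0 or pore_density < 0:
        raise AnalysisError("area and density must be non-negative")
    phi = pore_area_A2 * 1e-20 * pore_density
    if phi >= 1.0:
        warnings.warn(f"porosity {phi:.3g} at or beyond full coverage", stacklevel=2)
    return phi


def max_transfer_power(i_diff_pA: float, u_diff_mV: float) -> float:
    """Maximum extractable power |I_diff·U_diff|/4 of a linear source, W."""
    return abs(i_diff_pA * 1e-12 * u_diff_mV * 1e-3) / 4.0


def osmotic_output(
    fit: IVFit,
    patch_edge_nm: float = 10.0,
    single_pore_power: float | None = None,
) -> OsmoticOutput:
    """Bundle I–V intercepts with the areal scaling.

    ``single_pore_power`` defaults to the maximum-power-transfer value
    |I_diff·U_diff|/4; pass an operating-point power to override.
    """
    density = pore_density_from_pitch(patch_edge_nm)
    p1 = (
        single_pore_power
        if single_pore_power is not None
        else max_transfer_power(fit.i_diff, fit.u_diff)
    )
    return OsmoticOutput(
        i_diff=fit.i_diff,
        u_diff=fit.u_diff,
        single_pore_power=p1,
        pore_density=density,
        power_density=power_density(p1, density),
    )
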