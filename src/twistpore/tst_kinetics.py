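"""Transition-state-theory permeation kinetics from PMF profiles.

The rate-determining step of ion permeation through the bilayer pore is
the hop from the binding site at the first layer (L1) to the second (L2).
Given the free-energy barrier ΔG of that hop and the attempt period τ
(the vibration period of the adsorbed ion, read off as the second zero of
the velocity autocorrelation function), the permeation rate is

    k = τ⁻¹ · exp(−ΔG / k_B T),

and the K⁺/Na⁺ selectivity ratio is the ratio of the two rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .errors import NoOscillationError, ProfileError

__all__ = [
    "PMFProfile",
    "VelocitySeries",
    "KineticsResult",
    "read_pmf",
    "write_pmf",
    "normalize_pmf",
    "locate_extrema",
    "rate_determining_barrier",
    "attempt_period_from_vacf",
    "permeation_rate",
    "selectivity_ratio",
]


@dataclass(frozen=True)
class PMFProfile:
    """Free energy (kcal/mol) along the pore axis (Å).

    ``annotations`` marks named coordinate intervals, e.g. the axial
    positions of the two graphene layers ("L1", "L2").
    """

    coordinate: np.ndarray
    free_energy: np.ndarray
    reference_region: tuple[float, float] | None = None
    annotations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coord = np.asarray(self.coordinate, dtype=float)
        pmf = np.asarray(self.free_energy, dtype=float)
        if coord.ndim != 1 or coord.shape != pmf.shape:
            raise ProfileError("coordinate and free_energy must be 1-D and equal length")
        if not np.all(np.diff(coord) > 0):
            raise ProfileError("coordinate grid must be strictly increasing")
        if not np.all(np.isfinite(pmf)):
            raise ProfileError("free energy must be finite")
        object.__setattr__(self, "coordinate", coord)
        object.__setattr__(self, "free_energy", pmf)


@dataclass(frozen=True)
class VelocitySeries:
    """Evenly sampled velocity component of a site-bound ion."""

    timestep: float  # ps
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ProfileError("timestep must be positive")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class KineticsResult:
    barrier: float  # kcal/mol
    attempt_period: float  # ps
    temperature: float  # K
    rate: float  # 1/s


# ----------------------------------------------------------------------
# I/O: two-column TSV, '#' comments
# ----------------------------------------------------------------------

def read_pmf(path: str | Path) -> PMFProfile:
    df = pd.read_csv(path, sep="\t", comment="#", names=["coordinate_A", "pmf_kcal_mol"])
    return PMFProfile(df["coordinate_A"].to_numpy(), df["pmf_kcal_mol"].to_numpy())


def write_pmf(profile: PMFProfile, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# coordinate_A\tpmf_kcal_mol\n")
        for x, g in zip(profile.coordinate, profile.free_energy):
            fh.write(f"{x:.6f}\t{g:.6f}\n")
    return path


def read_velocity(path: str | Path) -> VelocitySeries:
    """One velocity sample per line; `# timestep_ps <dt>` in the header."""
    timestep = None
    values = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "timestep_ps":
                timestep = float(parts[1])
            continue
        values.append(float(line))
    if timestep is None:
        raise ProfileError("velocity file lacks a '# timestep_ps' header")
    return VelocitySeries(timestep=timestep, values=np.array(values))


def write_velocity(series: VelocitySeries, path: str | Path) -> Path:
    path = Path(path)
    body = "\n".join(f"{v:.8g}" for v in series.values)
    path.write_text(f"# timestep_ps {series.timestep}\n{body}\n")
    return path


# ----------------------------------------------------------------------
# profile operations
# ----------------------------------------------------------------------

def normalize_pmf(
    profile: PMFProfile, reference_region: tuple[float, float] | None = None
) -> PMFProfile:
    """Shift the profile so the mean over the bulk reference region is zero."""
    region = reference_region or profile.reference_region
    if region is None:
        raise ProfileError("no reference region given")
    lo, hi = sorted(region)
    mask = (profile.coordinate >= lo) & (profile.coordinate <= hi)
    if not mask.any():
        raise ProfileError(f"reference region {region} does not overlap the grid")
    offset = float(profile.free_energy[mask].mean())
    return PMFProfile(
        profile.coordinate,
        profile.free_energy - offset,
        reference_region=(lo, hi),
        annotations=dict(profile.annotations),
    )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(values)]
    return out


def locate_extrema(
    profile: PMFProfile,
    smoothing_window: int = 3,
    min_prominence: float = 0.0,
) -> list[tuple[float, float, str]]:
    """Interior minima and maxima of the (smoothed) profile.

    Returns an alternating ordered list of (position, value, kind); values
    are taken from the raw profile at the smoothed extremum location.
    Adjacent extremum pairs whose value gap is below ``min_prominence``
    (kcal/mol) are pruned, which suppresses noise wiggles on flat
    baselines.  Raises when the profile has no interior extremum.
    """
    g = _smooth(profile.free_energy, smoothing_window)
    x = profile.coordinate
    d = np.diff(g)
    sign = np.sign(d)
    # collapse zero-slope plateaus onto the previous direction
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    idx = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
    extrema: list[tuple[float, float, str]] = []
    for i in idx:
        kind = "min" if sign[i] > 0 else "max"
        # refine on the raw profile inside the smoothing neighbourhood
        lo = max(i - smoothing_window, 0)
        hi = min(i + smoothing_window + 1, len(x))
        local = slice(lo, hi)
        j = lo + (
            int(np.argmin(profile.free_energy[local]))
            if kind == "min"
            else int(np.argmax(profile.free_energy[local]))
        )
        entry = (float(x[j]), float(profile.free_energy[j]), kind)
        if extrema and extrema[-1][2] == kind:
            # enforce alternation: keep the more extreme of the run
            prev = extrema[-1]
            better = (
                entry[1] < prev[1] if kind == "min" else entry[1] > prev[1]
            )
            if better:
                extrema[-1] = entry
            continue
        extrema.append(entry)
    extrema = _prune_shallow(
        extrema,
        min_prominence,
        (float(profile.free_energy[0]), float(profile.free_energy[-1])),
    )
    if not extrema:
        raise ProfileError("no interior extremum found")
    return extrema


def _prune_shallow(
    extrema: list[tuple[float, float, str]],
    min_prominence: float,
    boundary: tuple[float, float],
) -> list[tuple[float, float, str]]:
    """Iteratively drop the least prominent extremum below the threshold.

    Prominence of an extremum is the smaller value gap to its two
    neighbours (adjacent extrema, or the profile end values at the
    edges).  Alternation is repaired after each removal by keeping the
    more extreme of same-kind neighbours.
    """
    if min_prominence <= 0:
        return extrema
    ext = list(extrema)
    while ext:
        proms = []
        for i, (_x, v, _k) in enumerate(ext):
            left = ext[i - 1][1] if i > 0 else boundary[0]
            right = ext[i + 1][1] if i + 1 < len(ext) else boundary[1]
            proms.append(min(abs(v - left), abs(v - right)))
        i = int(np.argmin(proms))
        if proms[i] >= min_prominence:
            break
        del ext[i]
        j = max(i - 1, 0)
        while j + 1 < len(ext):
            if ext[j][2] == ext[j + 1][2]:
                kind = ext[j][2]
                better = (
                    ext[j + 1][1] < ext[j][1]
                    if kind == "min"
                    else ext[j + 1][1] > ext[j][1]
                )
                del ext[j if better else j + 1]
            else:
                j += 1
    return ext


def rate_determining_barrier(
    profile: PMFProfile,
    layer_annotations: tuple[str, str] = ("L1", "L2"),
    smoothing_window: int = 3,
) -> float:
    """Barrier (kcal/mol) for the L1 → L2 hop.

    ΔG = highest free energy between the L1 and L2 minima, minus the L1
    minimum.  Layer intervals must be annotated on the profile.  With a
    monotone profile between the layer minima the barrier degenerates to
    the endpoint difference.
    """
    for name in layer_annotations:
        if name not in profile.annotations:
            raise ProfileError(f"missing layer annotation {name!r}")
    x = profile.coordinate
    g = profile.free_energy

    def interval_min(name: str) -> tuple[int, float]:
        lo, hi = sorted(profile.annotations[name])
        mask = (x >= lo) & (x <= hi)
        if not mask.any():
            raise ProfileError(f"annotation {name!r} does not overlap the grid")
        sub = np.where(mask)[0]
        j = sub[int(np.argmin(g[sub]))]
        return int(j), float(g[j])

    i1, g1 = interval_min(layer_annotations[0])
    i2, _g2 = interval_min(layer_annotations[1])
    lo, hi = sorted((i1, i2))
    if hi - lo < 1:
        raise ProfileError("layer minima coincide; no hop to measure")
    saddle = float(np.max(g[lo : hi + 1]))
    return saddle - g1


# ----------------------------------------------------------------------
# attempt period and rates
# ----------------------------------------------------------------------

def velocity_autocorrelation(series: VelocitySeries) -> np.ndarray:
    """Normalized VACF C(t)/C(0) by direct summation over all lags."""
    v = series.values - 0.0  # velocities are used as given (no mean removal)
    n = len(v)
    acf = np.correlate(v, v, mode="full")[n - 1 :]
    acf = acf / np.arange(n, 0, -1)  # unbiased lag average
    if acf[0] <= 0:
        raise NoOscillationError("zero-power velocity series")
    return acf / acf[0]


def attempt_period_from_vacf(
    series: VelocitySeries, min_dip: float = -0.2
) -> float:
    """Attempt period τ (ps): time of the second zero of the normalized VACF.

    Zero crossings are located by sign change with linear interpolation.
    The VACF must dip below ``min_dip`` before its second zero — this is
    the oscillatory-structure check that rejects noise-like series.
    """
    acf = velocity_autocorrelation(series)
    crossings = []
    for i in range(1, len(acf)):
        if acf[i - 1] > 0 >= acf[i] or acf[i - 1] < 0 <= acf[i]:
            t0 = (i - 1) + acf[i - 1] / (acf[i - 1] - acf[i])
            crossings.append(t0 * series.timestep)
            if len(crossings) == 2:
                break
    if len(crossings) < 2:
        raise NoOscillationError("fewer than two zero crossings in the VACF")
    i2 = int(np.ceil(crossings[1] / series.timestep))
    if float(np.min(acf[: i2 + 1])) > min_dip:
        raise NoOscillationError(
            "velocity autocorrelation shows no oscillatory structure "
            f"(no dip below {min_dip})"
        )
    return float(crossings[1])


def permeation_rate(
    barrier: float, attempt_period: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """TST permeation rate k = τ⁻¹ exp(−ΔG/k_BT), in ions/s (τ in ps)."""
    if attempt_period <= 0:
        raise ProfileError("attempt period must be positive")
    if temperature <= 0:
        raise ProfileError("temperature must be positive")
    return (1.0 / (attempt_period * 1e-12)) * float(
        np.exp(-barrier / thermal_energy(temperature))
    )


def selectivity_ratio(k_fast: float, k_slow: float) -> float:
    """Selectivity ratio k_K / k_Na of two permeation rates."""
    if k_fast <= 0 or k_slow <= 0:
        raise ProfileError("permeation rates must be positive")
    return k_fast / k_slow


def kinetics_from_profile(
    profile: PMFProfile,
    attempt_period: float,
    temperature: float = DEFAULT_TEMPERATURE,
    layer_annotations: tuple[str, str] = ("L1", "L2"),
) -> KineticsResult:
    """Convenience wrapper: barrier → rate for an annotated profile."""
    barrier = rate_determining_barrier(profile, layer_annotations)
    rate = permeation_rate(barrier, attempt_period, temperature)
    return KineticsResult(
        barrier=barrier,
        attempt_period=attempt_period,
        temperature=temperature,
        rate=rate,
    )
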