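"""Seeded generators for every input the analysis pipeline consumes.

The generators stand in for the MD engine: they produce PMF profiles,
velocity series, dual-ion/interlayer-water trajectories, I–V samples and
barrier-decomposition samples with the statistical structure the
analyses assume, so every stage is testable without molecular dynamics.
Default parameters are the study conditions of the bilayer-pore system:
K⁺-like PMFs with a 3.5 kcal/mol interlayer hop barrier (Na⁺-like: 8.9),
triplet episodes split 51.3%/48.7% between one and two bridging waters
with 300/2074 ps mean lifetimes, and orientation telegraph processes at
578/89.3 GHz.

All randomness flows from an integer seed through
``numpy.random.default_rng``; identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import GeometryError, ResolutionError
from .power import IVData
from .trajectory import Trajectory
from .tst_kinetics import PMFProfile, VelocitySeries
from .decomposition import DecompositionSample

__all__ = [
    "gen_pmf",
    "potassium_pmf",
    "sodium_pmf",
    "gen_oscillator_velocities",
    "gen_triplet_trajectory",
    "gen_permeation_trajectory",
    "gen_hydration_trajectory",
    "gen_iv",
    "gen_decomposition_samples",
    "write_metadata",
]

#: Default layer planes (Å) used by the PMF and trajectory generators.
LAYER_Z1 = 10.0
LAYER_SPACING = 3.35


# ----------------------------------------------------------------------
# PMF generator
# ----------------------------------------------------------------------

def gen_pmf(
    well_positions: list[float],
    well_depths: list[float],
    barrier_heights: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    x_range: tuple[float, float] | None = None,
    grid_step: float = 0.05,
    width: float = 0.7,
    annotations: dict[str, tuple[float, float]] | None = None,
) -> PMFProfile:
    """Multi-well PMF with prescribed extremum values.

    Wells (minima) sit at ``well_positions`` with values ``well_depths``
    (kcal/mol, relative to the bulk zero); ``barrier_heights`` are the
    saddle *values* between consecutive wells, placed at the midpoints.
    The profile is a sum of Gaussians (width ``width`` Å) whose
    amplitudes are refined iteratively until every requested extremum is
    met to 0.01 kcal/mol; the baseline decays to zero in the bulk.
    Gaussian noise of ``noise_sd`` is added afterwards.
    """
    wells = np.asarray(well_positions, dtype=float)
    depths = np.asarray(well_depths, dtype=float)
    saddles = np.asarray(barrier_heights, dtype=float)
    if len(wells) != len(depths):
        raise GeometryError("well positions and depths must pair up")
    if len(saddles) != max(len(wells) - 1, 0):
        raise GeometryError("need one barrier value between consecutive wells")
    if np.any(np.diff(wells) <= 0):
        raise GeometryError("well positions must increase")
    centers = []
    targets = []
    kinds = []
    for i, (x, v) in enumerate(zip(wells, depths)):
        centers.append(x)
        targets.append(v)
        kinds.append("min")
        if i < len(saddles):
            centers.append(0.5 * (x + wells[i + 1]))
            targets.append(saddles[i])
            kinds.append("max")
    for v, lo_neighbor, hi_neighbor in _extrema_consistency(targets):
        if not (v > lo_neighbor and v > hi_neighbor):
            raise GeometryError("saddle values must exceed both neighbouring wells")
    centers = np.array(centers)
    targets = np.array(targets)

    if x_range is None:
        x_range = (wells[0] - 8.0, wells[-1] + 8.0)
    x = np.arange(x_range[0], x_range[1] + grid_step / 2, grid_step)

    basis = np.exp(-((centers[:, None] - centers[None, :]) ** 2) / (2 * width**2))
    amp = np.linalg.solve(basis, targets)
    for _ in range(60):
        profile = _gaussian_sum(x, centers, amp, width)
        achieved = np.array(
            [
                _local_extremum(x, profile, c, width, kind)
                for c, kind in zip(centers, kinds)
            ]
        )
        residual = targets - achieved
        if np.max(np.abs(residual)) < 1e-3:
            break
        amp = amp + np.linalg.solve(basis, residual)
    profile = _gaussian_sum(x, centers, amp, width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        profile = profile + rng.normal(0.0, noise_sd, size=profile.shape)
    ann = annotations or {}
    return PMFProfile(
        x,
        profile,
        reference_region=(x_range[0], x_range[0] + 3.0),
        annotations=ann,
    )


def _extrema_consistency(targets):
    out = []
    for i in range(1, len(targets) - 1, 2):
        out.append((targets[i], targets[i - 1], targets[i + 1]))
    return out


def _gaussian_sum(x, centers, amp, width):
    return np.sum(
        amp[:, None] * np.exp(-((x[None, :] - centers[:, None]) ** 2) / (2 * width**2)),
        axis=0,
    )


def _local_extremum(x, profile, center, width, kind):
    """Value of the actual local extremum near ``center`` (overlap shifts it)."""
    mask = np.abs(x - center) <= 1.2 * width
    sub = profile[mask]
    return float(sub.min() if kind == "min" else sub.max())


def potassium_pmf(noise_sd: float = 0.0, seed: int = 0) -> PMFProfile:
    """K⁺-like single-ion PMF: binding ~6 kcal/mol at L1, interlayer hop 3.5.

    Wells −6.0 (L1) and −6.4 (L2) with a −2.5 saddle between give the
    3.5 kcal/mol rate-determining hop and the 6.4 kcal/mol exit barrier.
    """
    z1, z2 = LAYER_Z1, LAYER_Z1 + LAYER_SPACING
    return gen_pmf(
        [z1, z2],
        [-6.0, -6.4],
        [-2.5],
        noise_sd=noise_sd,
        seed=seed,
        annotations={"L1": (z1 - 1.0, z1 + 1.0), "L2": (z2 - 1.0, z2 + 1.0)},
    )


def sodium_pmf(noise_sd: float = 0.0, seed: int = 0) -> PMFProfile:
    """Na⁺-like PMF: −6.9 well at L1, +2.0 saddle → 8.9 kcal/mol hop barrier.

    The retreat barrier to bulk (6.9) is 2 kcal/mol below the forward
    hop, which is why captured Na⁺ retreats instead of permeating.
    """
    z1, z2 = LAYER_Z1, LAYER_Z1 + LAYER_SPACING
    return gen_pmf(
        [z1, z2],
        [-6.9, -0.5],
        [2.0],
        noise_sd=noise_sd,
        seed=seed,
        annotations={"L1": (z1 - 1.0, z1 + 1.0), "L2": (z2 - 1.0, z2 + 1.0)},
    )


# ----------------------------------------------------------------------
# damped-oscillator velocities
# ----------------------------------------------------------------------

def gen_oscillator_velocities(
    period: float,
    damping_ratio: float = 0.0,
    n_periods: int = 20,
    timestep: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VelocitySeries:
    """Damped-cosine velocity of a site-bound ion with vibration ``period`` (ps)."""
    if timestep is None:
        timestep = period / 40.0
    if timestep >= period / 10.0:
        raise ResolutionError("timestep must resolve the vibration (dt < T/10)")
    if n_periods < 3:
        raise ResolutionError("need at least 3 oscillation periods")
    t = np.arange(0.0, n_periods * period, timestep)
    omega = 2.0 * np.pi / period
    omega_d = omega * np.sqrt(max(1.0 - damping_ratio**2, 0.0))
    v = np.exp(-damping_ratio * omega * t) * np.cos(omega_d * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return VelocitySeries(timestep=timestep, values=v)


# ----------------------------------------------------------------------
# triplet trajectories
# ----------------------------------------------------------------------

_OH = 0.9572
_HALF_HOH = np.radians(104.52 / 2.0)


def _water_atoms(o_pos, theta_deg, phi, rng):
    """O/H/H coordinates with the dipole at angle θ from +z, azimuth φ."""
    theta = np.radians(theta_deg)
    u = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    # perpendicular unit vector
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, trial)
    p /= np.linalg.norm(p)
    h1 = o_pos + _OH * (np.cos(_HALF_HOH) * u + np.sin(_HALF_HOH) * p)
    h2 = o_pos + _OH * (np.cos(_HALF_HOH) * u - np.sin(_HALF_HOH) * p)
    return h1, h2


def gen_triplet_trajectory(
    fraction_n1: float = 0.513,
    lifetime_n1: float = 300.0,
    lifetime_n2: float = 2074.0,
    flip_rate_n1: float = 578.0,
    flip_rate_n2: float = 89.3,
    n_episodes: int = 50,
    timestep: float = 1.0,
    seed: int = 0,
    gap_ps: float = 10.0,
    interlayer_distance: float = LAYER_SPACING,
    angles_n1: tuple[float, float] = (55.0, 125.0),
    angles_n2: tuple[float, float] = (40.0, 120.0),
    theta_sd: float = 8.0,
    ion_jitter: float = 0.15,
    deterministic_lifetimes: bool = False,
) -> Trajectory:
    """Dual-ion trajectory whose K–nH₂O–K statistics are known by construction.

    Episodes of simultaneous P1/P2 occupancy are drawn with probability
    ``fraction_n1`` of carrying one bridging water (else two), with
    exponential lifetimes of the given means (ps).  While an episode
    lasts, the bridging-water dipole orientation follows a two-state
    telegraph process: holding times are exponential with rate 2f so
    that the estimator convention f = transitions/(2·duration) recovers
    the requested flip rate (GHz).  The telegraph is simulated in
    continuous time and sampled at ``timestep``, keeping flip-rate
    semantics timestep independent.  Ground truth is recorded in
    ``Trajectory.metadata``.

    Atom layout: K1 (P2-bound), K2 (P1-bound during episodes), two water
    molecules (O, H, H each); the second water is parked in the bulk
    during single-water episodes.
    """
    for f_ghz in (flip_rate_n1, flip_rate_n2):
        # mean telegraph holding time 1/(2f) must span several frames
        if f_ghz > 0 and timestep > 0.125 / (f_ghz * 1e-3):
            raise ResolutionError(
                f"timestep {timestep} ps cannot resolve a {f_ghz} GHz flip rate"
            )
    rng = np.random.default_rng(seed)
    z1 = LAYER_Z1
    z2 = z1 + interlayer_distance
    zmid = 0.5 * (z1 + z2)
    box = (24.0, 24.0, 30.0)
    bulk_z = z1 - 6.0

    frames = []
    episode_truth = []
    gap_frames = max(int(round(gap_ps / timestep)), 2)

    def add_gap():
        for _ in range(gap_frames):
            coords = np.zeros((8, 3))
            coords[0] = [0.3, 0.0, z2]  # K1 parked at P2
            coords[1] = [5.0, 5.0, bulk_z]  # K2 in bulk
            coords[2] = [6.0, -4.0, bulk_z]
            coords[3], coords[4] = _water_atoms(coords[2], 90.0, 0.0, rng)
            coords[5] = [-6.0, 4.0, bulk_z]
            coords[6], coords[7] = _water_atoms(coords[5], 90.0, 0.0, rng)
            frames.append(coords)

    add_gap()
    for _ep in range(n_episodes):
        n_waters = 1 if rng.random() < fraction_n1 else 2
        mean_life = lifetime_n1 if n_waters == 1 else lifetime_n2
        life = mean_life if deterministic_lifetimes else rng.exponential(mean_life)
        n_frames = max(int(round(life / timestep)), 3)
        rate_ps = 2.0 * (flip_rate_n1 if n_waters == 1 else flip_rate_n2) * 1e-3
        angles = angles_n1 if n_waters == 1 else angles_n2

        # continuous-time telegraph sampled at the frame times
        state = int(rng.random() < 0.5)
        t_next = rng.exponential(1.0 / rate_ps) if rate_ps > 0 else np.inf
        for f in range(n_frames):
            t = f * timestep
            while t >= t_next:
                state = 1 - state
                t_next += rng.exponential(1.0 / rate_ps)
            coords = np.zeros((8, 3))
            jit = lambda: rng.normal(0.0, ion_jitter) if ion_jitter > 0 else 0.0
            coords[0] = [jit(), jit(), z2 + jit()]
            coords[1] = [jit(), jit(), z1 + jit()]
            phi = rng.uniform(0.0, 2 * np.pi)
            if n_waters == 1:
                theta = rng.normal(angles[state], theta_sd)
                o1 = np.array([rng.normal(0.0, 0.3), rng.normal(0.0, 0.3), zmid])
                coords[2] = o1
                coords[3], coords[4] = _water_atoms(o1, theta, phi, rng)
                coords[5] = [-6.0, 4.0, bulk_z]
                coords[6], coords[7] = _water_atoms(coords[5], 90.0, 0.0, rng)
            else:
                th1 = rng.normal(angles[state], theta_sd)
                th2 = rng.normal(angles[1 - state], theta_sd)
                o1 = np.array([0.8, rng.normal(0.0, 0.2), zmid + 0.3])
                o2 = np.array([-0.8, rng.normal(0.0, 0.2), zmid - 0.3])
                coords[2] = o1
                coords[3], coords[4] = _water_atoms(o1, th1, phi, rng)
                coords[5] = o2
                coords[6], coords[7] = _water_atoms(o2, th2, phi + 1.0, rng)
            frames.append(coords)
        episode_truth.append({"n_waters": n_waters, "n_frames": n_frames})
        add_gap()

    coords = np.array(frames)
    roles = {
        0: "ion:K",
        1: "ion:K",
        2: "waterO",
        3: "waterH",
        4: "waterH",
        5: "waterO",
        6: "waterH",
        7: "waterH",
    }
    return Trajectory(
        timestep_ps=timestep,
        box=box,
        coords=coords,
        roles=roles,
        layer_z1=z1,
        layer_z2=z2,
        metadata={
            "kind": "triplet_traj",
            "seed": seed,
            "fraction_n1": fraction_n1,
            "lifetime_n1_ps": lifetime_n1,
            "lifetime_n2_ps": lifetime_n2,
            "flip_rate_n1_GHz": flip_rate_n1,
            "flip_rate_n2_GHz": flip_rate_n2,
            "episodes": episode_truth,
        },
    )


# ----------------------------------------------------------------------
# scripted permeation trajectories
# ----------------------------------------------------------------------

_DEFAULT_DWELL = {"I": 0.05, "II": 0.10, "III": 0.10, "IV": 0.70, "V": 0.05}


def gen_permeation_trajectory(
    n_events: int,
    event_duration_ps: float = 200.0,
    dwell_fractions: dict[str, float] | None = None,
    timestep: float = 1.0,
    seed: int = 0,
    wrap: bool = True,
) -> Trajectory:
    """Scripted capture → dual-occupancy → knock-on → release sequences.

    Each event moves the tagged K1 from the bulk below L1, through P1
    (stage II), P2 (stage III), a long dual-ion stage IV (K2 at P1,
    default 70% of the event), to release beyond L2 (stage V).  With
    ``wrap`` the ion keeps drifting in +z through the periodic boundary,
    so successive events traverse successive box images.  Ground truth
    (the event count) is in ``Trajectory.metadata``.
    """
    dwell = dict(_DEFAULT_DWELL, **(dwell_fractions or {}))
    total = sum(dwell.values())
    dwell = {k: v / total for k, v in dwell.items()}
    rng = np.random.default_rng(seed)
    z1 = LAYER_Z1
    z2 = z1 + LAYER_SPACING
    box = (24.0, 24.0, 30.0)
    below = z1 - 5.0
    above = z2 + 5.0

    frames_per_event = max(int(round(event_duration_ps / timestep)), 20)
    stage_frames = {k: max(int(round(v * frames_per_event)), 1) for k, v in dwell.items()}

    z_unwrapped = []
    k2_z = []
    stage_of_frame = []
    z_offset = 0.0
    for _ev in range(n_events):
        path = (
            [below - 1.0] * stage_frames["I"]
            + [z1] * stage_frames["II"]
            + [z2] * stage_frames["III"]
            + [z2] * stage_frames["IV"]
            + [above + 1.0] * stage_frames["V"]
        )
        stages = (
            ["I"] * stage_frames["I"]
            + ["II"] * stage_frames["II"]
            + ["III"] * stage_frames["III"]
            + ["IV"] * stage_frames["IV"]
            + ["V"] * stage_frames["V"]
        )
        for z, st in zip(path, stages):
            z_unwrapped.append(z + z_offset)
            k2_z.append(z1 if st == "IV" else below - 2.0)
            stage_of_frame.append(st)
        if wrap:
            z_offset += box[2]
        else:
            # retreat back below the pore between events
            for _ in range(5):
                z_unwrapped.append(below - 2.0)
                k2_z.append(below - 2.0)
                stage_of_frame.append("I")

    n_frames = len(z_unwrapped)
    coords = np.zeros((n_frames, 3, 3))
    coords[:, 0, 2] = np.mod(z_unwrapped, box[2]) if wrap else z_unwrapped
    coords[:, 0, 0] = rng.normal(0.0, 0.1, n_frames)
    coords[:, 0, 1] = rng.normal(0.0, 0.1, n_frames)
    coords[:, 1, 2] = np.mod(k2_z, box[2])
    coords[:, 1, 0] = rng.normal(0.0, 0.1, n_frames)
    coords[:, 1, 1] = rng.normal(0.0, 0.1, n_frames)
    # a single spectator water in the bulk keeps the role table complete
    coords[:, 2, :] = [8.0, 8.0, 2.0]
    roles = {0: "ion:K", 1: "ion:K", 2: "waterO"}
    stage_time = {
        st: stage_of_frame.count(st) / len(stage_of_frame) for st in dwell
    }
    return Trajectory(
        timestep_ps=timestep,
        box=box,
        coords=coords,
        roles=roles,
        layer_z1=z1,
        layer_z2=z2,
        metadata={
            "kind": "permeation_traj",
            "seed": seed,
            "n_events": n_events,
            "dwell_fractions": dwell,
            "stage_time_fractions": stage_time,
        },
    )


def gen_hydration_trajectory(
    mean_shell: float = 7.3,
    n_frames: int = 500,
    cutoff: float = 3.5,
    n_bulk: int = 12,
    seed: int = 0,
) -> Trajectory:
    """Ion with a Poisson-perturbed first hydration shell.

    Per frame, a Poisson(``mean_shell``) number of water oxygens is
    placed uniformly in the shell [2.6 Å, cutoff − 0.05 Å] around a
    fixed ion, plus ``n_bulk`` oxygens well outside the cutoff; unused
    shell slots are parked in the bulk so the atom count is constant.
    Ground truth (the realized per-frame counts) is in ``metadata``.
    """
    rng = np.random.default_rng(seed)
    box = (24.0, 24.0, 24.0)
    center = np.array([12.0, 12.0, 12.0])
    max_shell = int(mean_shell + 6 * np.sqrt(mean_shell)) + 1
    n_atoms = 1 + max_shell + n_bulk
    coords = np.zeros((n_frames, n_atoms, 3))
    counts = rng.poisson(mean_shell, n_frames)
    counts = np.minimum(counts, max_shell)
    for f in range(n_frames):
        coords[f, 0] = center
        k = counts[f]
        # uniform directions, radii in the shell
        u = rng.normal(size=(max_shell, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = rng.uniform(2.6, cutoff - 0.05, max_shell)
        pos = center + u * r[:, None]
        pos[k:] = center + u[k:] * rng.uniform(cutoff + 1.5, 9.0, max_shell - k)[:, None]
        coords[f, 1 : 1 + max_shell] = pos
        ub = rng.normal(size=(n_bulk, 3))
        ub /= np.linalg.norm(ub, axis=1, keepdims=True)
        coords[f, 1 + max_shell :] = center + ub * rng.uniform(cutoff + 1.5, 9.0, n_bulk)[:, None]
    roles = {0: "ion:K"}
    for i in range(1, n_atoms):
        roles[i] = "waterO"
    return Trajectory(
        timestep_ps=1.0,
        box=box,
        coords=coords,
        roles=roles,
        layer_z1=1.0,
        layer_z2=2.0,
        periodic=(False, False, False),
        metadata={
            "kind": "hydration_traj",
            "seed": seed,
            "mean_shell": mean_shell,
            "realized_mean": float(counts.mean()),
            "counts": counts.tolist(),
        },
    )


# ----------------------------------------------------------------------
# I-V and decomposition samples
# ----------------------------------------------------------------------

def gen_iv(
    u_diff: float = 73.1,
    i_diff: float | None = None,
    conductance: float = 0.097,
    noise_sd: float = 0.0,
    n_points: int = 11,
    v_range: tuple[float, float] = (-100.0, 100.0),
    seed: int = 0,
) -> IVData:
    """Linear I–V samples with prescribed intercepts.

    ``u_diff`` (mV) and ``conductance`` (pA/mV) fix the line; the current
    intercept is I_diff = −G·U_diff unless given explicitly (then the
    conductance is rescaled to stay consistent).
    """
    if i_diff is not None:
        if u_diff != 0:
            conductance = -i_diff / u_diff
    else:
        i_diff = -conductance * u_diff
    v = np.linspace(v_range[0], v_range[1], n_points)
    i = conductance * v + i_diff
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=i.shape)
    return IVData(applied_voltage=v, current=i)


def gen_decomposition_samples(
    a: float = 1.2,
    b: float = -2.55,
    c: float = 0.4,
    noise_sd: float = 0.0,
    n: int = 50,
    seed: int = 0,
) -> list[DecompositionSample]:
    """ΔG samples from the linear barrier decomposition a·ΔN_w + b·ΔN_c + c.

    ΔN_water is drawn uniformly in [−6, −1] (partial dehydration) and
    ΔN_carbonyl in [0, 4] (up to the four rim carbonyls), with Gaussian
    noise of ``noise_sd`` on ΔG.
    """
    rng = np.random.default_rng(seed)
    dn_w = rng.uniform(-6.0, -1.0, n)
    dn_c = rng.uniform(0.0, 4.0, n)
    dg = a * dn_w + b * dn_c + c + rng.normal(0.0, noise_sd, n)
    return [DecompositionSample(w, k, g) for w, k, g in zip(dn_w, dn_c, dg)]


def write_metadata(path: str | Path, spec: dict) -> Path:
    """Provenance sidecar: generator kind, parameters and seed as JSON."""
    path = Path(path)
    path.write_text(json.dumps(spec, indent=1, default=float))
    return path
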