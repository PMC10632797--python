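"""Statistics over dual-ion pore trajectories.

Operators for the quantities that characterize the dual-ion ("soft
knock-on") transport mechanism: binding-site occupancy at the two layer
pores (P1, P2), full permeation events, hydration numbers,
K–nH₂O–K triplet episodes with their bridging-water count and lifetime,
water dipole orientation relative to the inter-ion axis, and the
orientation switching frequency of the bridging waters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .trajectory import Trajectory

__all__ = [
    "PermeationEvent",
    "TripletEvent",
    "OrientationSeries",
    "assign_site_occupancy",
    "dual_occupancy_fraction",
    "detect_permeation_events",
    "hydration_number",
    "classify_triplets",
    "dipole_orientation",
    "switching_frequency",
]

#: First-shell ion-water oxygen cutoffs (Å), at the first RDF minimum of
#: common water models.
HYDRATION_CUTOFFS = {"K": 3.5, "Na": 3.2}

DEFAULT_AXIAL_TOL = 1.0
DEFAULT_RADIAL_CUTOFF = 3.0


@dataclass(frozen=True)
class PermeationEvent:
    ion: int
    start_frame: int
    end_frame: int
    direction: int  # +1: z1 -> z2 side, -1: reverse


@dataclass(frozen=True)
class TripletEvent:
    ion_p1: int
    ion_p2: int
    n_waters: int
    start_frame: int
    end_frame: int
    lifetime: float  # ps


@dataclass
class OrientationSeries:
    """Water dipole angle θ (deg, in [0, 180]) vs time while a triplet persists."""

    time: np.ndarray  # ps
    theta: np.ndarray  # (n_frames,) or (n_frames, n_waters)
    timestep_ps: float


# ----------------------------------------------------------------------
# occupancy and permeation
# ----------------------------------------------------------------------

def _minimum_image(delta: np.ndarray, box: tuple, periodic: tuple) -> np.ndarray:
    delta = np.array(delta, dtype=float, copy=True)
    for k in range(3):
        if periodic[k] and box[k] > 0:
            delta[..., k] -= box[k] * np.round(delta[..., k] / box[k])
    return delta


def assign_site_occupancy(
    traj: Trajectory,
    axial_tolerance: float = DEFAULT_AXIAL_TOL,
    radial_cutoff: float = DEFAULT_RADIAL_CUTOFF,
) -> list[dict[str, int | None]]:
    """Per-frame map of the two layer sites to the bound ion (or None).

    An ion occupies a site when it is within ``axial_tolerance`` of the
    layer plane and within ``radial_cutoff`` of the pore axis; the
    axially nearest ion wins when several qualify.
    """
    ions = traj.ion_indices()
    if not ions:
        raise AnalysisError("no tagged ions in trajectory")
    cx, cy = traj.pore_center
    out: list[dict[str, int | None]] = []
    planes = {"P1": traj.layer_z1, "P2": traj.layer_z2}
    for f in range(traj.n_frames):
        frame: dict[str, int | None] = {}
        for site, zplane in planes.items():
            best, best_d = None, np.inf
            for i in ions:
                x, y, z = traj.coords[f, i]
                dz = abs(z - zplane)
                if dz > axial_tolerance:
                    continue
                if np.hypot(x - cx, y - cy) > radial_cutoff:
                    continue
                if dz < best_d:
                    best, best_d = i, dz
            frame[site] = best
        out.append(frame)
    return out


def _unwrap(z: np.ndarray, lz: float) -> np.ndarray:
    dz = np.diff(z)
    dz -= lz * np.round(dz / lz)
    return np.concatenate([[z[0]], z[0] + np.cumsum(dz)])


def detect_permeation_events(
    traj: Trajectory,
    entry_margin: float = 2.0,
    exit_margin: float = 2.0,
) -> list[PermeationEvent]:
    """Count full pore crossings of every tagged ion.

    The ion's axial coordinate is unwrapped along the periodic axis; an
    event is a continuous passage from beyond ``entry_margin`` below the
    lower plane to beyond ``exit_margin`` above the upper plane (or the
    reverse), crossing both planes.  The margins act as hysteresis
    thresholds, so brief re-crossings and shuttling inside the pore are
    not counted.
    """
    lz = traj.box[2]
    lo = traj.layer_z1 - entry_margin
    hi = traj.layer_z2 + exit_margin
    mid = 0.5 * (lo + hi)
    period = lz if traj.periodic[2] else np.inf
    if np.isfinite(period) and period <= (hi - lo):
        raise AnalysisError("margins span the whole periodic box")
    events: list[PermeationEvent] = []
    for ion in traj.ion_indices():
        z = traj.coords[:, ion, 2]
        if traj.periodic[2]:
            z = _unwrap(z, lz)
        # ladder of pore copies: copy k has thresholds (lo + kP, hi + kP);
        # an event is below(k) -> above(k) or the reverse.  Transitions
        # between above(k) and below(k+1) are bulk traversal, not events.
        state: tuple[int, str] | None = None
        start = 0
        for f in range(len(z)):
            k = int(np.round((z[f] - mid) / period)) if np.isfinite(period) else 0
            rel = z[f] - (k * period if np.isfinite(period) else 0.0)
            if rel < lo:
                side = "below"
            elif rel > hi:
                side = "above"
            else:
                continue
            if state is None:
                state, start = (k, side), f
            elif state[0] == k and state[1] != side:
                events.append(
                    PermeationEvent(
                        ion=ion,
                        start_frame=start,
                        end_frame=f,
                        direction=+1 if side == "above" else -1,
                    )
                )
                state, start = (k, side), f
            else:
                state, start = (k, side), f
    return events


def hydration_number(
    traj: Trajectory, ion: int, cutoff: float | None = None
) -> tuple[np.ndarray, float]:
    """Per-frame count of water oxygens within ``cutoff`` of the ion, and its mean.

    Minimum-image distances are used along periodic box axes.  The cutoff
    defaults to the species value (K⁺ 3.5 Å, Na⁺ 3.2 Å).
    """
    oxygens = traj.water_oxygens()
    if not oxygens:
        raise AnalysisError("no tagged water oxygens in trajectory")
    role = traj.roles.get(ion, "")
    if cutoff is None:
        cutoff = HYDRATION_CUTOFFS.get(role.split(":")[-1], 3.5)
    delta = traj.coords[:, oxygens, :] - traj.coords[:, [ion], :]
    delta = _minimum_image(delta, traj.box, traj.periodic)
    dist = np.linalg.norm(delta, axis=2)
    counts = np.sum(dist <= cutoff, axis=1)
    return counts, float(counts.mean())


def dual_occupancy_fraction(
    traj: Trajectory, site_map: list[dict[str, int | None]] | None = None
) -> float:
    """Fraction of frames with both P1 and P2 occupied (stage-IV dwell)."""
    if site_map is None:
        site_map = assign_site_occupancy(traj)
    dual = sum(
        1
        for frame in site_map
        if frame.get("P1") is not None and frame.get("P2") is not None
    )
    return dual / len(site_map)


# ----------------------------------------------------------------------
# triplets
# ----------------------------------------------------------------------

def _bridging_waters(
    traj: Trajectory, f: int, i1: int, i2: int, radial_cutoff: float,
    band: tuple[float, float],
) -> list[int]:
    """Water oxygens strictly between the layer planes and near the inter-ion axis."""
    p1 = traj.coords[f, i1]
    p2 = traj.coords[f, i2]
    axis = p2 - p1
    norm = np.linalg.norm(axis)
    if norm == 0:
        return []
    axis = axis / norm
    out = []
    for o, _h1, _h2 in traj.water_groups():
        pos = traj.coords[f, o]
        if not band[0] < pos[2] < band[1]:
            continue
        rel = pos - p1
        radial = np.linalg.norm(rel - np.dot(rel, axis) * axis)
        if radial <= radial_cutoff:
            out.append(o)
    return out


def classify_triplets(
    traj: Trajectory,
    site_map: list[dict[str, int | None]] | None = None,
    radial_cutoff: float = DEFAULT_RADIAL_CUTOFF,
    interlayer_band: tuple[float, float] | None = None,
) -> tuple[list[TripletEvent], dict]:
    """K–nH₂O–K triplet episodes and their summary statistics.

    A triplet episode is a maximal run of frames in which both sites are
    occupied by the same ion pair; it is labelled by the modal number of
    bridging waters (n = 1 or 2) counted in the open slab strictly
    between the layer planes within ``radial_cutoff`` of the inter-ion
    axis.  Episodes with no bridging water are excluded and reported in
    the summary.  The lifetime is the episode duration.
    """
    if site_map is None:
        site_map = assign_site_occupancy(traj, radial_cutoff=radial_cutoff)
    band = interlayer_band or (traj.layer_z1, traj.layer_z2)
    dt = traj.timestep_ps

    episodes: list[tuple[int, int, int, int]] = []  # (start, end, i1, i2)
    current: tuple[int, int, int] | None = None  # (start, i1, i2)
    for f, frame in enumerate(site_map):
        i1, i2 = frame.get("P1"), frame.get("P2")
        dual = i1 is not None and i2 is not None and i1 != i2
        if dual:
            if current is None or current[1:] != (i1, i2):
                if current is not None:
                    episodes.append((current[0], f - 1, current[1], current[2]))
                current = (f, i1, i2)
        elif current is not None:
            episodes.append((current[0], f - 1, current[1], current[2]))
            current = None
    if current is not None:
        episodes.append((current[0], len(site_map) - 1, current[1], current[2]))

    events: list[TripletEvent] = []
    n_excluded = 0
    for start, end, i1, i2 in episodes:
        counts = [
            len(_bridging_waters(traj, f, i1, i2, radial_cutoff, band))
            for f in range(start, end + 1)
        ]
        vals, freq = np.unique(counts, return_counts=True)
        modal = int(vals[np.argmax(freq)])
        if modal == 0:
            n_excluded += 1
            continue
        events.append(
            TripletEvent(
                ion_p1=i1,
                ion_p2=i2,
                n_waters=modal,
                start_frame=start,
                end_frame=end,
                lifetime=(end - start + 1) * dt,
            )
        )

    summary: dict = {"n_episodes": len(events), "n_excluded": n_excluded}
    if events:
        for n in (1, 2):
            sel = [e for e in events if e.n_waters == n]
            summary[f"fraction_n{n}"] = len(sel) / len(events)
            summary[f"mean_lifetime_n{n}_ps"] = (
                float(np.mean([e.lifetime for e in sel])) if sel else float("nan")
            )
    return events, summary


# ----------------------------------------------------------------------
# orientations
# ----------------------------------------------------------------------

def _axis_waters(
    traj: Trajectory, f: int, i1: int, i2: int, radial_cutoff: float
) -> list[int]:
    """Water oxygens near the inter-ion segment, in frame-internal coordinates.

    Unlike the interlayer-band count used for episode labelling, this
    criterion (axial projection within the segment, radial distance
    within the cutoff) is invariant under rigid motions of the frame, so
    dipole angles computed from it are too.
    """
    p1 = traj.coords[f, i1]
    p2 = traj.coords[f, i2]
    axis = p2 - p1
    norm2 = float(np.dot(axis, axis))
    if norm2 == 0:
        return []
    out = []
    for o, _h1, _h2 in traj.water_groups():
        rel = traj.coords[f, o] - p1
        t = float(np.dot(rel, axis)) / norm2
        if not 0.0 < t < 1.0:
            continue
        radial = np.linalg.norm(rel - t * axis)
        if radial <= radial_cutoff:
            out.append(o)
    return out


def _dipole_angle(
    o: np.ndarray, h1: np.ndarray, h2: np.ndarray, axis: np.ndarray
) -> float:
    dipole = 0.5 * (h1 + h2) - o
    nd = np.linalg.norm(dipole)
    na = np.linalg.norm(axis)
    if nd < 1e-9 or na < 1e-9:
        raise AnalysisError("degenerate water/axis geometry")
    cosang = np.clip(np.dot(dipole, axis) / (nd * na), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dipole_orientation(
    traj: Trajectory,
    triplet: TripletEvent,
    radial_cutoff: float = DEFAULT_RADIAL_CUTOFF,
    bins: int = 36,
    smooth_bins: int = 3,
) -> tuple[OrientationSeries, dict]:
    """θ(t) of the bridging water dipoles and a histogram peak summary.

    θ is the angle between the water dipole (from O through the H–H
    midpoint) and the K(P1) → K(P2) axis.  The histogram of all samples
    is smoothed with a short moving average before peak detection.
    """
    frames = range(triplet.start_frame, triplet.end_frame + 1)
    thetas = []
    times = []
    for f in frames:
        axis = traj.coords[f, triplet.ion_p2] - traj.coords[f, triplet.ion_p1]
        waters = _axis_waters(
            traj, f, triplet.ion_p1, triplet.ion_p2, radial_cutoff
        )
        row = []
        groups = {o: (h1, h2) for o, h1, h2 in traj.water_groups()}
        for o in waters[: triplet.n_waters]:
            h1, h2 = groups[o]
            row.append(
                _dipole_angle(
                    traj.coords[f, o],
                    traj.coords[f, h1],
                    traj.coords[f, h2],
                    axis,
                )
            )
        while len(row) < triplet.n_waters:
            row.append(np.nan)
        thetas.append(row)
        times.append(traj.times[f])
    theta = np.array(thetas)
    if triplet.n_waters == 1:
        theta = theta[:, 0]
    series = OrientationSeries(
        time=np.array(times), theta=theta, timestep_ps=traj.timestep_ps
    )

    flat = np.asarray(theta).ravel()
    flat = flat[np.isfinite(flat)]
    hist, edges = np.histogram(flat, bins=bins, range=(0.0, 180.0), density=True)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        hist = np.convolve(np.pad(hist, smooth_bins // 2, mode="edge"), kernel, mode="same")[
            smooth_bins // 2 : smooth_bins // 2 + bins
        ]
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = [
        float(centers[i])
        for i in range(1, bins - 1)
        if hist[i] >= hist[i - 1] and hist[i] > hist[i + 1] and hist[i] > 0.2 * hist.max()
    ]
    # endpoint maxima count too (fully aligned/anti-aligned dipoles)
    if bins >= 2 and hist[0] > hist[1] and hist[0] > 0.2 * hist.max():
        peaks.insert(0, float(centers[0]))
    if bins >= 2 and hist[-1] > hist[-2] and hist[-1] > 0.2 * hist.max():
        peaks.append(float(centers[-1]))
    return series, {"peaks_deg": peaks, "histogram": hist, "bin_centers": centers}


def switching_frequency(
    series: OrientationSeries,
    threshold: float = 15.0,
    debounce: int = 2,
) -> float:
    """Orientation switching frequency in GHz.

    Frames are classified as state A (θ < 90 − threshold) or B
    (θ > 90 + threshold); ambiguous frames keep the previous state.
    State runs shorter than ``debounce`` frames are treated as flicker
    and merged.  The frequency is transitions / (2 · duration): one full
    switching cycle comprises two transitions.
    """
    theta = np.asarray(series.theta)
    if theta.ndim > 1:
        theta = theta[:, 0]
    if len(theta) < 10:
        raise AnalysisError("need at least 10 frames")
    states: list[int] = []
    prev = 0
    for t in theta:
        if np.isfinite(t):
            if t < 90.0 - threshold:
                prev = -1
            elif t > 90.0 + threshold:
                prev = +1
        states.append(prev)
    arr = np.array(states)
    known = arr != 0
    if not known.any():
        raise AnalysisError("orientation series entirely ambiguous")
    # merge runs shorter than the debounce length into their neighbour
    runs: list[tuple[int, int]] = []  # (state, length)
    for s in arr[known]:
        if runs and runs[-1][0] == s:
            runs[-1] = (s, runs[-1][1] + 1)
        else:
            runs.append((int(s), 1))
    merged: list[tuple[int, int]] = []
    pending = 0  # frames of leading flicker not yet attached to a run
    for s, length in runs:
        if length < debounce:
            if merged:
                merged[-1] = (merged[-1][0], merged[-1][1] + length)
            else:
                pending += length
        elif merged and merged[-1][0] == s:
            merged[-1] = (s, merged[-1][1] + length)
        else:
            merged.append((s, length + pending))
            pending = 0
    transitions = max(len(merged) - 1, 0)
    duration_ps = (len(theta) - 1) * series.timestep_ps
    if duration_ps <= 0:
        raise AnalysisError("zero-duration series")
    return transitions / (2.0 * duration_ps) * 1e3  # 1/ps -> GHz
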