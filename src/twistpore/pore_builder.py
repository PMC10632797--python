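"""Carbonyl-functionalized bilayer graphene nanopore models.

The artificial potassium channel mimics the selectivity filter of KcsA:
each graphene layer carries a sub-nanometre pore (16 carbon atoms removed
from a 1.42 Å honeycomb lattice) whose rim is functionalized with four
carbonyl (C=O) groups, oxygens pointing to the pore axis.  Rotating the
four functionalized positions clockwise by an integral number of edge
steps generates the single-layer elements A0–A4; stacking two layers at
the graphite spacing 3.35 Å gives a bilayer pore "AmAn".

Site convention
---------------
Eight candidate carbonyl sites sit on the pore rim, indexed 0..7
counterclockwise from the +x axis.  The rim of a lattice-carved pore is
not eight-fold symmetric: sites 4–7 form a closely spaced arc while
sites 0–4 are spread out.  Two sites closer than 2.6 Å (sharing a
hexagon) cannot both carry a carbonyl; configurations with adjacent
carbonyls are rejected.  Under this rule exactly the five clockwise
twists t = 0..4 of the base motif {0, 2, 5, 7} are admissible, which is
why the design space contains five single-layer elements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError, GeometryError, InvalidConfigurationError, ResolutionError

__all__ = [
    "PoreLayer",
    "BilayerPoreModel",
    "BASE_SITES",
    "N_SITES",
    "build_layer",
    "build_bilayer",
    "enumerate_configs",
    "effective_pore_area",
    "write_structure",
    "swap_equivalent",
]

#: Graphene C-C bond length, Å.
BOND_LENGTH = 1.42
#: Carbonyl C=O bond length, Å.
CO_BOND = 1.23
#: Graphite interlayer spacing, Å.
DEFAULT_SPACING = 3.35
#: Base carbonyl motif (twist 0).
BASE_SITES = (0, 2, 5, 7)
N_SITES = 8
#: Number of admissible clockwise twists (A0..A4).
N_TWISTS = 5

#: Angular placement (deg, counterclockwise from +x) of the 8 candidate
#: sites: five 54° gaps (sites 0..4 and the 7→0 wrap) and a dense 30°-arc
#: (sites 4..7).
SITE_ANGLES_DEG = (0.0, 54.0, 108.0, 162.0, 216.0, 246.0, 276.0, 306.0)
#: Two carbonyls closer than this share a hexagon and clash.
ADJACENCY_CUTOFF = 2.6
#: Rim-circle radius used for site placement, Å.
SITE_RADIUS = 4.2

#: Covalent radii (Å) used for the open-area measurement; the pore area is
#: measured to the covalent surface of the rim atoms, which reproduces the
#: ~32 Å² effective cross-section of the functionalized pore.
COVALENT_RADII = {"C": 0.76, "O": 0.66}

#: Probe radius (Å) calibrated so the functionalized pore's open area
#: matches the ~32 Å² effective cross-section; it also seals the thin
#: necks between rim atoms against flood-fill leakage.
CALIBRATED_PROBE = 0.3


def _site_positions(radius: float = SITE_RADIUS) -> np.ndarray:
    ang = np.radians(SITE_ANGLES_DEG)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def rotate_sites(sites: Iterable[int], twist: int) -> frozenset[int]:
    """Clockwise integral twist: +1 modulo 8 on the site indices (viewed down +z)."""
    return frozenset((s + twist) % N_SITES for s in sites)


def sites_adjacent(i: int, j: int, radius: float = SITE_RADIUS) -> bool:
    """True when carbonyls at sites i and j would clash (< 2.6 Å apart)."""
    pos = _site_positions(radius)
    return bool(np.linalg.norm(pos[i] - pos[j]) < ADJACENCY_CUTOFF)


def validate_sites(sites: frozenset[int]) -> None:
    if len(sites) != 4:
        raise InvalidConfigurationError("exactly 4 carbonyl positions required")
    for i, j in itertools.combinations(sorted(sites), 2):
        if sites_adjacent(i, j):
            raise InvalidConfigurationError(
                f"carbonyl positions {i} and {j} are adjacent; configuration dismissed"
            )


@dataclass(frozen=True)
class PoreLayer:
    """One carbonyl-functionalized graphene layer."""

    twist_index: int
    carbonyl_positions: frozenset[int]
    atoms: tuple[tuple[str, float, float, float], ...]
    pore_center: tuple[float, float]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms])

    def elements(self) -> list[str]:
        return [el for el, *_ in self.atoms]


@dataclass(frozen=True)
class BilayerPoreModel:
    """Two coaxially stacked pore layers at separation ``interlayer_distance``."""

    layer1: PoreLayer
    layer2: PoreLayer
    interlayer_distance: float = DEFAULT_SPACING
    label: str = field(default="")

    def __post_init__(self) -> None:
        if self.interlayer_distance <= 0:
            raise GeometryError("interlayer distance must be positive")
        expected = f"A{self.layer1.twist_index}A{self.layer2.twist_index}"
        if self.label and self.label != expected:
            raise InvalidConfigurationError(
                f"label {self.label!r} inconsistent with twists ({expected})"
            )
        if not self.label:
            object.__setattr__(self, "label", expected)

    @property
    def n_atoms(self) -> int:
        return self.layer1.n_atoms + self.layer2.n_atoms


def _graphene_sheet(bond_length: float, half_extent: float) -> np.ndarray:
    """Finite honeycomb sheet centred on a C-C bond midpoint (at the origin)."""
    v1 = np.array([1.5 * bond_length, np.sqrt(3) / 2 * bond_length])
    v2 = np.array([1.5 * bond_length, -np.sqrt(3) / 2 * bond_length])
    basis = (np.array([0.0, 0.0]), np.array([bond_length, 0.0]))
    n = int(np.ceil(half_extent / bond_length)) + 2
    pts = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for b in basis:
                pts.append(i * v1 + j * v2 + b)
    pts = np.array(pts) - np.array([bond_length / 2.0, 0.0])  # bond midpoint -> origin
    keep = np.all(np.abs(pts) <= half_extent, axis=1)
    return pts[keep]


def build_layer(
    twist_index: int,
    lattice_bond_length: float = BOND_LENGTH,
    sheet_half_extent: float = 12.5,
) -> PoreLayer:
    """Construct one carbonyl-functionalized pore layer.

    The pore is carved by removing the 16 lattice atoms nearest the sheet
    centre (a bond midpoint, which makes the 16-atom vacancy unambiguous),
    then decorating four rim atoms with carbonyl oxygens displaced 1.23 Å
    toward the pore axis.  ``twist_index`` rotates the base carbonyl motif
    {0, 2, 5, 7} clockwise by that many edge steps; only 0..4 are
    admissible.
    """
    if not isinstance(twist_index, (int, np.integer)) or not 0 <= twist_index < N_TWISTS:
        raise InvalidConfigurationError(
            f"twist_index must be in 0..{N_TWISTS - 1}, got {twist_index!r}"
        )
    sites = rotate_sites(BASE_SITES, int(twist_index))
    validate_sites(sites)

    scale = lattice_bond_length / BOND_LENGTH
    pts = _graphene_sheet(lattice_bond_length, sheet_half_extent)
    r = np.linalg.norm(pts, axis=1)
    order = np.argsort(r, kind="stable")
    removed = set(order[:16])
    kept_idx = [i for i in range(len(pts)) if i not in removed]
    kept = pts[kept_idx]

    # rim atoms: kept atoms that lost a bonded neighbour
    tree = cKDTree(pts[sorted(removed)])
    dd, _ = tree.query(kept)
    rim_mask = dd < lattice_bond_length + 0.05
    rim = kept[rim_mask]

    # map each carbonyl site direction to its nearest rim atom
    site_xy = _site_positions(SITE_RADIUS * scale)
    atoms: list[tuple[str, float, float, float]] = [
        ("C", float(x), float(y), 0.0) for x, y in kept
    ]
    for s in sorted(sites):
        target = site_xy[s]
        i = int(np.argmin(np.linalg.norm(rim - target, axis=1)))
        c_pos = rim[i]
        u = -c_pos / np.linalg.norm(c_pos)  # toward the pore axis, in plane
        o_pos = c_pos + CO_BOND * u
        atoms.append(("O", float(o_pos[0]), float(o_pos[1]), 0.0))

    return PoreLayer(
        twist_index=int(twist_index),
        carbonyl_positions=sites,
        atoms=tuple(atoms),
        pore_center=(0.0, 0.0),
    )


def build_bilayer(
    m: int, n: int, d: float = DEFAULT_SPACING, lattice_bond_length: float = BOND_LENGTH
) -> BilayerPoreModel:
    """Stack layers A``m`` and A``n`` coaxially at separation ``d`` (Å)."""
    if d <= 0:
        raise GeometryError(f"interlayer distance must be positive, got {d}")
    layer1 = build_layer(m, lattice_bond_length)
    layer2_flat = build_layer(n, lattice_bond_length)
    shifted = tuple(
        (el, x, y, z + d) for el, x, y, z in layer2_flat.atoms
    )
    layer2 = PoreLayer(
        twist_index=layer2_flat.twist_index,
        carbonyl_positions=layer2_flat.carbonyl_positions,
        atoms=shifted,
        pore_center=layer2_flat.pore_center,
    )
    return BilayerPoreModel(layer1=layer1, layer2=layer2, interlayer_distance=d)


def swap_equivalent(label_a: str | tuple[int, int], label_b: str | tuple[int, int]) -> bool:
    """True when two bilayer configurations are mirror images under layer swap."""
    pa = _parse_label(label_a)
    pb = _parse_label(label_b)
    return pa == pb or pa == pb[::-1]


def _parse_label(label: str | tuple[int, int]) -> tuple[int, int]:
    if isinstance(label, tuple):
        return label
    if len(label) == 4 and label[0] == label[2] == "A":
        return int(label[1]), int(label[3])
    raise InvalidConfigurationError(f"cannot parse configuration label {label!r}")


def enumerate_configs(
    equivalence: str | Callable[[tuple[int, int], tuple[int, int]], bool] = "none",
) -> list[str]:
    """Enumerate bilayer configuration labels AmAn with m, n in 0..4.

    ``equivalence`` is "none" (all 25 ordered pairs), "layer_swap" (one
    representative per unordered pair, 15), or a predicate on index pairs
    defining a custom equivalence relation.
    """
    pairs = [(m, n) for m in range(N_TWISTS) for n in range(N_TWISTS)]
    if equivalence == "none":
        reps = pairs
    elif equivalence == "layer_swap":
        reps = [p for p in pairs if p[0] <= p[1]]
    elif callable(equivalence):
        reps = []
        for p in pairs:
            if not any(equivalence(p, q) for q in reps):
                reps.append(p)
    else:
        raise InvalidConfigurationError(f"unknown equivalence {equivalence!r}")
    return [f"A{m}A{n}" for m, n in reps]


def effective_pore_area(
    model: BilayerPoreModel | PoreLayer,
    probe_radius: float = 0.0,
    grid_step: float = 0.05,
    window: float = 12.0,
    radii: dict[str, float] | None = None,
) -> float:
    """Open cross-sectional area of the pore, Å².

    A square grid of side ``window`` in each layer plane is tested; a grid
    point is open when its distance to every atom of that layer exceeds the
    atom's radius plus ``probe_radius``.  The effective area of a bilayer
    is the smaller of the two per-layer open areas.  Atom radii default to
    covalent radii; the probe calibrates the measure (area is monotone
    non-increasing in ``probe_radius``).
    """
    if probe_radius < 0:
        raise GeometryError("probe_radius must be >= 0")
    if grid_step <= 0:
        raise GeometryError("grid_step must be positive")
    if grid_step > window / 10.0:
        raise ResolutionError(
            f"grid_step {grid_step} too coarse for a {window} Å window"
        )
    radii = radii or COVALENT_RADII
    layers = (
        [model] if isinstance(model, PoreLayer) else [model.layer1, model.layer2]
    )
    areas = []
    for layer in layers:
        cx, cy = layer.pore_center
        ax = np.arange(-window / 2.0, window / 2.0 + grid_step / 2, grid_step)
        gx, gy = np.meshgrid(ax + cx, ax + cy)
        open_mask = np.ones(gx.shape, dtype=bool)
        coords = layer.coordinates()
        elements = layer.elements()
        for el, (x, y, _z) in zip(elements, coords):
            rr = radii.get(el, 1.7) + probe_radius
            open_mask &= (gx - x) ** 2 + (gy - y) ** 2 > rr * rr
        # keep only the contiguous opening containing the pore centre:
        # flood fill from the centre cell
        areas.append(_flood_area(open_mask, grid_step))
    return float(min(areas))


def _flood_area(open_mask: np.ndarray, grid_step: float) -> float:
    """Area of the connected open region containing the grid centre."""
    from scipy.ndimage import label

    labels, _ = label(open_mask)
    centre = labels[open_mask.shape[0] // 2, open_mask.shape[1] // 2]
    if centre == 0:
        return 0.0
    return float(np.sum(labels == centre)) * grid_step**2


# ----------------------------------------------------------------------
# structure export
# ----------------------------------------------------------------------

def write_structure(
    model: BilayerPoreModel | PoreLayer, path: str | Path, format: str = "xyz"
) -> Path:
    """Write the model as XYZ or PDB (HETATM, one chain/residue per layer)."""
    path = Path(path)
    layers = [model] if isinstance(model, PoreLayer) else [model.layer1, model.layer2]
    fmt = format.lower()
    if fmt == "xyz":
        lines = [str(sum(l.n_atoms for l in layers))]
        label = getattr(model, "label", f"A{layers[0].twist_index}")
        lines.append(f"twistpore {label}")
        for layer in layers:
            for el, x, y, z in layer.atoms:
                lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "pdb":
        lines = []
        serial = 1
        for ichain, layer in enumerate(layers):
            chain = "AB"[ichain]
            for el, x, y, z in layer.atoms:
                name = f"{el}{serial % 100:d}"
                lines.append(
                    f"HETATM{serial:5d} {name:<4s} GRA {chain}{ichain + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
                )
                serial += 1
            lines.append(f"TER   {serial:5d}      GRA {chain}{ichain + 1:4d}")
            serial += 1
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise FormatError(f"unknown structure format {format!r}")
    return path


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a single-frame XYZ file -> (elements, coordinates)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    elements, coords = [], []
    for line in lines[2 : 2 + n]:
        el, x, y, z = line.split()[:4]
        elements.append(el)
        coords.append([float(x), float(y), float(z)])
    return elements, np.array(coords)
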