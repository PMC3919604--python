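"""Accessible-volume (AV) modelling of dye mean positions.

A fluorophore on a flexible linker samples the sterically allowed space
around its attachment atom.  The single-radius AV model treats the dye
as a sphere of radius ``dye_radius`` on a linker of length
``linker_length`` and width ``linker_width``: a cubic grid around the
attachment point is flood-filled, keeping points whose shortest
through-grid path from the attachment stays clear of all atoms (corridor
clearance >= linker_width / 2), whose path length does not exceed the
linker length, and which themselves clear every atom by the dye radius.
The centroid of the allowed points is the mean dye position used to
compare structural models against FRET-derived distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "StructureModel",
    "AccessibleVolume",
    "load_structure",
    "compute_av",
    "mean_position_distance",
    "compare_to_fret",
]

#: fallback van der Waals radius (A) for unknown elements
DEFAULT_VDW_RADIUS = 1.7


@dataclass
class StructureModel:
    """Atomic coordinates with van der Waals radii and one attachment atom."""

    coords: np.ndarray           # (n, 3) A
    radii: np.ndarray            # (n,) A
    elements: np.ndarray
    attachment_index: int
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be > 0")
        if not 0 <= self.attachment_index < len(self.coords):
            raise ValueError("attachment atom index out of range")

    @property
    def attachment_point(self) -> np.ndarray:
        return self.coords[self.attachment_index]


def _vdw_radius(element: str) -> float:
    from biotite.structure.info import vdw_radius_single

    try:
        r = vdw_radius_single(element.upper())
    except Exception:
        r = None
    return float(r) if r else DEFAULT_VDW_RADIUS


def load_structure(
    pdb_path: str,
    chain_id: str | None = None,
    res_id: int | None = None,
    atom_name: str | None = None,
    model: int = 1,
) -> StructureModel:
    """Load a PDB file and resolve exactly one attachment atom.

    The selector (chain / residue id / atom name, all optional but
    jointly unambiguous) must match exactly one atom; zero or multiple
    matches are rejected.
    """
    import biotite.structure.io.pdb as pdb

    atoms = pdb.PDBFile.read(pdb_path).get_structure(model=model)
    sel = np.ones(atoms.array_length(), dtype=bool)
    if chain_id is not None:
        sel &= atoms.chain_id == chain_id
    if res_id is not None:
        sel &= atoms.res_id == res_id
    if atom_name is not None:
        sel &= atoms.atom_name == atom_name
    idx = np.flatnonzero(sel)
    if len(idx) != 1:
        raise ValueError(
            f"attachment selector matched {len(idx)} atoms (need exactly 1): "
            f"chain={chain_id!r} res={res_id!r} atom={atom_name!r}"
        )
    radii = np.array([_vdw_radius(e) for e in atoms.element])
    return StructureModel(
        coords=atoms.coord,
        radii=radii,
        elements=np.asarray(atoms.element),
        attachment_index=int(idx[0]),
        labels=np.asarray(atoms.atom_name),
    )


@dataclass
class AccessibleVolume:
    """Sterically allowed dye positions and their centroid."""

    grid_spacing: float
    points: np.ndarray            # (m, 3) allowed grid points, A
    mean_position: np.ndarray     # (3,) centroid, A
    linker_length: float
    linker_width: float
    dye_radius: float
    empty: bool = False

    @property
    def n_points(self) -> int:
        return 0 if self.empty else len(self.points)


def compute_av(
    structure: StructureModel,
    linker_length: float,
    linker_width: float = 4.5,
    dye_radius: float = 3.5,
    grid_spacing: float = 2.0,
) -> AccessibleVolume:
    """Single-radius accessible volume by flood fill on a cubic grid.

    A grid point is allowed iff (i) its shortest through-grid path from
    the attachment atom is <= ``linker_length``, (ii) every point on that
    path clears all atoms by ``linker_width / 2`` beyond their van der
    Waals surface, and (iii) the point itself clears every atom surface
    by ``dye_radius``.  The attachment atom is excluded from the clash
    test (the linker is bonded to it).  An attachment buried so deeply
    that no point is reachable yields an AV flagged empty.
    """
    if grid_spacing > linker_width:
        raise ValueError("grid_spacing must be <= linker_width")
    origin = structure.attachment_point
    half = linker_length
    axis = np.arange(-half, half + grid_spacing / 2, grid_spacing)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + origin
    shape = (len(axis),) * 3

    # surface clearance to the nearest atom (attachment atom excluded)
    others = np.ones(len(structure.coords), dtype=bool)
    others[structure.attachment_index] = False
    coords = structure.coords[others]
    radii = structure.radii[others]
    if len(coords):
        clearance = np.full(len(pts), np.inf)
        # chunked to bound memory on large scenes
        step = 200
        for i in range(0, len(coords), step):
            d = np.linalg.norm(pts[:, None, :] - coords[None, i:i + step, :], axis=2)
            clearance = np.minimum(clearance, (d - radii[None, i:i + step]).min(axis=1))
    else:
        clearance = np.full(len(pts), np.inf)

    passable = clearance >= linker_width / 2.0
    source = int(np.ravel_multi_index(tuple([len(axis) // 2]) * 3, shape))
    passable[source] = True  # the attachment point itself is always reachable

    dist = _grid_geodesics(shape, grid_spacing, passable, source)
    allowed = (dist <= linker_length) & (clearance >= dye_radius)
    allowed[source] = allowed[source] and clearance[source] >= dye_radius

    if not allowed.any():
        return AccessibleVolume(
            grid_spacing=grid_spacing,
            points=np.empty((0, 3)),
            mean_position=origin.copy(),
            linker_length=linker_length,
            linker_width=linker_width,
            dye_radius=dye_radius,
            empty=True,
        )
    sel = pts[allowed]
    return AccessibleVolume(
        grid_spacing=grid_spacing,
        points=sel,
        mean_position=sel.mean(axis=0),
        linker_length=linker_length,
        linker_width=linker_width,
        dye_radius=dye_radius,
    )


def _grid_geodesics(
    shape: tuple[int, int, int],
    spacing: float,
    passable: np.ndarray,
    source: int,
) -> np.ndarray:
    """Shortest path lengths from `source` through passable grid nodes
    (26-connectivity, Euclidean edge weights)."""
    nx, ny, nz = shape
    n = nx * ny * nz
    idx = np.arange(n).reshape(shape)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    rows, cols, weights = [], [], []
    for dx, dy, dz in offsets:
        src = idx[
            max(0, -dx): nx - max(0, dx),
            max(0, -dy): ny - max(0, dy),
            max(0, -dz): nz - max(0, dz),
        ].ravel()
        dst = idx[
            max(0, dx): nx - max(0, -dx),
            max(0, dy): ny - max(0, -dy),
            max(0, dz): nz - max(0, -dz),
        ].ravel()
        ok = passable[src] & passable[dst]
        rows.append(src[ok])
        cols.append(dst[ok])
        weights.append(
            np.full(ok.sum(), spacing * np.sqrt(dx * dx + dy * dy + dz * dz))
        )
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return dijkstra(graph.tocsr(), directed=False, indices=source)


def mean_position_distance(av1: AccessibleVolume, av2: AccessibleVolume) -> float:
    """Euclidean distance (A) between the mean dye positions of two AVs."""
    if av1.empty or av2.empty:
        raise ValueError("cannot measure distances from an empty accessible volume")
    return float(np.linalg.norm(av1.mean_position - av2.mean_position))


def compare_to_fret(
    model_distances: dict[str, float],
    fret_distances: dict[str, float],
    fret_errors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Agreement report between model (AV) and FRET-derived distances.

    Lists |model - FRET| per labelled pair and whether the deviation lies
    within the stated FRET error.
    """
    fret_errors = fret_errors or {}
    rows = []
    for name in model_distances:
        if name not in fret_distances:
            continue
        m = float(model_distances[name])
        f = float(fret_distances[name])
        err = float(fret_errors.get(name, np.nan))
        dev = abs(m - f)
        rows.append(
            {
                "pair": name,
                "model_A": m,
                "fret_A": f,
                "fret_error_A": err,
                "deviation_A": dev,
                "within_error": bool(dev <= err) if np.isfinite(err) else None,
            }
        )
    return pd.DataFrame(rows)
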