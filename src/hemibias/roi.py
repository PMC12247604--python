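"""Fixed-size ROI growth around seed points by iterative thresholding.

A region of interest is grown from a seed on a statistical map (volume) or
a per-vertex statistic (surface): the map is thresholded, the connected
component containing the seed is taken, and the threshold is iteratively
adjusted — here by exact search over the map's distinct values — until the
component reaches the target size.  Volume masks are then trimmed to an
exact voxel count; surface masks stop at minimal overshoot of the target
area because vertex areas are lumpy.

Default targets follow common practice for group-localiser ROIs:
250 voxels (2000 mm^3 at 2 mm isotropic) for volumes and 380 mm^2 for
surface clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: Default grown-cluster sizes.
DEFAULT_TARGET_VOXELS = 250
DEFAULT_TARGET_AREA_MM2 = 380.0


class UnreachableTargetError(ValueError):
    """The seed's component cannot reach the requested size at any threshold."""


@dataclass
class StatMap:
    """A 3D scalar statistical image.

    NaN values are treated as below every threshold (masked out) and can
    never join an ROI.
    """

    values: np.ndarray
    voxel_size: float | tuple[float, float, float] = 1.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.isscalar(self.voxel_size) or np.ndim(self.voxel_size) == 0:
            self.voxel_size = (float(self.voxel_size),) * 3
        else:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")
        if np.isinf(self.values).any():
            raise ValueError("stat map contains infinite values")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def world_to_index(self, xyz) -> tuple[int, int, int]:
        """Map a world coordinate (mm) to the nearest voxel index."""
        inv = np.linalg.inv(self.affine)
        ijk = inv @ np.append(np.asarray(xyz, dtype=float), 1.0)
        return tuple(int(round(c)) for c in ijk[:3])


@dataclass
class SurfaceMesh:
    """Triangulated surface with a per-vertex scalar statistic."""

    vertices: np.ndarray
    faces: np.ndarray
    scalars: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.scalars = np.asarray(self.scalars, dtype=float)
        nv = len(self.vertices)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) vertex-index triplets")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= nv):
            raise ValueError("face indices out of range")
        if self.scalars.shape != (nv,):
            raise ValueError("scalars must be per-vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def vertex_neighbors(self) -> list[set[int]]:
        """Adjacency over shared mesh edges."""
        neigh: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.faces:
            neigh[a].update((b, c))
            neigh[b].update((a, c))
            neigh[c].update((a, b))
        return neigh

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        ab = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        ac = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(ab, ac), axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())


@dataclass
class ROIMask:
    """A labelled, connected set of voxel or vertex indices."""

    kind: str  # "volume" | "surface"
    members: list
    seed: object
    region: str = ""
    hemisphere: str = ""
    network: str = ""
    achieved_size: float = 0.0
    final_threshold: float = float("nan")
    connectivity: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("volume", "surface"):
            raise ValueError("kind must be 'volume' or 'surface'")
        if self.seed not in self.members:
            raise ValueError("seed must be a member of the mask")

    def __len__(self) -> int:
        return len(self.members)

    def to_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Binary 0/1 volume of the mask (volume kind only)."""
        if self.kind != "volume":
            raise ValueError("to_volume applies to volume masks")
        out = np.zeros(shape, dtype=np.uint8)
        idx = np.array(self.members)
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        return out


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _seed_component(values: np.ndarray, seed: tuple[int, int, int],
                    threshold: float, structure: np.ndarray) -> np.ndarray:
    """Boolean mask of the seed's connected component at >= threshold."""
    with np.errstate(invalid="ignore"):
        supra = values >= threshold  # NaN compares False: treated as -inf
    if not supra[seed]:
        return np.zeros_like(supra)
    labels, _ = ndimage.label(supra, structure=structure)
    return labels == labels[seed]


def grow_volume_roi(
    statmap: StatMap,
    seed: tuple[int, int, int],
    target_voxels: int = DEFAULT_TARGET_VOXELS,
    connectivity: int = 26,
    region: str = "",
    hemisphere: str = "",
    network: str = "",
) -> ROIMask:
    """Grow a fixed-size volumetric ROI around a seed voxel.

    The threshold is searched over the sorted distinct finite map values
    (exact bisection on ranks): the returned mask derives from the seed's
    connected component at the LARGEST threshold whose component size
    reaches ``target_voxels``, then is trimmed to exactly ``target_voxels``
    by removing the lowest-valued boundary voxels (ties broken by
    lexicographic (x, y, z) index) without ever disconnecting the seed.

    Raises
    ------
    UnreachableTargetError
        If even at the minimum map value the seed's component stays below
        ``target_voxels``.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if target_voxels < 1:
        raise ValueError("target_voxels must be >= 1")
    seed = tuple(int(c) for c in seed)
    values = statmap.values
    if any(c < 0 or c >= s for c, s in zip(seed, values.shape)):
        raise ValueError(f"seed {seed} outside grid {values.shape}")
    if not np.isfinite(values[seed]):
        raise ValueError("map value at the seed is not finite")

    structure = _STRUCTURES[connectivity]

    # Candidate thresholds: distinct finite values not above the seed value
    # (any higher threshold excludes the seed itself).
    finite = values[np.isfinite(values)]
    cand = np.unique(finite[finite <= values[seed]])  # ascending

    # Component size is non-increasing in the threshold, so bisect for the
    # largest threshold with component size >= target.
    lo, hi = 0, len(cand) - 1  # indices into cand
    if _seed_component(values, seed, cand[0], structure).sum() < target_voxels:
        raise UnreachableTargetError(
            f"seed component holds fewer than {target_voxels} voxels even at "
            f"the minimum threshold"
        )
    # invariant: comp(cand[lo]) >= target; search upward
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _seed_component(values, seed, cand[mid], structure).sum() >= target_voxels:
            lo = mid
        else:
            hi = mid - 1
    threshold = float(cand[lo])
    comp = _seed_component(values, seed, threshold, structure)
    members = {tuple(ijk) for ijk in np.argwhere(comp)}

    members = _trim_to_exact(members, values, seed, target_voxels, structure)

    ordered = sorted(members)
    return ROIMask(
        kind="volume",
        members=ordered,
        seed=seed,
        region=region,
        hemisphere=hemisphere,
        network=network,
        achieved_size=float(len(ordered)),
        final_threshold=threshold,
        connectivity=connectivity,
    )


def _trim_to_exact(members: set, values: np.ndarray, seed, target: int,
                   structure: np.ndarray) -> set:
    """Remove lowest-valued boundary voxels until exactly ``target`` remain.

    Ties break lexicographically; a voxel whose removal would disconnect the
    seed's component is skipped.  Connectivity is re-checked per removal on
    an array cropped to the mask's bounding box.
    """
    members = set(members)
    if len(members) <= target:
        return members

    idx = np.array(sorted(members))
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = idx.max(axis=0) + 2
    mask = np.zeros(tuple(hi - lo), dtype=bool)
    local = idx - lo
    mask[local[:, 0], local[:, 1], local[:, 2]] = True
    seed_local = tuple(np.asarray(seed) - lo)

    vals_local = values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]

    def removal_keeps_connected(vox_local) -> bool:
        mask[tuple(vox_local)] = False
        labels, _ = ndimage.label(mask, structure=structure)
        ok = labels[seed_local] > 0 and \
            (labels == labels[seed_local]).sum() == mask.sum()
        mask[tuple(vox_local)] = True
        return ok

    while len(members) > target:
        interior = ndimage.binary_erosion(mask, structure=structure,
                                          border_value=0)
        cand = np.argwhere(mask & ~interior)
        if cand.size == 0:  # only interior voxels left to consider
            cand = np.argwhere(mask)
        keep = ~np.all(cand == seed_local, axis=1)
        cand = cand[keep]
        vals = vals_local[cand[:, 0], cand[:, 1], cand[:, 2]]
        order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], vals))
        for k in order:
            vox_local = cand[k]
            if removal_keeps_connected(vox_local):
                mask[tuple(vox_local)] = False
                members.discard(tuple(vox_local + lo))
                break
        else:
            raise RuntimeError("cannot trim mask without disconnecting the seed")
    return members


# ---------------------------------------------------------------------------
# Surface growth


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex area: one third of each incident triangle's area.

    The vertex areas tile the surface, so their sum equals the total mesh
    area exactly (up to floating-point error).  Vertices referenced by no
    face get area 0 and are logged.
    """
    areas = np.zeros(mesh.n_vertices, dtype=float)
    face_area_thirds = mesh.face_areas() / 3.0
    np.add.at(areas, mesh.faces[:, 0], face_area_thirds)
    np.add.at(areas, mesh.faces[:, 1], face_area_thirds)
    np.add.at(areas, mesh.faces[:, 2], face_area_thirds)
    referenced = np.zeros(mesh.n_vertices, dtype=bool)
    referenced[mesh.faces.ravel()] = True
    n_orphan = int((~referenced).sum())
    if n_orphan:
        log.warning("%d unreferenced vertices have zero area", n_orphan)
    return areas


def _surface_component(mesh_neigh, scalars, seed, threshold) -> set:
    """Edge-connected vertex component of the seed at >= threshold."""
    with np.errstate(invalid="ignore"):
        supra = scalars >= threshold
    if not supra[seed]:
        return set()
    comp = {seed}
    stack = [seed]
    while stack:
        cur = stack.pop()
        for nxt in mesh_neigh[cur]:
            if supra[nxt] and nxt not in comp:
                comp.add(nxt)
                stack.append(nxt)
    return comp


def grow_surface_roi(
    mesh: SurfaceMesh,
    seed: int,
    target_area: float = DEFAULT_TARGET_AREA_MM2,
    region: str = "",
    hemisphere: str = "",
    network: str = "",
) -> ROIMask:
    """Grow a surface ROI of approximately ``target_area`` mm^2 around a seed.

    The threshold is lowered over the distinct per-vertex values until the
    seed's edge-connected component first reaches ``target_area`` (summed
    vertex areas).  The component is then pared back to minimal overshoot:
    while the lowest-valued member whose removal keeps the mask connected
    can be dropped without falling below the target, it is dropped.  The
    result satisfies ``achieved_size >= target_area`` and removing the
    lowest-valued removable member would cross below the target.

    Raises
    ------
    UnreachableTargetError
        If the whole mesh area is below ``target_area``.
    """
    if target_area <= 0:
        raise ValueError("target_area must be > 0")
    seed = int(seed)
    if not 0 <= seed < mesh.n_vertices:
        raise ValueError("seed vertex index out of range")
    if not np.isfinite(mesh.scalars[seed]):
        raise ValueError("scalar at the seed is not finite")

    v_area = vertex_areas(mesh)
    if v_area.sum() < target_area:
        raise UnreachableTargetError(
            f"total mesh area {v_area.sum():.2f} mm^2 is below the target "
            f"{target_area} mm^2"
        )

    neigh = mesh.vertex_neighbors()
    scalars = mesh.scalars
    finite = scalars[np.isfinite(scalars)]
    cand = np.unique(finite[finite <= scalars[seed]])  # ascending

    comp0 = _surface_component(neigh, scalars, seed, cand[0])
    if float(v_area[list(comp0)].sum()) < target_area:
        raise UnreachableTargetError(
            "seed component area stays below the target even at the minimum "
            "threshold"
        )
    lo, hi = 0, len(cand) - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        comp = _surface_component(neigh, scalars, seed, cand[mid])
        if comp and float(v_area[list(comp)].sum()) >= target_area:
            lo = mid
        else:
            hi = mid - 1
    threshold = float(cand[lo])
    members = _surface_component(neigh, scalars, seed, threshold)
    area = float(v_area[list(members)].sum())

    # Pare back to minimal overshoot without disconnecting the seed.
    while True:
        removable = None
        for vtx in sorted(members - {seed}, key=lambda i: (scalars[i], i)):
            if _surface_connected(members, vtx, neigh, seed):
                removable = vtx
                break
        if removable is None or area - v_area[removable] < target_area:
            break
        members.discard(removable)
        area -= v_area[removable]

    ordered = sorted(members)
    return ROIMask(
        kind="surface",
        members=ordered,
        seed=seed,
        region=region,
        hemisphere=hemisphere,
        network=network,
        achieved_size=area,
        final_threshold=threshold,
    )


def _surface_connected(members: set, removed: int, neigh, seed: int) -> bool:
    remaining = members - {removed}
    if not remaining:
        return False
    stack = [seed]
    seen = {seed}
    while stack:
        cur = stack.pop()
        for nxt in neigh[cur]:
            if nxt in remaining and nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return len(seen) == len(remaining)
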