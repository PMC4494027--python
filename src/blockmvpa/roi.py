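"""Fixed-size contiguous ROI growth on statistical maps.

Selection is a deterministic greedy region growth: seed at the mask's
maximum-z voxel, then repeatedly absorb the highest-z frontier voxel
until the requested size is reached.  Ties break toward the lowest
linear voxel index (x fastest), so results are reproducible bit for bit.
This is a heuristic — globally maximizing summed z over connected subsets
is NP-hard and deliberately not attempted.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from blockmvpa.errors import RoiError
from blockmvpa.glm import ZMap

CONNECTIVITY_OFFSETS = {}
for conn in (6, 18, 26):
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if (conn == 6 and order == 1) or (conn == 18 and order <= 2) or conn == 26:
            offs.append(d)
    CONNECTIVITY_OFFSETS[conn] = tuple(offs)


@dataclass
class MaskSet:
    """Named binary 3-D masks sharing one grid (group-parcel surrogates)."""

    masks: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise RoiError(f"masks on mismatched grids: {shapes}")
        for name, m in self.masks.items():
            if m.dtype != bool:
                self.masks[name] = m.astype(bool)
            if not self.masks[name].any():
                raise RoiError(f"mask {name!r} is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape

    def voxel_counts(self) -> dict[str, int]:
        return {name: int(m.sum()) for name, m in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)


@dataclass
class ROI:
    """Contiguous fixed-size voxel set grown from a z-map."""

    name: str
    voxels: np.ndarray = field(repr=False)  # (size, 3) int coordinates
    connectivity: int = 26
    mean_z: float = float("nan")
    center_of_mass_mm: tuple[float, float, float] | None = None
    growth_order: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise RoiError("voxels must be an (n, 3) coordinate array")

    @property
    def size(self) -> int:
        return self.voxels.shape[0]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m

    def is_connected(self, connectivity: int | None = None) -> bool:
        """Breadth-first check that every voxel is reachable from the first."""
        conn = self.connectivity if connectivity is None else connectivity
        vox = {tuple(v) for v in self.voxels}
        seen = {tuple(self.voxels[0])}
        frontier = [tuple(self.voxels[0])]
        offs = CONNECTIVITY_OFFSETS[conn]
        while frontier:
            x, y, z = frontier.pop()
            for dx, dy, dz in offs:
                nb = (x + dx, y + dy, z + dz)
                if nb in vox and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        return len(seen) == len(vox)


def _linear_index(coord: tuple[int, int, int], shape: tuple[int, int, int]) -> int:
    # x fastest-varying; deterministic tie-break order
    x, y, z = coord
    nx, ny, _ = shape
    return x + nx * (y + ny * z)


def grow_roi(
    zmap: ZMap,
    mask: np.ndarray,
    size: int,
    connectivity: int = 26,
    name: str = "roi",
) -> ROI:
    """Grow the contiguous ``size``-voxel cluster of highest z inside a mask.

    Greedy: seed at the mask's maximum-z voxel; at each step add the
    frontier voxel (mask neighbors of the cluster) with the highest z.
    z-ties break toward the lowest linear index.  The size-k result is
    always a prefix of the size-(k+1) result (``growth_order`` records
    the full trace).
    """
    if connectivity not in CONNECTIVITY_OFFSETS:
        raise RoiError(f"connectivity must be one of 6/18/26, got {connectivity}")
    if size < 1:
        raise RoiError(f"size must be >= 1, got {size}")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != zmap.data.shape:
        raise RoiError(
            f"mask shape {mask.shape} does not match z-map {zmap.data.shape}"
        )
    n_mask = int(mask.sum())
    if n_mask < size:
        raise RoiError(
            f"mask {name!r} has {n_mask} voxels, {size - n_mask} short of the "
            f"requested {size}"
        )
    z = zmap.data
    shape = z.shape
    offs = CONNECTIVITY_OFFSETS[connectivity]

    in_mask = {tuple(c) for c in np.argwhere(mask)}
    seed = max(in_mask, key=lambda c: (z[c], -_linear_index(c, shape)))

    cluster: list[tuple[int, int, int]] = [seed]
    members = {seed}
    heap: list[tuple[float, int, tuple[int, int, int]]] = []
    queued = {seed}

    def push_neighbors(coord):
        x, y, zc = coord
        for dx, dy, dz in offs:
            nb = (x + dx, y + dy, zc + dz)
            if nb in in_mask and nb not in queued:
                heapq.heappush(heap, (-z[nb], _linear_index(nb, shape), nb))
                queued.add(nb)

    push_neighbors(seed)
    while len(cluster) < size:
        if not heap:
            raise RoiError(
                f"mask {name!r}: connected component of the seed exhausted at "
                f"{len(cluster)} voxels, {size - len(cluster)} short of {size}"
            )
        _, _, coord = heapq.heappop(heap)
        cluster.append(coord)
        members.add(coord)
        push_neighbors(coord)

    voxels = np.array(cluster, dtype=int)
    roi = ROI(
        name=name,
        voxels=voxels,
        connectivity=connectivity,
        mean_z=float(z[tuple(voxels.T)].mean()),
        growth_order=voxels.copy(),
    )
    if zmap.affine is not None:
        roi.center_of_mass_mm = tuple(center_of_mass_mm(voxels, zmap.affine))
    return roi


def center_of_mass_mm(voxels: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Unweighted mean of world-space voxel coordinates."""
    homog = np.column_stack([voxels, np.ones(len(voxels))])
    world = homog @ affine.T
    return world[:, :3].mean(axis=0)


def summarize_rois(
    rois: list[ROI],
    zmap: ZMap,
    voxel_size_mm=(2.0, 2.0, 3.0),
    affine: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-ROI table: name, size, volume mm3, mean z, center of mass (mm)."""
    if not rois:
        raise RoiError("no ROIs to summarize")
    if affine is None:
        affine = zmap.affine
    if affine is None:
        affine = np.diag([*voxel_size_mm, 1.0])
    vox_vol = float(np.prod(voxel_size_mm))
    shape = zmap.data.shape
    rows = []
    for roi in rois:
        if (roi.voxels < 0).any() or (roi.voxels >= np.array(shape)).any():
            raise RoiError(f"ROI {roi.name!r} has voxels outside the grid {shape}")
        com = center_of_mass_mm(roi.voxels, affine)
        rows.append(
            dict(
                name=roi.name,
                size=roi.size,
                volume_mm3=roi.size * vox_vol,
                mean_z=float(zmap.data[tuple(roi.voxels.T)].mean()),
                com_x_mm=com[0],
                com_y_mm=com[1],
                com_z_mm=com[2],
            )
        )
    return pd.DataFrame(rows)


# Parcel names follow the anatomical naming convention of published
# group-level functional language parcels: 7 temporo-parietal (5 left +
# 2 right homologues) and 4 left frontal regions.
TEMPORAL_REGIONS = (
    "L_AngularGyrus",
    "L_SupramarginalGyrus",
    "L_PosteriorSTS",
    "L_MidAnteriorTemporal",
    "L_AnteriorTemporal",
    "R_PosteriorSTS",
    "R_MidAnteriorTemporal",
)
FRONTAL_REGIONS = (
    "L_OrbitalIFG",
    "L_IFG",
    "L_MiddleFrontalGyrus",
    "L_SuperiorFrontalGyrus",
)
DEFAULT_REGIONS = TEMPORAL_REGIONS + FRONTAL_REGIONS


def _tiling(n: int) -> tuple[int, int, int]:
    """Near-cubic (a, b, c) with a*b*c >= n tiles."""
    best = None
    for a in range(1, n + 1):
        for b in range(a, n + 1):
            c = -(-n // (a * b))
            if c < b:
                continue
            waste = a * b * c - n
            spread = c - a
            key = (spread, waste)
            if best is None or key < best[0]:
                best = (key, (a, b, c))
    return best[1]


def _splits(extent: int, parts: int, rng: np.random.Generator, jitter: bool):
    base = np.linspace(0, extent, parts + 1).round().astype(int)
    if jitter and parts > 1:
        for i in range(1, parts):
            lo = base[i - 1] + 1
            hi = base[i + 1] - 1
            j = base[i] + rng.integers(-1, 2)
            base[i] = min(max(j, lo), hi)
    return base


def default_mask_set(
    shape: tuple[int, int, int],
    regions: tuple[str, ...] = DEFAULT_REGIONS,
    seed: int = 1234,
) -> MaskSet:
    """Synthetic surrogate parcels: a disjoint box tiling, one per region.

    Purely a stand-in for published probabilistic group parcels (which
    are not bundled): each named region is a rectangular, hence
    connected, sub-box of the grid; the seed jitters the cut planes.
    """
    rng = np.random.default_rng(seed)
    n = len(regions)
    a, b, c = _tiling(n)
    # Put the most tiles along the largest grid axis
    axes = np.argsort(shape)  # ascending
    parts = np.empty(3, dtype=int)
    parts[axes] = sorted((a, b, c))
    for ax in range(3):
        if parts[ax] > shape[ax]:
            raise RoiError(f"grid {shape} too small to tile {n} regions")
    sx = _splits(shape[0], parts[0], rng, jitter=True)
    sy = _splits(shape[1], parts[1], rng, jitter=True)
    sz = _splits(shape[2], parts[2], rng, jitter=True)
    boxes = [
        ((sx[i], sx[i + 1]), (sy[j], sy[j + 1]), (sz[k], sz[k + 1]))
        for i in range(parts[0])
        for j in range(parts[1])
        for k in range(parts[2])
    ]
    masks = {}
    for name, ((x0, x1), (y0, y1), (z0, z1)) in zip(regions, boxes):
        m = np.zeros(shape, dtype=bool)
        m[x0:x1, y0:y1, z0:z1] = True
        masks[name] = m
    return MaskSet(masks)
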