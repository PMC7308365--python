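"""Lattice geometry, state storage, neighborhoods and cluster analysis.

The landscape is a square L x L torus (periodic in both axes).  Every site
carries exactly one :class:`CellState`; distances are Manhattan (Hamming)
distances under the minimum-image convention.  Everything here is purely
spatial -- no dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

__all__ = [
    "CellState",
    "LandscapeGrid",
    "NeighborhoodSpec",
    "ClusterStats",
    "neighborhood_offsets",
    "count_neighbors",
    "connected_clusters",
    "write_snapshot_png",
]


class CellState(IntEnum):
    """Per-site state.

    ``DESTROYED`` habitat is unavailable for colonization until a niche
    constructor renews it; ``VACANT`` habitat is colonizable; ``NC`` is an
    occupied niche-constructor population and ``EXPLOITER`` an occupied
    plain-contact-process population (only present in competition runs).
    Integer codes (-1, 0, 1, 2) are the on-disk representation as well.
    """

    DESTROYED = -1
    VACANT = 0
    NC = 1
    EXPLOITER = 2


#: RGB palette used by snapshot images: occupied/NC green, vacant white,
#: destroyed black, exploiter red.
STATE_COLORS = {
    CellState.DESTROYED: (0, 0, 0),
    CellState.VACANT: (255, 255, 255),
    CellState.NC: (34, 139, 34),
    CellState.EXPLOITER: (200, 30, 30),
}


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A von Neumann (Manhattan-ball) interaction neighborhood of range ``r``.

    ``offsets`` holds every displacement ``d`` with ``1 <= |d|_1 <= r``; the
    focal site itself is excluded.  The number of offsets is ``2 r (r + 1)``.
    """

    range: int
    offsets: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.offsets)


def neighborhood_offsets(r: int) -> NeighborhoodSpec:
    """All toroidal displacements at Manhattan distance 1..r from a site.

    Parameters
    ----------
    r : int
        Interaction range, ``r >= 1``.  ``r = 1`` gives the four nearest
        neighbors (N, E, S, W); in general the ball contains ``2 r (r + 1)``
        sites.
    """
    r = int(r)
    if r < 1:
        raise ValueError(f"neighborhood range must be >= 1, got {r}")
    offs = [
        (di, dj)
        for di in range(-r, r + 1)
        for dj in range(-r, r + 1)
        if 1 <= abs(di) + abs(dj) <= r
    ]
    arr = np.array(sorted(offs), dtype=np.int64)
    return NeighborhoodSpec(range=r, offsets=arr)


@dataclass
class LandscapeGrid:
    """An L x L toroidal landscape of :class:`CellState` codes.

    ``states`` is an ``int8`` array using the integer codes of
    :class:`CellState`.  The grid is square and periodic in both axes.
    """

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[0] != self.states.shape[1]:
            raise ValueError("LandscapeGrid requires a square 2D state array")
        valid = np.isin(self.states, [s.value for s in CellState])
        if not valid.all():
            raise ValueError("state array contains codes outside {-1, 0, 1, 2}")

    # -- basic geometry -------------------------------------------------
    @property
    def size(self) -> int:
        """Side length L."""
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.size

    @classmethod
    def filled(cls, L: int, state: CellState) -> "LandscapeGrid":
        if L < 4:
            raise ValueError(f"lattice side must be >= 4, got {L}")
        return cls(np.full((L, L), int(state), dtype=np.int8))

    def copy(self) -> "LandscapeGrid":
        return LandscapeGrid(self.states.copy())

    # -- summaries ------------------------------------------------------
    def counts(self) -> dict[CellState, int]:
        return {s: int(np.count_nonzero(self.states == s)) for s in CellState}

    def fractions(self) -> dict[CellState, float]:
        n = self.n_sites
        return {s: c / n for s, c in self.counts().items()}

    # -- serialization --------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the integer-coded matrix as CSV (one row per lattice row)."""
        np.savetxt(path, self.states, fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandscapeGrid":
        return cls(np.loadtxt(path, delimiter=",", dtype=np.int8))

    def to_npz(self, path: str | Path) -> None:
        np.savez_compressed(path, states=self.states)

    @classmethod
    def from_npz(cls, path: str | Path) -> "LandscapeGrid":
        with np.load(path) as data:
            return cls(data["states"])


def count_neighbors(
    grid: LandscapeGrid,
    site: tuple[int, int],
    spec: NeighborhoodSpec,
    target: CellState,
) -> int:
    """Number of neighborhood offsets whose (wrapped) site has state ``target``.

    Offsets wrap around the torus.  On lattices narrower than the
    neighborhood diameter two distinct offsets may reach the same physical
    site; each offset is counted separately, matching the per-offset
    propagule semantics of the dynamics.
    """
    L = grid.size
    i, j = site
    if not (0 <= i < L and 0 <= j < L):
        raise ValueError(f"site {site} outside {L}x{L} grid")
    rows = (i + spec.offsets[:, 0]) % L
    cols = (j + spec.offsets[:, 1]) % L
    return int(np.count_nonzero(grid.states[rows, cols] == int(target)))


@dataclass
class ClusterStats:
    """Connected-component summary of the sites occupied by ``targets``."""

    cluster_sizes: list[int]
    n_clusters: int
    largest_fraction: float


def connected_clusters(
    grid: LandscapeGrid, targets: set[CellState] | frozenset[CellState]
) -> ClusterStats:
    """Connected components of target-state sites under toroidal 4-connectivity.

    Connectivity is fixed to the von Neumann (r = 1) graph -- the
    colonization graph that defines population contiguity -- independent of
    any construction range used by the dynamics.
    """
    from scipy import ndimage

    mask = np.isin(grid.states, [int(t) for t in targets])
    if not mask.any():
        return ClusterStats(cluster_sizes=[], n_clusters=0, largest_fraction=0.0)

    labels, n = ndimage.label(mask)  # 4-connectivity is scipy's default

    # merge labels across the periodic seams with a tiny union-find
    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    top, bottom = labels[0, :], labels[-1, :]
    left, right = labels[:, 0], labels[:, -1]
    for a, b in zip(top, bottom):
        if a and b:
            union(int(a), int(b))
    for a, b in zip(left, right):
        if a and b:
            union(int(a), int(b))

    roots = np.array([find(l) for l in range(n + 1)])
    merged = roots[labels]
    sizes = sorted(
        (int(s) for s in np.bincount(merged.ravel())[1:] if s > 0), reverse=True
    )
    total = int(mask.sum())
    return ClusterStats(
        cluster_sizes=sizes,
        n_clusters=len(sizes),
        largest_fraction=sizes[0] / total if sizes else 0.0,
    )


def write_snapshot_png(grid: LandscapeGrid, path: str | Path, scale: int = 1) -> None:
    """Render the lattice as a PNG with the standard palette.

    green = occupied (NC), white = vacant, black = destroyed, red = exploiter.
    ``scale`` magnifies each site to a ``scale x scale`` pixel block.
    """
    from PIL import Image

    L = grid.size
    rgb = np.zeros((L, L, 3), dtype=np.uint8)
    for state, color in STATE_COLORS.items():
        rgb[grid.states == int(state)] = color
    img = Image.fromarray(rgb, mode="RGB")
    if scale > 1:
        img = img.resize((L * scale, L * scale), Image.NEAREST)
    img.save(path)
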