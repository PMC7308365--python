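"""Continuous-time stochastic dynamics of the niche-construction lattice model.

This is the interacting-particle-system layer: initial conditions, per-site
transition rates, a single-event :class:`Simulation` (pure Python, for tiny
lattices and inspection) and the fast :func:`run` driver backed by the
compiled event loop in :mod:`nichesim._kernel`.

Reactions (rates per unit model time):

* occupied -> vacant at ``delta`` (local extinction),
* any non-destroyed site -> destroyed at ``e``,
* vacant site colonized by NC at ``(1-c)**alpha * n_NC(Z*) / |Z*|`` and by
  the exploiter at ``n_EX(Z*) / |Z*|``,
* destroyed site renewed to vacant at ``c * n_NC(Z) / |Z|`` (only NC
  constructs).

Waiting times are exponential; the all-destroyed (and, for ``e = 0``, the
all-unoccupied) configuration is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel
from .lattice import CellState, LandscapeGrid, NeighborhoodSpec, neighborhood_offsets
from .params import ModelParams

__all__ = [
    "ModelParams",
    "Trajectory",
    "Simulation",
    "site_rates",
    "init_full",
    "init_single_seed",
    "run",
    "spawn_seeds",
]

_EVENT_NAMES = (
    "death_nc",
    "death_ex",
    "destruction_occupied",
    "destruction_vacant",
    "colonization_nc",
    "colonization_ex",
    "construction",
    "null_attempt",
)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def init_full(
    L: int,
    mode: str = "nc",
    fraction: float = 0.5,
    seed: int | None = None,
) -> LandscapeGrid:
    """Fully occupied lattice.

    ``mode="nc"`` fills every site with NC.  ``mode="mixed"`` assigns each
    site independently to NC with probability ``fraction`` and to the
    exploiter otherwise (the symmetric competition start).
    """
    if mode == "nc":
        return LandscapeGrid.filled(L, CellState.NC)
    if mode == "mixed":
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
        rng = np.random.default_rng(seed)
        states = np.where(
            rng.random((L, L)) < fraction, int(CellState.NC), int(CellState.EXPLOITER)
        ).astype(np.int8)
        return LandscapeGrid(states)
    raise ValueError(f"unknown init mode {mode!r}")


def init_single_seed(
    L: int, background: CellState = CellState.DESTROYED
) -> LandscapeGrid:
    """One central NC founder on an otherwise homogeneous landscape.

    The default background is fully destroyed.  Range-expansion experiments
    instead start from a vacant background (``background=VACANT``): the far
    field then decays to the destroyed "vacuum" at rate ``e`` while the
    expanding population maintains its mosaic -- a lone founder on an
    all-destroyed landscape rarely establishes at all once the construction
    range is large, because renewed habitat scatters far beyond its
    nearest-neighbor colonization reach.
    """
    if background in (CellState.NC, CellState.EXPLOITER):
        raise ValueError("single-seed background must be DESTROYED or VACANT")
    grid = LandscapeGrid.filled(L, background)
    grid.states[L // 2, L // 2] = int(CellState.NC)
    return grid


# ---------------------------------------------------------------------------
# per-site rates (target-centric view; used by oracles and the Python stepper)
# ---------------------------------------------------------------------------

def site_rates(
    grid: LandscapeGrid, site: tuple[int, int], params: ModelParams
) -> dict[CellState, float]:
    """Admissible transitions of one site, as ``{new_state: rate}``.

    This is the target-centric description of the reaction scheme; the fast
    event loop uses the equivalent source-centric clocks.  Zero-rate
    transitions are omitted.
    """
    s = CellState(int(grid.states[site]))
    col = neighborhood_offsets(params.r_col)
    rates: dict[CellState, float] = {}
    if s in (CellState.NC, CellState.EXPLOITER):
        if params.delta > 0:
            rates[CellState.VACANT] = params.delta
        if params.e > 0:
            rates[CellState.DESTROYED] = params.e
    elif s is CellState.VACANT:
        if params.e > 0:
            rates[CellState.DESTROYED] = params.e
        from .lattice import count_neighbors

        n_nc = count_neighbors(grid, site, col, CellState.NC)
        if params.beta * n_nc > 0:
            rates[CellState.NC] = params.beta * n_nc / col.size
        n_ex = count_neighbors(grid, site, col, CellState.EXPLOITER)
        if n_ex > 0:
            rates[CellState.EXPLOITER] = n_ex / col.size
    else:  # DESTROYED
        if params.c > 0:
            if params.global_construction:
                n_nc = int(np.count_nonzero(grid.states == int(CellState.NC)))
                size = grid.n_sites
            else:
                from .lattice import count_neighbors

                con = neighborhood_offsets(params.construction_range)
                n_nc = count_neighbors(grid, site, con, CellState.NC)
                size = con.size
            if n_nc > 0:
                rates[CellState.VACANT] = params.c * n_nc / size
    return rates


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled global state fractions of one realization.

    ``p_minus + p_vac + p_nc + p_ex = 1`` at every sample.  ``absorbed`` is
    True when no occupied site remained at the end of the run;
    ``absorbed_at`` is the model time of the last occupied site's
    disappearance (-1.0 if the population survived).
    """

    times: np.ndarray
    p_minus: np.ndarray
    p_vac: np.ndarray
    p_nc: np.ndarray
    p_ex: np.ndarray
    absorbed: bool
    absorbed_at: float
    seed: int
    params: ModelParams
    event_counts: dict[str, int] = field(default_factory=dict)
    occupied_site_time: float = 0.0
    final_grid: LandscapeGrid | None = None
    extent: np.ndarray | None = None
    transect: np.ndarray | None = None
    snapshots: np.ndarray | None = None
    snapshot_times: np.ndarray | None = None

    @property
    def p_occupied(self) -> np.ndarray:
        return self.p_nc + self.p_ex

    def mean_occupancy(self, t_from: float, t_to: float | None = None) -> float:
        """Time-average of the occupied fraction over ``[t_from, t_to]``."""
        sel = self.times >= t_from
        if t_to is not None:
            sel &= self.times <= t_to
        if not sel.any():
            raise ValueError("averaging window contains no samples")
        return float(self.p_occupied[sel].mean())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "p_minus": self.p_minus,
                "p_vacant": self.p_vac,
                "p_nc": self.p_nc,
                "p_ex": self.p_ex,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run(
    params: ModelParams,
    init: LandscapeGrid,
    t_max: float,
    sample_dt: float = 1.0,
    seed: int = 0,
    *,
    keep_final_grid: bool = False,
    record_row: int | None = None,
    snapshot_stride: int = 0,
    track_extent: bool = False,
    center: tuple[int, int] | None = None,
) -> Trajectory:
    """Simulate the model from ``init`` until ``t_max`` model-time units.

    The trajectory is sampled every ``sample_dt`` units and is bitwise
    reproducible for a fixed seed.  Optional extras: ``record_row`` stores a
    1D spatial transect (that lattice row at every sample),
    ``snapshot_stride`` stores the full grid every that-many samples, and
    ``track_extent`` records the maximum Chebyshev radius of occupied sites
    around ``center`` (default: lattice center) at every sample -- the
    mosaic-extent proxy used by range-expansion experiments.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if sample_dt <= 0:
        raise ValueError("sample_dt must be positive")
    L = init.size
    if params.competition is False and (init.states == int(CellState.EXPLOITER)).any():
        raise ValueError("initial grid contains exploiters but competition is off")
    state = init.states.ravel().copy()
    col = neighborhood_offsets(params.r_col).offsets
    con = neighborhood_offsets(params.construction_range).offsets
    ci, cj = center if center is not None else (L // 2, L // 2)
    row_idx = -1 if record_row is None else int(record_row)
    if row_idx >= L:
        raise ValueError(f"record_row {row_idx} out of range for L={L}")

    times, fracs, counts, occ_time, absorbed, absorbed_at, extent, rows, snaps = (
        _kernel.run_kernel(
            state,
            L,
            float(params.delta),
            float(params.e),
            float(params.c),
            float(params.beta),
            col,
            con,
            bool(params.global_construction),
            float(t_max),
            float(sample_dt),
            int(seed) & 0x7FFFFFFF,
            row_idx,
            int(snapshot_stride),
            bool(track_extent),
            int(ci),
            int(cj),
        )
    )
    n_samples = len(times)
    snapshots = None
    snapshot_times = None
    if snapshot_stride > 0:
        snapshots = snaps.reshape(-1, L, L)
        snapshot_times = times[::snapshot_stride]
    return Trajectory(
        times=times,
        p_minus=fracs[:, 0],
        p_vac=fracs[:, 1],
        p_nc=fracs[:, 2],
        p_ex=fracs[:, 3],
        absorbed=bool(absorbed),
        absorbed_at=float(absorbed_at),
        seed=int(seed),
        params=params,
        event_counts=dict(zip(_EVENT_NAMES, (int(x) for x in counts))),
        occupied_site_time=float(occ_time),
        final_grid=LandscapeGrid(state.reshape(L, L)) if keep_final_grid else None,
        extent=extent[:n_samples] if track_extent else None,
        transect=rows if record_row is not None else None,
        snapshots=snapshots,
        snapshot_times=snapshot_times,
    )


# ---------------------------------------------------------------------------
# single-event stepper (reference implementation)
# ---------------------------------------------------------------------------

class Simulation:
    """Event-by-event simulator for small lattices.

    Implements the same source-centric exact scheme as the compiled kernel
    but one event at a time, which makes it convenient for inspection and
    for oracle comparisons.  Not meant for large lattices or long horizons.
    """

    def __init__(self, params: ModelParams, grid: LandscapeGrid, seed: int = 0):
        self.params = params
        self.grid = grid.copy()
        self.rng = np.random.default_rng(seed)
        self.t = 0.0
        self.absorbed = False
        self.event_counts = {name: 0 for name in _EVENT_NAMES}
        self._col = neighborhood_offsets(params.r_col).offsets
        self._con = neighborhood_offsets(params.construction_range).offsets

    def _sites_in(self, state: CellState) -> np.ndarray:
        return np.argwhere(self.grid.states == int(state))

    @property
    def counts(self) -> dict[CellState, int]:
        return self.grid.counts()

    def total_rate_bound(self) -> float:
        p = self.params
        cts = self.counts
        return (
            cts[CellState.NC] * (p.delta + p.e + p.beta + p.c)
            + cts[CellState.EXPLOITER] * (p.delta + p.e + 1.0)
            + cts[CellState.VACANT] * p.e
        )

    def step(self) -> bool:
        """Apply one event (possibly null).  Returns False when frozen.

        A frozen configuration (total clock rate zero -- no occupied site
        and, if ``e = 0``, nothing left to destroy) is a no-op that sets the
        ``absorbed`` flag.
        """
        p = self.params
        g = self.grid.states
        L = self.grid.size
        B = self.total_rate_bound()
        occupied = (g == 1).sum() + (g == 2).sum()
        if occupied == 0:
            self.absorbed = True
        if B <= 0.0:
            return False
        self.t += self.rng.exponential(1.0 / B)

        nc = np.argwhere(g == 1)
        ex = np.argwhere(g == 2)
        vac = np.argwhere(g == 0)
        R_nc = p.delta + p.e + p.beta + p.c
        R_ex = p.delta + p.e + 1.0
        u = self.rng.random() * B
        if u < len(nc) * R_nc:
            i, j = nc[self.rng.integers(len(nc))]
            v = self.rng.random() * R_nc
            if v < p.delta:
                g[i, j] = 0
                self.event_counts["death_nc"] += 1
            elif v < p.delta + p.e:
                g[i, j] = -1
                self.event_counts["destruction_occupied"] += 1
            elif v < p.delta + p.e + p.beta:
                di, dj = self._col[self.rng.integers(len(self._col))]
                ti, tj = (i + di) % L, (j + dj) % L
                if g[ti, tj] == 0:
                    g[ti, tj] = 1
                    self.event_counts["colonization_nc"] += 1
                else:
                    self.event_counts["null_attempt"] += 1
            else:
                if p.global_construction:
                    ti, tj = self.rng.integers(L), self.rng.integers(L)
                else:
                    di, dj = self._con[self.rng.integers(len(self._con))]
                    ti, tj = (i + di) % L, (j + dj) % L
                if g[ti, tj] == -1:
                    g[ti, tj] = 0
                    self.event_counts["construction"] += 1
                else:
                    self.event_counts["null_attempt"] += 1
        elif u < len(nc) * R_nc + len(ex) * R_ex:
            i, j = ex[self.rng.integers(len(ex))]
            v = self.rng.random() * R_ex
            if v < p.delta:
                g[i, j] = 0
                self.event_counts["death_ex"] += 1
            elif v < p.delta + p.e:
                g[i, j] = -1
                self.event_counts["destruction_occupied"] += 1
            else:
                di, dj = self._col[self.rng.integers(len(self._col))]
                ti, tj = (i + di) % L, (j + dj) % L
                if g[ti, tj] == 0:
                    g[ti, tj] = 2
                    self.event_counts["colonization_ex"] += 1
                else:
                    self.event_counts["null_attempt"] += 1
        else:
            i, j = vac[self.rng.integers(len(vac))]
            g[i, j] = -1
            self.event_counts["destruction_vacant"] += 1
        return True

    def run_until(self, t_stop: float, max_events: int | None = None) -> None:
        n = 0
        while self.t < t_stop:
            if not self.step():
                break
            n += 1
            if max_events is not None and n >= max_events:
                break
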