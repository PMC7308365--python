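"""Experiment harness: phase diagrams, critical transitions, range expansion
and competition-regime classification.

Each experiment runs the lattice model under a :class:`Protocol` (lattice
size, transient, averaging window, replicates) and reduces the trajectories
to the quantity of interest.  Defaults follow the reference protocol
(L = 256, 5000 time units of transient, 250 of averaging); the desk-scale
defaults used by sweeps are smaller and stated explicitly where they apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from enum import Enum
from pathlib import Path

import numpy as np

from .dynamics import ModelParams, Trajectory, init_full, init_single_seed, run, spawn_seeds
from .lattice import LandscapeGrid

__all__ = [
    "Protocol",
    "PhaseDiagram",
    "CriticalFit",
    "ExpansionResult",
    "RegimeLabel",
    "sweep_phase_diagram",
    "estimate_critical_point",
    "refine_critical_point_by_survival",
    "fit_order_parameter_exponent",
    "relaxation_profile",
    "range_expansion",
    "classify_regime",
    "transect",
]


@dataclass(frozen=True)
class Protocol:
    """Measurement protocol shared by the experiments.

    ``t_transient`` is discarded before averaging ``<p+>`` over the next
    ``t_avg`` units, sampling every ``sample_dt``.  ``t_max`` bounds
    survival-style runs.  Reference values are L=256, t_transient=5000,
    t_avg=250.
    """

    L: int = 256
    t_transient: float = 5000.0
    t_avg: float = 250.0
    t_max: float = 2000.0
    sample_dt: float = 1.0
    replicates: int = 1
    seed: int = 0


# ---------------------------------------------------------------------------
# phase diagrams
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """Long-term mean occupancy over a {c, e} parameter grid.

    ``mean_occupancy[i, j]`` is ``<p+>`` at ``e_values[i]``,
    ``c_values[j]`` (NC occupancy; absorbed runs report 0).  With
    competition enabled ``mean_occupancy_ex`` holds ``<p++>`` and
    ``relative_occupancy`` is ``<p+> / (<p+> + <p++>)``, NaN where both
    vanish.
    """

    c_values: np.ndarray
    e_values: np.ndarray
    mean_occupancy: np.ndarray
    mean_occupancy_ex: np.ndarray | None = None
    params: ModelParams | None = None
    protocol: Protocol | None = None

    @property
    def relative_occupancy(self) -> np.ndarray | None:
        if self.mean_occupancy_ex is None:
            return None
        tot = self.mean_occupancy + self.mean_occupancy_ex
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(tot > 0, self.mean_occupancy / np.where(tot > 0, tot, 1.0), np.nan)
        return rel

    def to_csv(self, path: str | Path) -> None:
        """Matrix CSV with c values as header row and e values as first column."""
        header = "e\\c," + ",".join(f"{c:.6g}" for c in self.c_values)
        body = np.column_stack([self.e_values, self.mean_occupancy])
        np.savetxt(path, body, delimiter=",", header=header, comments="", fmt="%.6g")


def sweep_phase_diagram(
    c_grid: np.ndarray,
    e_grid: np.ndarray,
    base_params: ModelParams,
    protocol: Protocol,
) -> PhaseDiagram:
    """Mean long-term occupancy over the {c, e} grid from full occupancy.

    One run per grid cell per replicate, each from a fully occupied lattice;
    ``<p+>`` is the time average over ``[t_transient, t_transient + t_avg]``
    (absorbed runs contribute 0).  Deterministic for a fixed protocol seed.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    e_grid = np.asarray(e_grid, dtype=float)
    if c_grid.size == 0 or e_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    occ = np.zeros((len(e_grid), len(c_grid)))
    occ_ex = np.zeros_like(occ) if base_params.competition else None
    t_end = protocol.t_transient + protocol.t_avg
    seeds = spawn_seeds(protocol.seed, occ.size * protocol.replicates)
    k = 0
    for i, e in enumerate(e_grid):
        for j, c in enumerate(c_grid):
            params = _dc_replace(base_params, e=float(e), c=float(c))
            if base_params.competition:
                acc = acc_ex = 0.0
                for _ in range(protocol.replicates):
                    init = init_full(protocol.L, mode="mixed", fraction=0.5, seed=seeds[k])
                    tr = run(params, init, t_end, protocol.sample_dt, seeds[k])
                    sel = tr.times >= protocol.t_transient
                    acc += float(tr.p_nc[sel].mean())
                    acc_ex += float(tr.p_ex[sel].mean())
                    k += 1
                occ[i, j] = acc / protocol.replicates
                occ_ex[i, j] = acc_ex / protocol.replicates
            else:
                acc = 0.0
                for _ in range(protocol.replicates):
                    tr = run(params, init_full(protocol.L), t_end, protocol.sample_dt, seeds[k])
                    acc += tr.mean_occupancy(protocol.t_transient)
                    k += 1
                occ[i, j] = acc / protocol.replicates
    return PhaseDiagram(
        c_values=c_grid,
        e_values=e_grid,
        mean_occupancy=occ,
        mean_occupancy_ex=occ_ex,
        params=base_params,
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# critical points and exponents
# ---------------------------------------------------------------------------

@dataclass
class CriticalFit:
    """Critical-point estimate and/or power-law fit for a control parameter.

    ``k_name`` is the swept rate (``"delta"`` or ``"e"``); ``k_crit`` the
    estimated critical value.  After an order-parameter fit, ``exponent``
    holds the slope of ``log <p+>`` vs ``log |k - k_crit|``, ``stderr`` its
    standard error and ``fit_window`` the (min, max) distance-to-criticality
    used.
    """

    k_name: str
    k_crit: float
    bracket: tuple[float, float] | None = None
    exponent: float | None = None
    stderr: float | None = None
    fit_window: tuple[float, float] | None = None
    n_points: int | None = None


def _survival_probability(
    params: ModelParams, L: int, t_max: float, replicates: int, seed: int
) -> float:
    alive = 0
    for s in spawn_seeds(seed, replicates):
        tr = run(params, init_full(L), t_max, sample_dt=max(t_max / 4, 1.0), seed=s)
        alive += 0 if tr.absorbed else 1
    return alive / replicates


def estimate_critical_point(
    control: str,
    fixed_params: ModelParams,
    bracket: tuple[float, float],
    protocol: Protocol,
    tol: float = 0.01,
) -> CriticalFit:
    """Locate the extinction threshold by survival-probability bisection.

    A parameter value is called surviving when at least half of
    ``protocol.replicates`` runs from full occupancy still hold occupied
    sites at ``protocol.t_max``.  ``bracket`` must be (surviving value,
    extinct value); bisection narrows it to width ``tol`` and the midpoint
    is reported.
    """
    if control not in ("delta", "e"):
        raise ValueError(f"control must be 'delta' or 'e', got {control!r}")
    lo, hi = bracket

    def survives(k: float, probe_seed: int) -> bool:
        params = _dc_replace(fixed_params, **{control: float(k)})
        p = _survival_probability(
            params, protocol.L, protocol.t_max, protocol.replicates, probe_seed
        )
        return p >= 0.5

    seeds = spawn_seeds(protocol.seed, 64)
    if not survives(lo, seeds[0]):
        raise ValueError(f"bracket bottom {control}={lo} is not surviving")
    if survives(hi, seeds[1]):
        raise ValueError(f"bracket top {control}={hi} is not extinct")
    i = 2
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if survives(mid, seeds[i]):
            lo = mid
        else:
            hi = mid
        i += 1
    return CriticalFit(k_name=control, k_crit=0.5 * (lo + hi), bracket=(lo, hi))


def refine_critical_point_by_survival(
    params: ModelParams,
    control: str,
    candidates: np.ndarray,
    protocol: Protocol,
) -> CriticalFit:
    """Refine a critical-point estimate on a fine grid by long-horizon survival.

    Each candidate value is run ``protocol.replicates`` times from full
    occupancy to ``protocol.t_max`` and its replicate survival fraction
    recorded.  At a horizon comparable to the lattice relaxation scale
    (t ~ L^z, e.g. ~5000 for L = 128) the survival probability collapses
    from near 1 to near 0 across a parameter window of order one grid step,
    so the 50% crossing of the survival curve localizes the critical point;
    it is read off by linear interpolation between the last candidate with
    majority survival and the following one, which removes the
    discretization of the grid.  The horizon must exceed the relaxation
    (crossover) time of the candidate spacing,
    Delta_step^(-nu_parallel), else a just-supercritical candidate outlives
    the run and the crossing lands high.  Replicate survival counts are
    binomial, making this far more stable than comparing decay-curve shapes
    between adjacent candidates.
    """
    if control not in ("delta", "e"):
        raise ValueError(f"control must be 'delta' or 'e', got {control!r}")
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if candidates.size < 2:
        raise ValueError("need at least two candidate values")
    seeds = spawn_seeds(protocol.seed, candidates.size * protocol.replicates)
    fractions = np.empty(candidates.size)
    for i, k in enumerate(candidates):
        p = _dc_replace(params, **{control: float(k)})
        alive = 0
        for j in range(protocol.replicates):
            tr = run(p, init_full(protocol.L), protocol.t_max,
                     max(protocol.t_max / 4, protocol.sample_dt),
                     seeds[i * protocol.replicates + j])
            alive += 0 if tr.absorbed else 1
        fractions[i] = alive / protocol.replicates
    majority = np.nonzero(fractions >= 0.5)[0]
    if majority.size == 0:
        raise ValueError("no candidate had majority survival; widen the grid downward")
    a = int(majority[-1])
    if a == candidates.size - 1:
        k_crit = float(candidates[-1])  # crossing above the grid top
    else:
        s_a, s_b = fractions[a], fractions[a + 1]
        k_crit = float(
            candidates[a]
            + (s_a - 0.5) / (s_a - s_b) * (candidates[a + 1] - candidates[a])
        )
    return CriticalFit(
        k_name=control, k_crit=k_crit,
        bracket=(float(candidates.min()), float(candidates.max())),
    )


def fit_order_parameter_exponent(
    k_samples: np.ndarray,
    occupancies: np.ndarray,
    k_crit: float,
    k_name: str = "delta",
) -> CriticalFit:
    """Power-law fit of the order parameter below the critical point.

    Least-squares slope of ``log <p+>`` versus ``log |k - k_crit|`` over the
    supplied subcritical samples.  All ``k_samples`` must be strictly below
    ``k_crit`` with positive occupancy; fewer than 3 usable points is an
    error.
    """
    from scipy import stats

    k_samples = np.asarray(k_samples, dtype=float)
    occupancies = np.asarray(occupancies, dtype=float)
    if np.any(k_samples >= k_crit):
        raise ValueError("all control-parameter samples must lie below k_crit")
    good = occupancies > 0
    if good.sum() < 3:
        raise ValueError("need at least 3 points with positive occupancy")
    dk = k_crit - k_samples[good]
    res = stats.linregress(np.log(dk), np.log(occupancies[good]))
    return CriticalFit(
        k_name=k_name,
        k_crit=k_crit,
        exponent=float(res.slope),
        stderr=float(res.stderr),
        fit_window=(float(dk.min()), float(dk.max())),
        n_points=int(good.sum()),
    )


def relaxation_profile(
    params: ModelParams,
    control: str,
    k_values: dict[str, float],
    protocol: Protocol,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mean occupancy decay curves at sub-, near- and super-critical values.

    ``k_values`` maps labels (e.g. ``"subcritical"``, ``"critical"``,
    ``"supercritical"``) to control-parameter values; each is run
    ``protocol.replicates`` times from full occupancy and the
    replicate-mean ``p+(t)`` curve returned per label.  At criticality the
    decay is a power law (linear on log-log axes); supercritical decay is
    exponential; subcritical curves plateau at the quasi-stationary
    occupancy -- the diverging relaxation time at the critical point is the
    signature of a continuous transition.
    """
    if control not in ("delta", "e"):
        raise ValueError(f"control must be 'delta' or 'e', got {control!r}")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label, k in k_values.items():
        p = _dc_replace(params, **{control: float(k)})
        acc = None
        seeds = spawn_seeds(protocol.seed + hash(label) % 10_000, protocol.replicates)
        for s in seeds:
            tr = run(p, init_full(protocol.L), protocol.t_max, protocol.sample_dt, s)
            acc = tr.p_occupied if acc is None else acc + tr.p_occupied
        out[label] = (tr.times, acc / protocol.replicates)
    return out


# ---------------------------------------------------------------------------
# range expansion
# ---------------------------------------------------------------------------

@dataclass
class ExpansionResult:
    """Range expansion from a single founder on a destroyed landscape.

    ``occupied_fraction(t)`` and ``mosaic_extent(t)`` (max Chebyshev radius
    of occupied sites around the founder) trace the expanding mosaic;
    ``t_saturation`` is the first time the occupancy enters the band
    ``>= saturation_band * plateau`` where the plateau is the mean occupancy
    over the final fifth of the run.  NaN if the founder lineage died or
    never saturated.
    """

    r: int
    times: np.ndarray
    occupied_fraction: np.ndarray
    mosaic_extent: np.ndarray
    t_saturation: float
    survived: bool


def _saturation_time(times: np.ndarray, occ: np.ndarray, band: float) -> float:
    tail = occ[int(0.8 * len(occ)):]
    plateau = float(tail.mean())
    if plateau <= 0:
        return float("nan")
    idx = np.nonzero(occ >= band * plateau)[0]
    return float(times[idx[0]]) if len(idx) else float("nan")


def range_expansion(
    params: ModelParams,
    r_list: list[int],
    protocol: Protocol,
    saturation_band: float = 0.9,
    establishment_retries: int = 0,
    background=None,
) -> dict[int, ExpansionResult]:
    """Expansion curves for a set of construction ranges ``r``.

    Each ``r`` runs from :func:`init_single_seed` with a seed derived from
    the protocol seed; wider construction neighborhoods renew the vacuum
    farther ahead of the front and saturate sooner, while the final
    occupancy is r-independent well below ``e_crit``.  The default
    background is vacant habitat: the far field then erodes into the
    destroyed vacuum at rate ``e`` while the founder expands its mosaic.
    A lone founder still dies before establishing with appreciable
    probability; with ``establishment_retries > 0`` an extinct run is
    re-drawn (fresh derived seed) up to that many times, conditioning the
    measurement on establishment.
    """
    from .lattice import CellState

    if background is None:
        background = CellState.VACANT
    out: dict[int, ExpansionResult] = {}
    seed_table = spawn_seeds(protocol.seed, len(r_list) * (establishment_retries + 1))
    for idx, r in enumerate(r_list):
        p = _dc_replace(params, r_con=int(r))
        for attempt in range(establishment_retries + 1):
            s = seed_table[idx * (establishment_retries + 1) + attempt]
            tr = run(
                p,
                init_single_seed(protocol.L, background=background),
                protocol.t_max,
                protocol.sample_dt,
                s,
                track_extent=True,
            )
            if not tr.absorbed:
                break
        occ = tr.p_occupied
        out[r] = ExpansionResult(
            r=int(r),
            times=tr.times,
            occupied_fraction=occ,
            mosaic_extent=tr.extent,
            t_saturation=_saturation_time(tr.times, occ, saturation_band),
            survived=not tr.absorbed,
        )
    return out


# ---------------------------------------------------------------------------
# competition regimes
# ---------------------------------------------------------------------------

class RegimeLabel(str, Enum):
    """Long-term outcome of a constructor-exploiter competition run."""

    NC_MONOPOLY = "NC_monopoly"
    COEXISTENCE = "coexistence"
    ECOLOGICAL_SUICIDE = "ecological_suicide"
    COMPETITIVE_EXCLUSION = "competitive_exclusion"
    TRIVIAL_EXTINCTION = "trivial_extinction"
    AMBIGUOUS = "ambiguous"


def classify_regime(
    trajectory: Trajectory,
    window: float = 250.0,
    theta: float = 0.01,
) -> RegimeLabel:
    """Label the outcome of a completed competition run.

    * ``NC_monopoly`` -- the exploiter died out and NC holds a positive
      plateau (the high-disturbance regime: short patch lifetimes fragment
      the exploiter while NC monopolizes its constructed niche).
    * ``coexistence`` -- both strategies average above ``theta`` over the
      final ``window`` time units (intermediate disturbance).
    * ``ecological_suicide`` -- NC went extinct first while the exploiter
      was still present, after which the exploiter (and the niche) collapsed
      with the landscape converging to all-destroyed (low disturbance).
    * ``competitive_exclusion`` -- with ``e = 0`` the exploiter's higher R0
      excludes NC and then persists.
    * ``trivial_extinction`` -- both strategies died under ``e > 0`` without
      the exploiter ever outliving NC (the landscape itself was lethal).
    * ``ambiguous`` -- none of the above at ``t_max`` (still transient).
    """
    t = trajectory.times
    nc, ex = trajectory.p_nc, trajectory.p_ex
    e = trajectory.params.e
    sel = t >= t[-1] - window
    nc_end, ex_end = float(nc[sel].mean()), float(ex[sel].mean())
    nc_zero = np.nonzero(nc == 0)[0]
    ex_zero = np.nonzero(ex == 0)[0]
    t_nc_ext = t[nc_zero[0]] if len(nc_zero) else None
    t_ex_ext = t[ex_zero[0]] if len(ex_zero) else None

    if t_nc_ext is None and t_ex_ext is None:
        if nc_end > theta and ex_end > theta:
            return RegimeLabel.COEXISTENCE
        return RegimeLabel.AMBIGUOUS
    if t_ex_ext is not None and t_nc_ext is None:
        return RegimeLabel.NC_MONOPOLY if nc_end > theta else RegimeLabel.AMBIGUOUS
    if t_nc_ext is not None and t_ex_ext is None:
        if e == 0 and ex_end > theta:
            return RegimeLabel.COMPETITIVE_EXCLUSION
        return RegimeLabel.AMBIGUOUS  # exploiter lingering after NC died
    # both went extinct
    ex_alive_at_nc_death = ex[nc_zero[0]] > 0
    if e > 0 and t_nc_ext < t_ex_ext and ex_alive_at_nc_death:
        return RegimeLabel.ECOLOGICAL_SUICIDE
    if e > 0:
        return RegimeLabel.TRIVIAL_EXTINCTION
    return RegimeLabel.AMBIGUOUS


# ---------------------------------------------------------------------------
# transects
# ---------------------------------------------------------------------------

def transect(snapshots: np.ndarray, row: int) -> np.ndarray:
    """1D space-time matrix: one lattice row extracted from stored snapshots.

    ``snapshots`` has shape (n_times, L, L); the result is (n_times, L) of
    integer state codes.
    """
    snapshots = np.asarray(snapshots)
    if snapshots.ndim != 3:
        raise ValueError("snapshots must be a (n_times, L, L) array")
    if not 0 <= row < snapshots.shape[1]:
        raise ValueError(f"row {row} out of range for L={snapshots.shape[1]}")
    return snapshots[:, row, :]
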