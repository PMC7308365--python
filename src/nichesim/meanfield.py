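"""Mean-field theory of the niche-construction metapopulation.

The well-mixed reduction tracks the destroyed fraction ``p_minus`` and the
occupied fraction ``p_plus`` (vacant is ``1 - p_plus - p_minus``):

.. math::

    \\dot p_- &= e (1 - p_-) - c\\, p_+ p_- \\\\
    \\dot p_+ &= (1-c)^{\\alpha} p_+ (1 - p_+ - p_-) - p_+ (\\delta + e)

With ``e = c = 0`` this collapses to the Levins equation
``dp/dt = p(1-p) - delta p`` with equilibrium ``1 - 1/R0`` (``R0 = 1/delta``)
and mean-field extinction threshold ``delta_c = 1``.  For ``e > 0`` the
interior equilibria solve a quadratic in ``p_+``; they vanish in a
saddle-node at a finite occupancy, so the mean-field extinction transition
at ``e_crit(c)`` is discontinuous.  Derived quantities at an interior
equilibrium: construction effort ``Lambda = c * p_+``, long-term suitable
habitat ``s_bar = Lambda / (Lambda + e)`` and the consistency identity
``p_+ = s_bar - (delta + e) / (1-c)**alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .params import ModelParams

__all__ = [
    "MFState",
    "MFEquilibrium",
    "mf_rhs",
    "mf_equilibria",
    "mf_ecrit",
    "mf_cstar",
    "mf_integrate",
    "levins_threshold",
]

_STAB_TOL = 1e-10


@dataclass(frozen=True)
class MFState:
    """Point of the mean-field phase plane (destroyed, occupied) fractions."""

    p_minus: float
    p_plus: float

    @property
    def p_vacant(self) -> float:
        return 1.0 - self.p_minus - self.p_plus

    def in_simplex(self, tol: float = 1e-9) -> bool:
        return (
            self.p_minus >= -tol
            and self.p_plus >= -tol
            and self.p_minus + self.p_plus <= 1.0 + tol
        )


@dataclass(frozen=True)
class MFEquilibrium:
    """A fixed point of the mean-field system with its stability.

    ``kind`` is ``"absorbing"`` (extinct population) or ``"interior"``
    (positive occupancy).  For interior equilibria the derived life-history
    quantities of the constructed niche are exposed: ``construction_effort``
    (Lambda), ``suitable_habitat`` (s_bar), ``delta_tilde`` and ``r0``.
    """

    state: MFState
    stable: bool
    kind: str
    marginal: bool = False
    params: ModelParams | None = None

    @property
    def construction_effort(self) -> float:
        """Lambda = c * p_plus, the metapopulation's total construction rate."""
        return self.params.c * self.state.p_plus if self.params else float("nan")

    @property
    def suitable_habitat(self) -> float:
        """s_bar = Lambda / (Lambda + e) = 1 - p_minus at equilibrium."""
        if self.params is None:
            return float("nan")
        lam = self.construction_effort
        if lam + self.params.e == 0:
            return 1.0 - self.state.p_minus
        return lam / (lam + self.params.e)

    @property
    def delta_tilde(self) -> float:
        return self.params.delta + self.params.e if self.params else float("nan")

    @property
    def r0(self) -> float:
        """Basic reproductive number 1/delta."""
        if self.params is None or self.params.delta == 0:
            return float("inf")
        return 1.0 / self.params.delta

    @property
    def patch_lifetime(self) -> float:
        """tau = 1/e."""
        if self.params is None or self.params.e == 0:
            return float("inf")
        return 1.0 / self.params.e


def levins_threshold() -> float:
    """Largest extinction rate with a positive Levins equilibrium.

    ``p_hat = 1 - delta`` is positive iff ``delta < 1``; the mean-field
    contact-process threshold is exactly ``delta_c = 1`` (``R0 = 1``).
    """
    return 1.0


def mf_rhs(state: MFState | tuple[float, float], params: ModelParams) -> tuple[float, float]:
    """Time derivatives ``(dp_minus/dt, dp_plus/dt)`` of the mean field."""
    if isinstance(state, MFState):
        pm, pp = state.p_minus, state.p_plus
    else:
        pm, pp = state
    beta = params.beta
    dpm = params.e * (1.0 - pm) - params.c * pp * pm
    dpp = beta * pp * (1.0 - pp - pm) - pp * (params.delta + params.e)
    return dpm, dpp


def _jacobian(pm: float, pp: float, params: ModelParams) -> np.ndarray:
    beta = params.beta
    return np.array(
        [
            [-params.e - params.c * pp, -params.c * pm],
            [-beta * pp, beta * (1.0 - 2.0 * pp - pm) - (params.delta + params.e)],
        ]
    )


def _stability(pm: float, pp: float, params: ModelParams) -> tuple[bool, bool]:
    """(stable, marginal) from the real parts of the Jacobian eigenvalues."""
    eig = np.linalg.eigvals(_jacobian(pm, pp, params))
    re = np.real(eig)
    marginal = bool(np.any(np.abs(re) <= _STAB_TOL))
    return bool(np.all(re < _STAB_TOL)), marginal


def _interior_pplus_roots(params: ModelParams) -> list[float]:
    """Real roots of the interior fixed-point condition for p_plus.

    Eliminating ``p_minus = e / (e + c p_+)`` gives the quadratic
    ``c p^2 + (e - c A) p + e dtil / beta = 0`` with ``A = 1 - dtil/beta``,
    ``dtil = delta + e``.  Special cases (``c = 0`` or ``e = 0``) reduce to
    the Levins-type linear solution ``p = 1 - dtil/beta`` (with ``p_- = 0``
    when ``e = 0``; no interior solution when ``c = 0 < e``).
    """
    beta = params.beta
    if beta <= 0.0:
        return []
    dtil = params.delta + params.e
    if params.e == 0.0 or params.c == 0.0:
        if params.c == 0.0 and params.e > 0.0:
            return []  # no construction: any destruction erodes all habitat
        return [1.0 - dtil / beta]
    A = 1.0 - dtil / beta
    a, b, cc = params.c, params.e - params.c * A, params.e * dtil / beta
    disc = b * b - 4.0 * a * cc
    if disc < 0.0:
        return []
    sq = float(np.sqrt(disc))
    return [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]


def mf_equilibria(params: ModelParams) -> list[MFEquilibrium]:
    """All mean-field fixed points in the simplex, with stability labels.

    The absorbing equilibrium (``p_+ = 0``; all-destroyed when ``e > 0``)
    always exists.  Interior equilibria come in pairs from the saddle-node
    structure; when two exist the upper branch is the stable one.  Both are
    returned -- the bistability between persistence and collapse is a
    defining feature of the mean field.
    """
    out: list[MFEquilibrium] = []
    pm_abs = 1.0 if params.e > 0 else 0.0
    st, mg = _stability(pm_abs, 0.0, params)
    out.append(
        MFEquilibrium(MFState(pm_abs, 0.0), stable=st, kind="absorbing", marginal=mg, params=params)
    )
    tol = 1e-12
    for pp in sorted(_interior_pplus_roots(params)):
        if pp <= tol or pp > 1.0 + tol:
            continue
        if params.e == 0.0 or params.c == 0.0:
            pm = 0.0 if params.e == 0.0 else 1.0
        else:
            pm = params.e / (params.e + params.c * pp)
        state = MFState(pm, min(pp, 1.0))
        if not state.in_simplex():
            continue
        st, mg = _stability(state.p_minus, state.p_plus, params)
        out.append(
            MFEquilibrium(state, stable=st, kind="interior", marginal=mg, params=params)
        )
    return out


def _has_interior(params: ModelParams) -> bool:
    """Existence of an interior fixed point (no stability computation)."""
    tol = 1e-12
    for pp in _interior_pplus_roots(params):
        if pp <= tol or pp > 1.0 + tol:
            continue
        if params.e == 0.0 or params.c == 0.0:
            pm = 0.0
        else:
            pm = params.e / (params.e + params.c * pp)
        if MFState(pm, min(pp, 1.0)).in_simplex():
            return True
    return False


def mf_ecrit(c: float, delta: float, alpha: float, tol: float = 1e-8) -> float:
    """Critical destruction rate of the mean field at allocation ``c``.

    The largest ``e`` for which an interior equilibrium exists; above it the
    stable branch disappears in a saddle-node and the occupancy jumps
    discontinuously to extinction.  Found by bisection on the existence of
    interior roots.  Returns 0 when no destruction is survivable
    (e.g. ``delta >= (1-c)**alpha``).
    """
    if not 0.0 < c < 1.0:
        raise ValueError(f"c must lie in (0, 1), got {c}")
    beta = (1.0 - c) ** alpha
    if delta >= beta:
        return 0.0
    # interior roots require delta + e < beta; beta - delta bounds the bracket
    lo, hi = 0.0, beta - delta
    if not _has_interior(ModelParams(delta=delta, e=lo + tol, c=c, alpha=alpha)):
        return 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _has_interior(ModelParams(delta=delta, e=mid, c=c, alpha=alpha)):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mf_cstar(
    delta: float, alpha: float, tol: float = 1e-4, grid_points: int = 201
) -> float:
    """Optimal construction allocation ``c**``: the argmax of ``e_crit(c)``.

    The vertex of the extinction-threshold curve -- the strategy persisting
    in the broadest range of landscapes.  A coarse grid scan brackets the
    maximum, then bounded golden-section refinement reaches ``tol``.
    """
    if delta >= 1.0:
        raise ValueError("delta must be < 1 for any strategy to persist")
    cs = np.linspace(0.0, 1.0, grid_points)[1:-1]
    vals = np.array([mf_ecrit(ci, delta, alpha, tol=1e-10) for ci in cs])
    if np.all(vals <= 0.0):
        raise ValueError("e_crit vanishes identically; no optimal strategy")
    k = int(np.argmax(vals))
    lo = cs[max(k - 1, 0)]
    hi = cs[min(k + 1, len(cs) - 1)]
    res = minimize_scalar(
        lambda ci: -mf_ecrit(float(ci), delta, alpha, tol=1e-10),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def mf_integrate(
    params: ModelParams,
    init: MFState | tuple[float, float],
    t_max: float,
    n_samples: int = 500,
    rtol: float = 1e-9,
):
    """Integrate the mean-field ODEs from ``init`` over ``[0, t_max]``.

    Uses an adaptive stiff-capable scheme (LSODA) at tight tolerance --
    trajectories become very slow near the saddle-node.  Returns
    ``(times, p_minus, p_plus)`` arrays; the trajectory remains in the
    simplex.
    """
    if isinstance(init, MFState):
        y0 = [init.p_minus, init.p_plus]
    else:
        y0 = list(init)
    if not MFState(*y0).in_simplex():
        raise ValueError(f"initial state {y0} outside the simplex")

    def rhs(_t, y):
        return mf_rhs((y[0], y[1]), params)

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
        t_eval=np.linspace(0.0, t_max, n_samples),
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]
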