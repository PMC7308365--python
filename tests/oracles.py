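"""Independent oracles used by the test suite.

These implement the model's definitions by brute force -- exhaustive flood
fill for clusters and the exact master equation of the reaction scheme on a
tiny lattice -- without using the package's simulation code paths, so they
can serve as ground truth for the fast implementations.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

# state digits used by the master equation: 0 destroyed, 1 vacant, 2 NC
DES, VAC, NC = 0, 1, 2


def flood_fill_clusters(mask: np.ndarray) -> list[int]:
    """Connected-component sizes of True cells under toroidal 4-connectivity.

    Plain breadth-first flood fill; quadratic and tiny-grid only.
    """
    L0, L1 = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    for i0 in range(L0):
        for j0 in range(L1):
            if not mask[i0, j0] or seen[i0, j0]:
                continue
            stack = [(i0, j0)]
            seen[i0, j0] = True
            size = 0
            while stack:
                i, j = stack.pop()
                size += 1
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = (i + di) % L0, (j + dj) % L1
                    if mask[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        stack.append((ni, nj))
            sizes.append(size)
    return sorted(sizes, reverse=True)


def _neighbors(site: int, L: int) -> list[int]:
    i, j = divmod(site, L)
    return [
        ((i + 1) % L) * L + j,
        ((i - 1) % L) * L + j,
        i * L + (j + 1) % L,
        i * L + (j - 1) % L,
    ]


def master_equation_generator(
    L: int, delta: float, e: float, c: float, alpha: float
) -> sp.csr_matrix:
    """Exact CTMC generator of the single-strategy model on an L x L torus.

    States are base-3 encodings of the lattice (digit 0 destroyed, 1 vacant,
    2 NC); colonization and construction both use the nearest-neighbor
    (r = 1) ball of size 4.  Entry (s, s') is the rate of the one-site
    transition s -> s'; the diagonal carries minus the exit rates.  Only
    feasible for tiny L (3**(L*L) states).
    """
    n_sites = L * L
    n_states = 3**n_sites
    beta = (1.0 - c) ** alpha
    pow3 = 3 ** np.arange(n_sites)
    rows, cols, vals = [], [], []
    for s in range(n_states):
        digits = (s // pow3) % 3
        for x in range(n_sites):
            d = digits[x]
            n_nc = sum(1 for y in _neighbors(x, L) if digits[y] == NC)
            moves: list[tuple[int, float]] = []
            if d == NC:
                if delta > 0:
                    moves.append((VAC, delta))
                if e > 0:
                    moves.append((DES, e))
            elif d == VAC:
                if e > 0:
                    moves.append((DES, e))
                rate = beta * n_nc / 4.0
                if rate > 0:
                    moves.append((NC, rate))
            else:  # destroyed
                rate = c * n_nc / 4.0
                if rate > 0:
                    moves.append((VAC, rate))
            for new_d, rate in moves:
                s2 = s + (new_d - d) * pow3[x]
                rows.append(s)
                cols.append(int(s2))
                vals.append(rate)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tocsr()
    out = np.asarray(Q.sum(axis=1)).ravel()
    Q = Q - sp.diags(out)
    return Q.tocsr()


def encode_grid(states: np.ndarray) -> int:
    """Encode a grid of CellState codes (-1/0/1) as a base-3 state index."""
    digits = states.ravel() + 1  # -1,0,1 -> 0,1,2
    if np.any((digits < 0) | (digits > 2)):
        raise ValueError("master equation covers single-strategy states only")
    return int(np.dot(digits, 3 ** np.arange(digits.size)))


def exact_moments(
    Q: sp.csr_matrix, s0: int, t: float, L: int
) -> dict[str, float]:
    """Exact E[#destroyed], E[#vacant], E[#NC] and P(no NC) at time t."""
    n_states = Q.shape[0]
    n_sites = L * L
    p0 = np.zeros(n_states)
    p0[s0] = 1.0
    pt = expm_multiply(Q.T.tocsc(), p0, start=0.0, stop=t, num=2)[-1]
    pow3 = 3 ** np.arange(n_sites)
    idx = np.arange(n_states)
    counts = {DES: np.zeros(n_states), VAC: np.zeros(n_states), NC: np.zeros(n_states)}
    for x in range(n_sites):
        dig = (idx // pow3[x]) % 3
        for d in (DES, VAC, NC):
            counts[d] += dig == d
    return {
        "n_destroyed": float(pt @ counts[DES]),
        "n_vacant": float(pt @ counts[VAC]),
        "n_nc": float(pt @ counts[NC]),
        "p_extinct": float(pt[counts[NC] == 0].sum()),
    }
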