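"""Independent oracles used by the test suite.

These deliberately avoid the package's own geometry tables and update kernels:
neighbourhoods are derived from the printed position formula by brute-force
distance checks, the one-step distribution is obtained by exhaustive
enumeration of selection/direction outcomes, and growth is checked against
the closed-form logistic solution.
"""

from __future__ import annotations

import math
from collections import defaultdict

SQRT3 = math.sqrt(3.0)


def hex_position(i: int, j: int, delta: float = 1.0) -> tuple[float, float]:
    """Printed position formula: odd rows shifted right by delta/2."""
    x = (i - 1.0) * delta if j % 2 == 0 else (i - 0.5) * delta
    return x, SQRT3 * (j - 1.0) * delta / 2.0


def neighbour_map(I: int, J: int) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """In-domain neighbours of every site, found by distance == spacing."""
    sites = [(i, j) for j in range(1, J + 1) for i in range(1, I + 1)]
    pos = {s: hex_position(*s) for s in sites}
    out: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for s in sites:
        xs, ys = pos[s]
        out[s] = [
            t
            for t in sites
            if t != s and math.isclose(math.hypot(pos[t][0] - xs, pos[t][1] - ys), 1.0, rel_tol=1e-9)
        ]
    return out


def one_step_distribution(
    initial: frozenset,
    I: int,
    J: int,
    pm: float,
    p: float,
) -> dict[frozenset, float]:
    """Exact distribution over occupancy configurations after one full step.

    ``initial`` is a frozenset of occupied (i, j) sites; every cell has the
    same proliferation probability ``p``, so configurations are exchangeable
    and the occupied-site set is a sufficient state. The step makes N(t)
    motility attempts (cell chosen uniformly; direction uniform over the six
    geometric directions; off-domain or occupied targets abort) followed by
    N(t) proliferation attempts with daughters joining the selection pool.
    """
    nmap = neighbour_map(I, J)
    n0 = len(initial)
    dist: dict[frozenset, float] = {frozenset(initial): 1.0}

    for _ in range(n0):  # motility attempts: population size is constant
        new: dict[frozenset, float] = defaultdict(float)
        for state, pr in dist.items():
            for cell in state:
                base = pr / len(state)
                stay = (1.0 - pm) + pm * (6 - len(nmap[cell])) / 6.0
                for nb in nmap[cell]:
                    if nb in state:
                        stay += pm / 6.0
                    else:
                        new[(state - {cell}) | {nb}] += base * pm / 6.0
                new[state] += base * stay
        dist = dict(new)

    for _ in range(n0):  # proliferation attempts: newborns join the pool
        new = defaultdict(float)
        for state, pr in dist.items():
            for cell in state:
                base = pr / len(state)
                stay = (1.0 - p) + p * (6 - len(nmap[cell])) / 6.0
                for nb in nmap[cell]:
                    if nb in state:
                        stay += p / 6.0
                    else:
                        new[state | {nb}] += base * p / 6.0
                new[state] += base * stay
        dist = dict(new)
    return dist


def logistic_time(c0: float, c1: float, lam: float) -> float:
    """Time for dC/dt = lam*C*(1-C) to go from density c0 to c1 (closed form)."""
    return math.log(c1 * (1.0 - c0) / (c0 * (1.0 - c1))) / lam


def clipped_normal_mean(mu: float, sigma: float) -> float:
    """E[max(X, 0)] for X ~ N(mu, sigma): mu*Phi(mu/sigma) + sigma*phi(mu/sigma)."""
    z = mu / sigma
    phi = math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    Phi = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    return mu * Phi + sigma * phi
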