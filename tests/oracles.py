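"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the bed resistance
oracle assembles the full physical binary tree as a resistor network and
solves it by nodal analysis; the steady-vessel oracle integrates the steady
momentum ODE with an adaptive integrator; the Sobol' oracle is a
pick-freeze Monte-Carlo estimator applied directly to the test function.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from pulmuq.structured_tree import TreeParameters, viscosity_of_radius


def bed_resistance_oracle(params: TreeParameters, viscosity_fn=None) -> float:
    """Effective DC resistance of a two-sided bed by brute-force nodal analysis.

    Enumerates every physical vessel of the binary tree (no index-pair
    memoization), wires artery and mirrored vein segments as Poiseuille
    resistors, and solves the Laplacian with unit pressure across the two
    root ports.
    """
    visc = viscosity_fn or viscosity_of_radius

    def seg_R(r: float, lrr: float) -> float:
        return 8.0 * float(visc(r)) * (r * lrr) / (np.pi * r**4)

    edges: list[tuple[int, int, float]] = []  # (node_a, node_b, conductance)
    counter = [2]  # 0 = arterial root port, 1 = venous root port

    def new_node() -> int:
        counter[0] += 1
        return counter[0] - 1

    def build(i: int, j: int, up_a: int, up_v: int) -> None:
        r = params.alpha**i * params.beta**j * params.root_radius
        if counter[0] > 200000:
            raise RuntimeError("oracle tree too large")
        if r < params.r_min:  # terminal: artery -> crossover -> vein
            mid = new_node()
            edges.append((up_a, mid, 1.0 / seg_R(r, params.lrr_A)))
            edges.append((mid, up_v, 1.0 / seg_R(r, params.lrr_V)))
            return
        down_a = new_node()
        down_v = new_node()
        edges.append((up_a, down_a, 1.0 / seg_R(r, params.lrr_A)))
        edges.append((down_v, up_v, 1.0 / seg_R(r, params.lrr_V)))
        build(i + 1, j, down_a, down_v)
        build(i, j + 1, down_a, down_v)

    build(0, 0, 0, 1)
    n = counter[0]
    G = np.zeros((n, n))
    for a, b, g in edges:
        G[a, a] += g
        G[b, b] += g
        G[a, b] -= g
        G[b, a] -= g
    # Dirichlet: P0 = 1 at the arterial port, P1 = 0 at the venous port
    interior = np.arange(2, n)
    P = np.zeros(n)
    P[0] = 1.0
    rhs = -G[np.ix_(interior, [0])].ravel() * 1.0
    P[interior] = np.linalg.solve(G[np.ix_(interior, interior)], rhs)
    flow_in = float(G[0, 0] * P[0] + G[0, 1:] @ P[1:])
    return 1.0 / flow_in


def steady_vessel_drop_oracle(
    q0: float,
    L: float,
    r0: float,
    K: float,
    p_out: float,
    rho: float = 1.055,
    nu: float = 3.03e-2,
    gamma: float = 9.0,
) -> float:
    """Inlet pressure of a single vessel carrying steady flow q0.

    Integrates the steady momentum balance backward from the outlet:
    dp/dx = -2 pi nu (g+2) q0 / A / (A/rho - fac q0^2 A'(p)/A^2) with the
    elastic wall law A(p) = A0 (1 + p/f)^2, f = 4K/3.
    """
    A0 = np.pi * r0**2
    f = 4.0 * K / 3.0
    fac = (gamma + 2.0) / (gamma + 1.0)

    def rhs(x, p):
        w = 1.0 + p[0] / f
        A = A0 * w**2
        dAdp = 2.0 * A0 * w / f
        num = -2.0 * np.pi * nu * (gamma + 2.0) * q0 / A
        den = A / rho - fac * q0**2 * dAdp / A**2
        return [num / den]

    sol = solve_ivp(rhs, [L, 0.0], [p_out], rtol=1e-10, atol=1e-8, dense_output=True)
    return float(sol.y[0, -1])


def pick_freeze_sobol(
    func, n: int, N: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Saltelli/Jansen pick-freeze estimates of (S_i, S_Ti) on [-1, 1]^n.

    ``func`` maps an (N, n) canonical-cube array to (N,) outputs.
    """
    rng = np.random.default_rng(seed)
    A = rng.uniform(-1, 1, (N, n))
    B = rng.uniform(-1, 1, (N, n))
    fA = func(A)
    fB = func(B)
    var = np.var(np.concatenate([fA, fB]), ddof=1)
    S1 = np.empty(n)
    ST = np.empty(n)
    for i in range(n):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = func(ABi)
        S1[i] = np.mean(fB * (fABi - fA)) / var
        ST[i] = 0.5 * np.mean((fA - fABi) ** 2) / var
    return S1, ST
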