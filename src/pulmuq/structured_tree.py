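"""Two-sided structured-tree microvascular beds and their admittances.

Each terminal proximal artery feeds a self-similar, strictly bifurcating tree
of small vessels: a daughter's radius is its parent's scaled by alpha (major
branch) or beta (minor branch), so every vessel is indexed by the pair
(i, j) of alpha/beta scalings with radius r_ij = alpha^i beta^j r_root.
Branching stops once the radius falls below r_min; every terminal arteriole
crosses over to a mirrored venous tree (same radii node-for-node, venous
lengths via lrr_V instead of lrr_A) that drains to the paired proximal vein.

Small-vessel hemodynamics are linear and periodic, so each vessel is a 2x2
frequency-domain admittance two-port (Womersley oscillatory flow with a
radius-dependent apparent viscosity); the whole bed condenses recursively to
a single "grand" 2x2 admittance between the terminal-artery outlet and the
terminal-vein inlet.  Matrices use the symmetric into-port convention: both
port flows are directed into the network, so Y is symmetric and at omega=0
reduces to a pure resistance, Y = (1/R_total) [[1, -1], [-1, 1]].

Inverse Fourier transform of the grand admittance gives real periodic
kernels y_ij(t) used by the time-domain solver as a convolution boundary
condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "TreeParameters",
    "TreeIndex",
    "SpectralGrid",
    "GrandAdmittance",
    "ResonanceError",
    "TreeSizeError",
    "generate_tree_index",
    "viscosity_of_radius",
    "vessel_admittance",
    "grand_admittance",
]

MU_PLASMA = 0.01  # g/(cm s); calibrated so the large-vessel limit is 3.2*mu_plasma = 0.032


class ResonanceError(ArithmeticError):
    """sin(omega L / c) vanished; the caller perturbs omega and retries."""


class TreeSizeError(ValueError):
    pass


@dataclass(frozen=True)
class TreeParameters:
    """Structured-tree geometry and wall stiffness.

    alpha/beta are the major/minor radius scaling factors; lrr_A / lrr_V the
    length-to-radius ratios of the arterial and venous sides; r_min (cm) the
    termination radius; K_ST (dyn/cm^2) the distal wall stiffness Eh/r0;
    root_radius (cm) the radius of the attached terminal proximal artery.
    """

    alpha: float = 0.86
    beta: float = 0.65
    lrr_A: float = 30.0
    lrr_V: float = 30.0
    r_min: float = 5.5e-3
    K_ST: float = 2.5e5
    root_radius: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.beta <= self.alpha < 1.0):
            raise ValueError(f"need 0 < beta <= alpha < 1, got {self.alpha}, {self.beta}")
        if self.r_min <= 0 or self.r_min >= self.root_radius:
            raise ValueError("need 0 < r_min < root_radius")
        if self.lrr_A <= 0 or self.lrr_V <= 0 or self.K_ST <= 0 or self.root_radius <= 0:
            raise ValueError("tree parameters must be positive")


@dataclass
class TreeIndex:
    """Distinct (i, j) scaling indices of a structured tree.

    Structurally the bed is a huge binary tree, but subtree geometry depends
    only on (i, j), so distinct index pairs suffice (memoization).  A node is
    terminal iff its radius fell below r_min (its parent's radius was still
    >= r_min, otherwise it would never have been spawned).
    """

    params: TreeParameters
    radii: dict[tuple[int, int], float]
    terminal: set[tuple[int, int]]

    @property
    def nodes(self) -> set[tuple[int, int]]:
        return set(self.radii)

    def radius(self, i: int, j: int) -> float:
        return self.radii[(i, j)]

    def length(self, i: int, j: int, side: str) -> float:
        lrr = self.params.lrr_A if side == "arterial" else self.params.lrr_V
        return self.radii[(i, j)] * lrr

    def is_terminal(self, i: int, j: int) -> bool:
        return (i, j) in self.terminal


def generate_tree_index(params: TreeParameters, max_nodes: int = 10**6) -> TreeIndex:
    """Enumerate the distinct (i, j) nodes of the tree defined by ``params``."""
    a, b, r0, rmin = params.alpha, params.beta, params.root_radius, params.r_min
    # conservative projection of the distinct-index count before enumerating
    i_cap = int(math.log(rmin / r0) / math.log(a)) + 2
    j_cap = int(math.log(rmin / r0) / math.log(b)) + 2
    if i_cap * j_cap > max_nodes:
        raise TreeSizeError(
            f"projected node count {i_cap * j_cap} exceeds cap {max_nodes}; "
            "increase r_min"
        )
    radii: dict[tuple[int, int], float] = {(0, 0): r0}
    terminal: set[tuple[int, int]] = set()
    frontier = [(0, 0)]
    while frontier:
        nxt = []
        for (i, j) in frontier:
            if radii[(i, j)] < rmin:
                terminal.add((i, j))
                continue
            for (ci, cj) in ((i + 1, j), (i, j + 1)):
                if (ci, cj) not in radii:
                    radii[(ci, cj)] = a**ci * b**cj * r0
                    nxt.append((ci, cj))
        frontier = nxt
    # root below r_min is excluded by TreeParameters; a node with r >= rmin
    # always has both children, so the closure above is minimal and unique.
    return TreeIndex(params, radii, terminal)


def viscosity_of_radius(r: float | np.ndarray) -> float | np.ndarray:
    """Apparent in-vitro blood viscosity (g/cm/s) of a vessel of radius r (cm).

    Empirical relative-viscosity law in terms of diameter d (um):
    eta_rel(d) = 220 exp(-1.3 d) + 3.2 - 2.44 exp(-0.06 d^0.645),
    scaled by a plasma viscosity calibrated so eta_rel -> 3.2 recovers the
    large-vessel value 0.032 g/(cm s).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    d = 2.0 * r * 1e4  # cm -> um
    eta = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    out = MU_PLASMA * eta
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform frequency grid omega_k = 2 pi k / T, k = 0..n_modes."""

    T: float
    n_modes: int = 512

    def __post_init__(self) -> None:
        if self.T <= 0 or self.n_modes < 1:
            raise ValueError("need T > 0 and n_modes >= 1")

    @property
    def omegas(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_modes + 1) / self.T

    @property
    def n_samples(self) -> int:
        """Time samples per period of the Hermitian-extended transform."""
        return 2 * self.n_modes


def _womersley_factor(r0: float, omega: np.ndarray, rho: float, mu: float) -> np.ndarray:
    """F_J = 2 J1(w0)/(w0 J0(w0)) with w0 = i^(3/2) r0 sqrt(omega rho / mu)."""
    w0 = 1j**1.5 * r0 * np.sqrt(omega * rho / mu)
    return 2.0 * special.jv(1, w0) / (w0 * special.jv(0, w0))


def _admittance_entries(
    r0: float, L: float, K_ST: float, omega: np.ndarray, rho: float, mu: float
):
    """(diag, offdiag) of the 2x2 admittance at each positive omega."""
    A0 = np.pi * r0**2
    C = 1.5 * A0 / K_ST  # compliance per unit length from the linear wall law
    fj = _womersley_factor(r0, omega, rho, mu)
    g = np.sqrt(C * A0 * (1.0 - fj) / rho)
    c = np.sqrt(A0 * (1.0 - fj) / (rho * C))  # viscous-corrected wave speed
    s = np.sin(omega * L / c)
    bad = np.abs(s) < 1e-13
    if np.any(bad):
        k = int(np.argmax(bad))
        raise ResonanceError(
            f"sin(omega L/c) ~ 0 at omega={float(np.atleast_1d(omega)[k]):.9g}"
        )
    pref = 1j * g / s
    return pref * (-np.cos(omega * L / c)), pref


def vessel_admittance(
    r0: float,
    L: float,
    K_ST: float,
    omega: float | np.ndarray,
    rho: float = 1.055,
    mu: float | None = None,
) -> np.ndarray:
    """2x2 complex admittance of a single distal vessel.

    Into-port convention (both flows directed into the vessel): at omega = 0
    this is the Poiseuille matrix (pi r0^4 / 8 mu L) [[1, -1], [-1, 1]].
    Returns shape (2, 2) for scalar omega, else (len(omega), 2, 2).
    """
    if r0 <= 0 or L <= 0 or K_ST <= 0:
        raise ValueError("r0, L, K_ST must be positive")
    if mu is None:
        mu = float(viscosity_of_radius(r0))
    omega_arr = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(omega_arr < 0):
        raise ValueError("omega must be >= 0")
    Y = np.empty((omega_arr.size, 2, 2), dtype=complex)
    zero = omega_arr == 0.0
    if np.any(zero):
        y0 = np.pi * r0**4 / (8.0 * mu * L)
        Y[zero] = y0 * np.array([[1.0, -1.0], [-1.0, 1.0]])
    if np.any(~zero):
        diag, off = _admittance_entries(r0, L, K_ST, omega_arr[~zero], rho, mu)
        Y[~zero, 0, 0] = Y[~zero, 1, 1] = diag
        Y[~zero, 0, 1] = Y[~zero, 1, 0] = off
    return Y[0] if np.isscalar(omega) or np.asarray(omega).ndim == 0 else Y


def _series(Ya: np.ndarray, Yb: np.ndarray) -> np.ndarray:
    """Condense two two-ports sharing one interior pressure node.

    Shapes (..., 2, 2); eliminates the node joining port 2 of ``Ya`` to
    port 1 of ``Yb``.
    """
    den = Ya[..., 1, 1] + Yb[..., 0, 0]
    out = np.empty(np.broadcast_shapes(Ya.shape, Yb.shape), dtype=complex)
    out[..., 0, 0] = Ya[..., 0, 0] - Ya[..., 0, 1] * Ya[..., 1, 0] / den
    out[..., 0, 1] = -Ya[..., 0, 1] * Yb[..., 0, 1] / den
    out[..., 1, 0] = -Yb[..., 1, 0] * Ya[..., 1, 0] / den
    out[..., 1, 1] = Yb[..., 1, 1] - Yb[..., 1, 0] * Yb[..., 0, 1] / den
    return out


@dataclass
class GrandAdmittance:
    """Condensed two-sided bed admittance plus time-domain kernels.

    ``Y`` has shape (n_modes+1, 2, 2) over ``grid.omegas`` (into-port
    convention); ``kernels`` has shape (n_samples, 2, 2) sampled at
    tau_s = s T / n_samples on [0, T).
    """

    params: TreeParameters
    grid: SpectralGrid
    Y: np.ndarray
    kernels: np.ndarray
    venous_root_radius: float | None = None
    subtree_Y: dict[tuple[int, int], np.ndarray] = field(default_factory=dict, repr=False)
    tree: TreeIndex | None = field(default=None, repr=False)
    omegas: np.ndarray | None = field(default=None, repr=False)  # possibly perturbed

    @property
    def dc_resistance(self) -> float:
        return float(1.0 / self.Y[0, 0, 0].real)

    def to_hdf5(self, group) -> None:
        group.create_dataset("omegas", data=self.grid.omegas)
        group.create_dataset("Y_real", data=self.Y.real)
        group.create_dataset("Y_imag", data=self.Y.imag)
        group.create_dataset("kernels", data=self.kernels)
        for k, v in vars(self.params).items():
            group.attrs[k] = v
        group.attrs["T"] = self.grid.T


def _kernels_from_modes(Y: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    """Real periodic kernels by inverse DFT with Hermitian extension."""
    M = grid.n_samples
    spec = np.zeros((M, 2, 2), dtype=complex)
    spec[: grid.n_modes + 1] = Y
    spec[grid.n_modes] = Y[grid.n_modes].real  # Nyquist must be real
    spec[grid.n_modes + 1 :] = np.conj(Y[1 : grid.n_modes][::-1])
    kern = np.fft.ifft(spec, axis=0) * (M / grid.T)
    resid = np.abs(kern.imag).max() / max(np.abs(kern.real).max(), 1e-300)
    if resid > 1e-10:
        raise AssertionError(f"kernel imaginary residue {resid:.2e} exceeds 1e-10")
    return np.ascontiguousarray(kern.real)


def grand_admittance(
    tree: TreeIndex,
    params: TreeParameters,
    grid: SpectralGrid,
    venous_root_radius: float | None = None,
    rho: float = 1.055,
    keep_subtrees: bool = False,
    viscosity_fn=None,
) -> GrandAdmittance:
    """Condense a two-sided bed into one 2x2 admittance per frequency.

    Processes distinct (i, j) nodes by generation, deepest first: a terminal
    node is its arterial segment in series with the mirrored venous segment;
    an interior node wraps the parallel sum of its daughters' sub-bed
    two-ports between its own arterial and venous segments.  Memoized on
    (i, j), so cost is O(#distinct nodes x n_modes).

    The venous mirror uses the same radii node-for-node (only lengths differ
    via lrr_V); ``venous_root_radius`` is recorded for provenance but does
    not alter radii generation.
    """
    omegas = grid.omegas.copy()
    for _attempt in range(8):
        try:
            Y_root, memo = _condense(tree, params, omegas, rho, viscosity_fn)
            break
        except ResonanceError as err:
            # perturb the offending frequency by one part in 1e9 and retry
            bad = float(str(err).rsplit("=", 1)[1])
            k = int(np.argmin(np.abs(omegas - bad)))
            omegas[k] *= 1.0 + 1e-9
    else:
        raise ResonanceError("persistent admittance resonance after 8 perturbations")
    kernels = _kernels_from_modes(Y_root, grid)
    if keep_subtrees:
        # the pathway walks only ever need daughters of (i,0) and (0,j) nodes
        sub = {ij: Yij for ij, Yij in memo.items() if ij[0] <= 1 or ij[1] <= 1}
    else:
        sub = {}
    return GrandAdmittance(
        params, grid, Y_root, kernels, venous_root_radius, sub,
        tree if keep_subtrees else None, omegas,
    )


def _condense(
    tree: TreeIndex,
    params: TreeParameters,
    omegas: np.ndarray,
    rho: float,
    viscosity_fn=None,
):
    visc = viscosity_fn or viscosity_of_radius
    memo: dict[tuple[int, int], np.ndarray] = {}
    order = sorted(tree.nodes, key=lambda ij: ij[0] + ij[1], reverse=True)
    for (i, j) in order:
        r = tree.radius(i, j)
        mu = float(visc(r))
        Ya = vessel_admittance(r, r * params.lrr_A, params.K_ST, omegas, rho, mu)
        Yv = vessel_admittance(r, r * params.lrr_V, params.K_ST, omegas, rho, mu)
        if tree.is_terminal(i, j):
            memo[(i, j)] = _series(Ya, Yv)
        else:
            Ysub = memo[(i + 1, j)] + memo[(i, j + 1)]  # daughters in full parallel
            memo[(i, j)] = _series(_series(Ya, Ysub), Yv)
    return memo[(0, 0)], memo
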