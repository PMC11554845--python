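"""Legendre polynomial-chaos emulation and variance-based sensitivity.

Model outputs Z(theta) over a uniform prior box are expanded in orthonormal
multivariate Legendre polynomials of total degree <= K,

    Z(theta) ~ sum_j c_j Psi_j(xi),   xi in [-1, 1]^n,

with coefficients fitted pointwise (one ordinary-least-squares solve per
output sample) on a random design.  In the orthonormal convention
E[Psi_j^2] = 1, so the mean is c_0, the variance is sum_{j>=1} c_j^2, and
Sobol' indices are coefficient sums of squares restricted to multi-indices
supported on the parameter (sub)sets of interest.  Time-dependent indices
are aggregated with variance-weighted integrals (generalized Sobol'
indices), reported at the end of the cycle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "ParameterPrior",
    "PCESurrogate",
    "SobolReport",
    "DEFAULT_BOUNDS",
    "sample_prior",
    "multi_indices",
    "fit_ols",
    "moments",
    "sobol_indices",
    "generalized_sobol",
    "validation_mse",
]

# uniform prior box for the eight model parameters
DEFAULT_BOUNDS = {
    "K_A": (5.60e5, 1.04e6),
    "K_ST": (1.75e5, 3.25e5),
    "K_V": (5.95e5, 1.11e6),
    "alpha": (0.80, 0.92),
    "beta": (0.60, 0.70),
    "lrr_A": (10.0, 50.0),
    "lrr_V": (10.0, 50.0),
    "r_min": (1e-3, 1e-2),
}


@dataclass(frozen=True)
class ParameterPrior:
    """Independent uniform priors with an affine map to the cube [-1, 1]^n."""

    names: tuple[str, ...] = tuple(DEFAULT_BOUNDS)
    bounds: tuple[tuple[float, float], ...] = tuple(DEFAULT_BOUNDS.values())

    def __post_init__(self) -> None:
        if len(self.names) != len(self.bounds):
            raise ValueError("names/bounds length mismatch")
        for nm, (lo, hi) in zip(self.names, self.bounds):
            if not lo < hi:
                raise ValueError(f"prior '{nm}': need lower < upper")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    def to_canonical(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(x) - self.lo) / (self.hi - self.lo) - 1.0

    def from_canonical(self, xi: np.ndarray) -> np.ndarray:
        return self.lo + 0.5 * (np.asarray(xi) + 1.0) * (self.hi - self.lo)


def sample_prior(
    prior: ParameterPrior, N: int, seed: int, design: str = "random"
) -> tuple[np.ndarray, np.ndarray]:
    """Draw N samples; returns (physical values, canonical-cube images)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if design == "random":
        rng = np.random.default_rng(seed)
        u = rng.random((N, prior.n))
    elif design == "lhs":
        u = qmc.LatinHypercube(d=prior.n, seed=seed).random(N)
    else:
        raise ValueError(f"unknown design '{design}'")
    xi = 2.0 * u - 1.0
    return prior.from_canonical(xi), xi


def multi_indices(n: int, order: int) -> np.ndarray:
    """All multi-indices over n variables with total degree <= order."""
    idx = [
        m
        for deg in range(order + 1)
        for m in itertools.product(range(deg + 1), repeat=n)
        if sum(m) == deg
    ]
    return np.array(idx, dtype=np.int64)


def _legendre_table(xi: np.ndarray, order: int) -> np.ndarray:
    """Orthonormal Legendre values, shape (N, n, order+1); E[psi_k^2] = 1."""
    xi = np.asarray(xi, dtype=float)
    N, n = xi.shape
    P = np.empty((N, n, order + 1))
    P[..., 0] = 1.0
    if order >= 1:
        P[..., 1] = xi
    for k in range(1, order):
        P[..., k + 1] = ((2 * k + 1) * xi * P[..., k] - k * P[..., k - 1]) / (k + 1)
    return P * np.sqrt(2.0 * np.arange(order + 1) + 1.0)


def design_matrix(xi: np.ndarray, mi: np.ndarray) -> np.ndarray:
    """Evaluate all basis functions at all points: (N, J)."""
    P = _legendre_table(xi, int(mi.max(initial=0)))
    out = np.ones((P.shape[0], mi.shape[0]))
    for d in range(mi.shape[1]):
        out *= P[:, d, mi[:, d]]
    return out


@dataclass
class PCESurrogate:
    """Fitted expansion: multi-index set, coefficient matrix, fit metadata."""

    prior: ParameterPrior
    mi: np.ndarray  # (J, n)
    coeffs: np.ndarray  # (J, n_out)
    order: int
    n_train: int
    condition: float
    seed: int | None = None
    output_labels: list | None = field(default=None, repr=False)

    @property
    def n_basis(self) -> int:
        return self.mi.shape[0]

    def predict(self, xi: np.ndarray) -> np.ndarray:
        xi = np.atleast_2d(xi)
        return design_matrix(xi, self.mi) @ self.coeffs

    def to_hdf5(self, group) -> None:
        group.create_dataset("multi_indices", data=self.mi)
        group.create_dataset("coefficients", data=self.coeffs)
        group.create_dataset("bounds", data=np.array(self.prior.bounds))
        group.attrs["names"] = list(self.prior.names)
        group.attrs["order"] = self.order
        group.attrs["n_train"] = self.n_train
        if self.seed is not None:
            group.attrs["seed"] = self.seed


def fit_ols(
    design_points: np.ndarray,
    outputs: np.ndarray,
    order: int,
    prior: ParameterPrior | None = None,
    seed: int | None = None,
    canonical: bool = False,
) -> PCESurrogate:
    """Least-squares fit of the degree-<=order expansion at each output point.

    ``design_points`` is (N, n) in physical units unless ``canonical``;
    ``outputs`` is (N,) or (N, n_out).  Warns when N < 2J (ill-conditioning
    risk) and raises on rank deficiency.
    """
    prior = prior or ParameterPrior()
    xi = np.asarray(design_points) if canonical else prior.to_canonical(design_points)
    Z = np.atleast_2d(np.asarray(outputs, dtype=float).T).T
    if xi.shape[0] != Z.shape[0]:
        raise ValueError("design/outputs size mismatch")
    mi = multi_indices(prior.n, order)
    J = mi.shape[0]
    if xi.shape[0] < J:
        raise ValueError(f"need at least J={J} samples, got {xi.shape[0]}")
    if xi.shape[0] < 2 * J:
        import warnings

        warnings.warn(
            f"N={xi.shape[0]} < 2J={2 * J}: least-squares problem may be "
            "ill-conditioned",
            stacklevel=2,
        )
    Psi = design_matrix(xi, mi)
    coeffs, _, rank, sv = np.linalg.lstsq(Psi, Z, rcond=None)
    if rank < J:
        raise np.linalg.LinAlgError(f"rank-deficient design: rank {rank} < J {J}")
    cond = float(sv[0] / sv[-1])
    return PCESurrogate(prior, mi, coeffs, order, xi.shape[0], cond, seed)


def moments(surrogate: PCESurrogate) -> tuple[np.ndarray, np.ndarray]:
    """(mean, variance) per output point; orthonormal basis, so the mean is
    the constant coefficient and the variance the sum of squared others."""
    c = surrogate.coeffs
    const = np.all(surrogate.mi == 0, axis=1)
    mean = c[const].sum(axis=0)
    var = (c[~const] ** 2).sum(axis=0)
    return mean, var


@dataclass
class SobolReport:
    """First/second/total (and optionally generalized) indices per output."""

    names: tuple[str, ...]
    S1: np.ndarray  # (n, n_out)
    ST: np.ndarray  # (n, n_out)
    S2: dict[tuple[int, int], np.ndarray]
    valid: np.ndarray  # mask of output points with positive variance

    def to_frame(self, output_labels=None) -> pd.DataFrame:
        rows = []
        n_out = self.S1.shape[1]
        labels = output_labels or list(range(n_out))
        for t in range(n_out):
            if not self.valid[t]:
                continue
            for i, nm in enumerate(self.names):
                rows.append((labels[t], nm, "", "S1", self.S1[i, t]))
                rows.append((labels[t], nm, "", "ST", self.ST[i, t]))
            for (i, j), v in self.S2.items():
                rows.append((labels[t], self.names[i], self.names[j], "S2", v[t]))
        return pd.DataFrame(
            rows, columns=["output", "param1", "param2", "index_type", "value"]
        )


def sobol_indices(surrogate: PCESurrogate) -> SobolReport:
    """Sobol' indices from the expansion coefficients.

    S_i sums squared coefficients over multi-indices involving only theta_i,
    S_ij over exactly the pair, S_Ti over any involvement of theta_i.
    Output points with zero variance are masked.
    """
    mi, c = surrogate.mi, surrogate.coeffs
    n = mi.shape[1]
    _, var = moments(surrogate)
    valid = var > 0
    safe = np.where(valid, var, 1.0)
    c2 = c**2
    active = mi > 0
    S1 = np.empty((n, c.shape[1]))
    ST = np.empty((n, c.shape[1]))
    for i in range(n):
        only_i = active[:, i] & (active.sum(axis=1) == 1)
        S1[i] = c2[only_i].sum(axis=0) / safe
        ST[i] = c2[active[:, i]].sum(axis=0) / safe
    S2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            pair = active[:, i] & active[:, j] & (active.sum(axis=1) == 2)
            if pair.any():
                S2[(i, j)] = c2[pair].sum(axis=0) / safe
            else:
                S2[(i, j)] = np.zeros(c.shape[1])
    S1[:, ~valid] = np.nan
    ST[:, ~valid] = np.nan
    return SobolReport(surrogate.prior.names, S1, ST, S2, valid)


def generalized_sobol(
    indices_t: np.ndarray, variance_t: np.ndarray, times: np.ndarray | None = None
) -> np.ndarray:
    """Variance-weighted cumulative Sobol' index evaluated at the final time.

    GS(t_j) = int_0^{t_j} S(t) Var(t) dt / int_0^{t_j} Var(t) dt by the
    trapezoid rule; ``indices_t`` has time as its last axis.
    """
    indices_t = np.asarray(indices_t, dtype=float)
    variance_t = np.asarray(variance_t, dtype=float)
    if times is None:
        times = np.arange(variance_t.size, dtype=float)
    den = np.trapezoid(variance_t, times)
    if den <= 0:
        raise ValueError("output variance is identically zero")
    num = np.trapezoid(indices_t * variance_t, times, axis=-1)
    return num / den


def validation_mse(
    surrogate: PCESurrogate,
    validation_points: np.ndarray,
    validation_outputs: np.ndarray,
    canonical: bool = False,
) -> tuple[np.ndarray, float]:
    """Per-output-point mean squared error on held-out data, and its mean."""
    xi = (
        np.asarray(validation_points)
        if canonical
        else surrogate.prior.to_canonical(validation_points)
    )
    Z = np.atleast_2d(np.asarray(validation_outputs, dtype=float).T).T
    pred = surrogate.predict(xi)
    if pred.shape != Z.shape:
        raise ValueError("validation outputs shape mismatch")
    err = ((pred - Z) ** 2).mean(axis=0)
    return err, float(err.mean())
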