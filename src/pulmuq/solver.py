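"""Nonlinear 1D hemodynamics on the proximal network.

Mass and momentum balance in each vessel,

    dA/dt + dq/dx = 0
    dq/dt + (g+2)/(g+1) d(q^2/A)/dx + (A/rho) dp/dx = -2 pi nu (g+2) q/A,

close with the linearly elastic wall law p = (4/3)(Eh/r0)(sqrt(A/A0) - 1)
and are advanced with the two-step Lax-Wendroff scheme (compiled kernels in
:mod:`pulmuq._core`).  Boundary conditions: prescribed periodic inflow at the
MPA inlet, static-pressure/flow continuity at bifurcations, a left-atrial
pressure at the four venous outlets, and structured-tree grand-admittance
convolutions at the eight terminal artery-vein pairs.  Whole cycles are
iterated until beat-to-beat periodicity (max pressure change at the inlet
vessel below ``convergence_tol``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _core
from .network import MMHG, MaterialParameters, ProximalNetwork
from .structured_tree import GrandAdmittance
from .waveforms import Waveform

__all__ = [
    "SolverConfig",
    "HemodynamicField",
    "SolverError",
    "ConvergenceError",
    "run_simulation",
    "coupling_convolution",
    "junction_condition",
]


class SolverError(RuntimeError):
    pass


class ConvergenceError(SolverError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Discretization and convergence settings.

    dx is the target node spacing (each vessel uses n = max(3, round(L/dx)+1)
    nodes so endpoints land on nodes); dt_target is rounded so a cycle holds a
    multiple of the admittance-kernel sample count; convergence_tol is the
    beat-to-beat pressure error (dyn/cm^2) at which the periodic state is
    accepted.
    """

    dx: float = 0.125
    dt_target: float = 1.04e-4
    max_cycles: int = 80
    convergence_tol: float = 1.0
    cfl_safety: float = 1.0  # hard CFL bound; the scheme enforces < 1 each step

    def n_steps(self, T: float, kernel_samples: int) -> int:
        blocks = max(1, round(T / (self.dt_target * kernel_samples)))
        return blocks * kernel_samples


@dataclass
class HemodynamicField:
    """(pressure, flow, area) over the final converged cycle on the solver grid."""

    network: ProximalNetwork
    config: SolverConfig
    names: list[str]
    offsets: np.ndarray
    nnod: np.ndarray
    dxv: np.ndarray
    T: float
    p: np.ndarray  # (n_steps, n_nodes_total), dyn/cm^2
    q: np.ndarray  # cm^3/s
    A: np.ndarray  # cm^2
    converged: bool
    n_cycles: int
    cycle_error: float  # final beat-to-beat max pressure change, dyn/cm^2
    cfl_max: float

    @property
    def n_steps(self) -> int:
        return self.p.shape[0]

    @property
    def dt(self) -> float:
        return self.T / self.n_steps

    @property
    def times(self) -> np.ndarray:
        return (1 + np.arange(self.n_steps)) * self.dt

    def _vslice(self, vessel: str) -> slice:
        v = self.names.index(vessel)
        return slice(self.offsets[v], self.offsets[v] + self.nnod[v])

    def vessel(self, vessel: str, quantity: str = "p") -> np.ndarray:
        """Time x space block for one vessel; quantity in {'p','q','A'}."""
        return getattr(self, quantity)[:, self._vslice(vessel)]

    def midpoint(self, vessel: str, quantity: str = "p") -> np.ndarray:
        block = self.vessel(vessel, quantity)
        return block[:, block.shape[1] // 2]

    def end(self, vessel: str, quantity: str = "p", x: str = "L") -> np.ndarray:
        block = self.vessel(vessel, quantity)
        return block[:, -1] if x == "L" else block[:, 0]

    def summary(self) -> pd.DataFrame:
        """Per-vessel systolic/diastolic/mean pressure (mmHg) and mean flow."""
        rows = []
        for name in self.names:
            pm = self.midpoint(name, "p")
            rows.append(
                {
                    "vessel": name,
                    "sys_p_mmHg": pm.max() / MMHG,
                    "dia_p_mmHg": pm.min() / MMHG,
                    "mean_p_mmHg": pm.mean() / MMHG,
                    "mean_q_cm3s": self.midpoint(name, "q").mean(),
                }
            )
        return pd.DataFrame(rows)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs["T"] = self.T
            h5.attrs["converged"] = self.converged
            h5.attrs["n_cycles"] = self.n_cycles
            h5.attrs["dx"] = self.config.dx
            for name in self.names:
                g = h5.create_group(name.replace("/", "_"))
                for qty in ("p", "q", "A"):
                    g.create_dataset(qty, data=self.vessel(name, qty))


def _discretize(network: ProximalNetwork, dx: float):
    names = [s.name for s in network]
    nnod = np.array(
        [max(3, int(round(s.length / dx)) + 1) for s in network], dtype=np.int64
    )
    offsets = np.zeros(len(names) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum(nnod)
    dxv = np.array([s.length / (n - 1) for s, n in zip(network, nnod)])
    A0v = np.array([np.pi * s.radius**2 for s in network])
    fv = np.array(
        [4.0 / 3.0 * network.materials.stiffness(s.side) for s in network]
    )
    return names, offsets, nnod, dxv, A0v, fv


def run_simulation(
    network: ProximalNetwork,
    beds: dict[str, GrandAdmittance],
    inflow: Waveform,
    la: Waveform,
    config: SolverConfig = SolverConfig(),
) -> HemodynamicField:
    """Iterate whole cardiac cycles to a periodic steady state.

    ``beds`` maps each terminal artery name to the grand admittance of its
    two-sided bed; all beds must share the inflow period.  Raises
    :class:`SolverError` on instability and :class:`ConvergenceError` if
    ``max_cycles`` elapse without meeting the beat-to-beat tolerance.
    """
    if abs(inflow.T - la.T) > 1e-12 * inflow.T:
        raise ValueError("inflow and LA waveform periods differ")
    T = inflow.T
    pairs = network.terminal_pairs
    for a, _ in pairs:
        if a not in beds:
            raise ValueError(f"missing structured-tree bed for terminal artery '{a}'")
        if abs(beds[a].grid.T - T) > 1e-12 * T:
            raise ValueError(f"bed '{a}' spectral grid period mismatch")

    names, offsets, nnod, dxv, A0v, fv = _discretize(network, config.dx)
    mats = network.materials

    kernel_samples = (
        beds[pairs[0][0]].kernels.shape[0] if pairs else 1024
    )
    n_steps = config.n_steps(T, kernel_samples)
    if pairs and n_steps % kernel_samples != 0:
        raise ValueError("cycle step count must be a multiple of the kernel samples")
    dt = T / n_steps

    qin = inflow.resample(n_steps)
    pla = la.resample(n_steps)

    # initial state: veins at the mean LA pressure, arteries offset by the
    # expected mean perfusion pressure (mean inflow x parallel bed
    # resistance), zero flow.  This only shortens the transient; the
    # converged periodic state does not depend on it.
    p0 = float(pla.mean())
    if pairs:
        R_par = 1.0 / sum(1.0 / beds[a].dc_resistance for a, _ in pairs)
        p0a = p0 + float(qin.mean()) * R_par
    else:
        p0a = p0
    N = int(offsets[-1])
    A = np.empty(N)
    for v, seg in enumerate(network):
        pinit = p0a if seg.side == "arterial" else p0
        A[offsets[v] : offsets[v + 1]] = A0v[v] * (1.0 + pinit / fv[v]) ** 2
    q = np.zeros(N)

    inlet_v = names.index(network.inlet)
    outlet_v = np.array([names.index(n) for n in network.venous_outlets], np.int64)
    juncs = network.junctions()
    junc_v = np.zeros((len(juncs), 3), np.int64)
    junc_end = np.zeros((len(juncs), 3), np.int64)
    for k, (par, d1, d2) in enumerate(juncs):
        side = network[par].side
        junc_v[k] = [names.index(par), names.index(d1), names.index(d2)]
        # arteries diverge (parent x=L feeds daughters x=0); veins converge
        junc_end[k] = [1, 0, 0] if side == "arterial" else [0, 1, 1]

    pair_art = np.array([names.index(a) for a, _ in pairs], np.int64)
    pair_vein = np.array([names.index(v) for _, v in pairs], np.int64)
    if pairs:
        kern = np.stack(
            [np.transpose(beds[a].kernels, (1, 2, 0)) for a, _ in pairs]
        ).copy()
    else:
        kern = np.zeros((0, 2, 2, n_steps))
    ring_pA = np.full((len(pairs), n_steps), p0a)
    ring_pV = np.full((len(pairs), n_steps), p0)

    P = np.empty((n_steps, N))
    Q = np.empty((n_steps, N))
    Aout = np.empty((n_steps, N))
    mpa_sl = slice(offsets[inlet_v], offsets[inlet_v] + nnod[inlet_v])
    p_prev = None
    err = np.inf
    cfl_max = 0.0
    n_cycles = 0
    converged = False
    for cycle in range(config.max_cycles):
        status, cfl, bad = _core.advance_cycle(
            A, q, offsets, nnod, A0v, fv, dxv,
            mats.rho, mats.nu, mats.gamma, dt, n_steps, cycle * n_steps,
            qin, pla, inlet_v, outlet_v, junc_v, junc_end,
            pair_art, pair_vein, kern, ring_pA, ring_pV,
            P, Q, Aout,
        )
        cfl_max = max(cfl_max, cfl)
        n_cycles = cycle + 1
        if status == _core.STATUS_CFL:
            raise SolverError(
                f"CFL violation in vessel '{names[bad]}' (worst Courant {cfl:.3f}); "
                "reduce dt_target or refine dx"
            )
        if status == _core.STATUS_NONPHYSICAL:
            raise SolverError(f"nonpositive area / NaN in vessel '{names[bad]}'")
        if status == _core.STATUS_NEWTON:
            raise SolverError(f"boundary Newton failed at vessel '{names[bad]}'")
        p_mpa = P[:, mpa_sl]
        if p_prev is not None:
            err = float(np.abs(p_mpa - p_prev).max())
            if err <= config.convergence_tol:
                converged = True
                break
        p_prev = p_mpa.copy()
    if not converged:
        raise ConvergenceError(
            f"no beat-to-beat convergence after {n_cycles} cycles "
            f"(last error {err:.3g} dyn/cm^2)"
        )
    return HemodynamicField(
        network, config, names, offsets, nnod, dxv, T,
        P, Q, Aout, converged, n_cycles, err, cfl_max,
    )


def coupling_convolution(
    p_A_history: np.ndarray,
    p_V_history: np.ndarray,
    kernels: np.ndarray,
    T: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Periodic convolution of terminal pressures with admittance kernels.

    Histories cover exactly one period (uniform samples); ``kernels`` is the
    (M, 2, 2) array from :class:`GrandAdmittance`.  Returns the physical
    flows (q_A into the bed at the artery outlet, q_V out of the bed at the
    vein inlet) over the same period.
    """
    M = kernels.shape[0]
    n = p_A_history.size
    if p_V_history.size != n or n % M != 0:
        raise ValueError("history length must be a common multiple of kernel samples")
    stride = n // M
    dtau = T / M
    lags = (np.arange(n)[:, None] - np.arange(M)[None, :] * stride) % n
    pa = p_A_history[lags]
    pv = p_V_history[lags]
    qa = (pa @ kernels[:, 0, 0] + pv @ kernels[:, 0, 1]) * dtau
    qv = -(pa @ kernels[:, 1, 0] + pv @ kernels[:, 1, 1]) * dtau
    return qa, qv


def junction_condition(
    parent_state: tuple[float, float, float, float],
    d1_state: tuple[float, float, float, float],
    d2_state: tuple[float, float, float, float],
    materials: MaterialParameters | None = None,
    converging: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve one junction closure given per-end (A0, f, W*, A_guess).

    Each state is (reference area A0, wall coefficient f=4K/3, outgoing
    Riemann invariant W*, area guess).  ``converging=False`` is an arterial
    junction (parent x=L feeds two daughters at x=0); ``converging=True`` a
    venous one.  Returns (areas, flows) with flows signed along each vessel's
    +x axis; mass balance and static-pressure continuity hold to the Newton
    tolerance.
    """
    rho = (materials or MaterialParameters()).rho
    states = [parent_state, d1_state, d2_state]
    A0s = np.array([s[0] for s in states])
    fs = np.array([s[1] for s in states])
    W = np.array([s[2] for s in states])
    A = np.array([s[3] for s in states])
    sgn = np.array([-1.0, 1.0, 1.0]) if converging else np.array([1.0, -1.0, -1.0])
    ok = _core._solve_junction(W, A0s, fs, rho, sgn, A)
    if not ok:
        raise SolverError("junction Newton iteration did not converge")
    c = np.sqrt(0.5 * fs / rho * np.sqrt(A / A0s))
    u = W - sgn * 4.0 * c
    return A, A * u
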