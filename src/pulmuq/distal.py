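"""Hemodynamics along the alpha/beta pathways of a structured-tree bed.

The alpha pathway follows only major daughters (most generations, smallest
terminal flow), the beta pathway only minor daughters (fewest generations).
Given the frequency-domain pressures at the bed's two roots -- taken from
the converged proximal solution at the terminal artery outlet and terminal
vein inlet -- pressures and flows are reconstructed vessel by vessel: at
each junction the two interior port pressures (arterial and mirrored venous)
solve a 2x2 nodal system built from the parent segment admittances and the
condensed daughter sub-beds, and the walk descends into the pathway
daughter.  At the terminal node the arterial segment crosses to its venous
mirror through a single interior pressure node.

Mechanotransduction readouts per vessel: time-averaged Poiseuille wall
shear stress WSS = 4 mu(r) Qbar / (pi Rbar^3) and cyclic stretch
CS = (max R - min R)/min R with R(t) = r0 (1 + 3 p(t) / (4 K_ST)) from the
linearized wall law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structured_tree import GrandAdmittance, vessel_admittance, viscosity_of_radius

__all__ = [
    "PathwayProfile",
    "pressure_spectrum",
    "propagate_pathway",
    "distal_wss",
    "distal_cs",
]


def pressure_spectrum(p: np.ndarray, n_modes: int) -> np.ndarray:
    """One-sided complex Fourier coefficients S_k of a periodic pressure trace.

    Convention: p(t) = S_0 + 2 sum_{k>=1} Re(S_k e^{i omega_k t}); S_0 is the
    time mean.
    """
    return np.fft.rfft(p)[: n_modes + 1] / p.size


def _reconstruct(spec: np.ndarray, n_samples: int) -> np.ndarray:
    return np.fft.irfft(spec * n_samples, n=n_samples)


@dataclass
class PathwayProfile:
    """Per-vessel profile along one pathway, arterial root to venous root.

    ``table`` rows are ordered along the traversal: arterial vessels from the
    bed root down to the termination, then the mirrored venous vessels from
    the termination back up to the venous root.  ``norm_dist`` is the
    distance-from-termination coordinate within each side, 0 at the smallest
    vessel and 1 at the side's root, used to pool ensembles whose r_min (and
    hence pathway length) differ.
    """

    pathway: str
    table: pd.DataFrame

    def side(self, side: str) -> pd.DataFrame:
        return self.table[self.table["side"] == side]

    def on_normalized_grid(
        self, grid: np.ndarray, column: str, side: str = "arterial"
    ) -> np.ndarray:
        df = self.side(side)
        x = df["norm_dist"].to_numpy()
        y = df[column].to_numpy()
        order = np.argsort(x)
        return np.interp(grid, x[order], y[order])


def propagate_pathway(
    bed: GrandAdmittance,
    root_pressure_spectrum_A: np.ndarray,
    root_pressure_spectrum_V: np.ndarray,
    pathway: str = "alpha",
    rho: float = 1.055,
) -> PathwayProfile:
    """Walk one pathway of a two-sided bed and tabulate per-vessel quantities.

    The bed must have been built with ``keep_subtrees=True`` so the condensed
    daughter two-ports along the pathways are available.  Spectra are on the
    bed's spectral grid (see :func:`pressure_spectrum`).
    """
    if pathway not in ("alpha", "beta"):
        raise ValueError("pathway must be 'alpha' or 'beta'")
    if bed.tree is None or not bed.subtree_Y:
        raise ValueError("bed was built without keep_subtrees=True")
    tree, params = bed.tree, bed.params
    om = bed.omegas
    nw = om.size
    if root_pressure_spectrum_A.size != nw or root_pressure_spectrum_V.size != nw:
        raise ValueError("spectra do not match the bed's spectral grid")
    n_rec = bed.grid.n_samples
    K = params.K_ST

    step = (1, 0) if pathway == "alpha" else (0, 1)
    P1 = root_pressure_spectrum_A.astype(complex).copy()
    P2 = root_pressure_spectrum_V.astype(complex).copy()
    i = j = 0
    dist = 0.0
    art_rows: list[dict] = []
    ven_rows: list[dict] = []
    while True:
        r = tree.radius(i, j)
        mu = float(viscosity_of_radius(r))
        La, Lv = r * params.lrr_A, r * params.lrr_V
        Ya = vessel_admittance(r, La, K, om, rho, mu)
        Yv = vessel_admittance(r, Lv, K, om, rho, mu)
        terminal = tree.is_terminal(i, j)
        if terminal:
            # artery in series with its venous mirror through one node
            den = Ya[:, 1, 1] + Yv[:, 0, 0]
            PmA = PmV = -(Ya[:, 1, 0] * P1 + Yv[:, 0, 1] * P2) / den
        else:
            d_path = bed.subtree_Y[(i + step[0], j + step[1])]
            d_sib = bed.subtree_Y[(i + 1 - step[0], j + 1 - step[1])]
            Ysub = d_path + d_sib
            a11 = Ya[:, 1, 1] + Ysub[:, 0, 0]
            a12 = Ysub[:, 0, 1]
            a21 = Ysub[:, 1, 0]
            a22 = Ysub[:, 1, 1] + Yv[:, 0, 0]
            r1 = -Ya[:, 1, 0] * P1
            r2 = -Yv[:, 0, 1] * P2
            det = a11 * a22 - a12 * a21
            PmA = (r1 * a22 - a12 * r2) / det
            PmV = (a11 * r2 - a21 * r1) / det

        Qa = Ya[:, 0, 0] * P1 + Ya[:, 0, 1] * PmA  # +x flow entering the artery
        Qv = -(Yv[:, 1, 0] * PmV + Yv[:, 1, 1] * P2)  # +x flow leaving the vein
        for side, L_seg, spec_mid, Q, d0 in (
            ("arterial", La, 0.5 * (P1 + PmA), Qa, dist),
            ("venous", Lv, 0.5 * (PmV + P2), Qv, dist),
        ):
            p_mean = float(spec_mid[0].real)
            q_mean = float(Q[0].real)
            p_t = _reconstruct(spec_mid, n_rec)
            row = {
                "side": side,
                "pathway": pathway,
                "i": i,
                "j": j,
                "radius_cm": r,
                "dist_cm": d0 + 0.5 * L_seg,
                "mean_p_dyncm2": p_mean,
                "mean_q_cm3s": q_mean,
                "wss_dyncm2": distal_wss(q_mean, r, p_mean, K, mu),
                "cs": distal_cs(p_t, K),
            }
            (art_rows if side == "arterial" else ven_rows).append(row)
        if terminal:
            break
        P1, P2 = PmA, PmV
        dist += La  # walk coordinate follows the arterial side
        i += step[0]
        j += step[1]

    # normalized distance from termination within each side (0 = smallest)
    for rows in (art_rows, ven_rows):
        n = len(rows)
        for k, row in enumerate(rows):
            row["norm_dist"] = 1.0 if n == 1 else 1.0 - k / (n - 1)
    table = pd.DataFrame(art_rows + ven_rows[::-1]).reset_index(drop=True)
    return PathwayProfile(pathway, table)


def distal_wss(
    mean_q: float, r0: float, mean_p: float, K_ST: float, mu: float | None = None
) -> float:
    """Time-averaged Poiseuille wall shear stress, 4 mu Qbar / (pi Rbar^3).

    Rbar is the reference radius dilated by the mean pressure through the
    linear wall law, Rbar = r0 (1 + 3 pbar / (4 K_ST)).
    """
    if mu is None:
        mu = float(viscosity_of_radius(r0))
    Rbar = r0 * (1.0 + 0.75 * mean_p / K_ST)
    if Rbar <= 0:
        raise ValueError("mean pressure implies nonpositive radius")
    return 4.0 * mu * mean_q / (np.pi * Rbar**3)


def distal_cs(p_t: np.ndarray, K_ST: float) -> float:
    """Cyclic stretch of a small vessel from its pressure waveform.

    R(t) = r0 (1 + 3 p(t)/(4 K_ST)) makes CS independent of r0:
    CS = 3 (p_max - p_min) / (4 K_ST + 3 p_min).
    """
    w_max = 1.0 + 0.75 * p_t.max() / K_ST
    w_min = 1.0 + 0.75 * p_t.min() / K_ST
    if w_min <= 0:
        raise ValueError("pressure excursion implies nonpositive radius")
    return float((w_max - w_min) / w_min)
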