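"""Proximal quantities of interest: wall shear stress, cyclic stretch, WIA.

All quantities are evaluated at the vessel midpoint (x = L/2) of the
converged cycle.  Wave intensity analysis splits successive pressure and
velocity increments into characteristic components using the local wall-law
wave speed c = sqrt((2K/3 rho) sqrt(A/A0)): dP+- = (dP +- rho c dU)/2,
dU+- = +- dP+- / (rho c), dI+- = dP+- dU+-, so dI+ >= 0 >= dI- and
dI+ + dI- = dP dU identically.  Each nonzero sample of the forward
(backward) intensity is a compression wave if its pressure increment is
positive, an expansion wave otherwise: FCW/FEW/BCW/BEW.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import MMHG, MaterialParameters
from .solver import HemodynamicField

__all__ = [
    "WaveIntensityTrace",
    "proximal_wss",
    "cyclic_stretch",
    "wave_intensity",
    "qoi_table",
]

WAVE_TYPES = ("FCW", "FEW", "BCW", "BEW")


@dataclass
class WaveIntensityTrace:
    """Pointwise forward/backward wave intensity and per-type energies."""

    times: np.ndarray
    dI_forward: np.ndarray  # >= 0
    dI_backward: np.ndarray  # <= 0
    dP_forward: np.ndarray
    dP_backward: np.ndarray
    energies: dict[str, float]  # time-integrated |dI| per wave type

    @property
    def labels(self) -> np.ndarray:
        """Dominant wave type per sample (ties go to the forward component)."""
        fwd = self.dI_forward >= -self.dI_backward
        lab = np.where(
            fwd,
            np.where(self.dP_forward >= 0, "FCW", "FEW"),
            np.where(self.dP_backward >= 0, "BCW", "BEW"),
        )
        return lab


def proximal_wss(
    field: HemodynamicField, vessel: str, materials: MaterialParameters | None = None
) -> np.ndarray:
    """WSS(t) = mu (q/A) (gamma+2) / R at the vessel midpoint (dyn/cm^2)."""
    m = materials or field.network.materials
    q = field.midpoint(vessel, "q")
    A = field.midpoint(vessel, "A")
    R = np.sqrt(A / np.pi)
    return m.mu * (q / A) * (m.gamma + 2.0) / R


def cyclic_stretch(field: HemodynamicField, vessel: str) -> float:
    """CS = (max R - min R)/min R from the midpoint area waveform."""
    R = np.sqrt(field.midpoint(vessel, "A") / np.pi)
    rmin = R.min()
    if rmin <= 0:
        raise ValueError(f"nonpositive radius in vessel '{vessel}'")
    return float((R.max() - rmin) / rmin)


def wave_intensity(
    field: HemodynamicField, vessel: str, materials: MaterialParameters | None = None
) -> WaveIntensityTrace:
    """Characteristic wave-intensity decomposition at the vessel midpoint.

    Increments are first-order successive differences with periodic wrap;
    intensities are per-sample dP dU products (no dt normalization), so the
    reported energies are shape-level quantities suitable for relative
    comparison.
    """
    m = materials or field.network.materials
    K = m.stiffness(field.network[vessel].side)
    p = field.midpoint(vessel, "p")
    q = field.midpoint(vessel, "q")
    A = field.midpoint(vessel, "A")
    A0 = np.pi * field.network[vessel].radius ** 2
    u = q / A
    c = np.sqrt((2.0 * K / (3.0 * m.rho)) * np.sqrt(A / A0))
    dP = p - np.roll(p, 1)
    dU = u - np.roll(u, 1)
    rc = m.rho * c
    dPf = 0.5 * (dP + rc * dU)
    dPb = 0.5 * (dP - rc * dU)
    dIf = dPf**2 / rc
    dIb = -(dPb**2) / rc
    energies = {
        "FCW": float(dIf[dPf >= 0].sum()),
        "FEW": float(dIf[dPf < 0].sum()),
        "BCW": float(-dIb[dPb >= 0].sum()),
        "BEW": float(-dIb[dPb < 0].sum()),
    }
    return WaveIntensityTrace(field.times, dIf, dIb, dPf, dPb, energies)


def qoi_table(field: HemodynamicField) -> pd.DataFrame:
    """Per-vessel summary: pressures, flow, CS, WSS, and WIA energies."""
    rows = []
    for name in field.names:
        p = field.midpoint(name, "p")
        wss = proximal_wss(field, name)
        wia = wave_intensity(field, name)
        rows.append(
            {
                "vessel": name,
                "mean_p_mmHg": p.mean() / MMHG,
                "sys_p_mmHg": p.max() / MMHG,
                "dia_p_mmHg": p.min() / MMHG,
                "mean_q": field.midpoint(name, "q").mean(),
                "cs": cyclic_stretch(field, name),
                "mean_wss": wss.mean(),
                "peak_wss": wss.max(),
                **wia.energies,
            }
        )
    return pd.DataFrame(rows)
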