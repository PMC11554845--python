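"""Parametric periodic boundary waveforms.

The solver needs a main-pulmonary-artery (MPA) flow-rate waveform and a
left-atrial (LA) pressure waveform.  The reference versions of these signals
come from imaging and lumped-parameter modelling and are not distributed, so
this module synthesizes parametric stand-ins: a half-sine systolic ejection
pulse (optionally with a small backflow lobe) for the inflow, and a baseline
plus a-/v-wave Gaussian bumps for LA pressure.  Defaults give an adult at
rest: cardiac output ~4.9 L/min and LA pressures in the wedge-pressure range.
These are explicitly NOT the original subject data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .network import MMHG

__all__ = ["Waveform", "mpa_inflow", "la_pressure", "read_waveform", "write_waveform"]


@dataclass(frozen=True)
class Waveform:
    """Periodic signal sampled uniformly on [0, T); first sample follows the last."""

    T: float
    samples: np.ndarray
    kind: str  # "flow" (cm^3/s) | "pressure" (dyn/cm^2)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("period must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.T / self.n_samples

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    def resample(self, n: int) -> np.ndarray:
        """Values at n uniform times on [0, T) by periodic cubic interpolation."""
        t = np.append(self.times, self.T)
        v = np.append(self.samples, self.samples[0])
        return CubicSpline(t, v, bc_type="periodic")(np.arange(n) * self.T / n)


def _gaussian_smooth_periodic(y: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Circular Gaussian smoothing; preserves the mean exactly, keeps y >= 0."""
    n = y.size
    x = np.arange(n)
    d = np.minimum(x, n - x).astype(float)
    kern = np.exp(-0.5 * (d / sigma_samples) ** 2)
    kern /= kern.sum()
    return np.real(np.fft.ifft(np.fft.fft(y) * np.fft.fft(kern)))


def mpa_inflow(
    T: float = 0.85,
    stroke_volume: float = 70.0,
    systolic_fraction: float = 0.4,
    backflow_fraction: float = 0.02,
    n_samples: int = 2048,
) -> Waveform:
    """Synthetic MPA inflow: half-sine ejection plus an optional backflow lobe.

    The positive half-sine over [0, systolic_fraction*T] carries exactly
    ``stroke_volume``; a short negative lobe after valve closure carries
    ``backflow_fraction`` of it away, so the net integral is
    SV * (1 - backflow_fraction).  The pulse is lightly smoothed (circular
    Gaussian, sigma = 0.5% of T) to make it C1 without moving the integral.
    """
    if T <= 0 or stroke_volume <= 0:
        raise ValueError("T and stroke_volume must be positive")
    if not 0.0 < systolic_fraction < 1.0:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    if not 0.0 <= backflow_fraction < 0.1:
        raise ValueError("backflow_fraction must lie in [0, 0.1)")
    t = np.arange(n_samples) * T / n_samples
    t_sys = systolic_fraction * T
    q = np.where(t < t_sys, np.sin(np.pi * t / max(t_sys, 1e-12)), 0.0)
    q *= np.pi * stroke_volume / (2.0 * t_sys)  # half-sine amplitude
    if backflow_fraction > 0.0:
        t_b = min(0.08 * T, 0.5 * (T - t_sys))
        lobe = (t >= t_sys) & (t < t_sys + t_b)
        q[lobe] -= (
            np.pi * backflow_fraction * stroke_volume / (2.0 * t_b)
        ) * np.sin(np.pi * (t[lobe] - t_sys) / t_b)
    q = _gaussian_smooth_periodic(q, 0.005 * n_samples)
    if backflow_fraction == 0.0:
        q = np.maximum(q, 0.0)
    return Waveform(T, q, "flow")


def la_pressure(
    T: float = 0.85,
    p_base: float = 8.0,
    a_amp: float = 3.0,
    v_amp: float = 2.0,
    n_samples: int = 2048,
    width_fraction: float = 0.05,
) -> Waveform:
    """Synthetic left-atrial pressure: baseline plus v- and a-wave bumps.

    ``p_base``, ``a_amp`` and ``v_amp`` are in mmHg; the v wave peaks
    mid-cycle (atrial filling against a closed mitral valve) and the a wave
    at 0.9 T (atrial contraction).  Output is in dyn/cm^2.
    """
    if p_base <= 0:
        raise ValueError("p_base must be positive")
    if a_amp < 0 or v_amp < 0:
        raise ValueError("wave amplitudes must be >= 0")
    t = np.arange(n_samples) * T / n_samples
    sig = width_fraction * T

    def bump(center: float, amp: float) -> np.ndarray:
        # periodic Gaussian (wrap nearest image)
        d = np.abs(t - center)
        d = np.minimum(d, T - d)
        return amp * np.exp(-0.5 * (d / sig) ** 2)

    p = p_base + bump(0.5 * T, v_amp) + bump(0.9 * T, a_amp)
    p = p * MMHG
    if np.any(p <= 0):
        raise ValueError("resulting left-atrial pressure is not strictly positive")
    return Waveform(T, p, "pressure")


def read_waveform(path: str | Path, kind: str) -> Waveform:
    """Read a two-column `time_s,value` CSV; samples must be uniform on [0, T)."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    dt = np.diff(t)
    if t.size < 4 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: expected uniform time samples")
    return Waveform(float(t[-1] + dt[0]), v, kind)


def write_waveform(wf: Waveform, path: str | Path) -> None:
    pd.DataFrame({"time_s": wf.times, "value": wf.samples}).to_csv(path, index=False)
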