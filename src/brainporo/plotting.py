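"""Matplotlib helpers for the standard figures of the specimen studies."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_stress_stretch", "plot_relaxation", "plot_dissipation"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_stress_stretch(record, height_mm: float, ax=None, **kw):
    """Nominal stress vs. overall axial stretch (hysteresis loops)."""
    ax = _ax(ax)
    lam = 1.0 + np.asarray(record.displacement) / height_mm
    ax.plot(lam, record.nominal_stress, **kw)
    ax.set_xlabel("stretch $\\lambda$ (-)")
    ax.set_ylabel("nominal stress (Pa)")
    ax.axhline(0.0, color="0.8", lw=0.5)
    ax.axvline(1.0, color="0.8", lw=0.5)
    return ax


def plot_relaxation(metrics, ax=None, shifted: bool = True, **kw):
    """Normalized relaxation curve: stress/peak, or shifted by the
    equilibrium level so the curve decays from 1 towards 0."""
    ax = _ax(ax)
    t = metrics.t_hold - metrics.t_hold[0]
    y = metrics.normalized_shifted if shifted else metrics.normalized
    if y is None:
        raise ValueError("record does not relax; no shifted curve")
    ax.plot(t, y, **kw)
    ax.set_xlabel("hold time (s)")
    ax.set_ylabel("(stress - eq.)/(peak - eq.)" if shifted
                  else "stress / peak")
    return ax


def plot_dissipation(trajectory, ax=None, **kw):
    """Volume-integrated porous and viscous dissipation rates vs. time."""
    ax = _ax(ax)
    df = trajectory.summary
    ax.plot(df["t_s"], df["Dp_total_W"], label="porous $D_p$", **kw)
    if (df["Dv_total_W"] > 0).any():
        ax.plot(df["t_s"], df["Dv_total_W"], label="viscous $D_v$", **kw)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("dissipation rate (W)")
    ax.legend(frameon=False)
    return ax
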