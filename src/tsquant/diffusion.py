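"""Diffusion spatial-resolution calculator.

For a freely diffusing particle the mean-squared displacement after time t
is <x^2> = 2 n D t, with n the dimensionality and D the diffusion
coefficient.  With the cytosolic GFP value D = 126 um^2/s this sets the
spatial resolution of any puromycin-release labeling method: even confined
to one dimension a released protein travels ~100 um in under a minute.
Units are um and s throughout; callers convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: cytosolic GFP diffusion coefficient, um^2/s
DEFAULT_D = 126.0


@dataclass(frozen=True)
class DiffusionQuery:
    """D (um^2/s), dimensionality n in {1, 2, 3}, time t (s)."""

    D: float = DEFAULT_D
    n: int = 1
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.n not in (1, 2, 3):
            raise ValueError("dimensionality must be 1, 2 or 3")
        if self.t < 0:
            raise ValueError("time must be nonnegative")


@dataclass(frozen=True)
class DisplacementCurve:
    """RMS displacement sqrt(2 n D t) over a time grid, for n = 1, 2, 3."""

    t: np.ndarray
    rms: dict[int, np.ndarray]  # dimensionality -> um


def rms_displacement(q: DiffusionQuery) -> float:
    """Root-mean-squared displacement sqrt(2 n D t), in um."""
    return float(np.sqrt(2.0 * q.n * q.D * q.t))


def time_to_reach(D: float, n: int, x: float) -> float:
    """Time (s) for the RMS displacement to reach x um: x^2 / (2 n D)."""
    q = DiffusionQuery(D=D, n=n, t=0.0)  # validates D and n
    if x < 0:
        raise ValueError("distance must be nonnegative")
    return float(x**2 / (2.0 * q.n * q.D))


def displacement_curve(D: float = DEFAULT_D, t_grid: np.ndarray | None = None) -> DisplacementCurve:
    """RMS-displacement-vs-time curves for 1, 2 and 3 dimensions."""
    t = np.asarray(t_grid if t_grid is not None else np.linspace(0.0, 60.0, 601), dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("time grid must be nonnegative and nondecreasing")
    return DisplacementCurve(
        t=t, rms={n: np.sqrt(2.0 * n * D * t) for n in (1, 2, 3)}
    )


def plot_displacement_curve(curve: DisplacementCurve, out_path: str | None = None):
    """Log-log RMS displacement vs time, one line per dimensionality."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for n, rms in sorted(curve.rms.items()):
        ax.plot(curve.t, rms, label=f"n = {n}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("RMS displacement (µm)")
    ax.legend(title="dimensionality")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
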