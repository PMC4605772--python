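"""Chemical environments and closed-loop klinotaxis behavior.

The worm is a point moving at constant speed in a planar radial gradient;
the circuit steers by modulating the neck-angle velocity.  This module
provides the gradient fields, the closed-loop simulation (used as the
fitness evaluation of the evolutionary search), the behavioral score, and
the empirical distribution of concentration changes perceived during
klinotaxis runs.

Default field: a conical (linear-in-distance) gradient whose slope is
chosen so that the perceived rate of concentration change, bounded by
``v * slope``, spans roughly +/-0.01 per second -- the range to which the
open-loop stimulus ensembles are calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import _kernels
from .circuit import DT, NO_LESION, CircuitParams, LesionSet

__all__ = [
    "GradientField",
    "Trajectory",
    "run_closed_loop",
    "chemotaxis_index",
    "empirical_cdot_distribution",
    "orientation_info_map",
]


@dataclass(frozen=True)
class GradientField:
    """Radial chemical gradient, decreasing with distance from the peak.

    ``kind`` is "conical" (concentration = peak - slope * r, floored at 0)
    or "gaussian" (peak * exp(-r^2 / (2 scale^2))); ``scale`` is the slope
    (concentration/cm) for the conical form and the length scale (cm) for
    the gaussian form.
    """

    kind: str = "conical"
    peak_position: tuple[float, float] = (0.0, 0.0)
    peak_concentration: float = 2.0
    scale: float = 0.45

    def __post_init__(self) -> None:
        if self.kind not in ("conical", "gaussian"):
            raise ValueError("kind must be 'conical' or 'gaussian'")
        if self.peak_concentration <= 0 or self.scale <= 0:
            raise ValueError("peak concentration and scale must be positive")

    @property
    def _kind_code(self) -> int:
        return 0 if self.kind == "conical" else 1

    def concentration(self, x, y):
        r = np.hypot(
            np.asarray(x, float) - self.peak_position[0],
            np.asarray(y, float) - self.peak_position[1],
        )
        if self.kind == "conical":
            return np.maximum(self.peak_concentration - self.scale * r, 0.0)
        return self.peak_concentration * np.exp(-0.5 * (r / self.scale) ** 2)

    def slope_at(self, r):
        """Magnitude of the radial concentration derivative dC/dr at radius r."""
        r = np.asarray(r, float)
        if self.kind == "conical":
            inside = r < self.peak_concentration / self.scale
            return np.where(inside, self.scale, 0.0)
        return (
            self.peak_concentration
            * r
            / self.scale**2
            * np.exp(-0.5 * (r / self.scale) ** 2)
        )


@dataclass
class Trajectory:
    """Closed-loop run traces (per integration step)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    c: np.ndarray
    d: np.ndarray
    phi: np.ndarray
    dt: float
    truncated: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "x": self.x, "y": self.y, "c": self.c, "d": self.d,
             "phi": self.phi}
        )


def run_closed_loop(
    params: CircuitParams,
    field: GradientField,
    duration: float = 400.0,
    start: tuple[float, float] | None = None,
    start_bearing: float = 0.0,
    seed: int | None = None,
    lesions: LesionSet = NO_LESION,
    arena_radius: float = 10.0,
    dt: float = DT,
) -> Trajectory:
    """Simulate embodied klinotaxis in a gradient field.

    ``start`` defaults to 2 cm from the peak along +x; ``start_bearing`` is
    the initial heading.  With ``seed`` given, the start pose is drawn at
    random (bearing uniform, distance 2 cm) instead.  The run is truncated
    with a warning if the worm leaves the arena.  Deterministic for a fixed
    seed/pose.
    """
    if duration < 2 * params.T:
        raise ValueError("duration should cover at least a few locomotion cycles")
    px, py = field.peak_position
    if seed is not None:
        rng = np.random.default_rng(seed)
        angle = rng.uniform(0.0, 2.0 * np.pi)
        start = (px + 2.0 * np.cos(angle), py + 2.0 * np.sin(angle))
        start_bearing = rng.uniform(0.0, 2.0 * np.pi)
    elif start is None:
        start = (px + 2.0, py)
    n_steps = int(round(duration / dt))
    xs, ys, cs, ds, phis, n_done = _kernels.run_closed_loop_kernel(
        _kernels.pack_params(params),
        params.N,
        params.M,
        dt,
        n_steps,
        float(start[0]),
        float(start[1]),
        float(start_bearing),
        float(px),
        float(py),
        field.peak_concentration,
        field.scale,
        field._kind_code,
        float(arena_radius),
        lesions.block_gap_AIY,
        lesions.block_gap_AIZ,
    )
    truncated = n_done < n_steps
    if truncated:
        warnings.warn(
            f"worm left the arena (radius {arena_radius} cm); run truncated "
            f"after {n_done * dt:.1f} s",
            stacklevel=2,
        )
    sl = slice(0, n_done)
    return Trajectory(
        t=np.arange(n_done) * dt,
        x=xs[sl].copy(),
        y=ys[sl].copy(),
        c=cs[sl].copy(),
        d=ds[sl].copy(),
        phi=phis[sl].copy(),
        dt=dt,
        truncated=truncated,
    )


def chemotaxis_index(traj: Trajectory, field: GradientField) -> float:
    """Gradient-climbing score in [0, 1], the fitness of the search.

    1 - (time-averaged distance to the peak) / (initial distance), clipped
    to [0, 1]: 1 for a worm parked at the peak, 0 for no net approach.
    """
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    px, py = field.peak_position
    dist = np.hypot(traj.x - px, traj.y - py)
    if dist[0] == 0:
        raise ValueError("zero initial distance to the peak")
    return float(np.clip(1.0 - dist.mean() / dist[0], 0.0, 1.0))


def empirical_cdot_distribution(
    params: CircuitParams,
    field: GradientField,
    n_runs: int = 10,
    duration: float = 500.0,
    seed: int = 0,
    n_bins: int = 50,
    dt: float = DT,
):
    """Pooled histogram of perceived concentration-change rates.

    Runs ``n_runs`` klinotaxis simulations from random start poses and
    histograms the per-step concentration change, rescaled to per-second
    units.  Returns (density, bin_edges, samples); the density integrates
    to 1 over the bin widths and the probability masses sum to 1.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    pooled = []
    for i in range(n_runs):
        traj = run_closed_loop(
            params, field, duration=duration, seed=seed + i, dt=dt
        )
        cdot = np.diff(traj.c) / dt
        pooled.append(cdot)
    samples = np.concatenate(pooled)
    lo, hi = samples.min(), samples.max()
    if hi - lo < 1e-12 * max(1.0, abs(lo), abs(hi)):
        # e.g. a flat field: all mass at one value (up to float noise)
        edges = np.array([lo - 0.5, lo + 0.5])
        return np.array([1.0]), edges, samples
    density, edges = np.histogram(samples, bins=n_bins, density=True)
    return density, edges, samples


def orientation_info_map(
    specific_info_vs_cdot: Callable[[np.ndarray], np.ndarray] | tuple,
    field: GradientField,
    v: float = 0.022,
    radius: float = 1.0,
    n_bearings: int = 181,
):
    """Re-parameterize a neck specific-information profile to bearing.

    A worm moving at speed ``v`` with bearing ``beta`` relative to the peak
    direction at radius ``radius`` perceives
    ``cdot = v * dC/dr * cos(beta)``, so beta = 90 degrees maps to
    cdot = 0 and the map is monotone on [0, 180] degrees.  The profile may
    be a callable cdot -> info or a (cdot_grid, info_values) pair
    (interpolated).  Bearings outside [0, 180] fold by symmetry.  Returns
    (bearing_degrees, info).
    """
    if isinstance(specific_info_vs_cdot, tuple):
        grid, vals = specific_info_vs_cdot
        grid = np.asarray(grid, float)
        vals = np.asarray(vals, float)
        ok = np.isfinite(vals)

        def profile(c):
            return np.interp(c, grid[ok], vals[ok])

    else:
        profile = specific_info_vs_cdot
    bearings = np.linspace(0.0, 180.0, n_bearings)
    folded = np.abs(((bearings + 180.0) % 360.0) - 180.0)  # fold into [0, 180]
    slope = float(np.asarray(field.slope_at(radius)))
    # moving toward the peak (bearing 0) means concentration increases
    cdot = v * slope * np.cos(np.deg2rad(folded))
    return bearings, np.asarray(profile(cdot), dtype=float)
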