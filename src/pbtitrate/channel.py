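"""Pore-radius profiling along a channel axis (sphere-probe analysis).

At each step along a straight axis the profiler finds the largest sphere
centered in the plane normal to the axis (within a capped lateral search
disc) that touches no atom: a greedy, locally re-centered approximation
to tunnel analysis, sufficient to localize constrictions such as a side
chain swinging into an open pore.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .structure import Structure


@dataclass
class ChannelProfile:
    axial: np.ndarray  # distance along the axis from start, A
    points: np.ndarray  # (n, 3) re-centered probe positions
    radii: np.ndarray  # clearance radius at each point, A
    search_cap: float
    capped: bool = False  # any radius limited by the search cap

    @property
    def min_radius(self) -> float:
        return float(self.radii.min())

    @property
    def min_position(self) -> float:
        return float(self.axial[int(np.argmin(self.radii))])


@dataclass
class Constriction:
    position: float  # axial coordinate of the narrowest point
    radius: float
    tie: bool = False  # True when multiple points share the minimum


def _clearances(points: np.ndarray, pos: np.ndarray, rad: np.ndarray,
                cap: float) -> np.ndarray:
    """Distance from each probe point to the nearest atom surface."""
    if len(pos) == 0:
        return np.full(len(points), cap)
    d = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2) - rad[None, :]
    return np.minimum(d.min(axis=1), cap)


def _plane_basis(axis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def radius_profile(
    s: Structure,
    start: np.ndarray,
    end: np.ndarray,
    step: float = 0.5,
    lateral_cap: float = 5.0,
    search_cap: float = 10.0,
    lateral_step: float = 0.25,
) -> ChannelProfile:
    """Pore radius along the axis from ``start`` to ``end``.

    At each axial sample the probe center is moved within the normal
    plane (up to ``lateral_cap`` off-axis) to the largest-clearance
    position; the radius is the clearance there, capped at
    ``search_cap``.  A warning is issued when the path leaves the
    structure's bounding box (open ends report the cap).
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if np.allclose(start, end):
        raise ValueError("start and end must differ")
    axis = end - start
    length = float(np.linalg.norm(axis))
    axis /= length
    u, v = _plane_basis(axis)

    pos = s.positions()
    rad = s.radii()
    if len(pos):
        lo, hi = pos.min(axis=0) - 2.0, pos.max(axis=0) + 2.0
        if np.any(start < lo) or np.any(start > hi) or np.any(end < lo) or np.any(end > hi):
            warnings.warn("channel path extends outside the structure; radii capped")

    # polar offset grid in the normal plane (includes the on-axis point)
    offsets = [np.zeros(3)]
    nr = int(round(lateral_cap / lateral_step))
    for ir in range(1, nr + 1):
        r = ir * lateral_step
        nt = max(int(math.ceil(2 * math.pi * r / lateral_step)), 8)
        for it in range(nt):
            t = 2 * math.pi * it / nt
            offsets.append(r * (math.cos(t) * u + math.sin(t) * v))
    offsets = np.array(offsets)

    n_steps = int(math.floor(length / step)) + 1
    axial = np.arange(n_steps) * step
    points = np.empty((n_steps, 3))
    radii = np.empty(n_steps)
    for k, t in enumerate(axial):
        base = start + t * axis
        cand = base[None, :] + offsets
        clear = _clearances(cand, pos, rad, search_cap)
        best = int(np.argmax(clear))
        points[k] = cand[best]
        radii[k] = max(clear[best], 0.0)
    return ChannelProfile(
        axial=axial, points=points, radii=radii, search_cap=search_cap,
        capped=bool(np.any(radii >= search_cap)),
    )


def constriction(profile: ChannelProfile) -> Constriction:
    """Global minimum of the radius curve (first one along the path on ties)."""
    if len(profile.radii) == 0:
        raise ValueError("empty profile")
    rmin = profile.radii.min()
    where = np.flatnonzero(np.abs(profile.radii - rmin) < 1e-9)
    return Constriction(
        position=float(profile.axial[where[0]]),
        radius=float(rmin),
        tie=len(where) > 1,
    )


def compare_profiles(a: ChannelProfile, b: ChannelProfile) -> pd.DataFrame:
    """Per-point radius difference b - a on a shared path parameterization."""
    if len(a.axial) != len(b.axial) or not np.allclose(a.axial, b.axial):
        raise ValueError("profiles have different path parameterizations")
    if not np.all(np.diff(a.axial) > 0):
        raise ValueError("path points out of order")
    df = pd.DataFrame(
        {
            "axial_A": a.axial,
            "radius_a_A": a.radii,
            "radius_b_A": b.radii,
            "difference_A": b.radii - a.radii,
        }
    )
    df["b_narrower"] = df["difference_A"] < 0
    return df


def profile_tsv(profile: ChannelProfile) -> str:
    lines = ["axial_A\tx\ty\tz\tradius_A"]
    for t, p, r in zip(profile.axial, profile.points, profile.radii):
        lines.append(f"{t:.2f}\t{p[0]:.3f}\t{p[1]:.3f}\t{p[2]:.3f}\t{r:.3f}")
    return "\n".join(lines) + "\n"
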