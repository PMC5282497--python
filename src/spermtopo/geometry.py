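"""Analytic ellipsoid geometry for the synthetic nucleus.

The synthetic nucleus is an axis-aligned (optionally rotated) ellipsoid with
semi-axes ``(a, b, c)`` along ``(x, y, z)``; the tail attachment sits at the
``-a`` pole of the long axis and the head apex at ``+a``, so the tail->head
length is ``L = 2a`` and the widest diameter orthogonal to the axis is
``D = 2 max(b, c)``.

The exact point-to-surface distance for interior points is obtained from the
standard Lagrange parametrisation: the foot point of ``q`` (in the ellipsoid
frame) is ``s_i = a_i^2 q_i / (a_i^2 + t)`` where ``t <= 0`` solves
``sum_i (a_i q_i / (a_i^2 + t))^2 = 1``.  The equation is solved with a
vectorised Newton iteration (the function is convex and decreasing in ``t``,
so Newton started at ``t = 0`` converges monotonically); points on a symmetry
axis, where the foot point leaves the parametrisation, fall back to the
closed-form off-axis solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def rotation_matrix_z(theta: float) -> np.ndarray:
    """Right-handed rotation about the z axis by ``theta`` radians."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _distance_on_axis_fallback(q: np.ndarray, axes2: np.ndarray) -> float:
    """Nearest-surface distance when the foot point leaves the main branch.

    Happens for points near a symmetry axis inside the evolute.  For each
    candidate dropped axis ``j`` the foot point has ``s_i = a_i^2 q_i /
    (a_i^2 - a_j^2)`` for ``i != j`` and picks up an off-axis component along
    ``j``; the candidate is feasible when the remaining coordinates fit inside
    the ellipsoid cross-section.
    """
    best = np.inf
    a = np.sqrt(axes2)
    for j in range(3):
        denom = axes2 - axes2[j]
        ok = True
        s = np.zeros(3)
        acc = 0.0
        for i in range(3):
            if i == j:
                continue
            if abs(denom[i]) < 1e-15:
                if abs(q[i]) > 1e-12:
                    ok = False
                    break
                continue
            s[i] = axes2[i] * q[i] / denom[i]
            acc += s[i] ** 2 / axes2[i]
        if not ok or acc > 1.0:
            continue
        s[j] = a[j] * np.sqrt(max(1.0 - acc, 0.0))
        # q[j] ~ 0 on this branch; the off-axis component contributes fully.
        d2 = 0.0
        for i in range(3):
            d2 += (q[i] - s[i]) ** 2 if i != j else s[j] ** 2
        best = min(best, float(np.sqrt(d2)))
    return best


def ellipsoid_interior_distance(q: np.ndarray, semi_axes) -> np.ndarray:
    """Exact distance to the ellipsoid surface for interior points.

    ``q``: (n, 3) points in the ellipsoid frame (centre at origin, axes along
    the coordinate axes).  Points must satisfy ``sum (q_i/a_i)^2 <= 1``.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    axes2 = np.asarray(semi_axes, dtype=float) ** 2
    a_min = float(np.sqrt(axes2.min()))
    w = axes2 * q * q  # a_i^2 q_i^2

    t = np.zeros(len(q))
    floor = -axes2.min() + 1e-12
    for _ in range(80):
        denom = axes2 + t[:, None]
        g = np.sum(w / denom**2, axis=1)
        gp = -2.0 * np.sum(w / denom**3, axis=1)
        safe = np.where(gp == 0.0, -1.0, gp)
        step = np.where(gp != 0, (g - 1.0) / safe, 0.0)
        t = np.maximum(t - step, floor)

    denom = axes2 + t[:, None]
    s = axes2 * q / denom
    d = np.linalg.norm(q - s, axis=1)

    # near-centre points: distance ~ shortest semi-axis
    norm2 = np.sum(q * q / axes2, axis=1)
    central = norm2 < 1e-12
    d[central] = a_min

    # points whose Newton solution hit the domain floor need the fallback
    stuck = (t <= floor + 1e-9) & ~central
    for i in np.where(stuck)[0]:
        fb = _distance_on_axis_fallback(q[i], axes2)
        if np.isfinite(fb):
            d[i] = fb
    return d


@dataclass
class EllipsoidGeometry:
    """Analytic description of a synthetic nucleus."""

    center: np.ndarray  # physical (x, y, z), um
    semi_axes: tuple  # (a, b, c) along the (unrotated) x, y, z axes, um
    rotation: Optional[np.ndarray] = None  # world = center + R @ body

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.semi_axes = tuple(float(v) for v in self.semi_axes)
        if any(v <= 0 for v in self.semi_axes):
            bad = "abc"[int(np.argmin(self.semi_axes))]
            raise ValueError(f"semi-axis {bad} must be positive")
        if self.rotation is not None:
            self.rotation = np.asarray(self.rotation, dtype=float)

    # -- frames ---------------------------------------------------------
    def to_body(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        if self.rotation is not None:
            p = p @ self.rotation  # R^T applied to rows
        return p

    def to_world(self, body: np.ndarray) -> np.ndarray:
        b = np.atleast_2d(np.asarray(body, dtype=float))
        if self.rotation is not None:
            b = b @ self.rotation.T
        return b + self.center

    # -- landmarks ------------------------------------------------------
    @property
    def tail_point(self) -> np.ndarray:
        return self.to_world([-self.semi_axes[0], 0.0, 0.0])[0]

    @property
    def head_point(self) -> np.ndarray:
        return self.to_world([self.semi_axes[0], 0.0, 0.0])[0]

    @property
    def length_L(self) -> float:
        return 2.0 * self.semi_axes[0]

    @property
    def widest_diameter_D(self) -> float:
        return 2.0 * max(self.semi_axes[1], self.semi_axes[2])

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    # -- queries --------------------------------------------------------
    def contains(self, points: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """True for points strictly inside (optionally shrunk) ellipsoid."""
        q = self.to_body(points)
        ax = np.asarray(self.semi_axes) - shrink
        return np.sum((q / ax) ** 2, axis=1) < 1.0

    def distance_to_surface(self, points: np.ndarray) -> np.ndarray:
        """Exact distance from interior points to the ellipsoid surface."""
        q = self.to_body(points)
        return ellipsoid_interior_distance(q, self.semi_axes)

    def axial_position(self, points: np.ndarray) -> np.ndarray:
        """Scalar projection onto the tail->head axis, measured from the tail."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        axis = self.head_point - self.tail_point
        axis = axis / np.linalg.norm(axis)
        return (pts - self.tail_point) @ axis

    def sample_uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform random points inside the ellipsoid (world frame)."""
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
        body = v * r * np.asarray(self.semi_axes)
        return self.to_world(body)
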