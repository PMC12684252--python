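"""Spherocylindrical cell geometry.

A rod-shaped bacterium is modelled as a 3D spherocylinder: a cylinder of
length ``length - 2*radius`` capped by two hemispheres, lying flat in the
imaging plane (the cylinder axis is in the x-y plane at z = 0).  All
lengths are in micrometres; image-plane coordinates follow the camera
convention x = column, y = row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CellGeometry"]


@dataclass(frozen=True)
class CellGeometry:
    """One spherocylindrical cell in the imaging plane.

    Parameters
    ----------
    center : (float, float)
        Mid-point of the cell in the image plane (x, y), micrometres.
    orientation : float
        Angle of the long axis relative to the image x axis, radians.
    length : float
        Pole-to-pole extent, micrometres.  Must satisfy ``length >= 2*radius``.
    radius : float
        Cylinder / cap radius, micrometres.
    """

    center: tuple[float, float]
    orientation: float
    length: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.length < 2 * self.radius:
            raise ValueError("length must be at least 2*radius")

    # -- axis handling ------------------------------------------------

    @property
    def axis_half_length(self) -> float:
        """Half-length of the cylindrical axis segment (pole centres)."""
        return self.length / 2.0 - self.radius

    @property
    def direction(self) -> np.ndarray:
        u = np.array([np.cos(self.orientation), np.sin(self.orientation), 0.0])
        return u

    def axis_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """3D centres of the two hemispherical caps."""
        c = np.array([self.center[0], self.center[1], 0.0])
        u = self.direction
        h = self.axis_half_length
        return c - h * u, c + h * u

    def _axis_distance(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distance from 3D points to the axis segment and the foot points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.array([self.center[0], self.center[1], 0.0])
        u = self.direction
        h = self.axis_half_length
        t = (pts - c) @ u
        t_cl = np.clip(t, -h, h)
        foot = c + t_cl[:, None] * u
        d = np.linalg.norm(pts - foot, axis=1)
        return d, foot

    # -- predicates and transforms ------------------------------------

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Exact membership test for 3D points (shape (3,) or (n, 3))."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        d, _ = self._axis_distance(pts)
        inside = d <= self.radius
        return bool(inside[0]) if single else inside

    def contains_2d(self, points_xy: np.ndarray) -> np.ndarray:
        """Membership of 2D points in the projected capsule outline."""
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        pts3 = np.column_stack([pts, np.zeros(len(pts))])
        d, _ = self._axis_distance(pts3)
        res = d <= self.radius
        return res if np.asarray(points_xy).ndim > 1 else bool(res[0])

    def reflect_inside(self, points: np.ndarray, max_iter: int = 12) -> np.ndarray:
        """Specular reflection of 3D points back through the surface.

        Points already inside are returned unchanged.  After ``max_iter``
        reflections any stragglers are clamped radially just inside the
        surface, so the confinement invariant holds exactly.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        for _ in range(max_iter):
            d, foot = self._axis_distance(pts)
            out = d > self.radius
            if not out.any():
                break
            n = (pts[out] - foot[out]) / d[out, None]
            pts[out] = pts[out] - 2.0 * (d[out] - self.radius)[:, None] * n
        d, foot = self._axis_distance(pts)
        out = d > self.radius
        if out.any():
            n = (pts[out] - foot[out]) / d[out, None]
            pts[out] = foot[out] + self.radius * (1.0 - 1e-12) * n
        return pts if np.asarray(points).ndim > 1 else pts[0]

    # -- analytic quantities ------------------------------------------

    def projected_area(self) -> float:
        """Area of the 2D projection (stadium): 2 r (L - 2r) + pi r^2."""
        return 2.0 * self.radius * (self.length - 2.0 * self.radius) + np.pi * self.radius**2

    def volume(self) -> float:
        r, lc = self.radius, self.length - 2.0 * self.radius
        return np.pi * r**2 * lc + 4.0 / 3.0 * np.pi * r**3

    # -- sampling ------------------------------------------------------

    def sample_volume(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform 3D points inside the spherocylinder (rejection sampling)."""
        out = np.empty((0, 3))
        c = np.array([self.center[0], self.center[1], 0.0])
        u = self.direction
        v = np.array([-u[1], u[0], 0.0])
        w = np.array([0.0, 0.0, 1.0])
        hl = self.length / 2.0
        r = self.radius
        while len(out) < n:
            m = max(2 * (n - len(out)), 64)
            a = rng.uniform(-hl, hl, m)
            b = rng.uniform(-r, r, m)
            cz = rng.uniform(-r, r, m)
            pts = c + a[:, None] * u + b[:, None] * v + cz[:, None] * w
            keep = self.contains(pts)
            out = np.vstack([out, pts[keep]])
        return out[:n]

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform 3D points on the spherocylinder surface (area-weighted)."""
        r = self.radius
        lc = self.length - 2.0 * r
        area_cyl = 2.0 * np.pi * r * lc
        area_caps = 4.0 * np.pi * r**2
        p_cyl = area_cyl / (area_cyl + area_caps)
        c = np.array([self.center[0], self.center[1], 0.0])
        u = self.direction
        v = np.array([-u[1], u[0], 0.0])
        w = np.array([0.0, 0.0, 1.0])
        on_cyl = rng.random(n) < p_cyl
        pts = np.empty((n, 3))
        # cylindrical part
        m = int(on_cyl.sum())
        t = rng.uniform(-lc / 2.0, lc / 2.0, m)
        th = rng.uniform(0, 2 * np.pi, m)
        pts[on_cyl] = c + t[:, None] * u + (r * np.cos(th))[:, None] * v + (r * np.sin(th))[:, None] * w
        # hemispherical caps: uniform on sphere, assigned to the matching cap
        k = n - m
        z = rng.uniform(-1, 1, k)
        phi = rng.uniform(0, 2 * np.pi, k)
        s = np.sqrt(1 - z**2)
        sph = np.column_stack([z, s * np.cos(phi), s * np.sin(phi)])  # (axial, v, w)
        sign = np.where(sph[:, 0] >= 0, 1.0, -1.0)
        ax = sign * (lc / 2.0) + r * sph[:, 0]
        pts[~on_cyl] = c + ax[:, None] * u + (r * sph[:, 1])[:, None] * v + (r * sph[:, 2])[:, None] * w
        return pts
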