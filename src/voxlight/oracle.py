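"""Analytic ray tracing through spheres and spherical lens surfaces.

Exact ray-sphere intersections with Snell refraction and unpolarized
Fresnel bookkeeping provide ground-truth trajectories for the validation
scenes: the refractive sphere (specular reflection of a collimated beam) and
the biconvex lens (focal behavior).  The tracer is deterministic: at every
surface hit it follows the transmitted branch (recording the reflectance R),
or the reflected branch under total internal reflection; the specular
reflection of the *first* hit is available separately for comparing against
Monte Carlo photons that bounced off the surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .optics import BoundaryEvent, fresnel_reflectance, reflect, refract

__all__ = [
    "Sphere",
    "AnalyticScene",
    "sphere_scene",
    "lens_scene",
    "trace_ray",
    "first_hit",
    "specular_reflection",
    "reflected_angle_error",
]

_EPS = 1e-9


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float
    n_in: float
    n_out: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def intersect(self, origin: np.ndarray, direction: np.ndarray) -> float | None:
        """Smallest positive ray parameter of the surface hit, or None."""
        oc = origin - np.asarray(self.center)
        b = float(np.dot(oc, direction))
        c = float(np.dot(oc, oc)) - self.radius ** 2
        disc = b * b - c
        if disc < 0:
            return None
        sq = math.sqrt(disc)
        for t in (-b - sq, -b + sq):
            if t > _EPS:
                return t
        return None

    def outward_normal(self, point: np.ndarray) -> np.ndarray:
        n = point - np.asarray(self.center)
        return n / np.linalg.norm(n)


@dataclass
class AnalyticScene:
    """Spherical surfaces plus a piecewise refractive-index field.

    ``n_at(point)`` evaluates the medium's index at a point; it resolves
    which side of each surface the ray is on, which keeps overlapping-sphere
    solids (the biconvex lens) unambiguous.
    """

    surfaces: list[Sphere]
    n_ambient: float
    n_at: Callable[[np.ndarray], float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_at is None:
            def _default(point: np.ndarray) -> float:
                for s in self.surfaces:
                    if np.linalg.norm(point - np.asarray(s.center)) < s.radius:
                        return s.n_in
                return self.n_ambient
            self.n_at = _default


def sphere_scene(center: Sequence[float], radius: float,
                 n_in: float, n_out: float) -> AnalyticScene:
    return AnalyticScene([Sphere(tuple(center), radius, n_in, n_out)], n_out)


def lens_scene(center: Sequence[float], r1: float, r2: float, thickness: float,
               n_lens: float, n_ambient: float) -> AnalyticScene:
    """Biconvex lens (axis along z) as the intersection of two balls."""
    cx, cy, cz = center
    s1 = Sphere((cx, cy, cz - thickness / 2.0 + r1), r1, n_lens, n_ambient)
    s2 = Sphere((cx, cy, cz + thickness / 2.0 - r2), r2, n_lens, n_ambient)

    def n_at(point: np.ndarray) -> float:
        in1 = np.linalg.norm(point - np.asarray(s1.center)) < r1
        in2 = np.linalg.norm(point - np.asarray(s2.center)) < r2
        return n_lens if (in1 and in2) else n_ambient

    return AnalyticScene([s1, s2], n_ambient, n_at)


def first_hit(origin: Sequence[float], direction: Sequence[float],
              scene: AnalyticScene) -> tuple[np.ndarray, Sphere, float] | None:
    """Nearest surface intersection of the ray, or None."""
    o = np.asarray(origin, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    best = None
    for s in scene.surfaces:
        t = s.intersect(o, d)
        if t is not None and (best is None or t < best[2]):
            best = (o + t * d, s, t)
    return best


def trace_ray(origin: Sequence[float], direction: Sequence[float],
              scene: AnalyticScene, max_events: int = 16,
              t_max: float = 1e3) -> dict:
    """Deterministic transmitted-branch trace.

    Returns a dict with the polyline vertices, the final direction, and one
    record per surface event: (theta_i, theta_t, R).  Under total internal
    reflection the reflected branch is followed (theta_t = nan, R = 1).
    """
    o = np.asarray(origin, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    vertices = [o.copy()]
    events = []
    for _ in range(max_events):
        hit = first_hit(o, d, scene)
        if hit is None:
            vertices.append(o + t_max * d)
            break
        point, surface, _t = hit
        # indices on the two sides of the crossing, sampled just off the surface
        n_before = scene.n_at(point - 1e-6 * d)
        n_after = scene.n_at(point + 1e-6 * d)
        if n_before == n_after:
            # null crossing (e.g. the far wall of one ball of a lens while
            # outside the other): no optical surface here
            o = point + 1e-9 * d
            continue
        normal = surface.outward_normal(point)
        event = BoundaryEvent(d, normal, n_before, n_after)
        r_prob = fresnel_reflectance(event)
        theta_i = math.degrees(math.acos(event.cos_incidence))
        if r_prob >= 1.0:
            d = reflect(event)
            theta_t = math.nan
        else:
            d_new = refract(event)
            theta_t = math.degrees(math.acos(
                float(np.clip(-np.dot(d_new, event.normal), -1.0, 1.0))))
            d = d_new
        events.append({"theta_i": theta_i, "theta_t": theta_t, "R": r_prob,
                       "point": point.copy()})
        o = point + 1e-9 * d
        vertices.append(point.copy())
    return {"vertices": np.asarray(vertices), "direction": d, "events": events}


def specular_reflection(origin: Sequence[float], direction: Sequence[float],
                        scene: AnalyticScene) -> np.ndarray | None:
    """Analytic specular reflection at the ray's first surface hit."""
    hit = first_hit(origin, direction, scene)
    if hit is None:
        return None
    point, surface, _ = hit
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    n_before = scene.n_at(point - 1e-6 * d)
    n_after = scene.n_at(point + 1e-6 * d)
    event = BoundaryEvent(d, surface.outward_normal(point), n_before, n_after)
    return reflect(event)


def reflected_angle_error(escape_record, scene: AnalyticScene,
                          single_bounce_only: bool = True
                          ) -> tuple[np.ndarray, int]:
    """Angle (degrees) between each escaped photon's direction and the
    analytic specular reflection of its own launch ray.

    By default only single-bounce photons (one Fresnel reflection, no
    transmission) are compared — those are the reflected beam.  Photons whose
    launch ray misses every analytic surface are excluded and counted.
    """
    table = escape_record.table
    if single_bounce_only:
        table = table[(table["n_reflect"] == 1) & (table["n_transmit"] == 0)]
    origins = table[["launch_x_cm", "launch_y_cm", "launch_z_cm"]].to_numpy()
    dirs_launch = table[["launch_ux", "launch_uy", "launch_uz"]].to_numpy()
    dirs_mc = table[["ux", "uy", "uz"]].to_numpy()
    errors = []
    excluded = 0
    for o, dl, dm in zip(origins, dirs_launch, dirs_mc):
        ref = specular_reflection(o, dl, scene)
        if ref is None:
            excluded += 1
            continue
        cosang = float(np.clip(np.dot(ref, dm / np.linalg.norm(dm)), -1.0, 1.0))
        errors.append(math.degrees(math.acos(cosang)))
    return np.asarray(errors), excluded
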