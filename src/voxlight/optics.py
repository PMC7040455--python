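"""Vector Fresnel/Snell optics for unpolarized light at a boundary.

Conventions: the incident direction ``d`` and boundary normal ``n`` are unit
vectors, with the normal oriented *against* the incident ray
(``dot(n, d) <= 0``) before any reflectance or refraction is evaluated.
Reflectance is the unpolarized average of the s- and p-polarized Fresnel
intensity coefficients; at or beyond the critical angle the reflectance is 1
(total internal reflection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BoundaryEvent",
    "orient_normal",
    "fresnel_reflectance",
    "reflect",
    "refract",
]


def _unit(v: Sequence[float], name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError(f"{name} must be a nonzero vector")
    return v / norm


def orient_normal(normal: Sequence[float], incident_dir: Sequence[float]) -> np.ndarray:
    """Return the normal (or its negation) facing the incoming photon."""
    n = _unit(normal, "normal")
    d = _unit(incident_dir, "incident direction")
    return -n if float(np.dot(n, d)) > 0.0 else n


@dataclass
class BoundaryEvent:
    """An oriented refractive-boundary encounter."""

    incident_dir: np.ndarray
    normal: np.ndarray
    n1: float
    n2: float

    def __post_init__(self) -> None:
        self.incident_dir = _unit(self.incident_dir, "incident direction")
        self.normal = orient_normal(self.normal, self.incident_dir)
        if self.n1 < 1.0 or self.n2 < 1.0:
            raise ValueError("refractive indices must be >= 1")

    @property
    def cos_incidence(self) -> float:
        return float(np.clip(-np.dot(self.incident_dir, self.normal), 0.0, 1.0))


def fresnel_reflectance(event: BoundaryEvent) -> float:
    """Unpolarized reflectance R = (Rs + Rp) / 2, with R = 1 under TIR."""
    n1, n2 = event.n1, event.n2
    if n1 == n2:
        return 0.0
    ci = event.cos_incidence
    sin_t2 = (n1 / n2) ** 2 * (1.0 - ci * ci)
    if sin_t2 >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - sin_t2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return float(0.5 * (rs * rs + rp * rp))


def reflect(event: BoundaryEvent) -> np.ndarray:
    """Specular reflection d - 2 (d . n) n."""
    d, n = event.incident_dir, event.normal
    r = d - 2.0 * np.dot(d, n) * n
    return r / np.linalg.norm(r)


def refract(event: BoundaryEvent) -> np.ndarray:
    """Transmitted direction from the vector Snell law.

    Raises on total internal reflection; callers must branch on
    :func:`fresnel_reflectance` first.
    """
    n1, n2 = event.n1, event.n2
    d, n = event.incident_dir, event.normal
    if n1 == n2:
        return d.copy()
    eta = n1 / n2
    ci = event.cos_incidence
    sin_t2 = eta * eta * (1.0 - ci * ci)
    if sin_t2 >= 1.0:
        raise ValueError("total internal reflection: no transmitted ray")
    ct = np.sqrt(1.0 - sin_t2)
    t = eta * d + (eta * ci - ct) * n
    return t / np.linalg.norm(t)
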