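"""Masked trilinear interpolation of the boundary-normal field.

When a photon is about to cross a mismatched voxel face, the stored normals
of the eight voxels whose centroids bracket the crossing point are blended
trilinearly — but only vertices on the photon's own side of the boundary
(same refractive index as the photon's current voxel) contribute.  Masked
vertices are simply zeroed, not re-weighted; the final unit normalization
absorbs the lost magnitude.

All positions here are in voxel coordinates (world cm / dx), with voxel
(i, j, k) spanning [i, i+1) x [j, j+1) x [k, k+1) and centred at
(i+0.5, j+0.5, k+0.5).  Rounding is half-away-from-zero so a query exactly at
a voxel centroid has fractions (0, 0, 0) and returns that voxel's own vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .normalmap import NormalMap
from .phantoms import LabeledVolume, MediumTable

__all__ = [
    "InterpolationCube",
    "fractional_coords",
    "build_cube",
    "interpolate_normal",
]

ZERO_TOL = 1e-9


def _round_half_away(x: float) -> float:
    return np.floor(np.abs(x) + 0.5) * np.sign(x) if x < 0 else np.floor(x + 0.5)


def fractional_coords(pos: Sequence[float]) -> tuple[float, float, float]:
    """Interpolation fractions (xd, yd, zd) in [0, 1] for a voxel-space point.

    Each fraction is ``coord - round(coord) + 0.5`` with round =
    half-away-from-zero, so a voxel centroid gives 0 and a voxel face gives
    0.5 (midway between the two adjacent centroids).
    """
    out = []
    for c in pos:
        d = float(c) - _round_half_away(float(c)) + 0.5
        if not -1e-12 <= d <= 1.0 + 1e-12:
            raise ValueError(f"fraction {d} out of [0, 1] for coordinate {c}")
        out.append(min(max(d, 0.0), 1.0))
    return tuple(out)  # type: ignore[return-value]


@dataclass
class InterpolationCube:
    """Eight bracketing vertex vectors, same-medium mask, and fractions.

    ``vertex_vectors[a, b, c]`` is the stored normal at the voxel centroid
    offset (a, b, c) from the cube's lower corner; ``vertex_mask[a, b, c]``
    is True iff that voxel shares the refractive index of the photon's
    current voxel (vertices outside the grid are False).
    """

    vertex_vectors: np.ndarray  # (2, 2, 2, 3)
    vertex_mask: np.ndarray     # (2, 2, 2) bool
    fractions: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.vertex_vectors = np.asarray(self.vertex_vectors, dtype=np.float64)
        self.vertex_mask = np.asarray(self.vertex_mask, dtype=bool)
        if self.vertex_vectors.shape != (2, 2, 2, 3):
            raise ValueError("vertex_vectors must have shape (2, 2, 2, 3)")
        if self.vertex_mask.shape != (2, 2, 2):
            raise ValueError("vertex_mask must have shape (2, 2, 2)")
        for f in self.fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")


def build_cube(pos: Sequence[float], volume: LabeledVolume, media: MediumTable,
               normal_map: NormalMap,
               current_voxel: Sequence[int] | None = None) -> InterpolationCube:
    """Assemble the interpolation cube around a voxel-space position.

    The cube's vertices are the centroids of the eight voxels bracketing
    ``pos`` (lower corner index = round(coord) - 1 per axis).  The mask keeps
    only vertices whose medium has the same refractive index as the photon's
    current voxel — by default the voxel containing ``pos``, which is
    ambiguous exactly on a face, so transport passes the pre-crossing voxel
    explicitly.
    """
    shape = volume.shape
    p = [float(c) for c in pos]
    for c, n in zip(p, shape):
        if not 0.0 <= c <= n:
            raise ValueError(f"position {pos} outside grid of shape {shape}")
    if current_voxel is None:
        current_voxel = [min(int(np.floor(c)), n - 1) for c, n in zip(p, shape)]
    ci, cj, ck = (int(v) for v in current_voxel)
    n_of_label, _, _, _ = media.property_arrays()
    n_cur = n_of_label[volume.labels[ci, cj, ck]]

    lower = [int(_round_half_away(c)) - 1 for c in p]
    vectors = np.zeros((2, 2, 2, 3))
    mask = np.zeros((2, 2, 2), dtype=bool)
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                i, j, k = lower[0] + a, lower[1] + b, lower[2] + c
                if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
                    continue
                if n_of_label[volume.labels[i, j, k]] == n_cur:
                    mask[a, b, c] = True
                    vectors[a, b, c] = (normal_map.gx[i, j, k],
                                        normal_map.gy[i, j, k],
                                        normal_map.gz[i, j, k])
    return InterpolationCube(vectors, mask, fractional_coords(p))


def interpolate_normal(cube: InterpolationCube) -> np.ndarray:
    """Masked trilinear blend of the cube's vertex vectors.

    Applied independently to the x, y and z components; the blend is
    normalized to unit length, or the zero vector is returned when the
    masked blend (nearly) vanishes so the caller can fall back to the stored
    voxel normal or the facet normal.
    """
    xd, yd, zd = cube.fractions
    v = cube.vertex_vectors * cube.vertex_mask[..., None]
    c00 = v[0, 0, 0] * (1 - xd) + v[1, 0, 0] * xd
    c01 = v[0, 0, 1] * (1 - xd) + v[1, 0, 1] * xd
    c10 = v[0, 1, 0] * (1 - xd) + v[1, 1, 0] * xd
    c11 = v[0, 1, 1] * (1 - xd) + v[1, 1, 1] * xd
    c0 = c00 * (1 - yd) + c10 * yd
    c1 = c01 * (1 - yd) + c11 * yd
    c = c0 * (1 - zd) + c1 * zd
    norm = np.linalg.norm(c)
    if norm < ZERO_TOL:
        return np.zeros(3)
    return c / norm
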