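"""Labeled voxel phantoms and optical-property tables.

A simulation domain is a cubic-voxel grid of small integer labels
(:class:`LabeledVolume`) plus a :class:`MediumTable` mapping each label to the
optical properties (n, mua, mus, g) of the medium it stands for.  All
geometric containment tests use voxel *centroids*: voxel (i, j, k) is centred
at ((i + 0.5) dx, (j + 0.5) dx, (k + 0.5) dx) in world (cm) coordinates, the
same convention the normal-field interpolation uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Medium",
    "MediumTable",
    "LabeledVolume",
    "make_slab",
    "make_sphere",
    "make_biconvex_lens",
]


@dataclass(frozen=True)
class Medium:
    """Optical properties of one labeled medium.

    Parameters
    ----------
    label : int
        Integer voxel label.
    n : float
        Refractive index (dimensionless, >= 1).
    mua : float
        Absorption coefficient, cm^-1.
    mus : float
        Scattering coefficient, cm^-1.
    g : float
        Henyey-Greenstein anisotropy, in (-1, 1).
    """

    label: int
    n: float
    mua: float = 0.0
    mus: float = 0.0
    g: float = 0.0

    def __post_init__(self) -> None:
        if self.label < 0:
            raise ValueError(f"label must be non-negative, got {self.label}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if self.mua < 0.0 or self.mus < 0.0:
            raise ValueError("mua and mus must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g}")


class MediumTable:
    """Ordered label -> (n, mua, mus, g) lookup with unique labels."""

    def __init__(self, entries: Iterable[Medium]):
        self._entries: dict[int, Medium] = {}
        for m in entries:
            if m.label in self._entries:
                raise ValueError(f"duplicate label {m.label} in medium table")
            self._entries[m.label] = m
        if not self._entries:
            raise ValueError("medium table must contain at least one entry")

    @classmethod
    def from_rows(cls, rows: Iterable[Sequence[float]]) -> "MediumTable":
        """Build from (label, n, mua, mus, g) rows."""
        return cls(Medium(int(r[0]), *map(float, r[1:])) for r in rows)

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: int) -> bool:
        return int(label) in self._entries

    def __getitem__(self, label: int) -> Medium:
        try:
            return self._entries[int(label)]
        except KeyError:
            raise KeyError(f"label {label} missing from medium table") from None

    @property
    def labels(self) -> list[int]:
        return list(self._entries)

    def property_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Dense (n, mua, mus, g) arrays indexed directly by label value.

        Unused label slots are filled with NaN so an out-of-table lookup
        poisons the result instead of silently succeeding.
        """
        size = max(self._entries) + 1
        n = np.full(size, np.nan)
        mua = np.full(size, np.nan)
        mus = np.full(size, np.nan)
        g = np.full(size, np.nan)
        for m in self:
            n[m.label] = m.n
            mua[m.label] = m.mua
            mus[m.label] = m.mus
            g[m.label] = m.g
        return n, mua, mus, g

    def to_rows(self) -> list[list[float]]:
        return [[m.label, m.n, m.mua, m.mus, m.g] for m in self]


@dataclass
class LabeledVolume:
    """3-D integer label grid with cubic voxels of edge length ``dx`` (cm)."""

    labels: np.ndarray
    dx: float
    media: MediumTable | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if self.dx <= 0:
            raise ValueError(f"voxel edge length dx must be positive, got {self.dx}")
        if min(self.labels.shape) < 3:
            raise ValueError("each axis needs at least 3 voxels (Sobel support)")
        if self.media is not None:
            self.validate_media(self.media)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def validate_media(self, media: MediumTable) -> None:
        present = np.unique(self.labels)
        for lab in present:
            if int(lab) not in media:
                raise ValueError(f"label {int(lab)} present in volume but missing "
                                 "from medium table")

    def centroid_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World (cm) centroid coordinates along each axis."""
        return tuple((np.arange(n) + 0.5) * self.dx for n in self.shape)  # type: ignore[return-value]


def _centroid_grids(shape: tuple[int, int, int], dx: float):
    x = (np.arange(shape[0]) + 0.5) * dx
    y = (np.arange(shape[1]) + 0.5) * dx
    z = (np.arange(shape[2]) + 0.5) * dx
    return (x[:, None, None], y[None, :, None], z[None, None, :])


def make_slab(shape: tuple[int, int, int], dx: float, z_interface: float,
              label_top: int = 1, label_bottom: int = 2,
              media: MediumTable | None = None) -> LabeledVolume:
    """Two-layer slab split by the plane z = ``z_interface`` (cm).

    Voxels whose centroid has z <= z_interface get ``label_top``; the rest
    get ``label_bottom`` (a centroid exactly on the interface counts as top,
    so an interface at the first centroid depth yields one top layer).
    """
    nz = shape[2]
    if not 0.0 < z_interface < nz * dx:
        raise ValueError(
            f"z_interface must lie strictly inside the grid (0, {nz * dx:g}) cm, "
            f"got {z_interface:g}")
    z = (np.arange(nz) + 0.5) * dx
    col = np.where(z <= z_interface, label_top, label_bottom).astype(np.uint8)
    labels = np.broadcast_to(col[None, None, :], shape).copy()
    return LabeledVolume(labels, dx, media)


def make_sphere(shape: tuple[int, int, int], dx: float,
                center: Sequence[float], radius: float,
                label_in: int = 1, label_out: int = 0,
                media: MediumTable | None = None) -> LabeledVolume:
    """Sphere of ``radius`` cm centred at ``center`` (cm).

    A voxel is labeled ``label_in`` iff its centroid lies strictly inside the
    sphere.
    """
    if radius <= dx:
        raise ValueError(f"radius ({radius:g} cm) must exceed one voxel ({dx:g} cm)")
    x, y, z = _centroid_grids(shape, dx)
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    labels = np.where(r2 < radius * radius, label_in, label_out).astype(np.uint8)
    return LabeledVolume(labels, dx, media)


def make_biconvex_lens(shape: tuple[int, int, int], dx: float,
                       center: Sequence[float], r1: float, r2: float,
                       thickness: float, aperture: float,
                       label_lens: int = 1, label_ambient: int = 0,
                       media: MediumTable | None = None) -> LabeledVolume:
    """Biconvex spherical lens with its optical axis along z.

    The lens is the intersection of two balls (surface radii ``r1`` upper /
    ``r2`` lower, centre thickness ``thickness`` along the axis) clipped to a
    cylinder of diameter ``aperture``; ``center`` (cm) is the mid-point of the
    lens on its axis.  A voxel is labeled ``label_lens`` iff its centroid lies
    inside that solid.
    """
    half_ap = aperture / 2.0
    if r1 < half_ap or r2 < half_ap:
        raise ValueError("surface radii must be at least half the aperture "
                         f"(r1={r1:g}, r2={r2:g}, aperture/2={half_ap:g})")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    cx, cy, cz = center
    # ball centres on the axis: upper surface bulges toward -z, lower toward +z
    c1z = cz - thickness / 2.0 + r1
    c2z = cz + thickness / 2.0 - r2
    x, y, z = _centroid_grids(shape, dx)
    rho2 = (x - cx) ** 2 + (y - cy) ** 2
    in_ball1 = rho2 + (z - c1z) ** 2 < r1 * r1
    in_ball2 = rho2 + (z - c2z) ** 2 < r2 * r2
    in_cyl = rho2 < half_ap * half_ap
    labels = np.where(in_ball1 & in_ball2 & in_cyl, label_lens,
                      label_ambient).astype(np.uint8)
    return LabeledVolume(labels, dx, media)
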