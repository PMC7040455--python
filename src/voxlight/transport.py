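"""Monte Carlo photon transport through a labeled voxel volume.

The loop is the canonical hop/drop/spin scheme with statistical weights:
a dimensionless step ``s = -ln(xi)`` is consumed across voxels as partial
paths ``mu_t * l`` (so heterogeneous media are sampled without bias), a
fraction ``mu_a / mu_t`` of the weight is deposited at each interaction,
directions are redrawn from the Henyey-Greenstein phase function, and
low-weight photons play Russian roulette.  Voxels with ``mu_t = 0`` (the
clear media of the sphere/lens validation scenes) are traversed
ballistically without consuming step.

At every voxel-face crossing the refractive indices of the two voxels are
compared; on a mismatch an unpolarized Fresnel draw decides specular
reflection versus Snell refraction, with the boundary normal taken from the
configured mode: the axis-aligned facet normal, the stored smoothed surface
normal of the pre-crossing voxel, or the masked trilinear interpolation of
same-medium normals at the crossing point.  ``matched`` disables Fresnel
handling entirely.

:func:`run` drives the compiled kernel; the module-level ``hop`` / ``drop``
/ ``spin`` / ``cross_boundary`` operations and :func:`trace_photon` form a
pure-Python reference stepper that consumes the exact same random stream,
used to cross-check the kernel in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernel
from ._kernel import (E_FACE, E_NREFL, E_NTRANS, E_W, E_X, E_UX, NUDGE,
                      run_kernel)
from .normalmap import NormalMap
from .optics import BoundaryEvent, fresnel_reflectance, orient_normal, reflect, refract
from .phantoms import LabeledVolume, MediumTable
from .record_io import EscapeRecord, FluenceGrid

__all__ = [
    "Photon",
    "SourceSpec",
    "SimulationConfig",
    "MODES",
    "launch",
    "hop",
    "drop",
    "spin",
    "get_boundary_normal",
    "cross_boundary",
    "roulette",
    "trace_photon",
    "run",
    "XorShiftRNG",
]

MODES = {"matched": 0, "facet": 1, "surface": 2, "interp": 3}


class XorShiftRNG:
    """Pure-Python mirror of the kernel's per-photon xorshift64* stream."""

    def __init__(self, seed: int, index: int = 0):
        with np.errstate(over="ignore"):  # uint64 wrap-around is the point
            golden = np.uint64(0x9E3779B97F4A7C15)
            z = (np.uint64(seed) + np.uint64(1)) * golden \
                + (np.uint64(index) + np.uint64(1)) * golden
            z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
            z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
            z = z ^ (z >> np.uint64(31))
        self._s = z if z != 0 else golden

    def random(self) -> float:
        with np.errstate(over="ignore"):
            s = self._s
            s ^= s >> np.uint64(12)
            s ^= s << np.uint64(25)
            s ^= s >> np.uint64(27)
            self._s = s
            return float((s * np.uint64(2685821657736338717)) >> np.uint64(11)) \
                * (1.0 / 9007199254740992.0)


@dataclass
class Photon:
    """A photon packet in voxel coordinates with statistical weight W."""

    pos: np.ndarray
    dir: np.ndarray
    weight: float = 1.0
    alive: bool = True
    n_reflect: int = 0
    n_transmit: int = 0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.float64)
        self.dir = np.asarray(self.dir, dtype=np.float64)
        norm = np.linalg.norm(self.dir)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("photon direction must be a unit vector")
        if not 0.0 < self.weight <= 1.0 + 1e-12:
            raise ValueError("photon weight must lie in (0, 1]")


@dataclass(frozen=True)
class SourceSpec:
    """Collimated disk source: uniform over a disk of ``radius`` cm normal
    to ``direction``, all photons launched along ``direction``.  Radius 0 is
    a pencil beam."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius: float = 0.0
    kind: str = "collimated_disk"

    def __post_init__(self) -> None:
        if self.kind != "collimated_disk":
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.radius < 0:
            raise ValueError("source radius must be >= 0")
        d = np.linalg.norm(self.direction)
        if abs(d - 1.0) > 1e-6:
            raise ValueError("source direction must be a unit vector")


@dataclass(frozen=True)
class SimulationConfig:
    n_photons: int
    mode: str = "interp"
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 10.0
    source: SourceSpec = field(default=SourceSpec((0.0, 0.0, 0.0), (0.0, 0.0, 1.0)))

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {sorted(MODES)}, got {self.mode!r}")
        if not 0.0 < self.roulette_threshold < 1.0:
            raise ValueError("roulette threshold must lie in (0, 1)")
        if self.roulette_survival <= 1.0:
            raise ValueError("roulette survival multiplier must exceed 1")


def launch(source: SourceSpec, rng, dx: float,
           shape: Sequence[int] | None = None) -> Photon:
    """Sample one photon from the source (position in voxel coordinates)."""
    ox, oy, oz = (c / dx for c in source.origin)
    if shape is not None:
        for c, n in zip((ox, oy, oz), shape):
            if not 0.0 <= c <= n:
                raise ValueError("source origin lies outside the grid")
    d = np.asarray(source.direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    pos = np.array([ox, oy, oz])
    if source.radius > 0.0:
        v = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, v)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        r = (source.radius / dx) * math.sqrt(rng.random())
        th = 2.0 * math.pi * rng.random()
        pos = pos + r * math.cos(th) * e1 + r * math.sin(th) * e2
    pos = pos + 1e-6 * d
    return Photon(pos, d, 1.0)


def _face_distance(pos: np.ndarray, direction: np.ndarray,
                   voxel: tuple[int, int, int]) -> tuple[float, int, int]:
    best = 1e30
    axis = 0
    sgn = 1
    for a in range(3):
        u = direction[a]
        if u > 1e-12:
            t = (voxel[a] + 1 - pos[a]) / u
            s = 1
        elif u < -1e-12:
            t = (voxel[a] - pos[a]) / u
            s = -1
        else:
            continue
        if t < best:
            best = t
            axis = a
            sgn = s
    return best, axis, sgn


def hop(photon: Photon, volume: LabeledVolume, media: MediumTable, rng,
        sleft: float = 0.0) -> tuple[Photon, str, float, int, int]:
    """Advance the photon to its next interaction site or voxel face.

    Returns ``(photon, event, sleft, axis, sgn)`` where event is one of
    ``"scatter"`` (step exhausted inside the voxel), ``"face"`` (reached a
    voxel face; caller inspects the neighbor for mismatch/exit) and the
    remaining dimensionless step is carried across faces.
    """
    if not photon.alive:
        raise ValueError("cannot hop a dead photon")
    voxel = tuple(int(math.floor(c)) for c in photon.pos)
    lab = int(volume.labels[voxel])
    m = media[lab]
    mut = m.mua + m.mus
    tface, axis, sgn = _face_distance(photon.pos, photon.dir, voxel)
    if mut > 0.0:
        if sleft <= 0.0:
            sleft = -math.log(1.0 - rng.random())
        tint = sleft / (mut * volume.dx)
        if tint <= tface:
            photon.pos = photon.pos + tint * photon.dir
            return photon, "scatter", 0.0, axis, sgn
        sleft -= tface * mut * volume.dx
    photon.pos = photon.pos + tface * photon.dir
    photon.pos[axis] = float(voxel[axis] + 1) if sgn > 0 else float(voxel[axis])
    if not np.isfinite(photon.pos).all():
        raise FloatingPointError(f"non-finite photon position {photon.pos}")
    return photon, "face", sleft, axis, sgn


def drop(photon: Photon, medium) -> tuple[Photon, float]:
    """Deposit the absorbed weight fraction mua/mut at an interaction."""
    mut = medium.mua + medium.mus
    if mut <= 0.0:
        raise ValueError("drop requires a voxel with mu_t > 0")
    dw = photon.weight * medium.mua / mut
    photon.weight -= dw
    return photon, dw


def spin(photon: Photon, g: float, rng) -> Photon:
    """Redraw the direction from the Henyey-Greenstein phase function."""
    if abs(g) >= 1.0:
        raise ValueError("anisotropy |g| must be < 1")
    ct = _kernel._hg_cos(g, rng.random())
    phi = 2.0 * math.pi * rng.random()
    photon.dir = np.array(_kernel._spin_dir(*photon.dir, ct, phi))
    return photon


def get_boundary_normal(photon: Photon, mode: str, volume: LabeledVolume,
                        media: MediumTable, normal_map: NormalMap | None,
                        axis: int, sgn: int,
                        current_voxel: tuple[int, int, int]) -> np.ndarray:
    """Boundary normal for the face being crossed, oriented against the
    photon, with the zero-vector fallback chain interp -> surface -> facet."""
    if mode == "matched":
        raise RuntimeError("matched mode performs no boundary handling")
    facet = np.zeros(3)
    facet[axis] = -float(sgn)
    normal = facet
    if mode in ("surface", "interp"):
        if normal_map is None:
            raise ValueError(f"mode {mode!r} requires a normal map")
        stored = np.array([normal_map.gx[current_voxel],
                           normal_map.gy[current_voxel],
                           normal_map.gz[current_voxel]], dtype=np.float64)
        if mode == "interp":
            cand = np.array(_kernel._interp_normal(
                normal_map.gx, normal_map.gy, normal_map.gz, volume.labels,
                media.property_arrays()[0], *photon.pos, *current_voxel))
            if np.any(cand != 0.0):
                normal = cand
            elif np.any(stored != 0.0):
                normal = stored
        elif np.any(stored != 0.0):
            normal = stored
    return orient_normal(normal, photon.dir)


def cross_boundary(photon: Photon, normal: np.ndarray, n1: float, n2: float,
                   rng) -> tuple[Photon, bool]:
    """Single-draw probabilistic Fresnel split: reflect or refract in place.

    Returns ``(photon, reflected)``; the weight is never split.
    """
    event = BoundaryEvent(photon.dir, normal, n1, n2)
    if rng.random() <= fresnel_reflectance(event):
        photon.dir = reflect(event)
        photon.n_reflect += 1
        return photon, True
    photon.dir = refract(event)
    photon.n_transmit += 1
    return photon, False


def roulette(photon: Photon, cfg: SimulationConfig, rng) -> Photon:
    """Unbiased low-weight termination: survive with probability 1/m at m
    times the weight."""
    if photon.weight >= cfg.roulette_threshold:
        return photon
    if rng.random() <= 1.0 / cfg.roulette_survival:
        photon.weight *= cfg.roulette_survival
    else:
        photon.alive = False
    return photon


def trace_photon(volume: LabeledVolume, media: MediumTable,
                 normal_map: NormalMap | None, photon: Photon,
                 cfg: SimulationConfig, rng,
                 fluence: np.ndarray | None = None,
                 max_events: int = 1_000_000) -> dict:
    """Pure-Python reference trace of one photon (mirrors the kernel).

    Returns a summary dict with the terminal state; used for validation, not
    for production runs.
    """
    shape = volume.shape
    mode = cfg.mode
    sleft = 0.0
    out = {"escaped": False, "face": -1, "deposited": 0.0}
    for _ in range(max_events):
        voxel = tuple(int(math.floor(c)) for c in photon.pos)
        if not all(0 <= v < n for v, n in zip(voxel, shape)):
            break
        lab = int(volume.labels[voxel])
        m = media[lab]
        photon, event, sleft, axis, sgn = hop(photon, volume, media, rng, sleft)
        if event == "scatter":
            photon, dw = drop(photon, m)
            out["deposited"] += dw
            if fluence is not None:
                fluence[voxel] += dw
            photon = spin(photon, m.g, rng)
            if photon.weight < cfg.roulette_threshold:
                photon = roulette(photon, cfg, rng)
                if not photon.alive:
                    break
            continue
        nxt = list(voxel)
        nxt[axis] += sgn
        if not all(0 <= v < n for v, n in zip(nxt, shape)):
            out["escaped"] = True
            out["face"] = 2 * axis + (1 if sgn > 0 else 0)
            break
        n1 = m.n
        n2 = media[int(volume.labels[tuple(nxt)])].n
        if mode != "matched" and n1 != n2:
            normal = get_boundary_normal(photon, mode, volume, media,
                                         normal_map, axis, sgn, voxel)
            photon, _ = cross_boundary(photon, normal, n1, n2, rng)
        photon.pos = photon.pos + NUDGE * photon.dir
    out["photon"] = photon
    return out


def run(volume: LabeledVolume, media: MediumTable,
        normal_map: NormalMap | None, cfg: SimulationConfig
        ) -> tuple[FluenceGrid, EscapeRecord]:
    """Run the full simulation and return fluence and escape records.

    The fluence grid is normalized voxel-wise to W/cm^2 per W delivered,
    ``phi = deposited / (mu_a * dx^3 * n_photons)`` (voxels of zero-
    absorption media keep zero).  The escape record has one row per escaped
    photon with exit face, position (cm), direction, weight, and the
    photon's Fresnel reflection/transmission counts; launch positions are
    returned alongside so each escape can be paired with its launch ray.
    """
    volume.validate_media(media)
    if cfg.mode in ("surface", "interp"):
        if normal_map is None:
            raise ValueError(f"mode {cfg.mode!r} requires a normal map")
        if normal_map.shape != volume.shape:
            raise ValueError("normal map shape does not match volume")
    if normal_map is None:
        normal_map = NormalMap.zeros(volume.shape)
    nv, muav, musv, gv = media.property_arrays()
    dx = volume.dx
    src = cfg.source
    origin_vox = tuple(c / dx for c in src.origin)
    for c, n in zip(origin_vox, volume.shape):
        if not 0.0 <= c <= n:
            raise ValueError("source origin lies outside the grid")
    d = np.asarray(src.direction, dtype=np.float64)
    d = d / np.linalg.norm(d)

    fluence_raw = np.zeros(volume.shape, dtype=np.float64)
    esc = np.zeros((cfg.n_photons, 10), dtype=np.float64)
    esc[:, E_FACE] = -1.0
    launches = np.zeros((cfg.n_photons, 6), dtype=np.float64)
    stats = np.zeros(6, dtype=np.float64)
    run_kernel(volume.labels, nv, muav, musv, gv,
               normal_map.gx, normal_map.gy, normal_map.gz, dx,
               MODES[cfg.mode], cfg.n_photons, cfg.seed,
               origin_vox[0], origin_vox[1], origin_vox[2],
               d[0], d[1], d[2], src.radius / dx,
               cfg.roulette_threshold, cfg.roulette_survival,
               fluence_raw, esc, launches, stats)

    mua_map = muav[volume.labels]
    phi = np.zeros_like(fluence_raw)
    nonzero = mua_map > 0
    phi[nonzero] = fluence_raw[nonzero] / (mua_map[nonzero] * dx ** 3 * cfg.n_photons)
    stats_d = {
        "launched": stats[0], "deposited": stats[1], "escaped": stats[2],
        "roulette_killed": stats[3], "roulette_boosted": stats[4],
        "lost": stats[5],
    }
    grid = FluenceGrid(values=phi, dx=dx, n_photons=cfg.n_photons,
                       seed=cfg.seed, mode=cfg.mode, raw=fluence_raw,
                       stats=stats_d)
    escaped_rows = esc[esc[:, E_FACE] >= 0]
    photon_ids = np.nonzero(esc[:, E_FACE] >= 0)[0]
    record = EscapeRecord.from_kernel(escaped_rows, photon_ids, launches)
    return grid, record
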