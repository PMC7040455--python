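"""Validation-scene drivers: the sphere, edge-sweep and lens experiments.

These reproduce the package's headline checks end-to-end (phantom ->
normal map -> transport -> comparison against the analytic oracle) with the
documented default geometries, and are shared by the test suite, the
acceptance script and the CLI.

Default scene parameters (the sources never state beam geometry or lens
dimensions; these are this package's documented choices):

* sphere scene — radius 1 cm, n 1.33 inside / 1.00 outside, dx 0.01 cm on a
  220^3 grid; collimated beam along +z of radius 0.15 cm whose axis passes
  0.7 cm from the sphere centre, so the beam strikes the sphere's side at
  incidence angles of roughly 33-58 degrees; all media are non-scattering
  and non-absorbing, so trajectories are purely refractive.
* lens scene — symmetric biconvex lens, surface radii 1 cm, centre
  thickness 0.4 cm, aperture 0.8 cm, n 1.52, mid-point 0.35 cm deep on the
  axis of a 128^3 grid at dx 0.01 cm; clear water (n 1.33) around the lens
  and an aqueous scattering solution (n 1.33, mus 100 /cm, g 0.90, mua
  0.1 /cm) filling z >= 0.55 cm below it; collimated beam of radius 0.3 cm
  along +z through the lens.
"""

from __future__ import annotations

import numpy as np

from .normalmap import SmoothingConfig, compute_normal_map
from .oracle import lens_scene, reflected_angle_error, sphere_scene
from .phantoms import LabeledVolume, Medium, MediumTable, make_biconvex_lens, make_sphere
from .record_io import percent_change_map
from .transport import SimulationConfig, SourceSpec, run
from . import edges2d

__all__ = [
    "build_sphere_scene",
    "sphere_reflection_experiment",
    "edge_error_experiment",
    "build_lens_scene",
    "lens_discrepancy_experiment",
]

SPHERE_GRID = 220
SPHERE_RADIUS = 1.0
SPHERE_DX = 0.01
SPHERE_BEAM_OFFSET = 0.7
SPHERE_BEAM_RADIUS = 0.15

LENS_GRID = 128
LENS_DX = 0.01
LENS_R = 1.0
LENS_THICKNESS = 0.4
LENS_APERTURE = 0.8
LENS_DEPTH = 0.35          # mid-plane depth on the axis, cm
SCATTER_Z = 0.55           # top of the scattering solution, cm
LENS_BEAM_RADIUS = 0.3


def build_sphere_scene(smoothing: float = 2.0):
    """Sphere phantom + media + normal map + analytic scene."""
    n = SPHERE_GRID
    center = (n / 2 * SPHERE_DX,) * 3
    media = MediumTable([
        Medium(0, n=1.00),     # clear surround
        Medium(1, n=1.33),     # sphere interior (water)
    ])
    volume = make_sphere((n, n, n), SPHERE_DX, center, SPHERE_RADIUS,
                         label_in=1, label_out=0, media=media)
    normal_map = compute_normal_map(volume, media, SmoothingConfig(smoothing))
    scene = sphere_scene(center, SPHERE_RADIUS, 1.33, 1.00)
    return volume, media, normal_map, scene


def sphere_reflection_experiment(seed: int, n_photons: int = 10_000,
                                 mode: str = "surface",
                                 smoothing: float = 2.0,
                                 prebuilt=None) -> dict:
    """Collimated beam on the side of a refractive sphere, scattering off.

    Every escaping photon that underwent exactly one Fresnel reflection (and
    no transmission) is compared with the analytic specular reflection of
    its own launch ray.  Returns the per-photon angular errors, their
    maximum over the beam edge (launch offset >= 95% of the beam radius, the
    paper-style beam-edge juxtaposition) and over the whole reflected beam.
    """
    volume, media, normal_map, scene = prebuilt or build_sphere_scene(smoothing)
    center = (SPHERE_GRID / 2 * SPHERE_DX,) * 3
    origin = (center[0] + SPHERE_BEAM_OFFSET, center[1], 1.5 * SPHERE_DX)
    cfg = SimulationConfig(
        n_photons=n_photons, mode=mode, seed=seed,
        source=SourceSpec(origin, (0.0, 0.0, 1.0), SPHERE_BEAM_RADIUS))
    fluence, escapes = run(volume, media, normal_map, cfg)

    errors, excluded = reflected_angle_error(escapes, scene)
    table = escapes.table
    single = table[(table["n_reflect"] == 1) & (table["n_transmit"] == 0)]
    r_launch = np.hypot(single["launch_x_cm"].to_numpy() - origin[0],
                        single["launch_y_cm"].to_numpy() - origin[1])
    edge = r_launch >= 0.95 * SPHERE_BEAM_RADIUS
    # reflected_angle_error preserves row order; excluded rays never occur
    # here (every launch ray intersects the sphere)
    return {
        "errors": errors,
        "edge_errors": errors[edge[:errors.size]] if errors.size else errors,
        "max_error": float(errors.max()) if errors.size else np.nan,
        "max_edge_error": (float(errors[edge[:errors.size]].max())
                           if errors.size and edge.any() else np.nan),
        "n_reflected": int(errors.size),
        "n_excluded": excluded,
        "fluence": fluence,
        "escapes": escapes,
    }


def edge_error_experiment() -> dict:
    """Worst-case facet and Sobel edge-normal errors in 2-D (degrees)."""
    return {
        "facet_max_error_deg": edges2d.facet_normal_max_error(),
        "sobel_max_error_deg": edges2d.sobel_normal_max_error(),
    }


def build_lens_scene():
    """Lens phantom + media (clear water, glass lens, scattering solution)."""
    n = LENS_GRID
    cx = n / 2 * LENS_DX
    media = MediumTable([
        Medium(0, n=1.33),                                 # clear water
        Medium(1, n=1.52),                                 # lens glass
        Medium(2, n=1.33, mua=0.1, mus=100.0, g=0.90),     # scattering solution
    ])
    volume = make_biconvex_lens(
        (n, n, n), LENS_DX, (cx, cx, LENS_DEPTH), LENS_R, LENS_R,
        LENS_THICKNESS, LENS_APERTURE, label_lens=1, label_ambient=0)
    z = (np.arange(n) + 0.5) * LENS_DX
    lower = (z >= SCATTER_Z)[None, None, :] & (volume.labels == 0)
    labels = volume.labels.copy()
    labels[np.broadcast_to(lower, labels.shape)] = 2
    volume = LabeledVolume(labels, LENS_DX, media)
    scene = lens_scene((cx, cx, LENS_DEPTH), LENS_R, LENS_R, LENS_THICKNESS,
                       1.52, 1.33)
    return volume, media, scene


def lens_discrepancy_experiment(seed: int, n_photons: int = 100_000,
                                smoothing: float = 2.0,
                                prebuilt=None) -> dict:
    """Facet-normal vs interpolated-surface-normal fluence through the lens.

    Both runs share the same seed (identical launch rays); the figure of
    merit is the maximum of the percent-change map 100 (phi_FN - phi_ISN) /
    phi_ISN over the scattering region below and lateral to the lens.  The
    low-fluence floor is 1e-3 of the peak reference fluence, which excludes
    statistically unvisited voxels.
    """
    if prebuilt is None:
        volume, media, scene = build_lens_scene()
    else:
        volume, media, scene = prebuilt
    normal_map = compute_normal_map(volume, media, SmoothingConfig(smoothing))
    cx = LENS_GRID / 2 * LENS_DX
    source = SourceSpec((cx, cx, 1.5 * LENS_DX), (0.0, 0.0, 1.0), LENS_BEAM_RADIUS)
    results = {}
    for mode in ("facet", "interp"):
        cfg = SimulationConfig(n_photons=n_photons, mode=mode, seed=seed,
                               source=source)
        results[mode], _ = run(volume, media, normal_map, cfg)
    phi_fn = results["facet"].values
    phi_isn = results["interp"].values
    floor = 1e-3 * float(phi_isn.max())
    pct = percent_change_map(phi_fn, phi_isn, floor=floor)
    z = (np.arange(LENS_GRID) + 0.5) * LENS_DX
    region = np.zeros(volume.shape, dtype=bool)
    region[:, :, z >= SCATTER_Z] = True
    sub = pct[region]
    max_pct = float(sub.max()) if sub.count() else np.nan
    return {
        "phi_fn": results["facet"],
        "phi_isn": results["interp"],
        "percent_change": pct,
        "max_percent_change": max_pct,
        "floor": floor,
        "scene": scene,
    }
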