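"""Result containers and file I/O.

Native on-disk format: raw little-endian binaries (uint8 labels, float32
fields) in x-fastest ordering, each with a JSON sidecar carrying the shape,
voxel size, and enough run metadata (seed, mode, photon count) to re-run the
simulation.  Round-trips are bit-exact.  Escape records are flat CSV tables.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .phantoms import LabeledVolume, MediumTable

__all__ = [
    "FluenceGrid",
    "EscapeRecord",
    "percent_change_map",
    "write_volume",
    "read_volume",
    "write_normals",
    "read_normals",
    "write_fluence",
    "read_fluence",
]

FORMAT_VERSION = 1

ESCAPE_COLUMNS = ["photon_id", "face", "x_cm", "y_cm", "z_cm",
                  "ux", "uy", "uz", "weight", "n_reflect", "n_transmit",
                  "launch_x_cm", "launch_y_cm", "launch_z_cm",
                  "launch_ux", "launch_uy", "launch_uz"]


@dataclass
class FluenceGrid:
    """Fluence rate phi in W/cm^2 per W delivered, plus run metadata."""

    values: np.ndarray
    dx: float
    n_photons: int
    seed: int
    mode: str = "unknown"
    raw: np.ndarray | None = None        # deposited weight per voxel
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("fluence values must be 3-D")
        if np.any(self.values < 0):
            raise ValueError("fluence must be non-negative")
        if self.dx <= 0:
            raise ValueError("dx must be positive")


@dataclass
class EscapeRecord:
    """Per-escaped-photon bookkeeping: exit face, state, and launch ray."""

    table: pd.DataFrame

    @classmethod
    def from_kernel(cls, esc_rows: np.ndarray, photon_ids: np.ndarray,
                    launches: np.ndarray) -> "EscapeRecord":
        df = pd.DataFrame({
            "photon_id": photon_ids.astype(np.int64),
            "face": esc_rows[:, 0].astype(np.int64),
            "x_cm": esc_rows[:, 1], "y_cm": esc_rows[:, 2], "z_cm": esc_rows[:, 3],
            "ux": esc_rows[:, 4], "uy": esc_rows[:, 5], "uz": esc_rows[:, 6],
            "weight": esc_rows[:, 7],
            "n_reflect": esc_rows[:, 8].astype(np.int64),
            "n_transmit": esc_rows[:, 9].astype(np.int64),
            "launch_x_cm": launches[photon_ids, 0],
            "launch_y_cm": launches[photon_ids, 1],
            "launch_z_cm": launches[photon_ids, 2],
            "launch_ux": launches[photon_ids, 3],
            "launch_uy": launches[photon_ids, 4],
            "launch_uz": launches[photon_ids, 5],
        })
        return cls(df)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def total_weight(self) -> float:
        return float(self.table["weight"].sum())

    def directions(self) -> np.ndarray:
        return self.table[["ux", "uy", "uz"]].to_numpy()

    def launch_rays(self) -> tuple[np.ndarray, np.ndarray]:
        origins = self.table[["launch_x_cm", "launch_y_cm", "launch_z_cm"]].to_numpy()
        dirs = self.table[["launch_ux", "launch_uy", "launch_uz"]].to_numpy()
        return origins, dirs

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "EscapeRecord":
        df = pd.read_csv(path)
        missing = set(ESCAPE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"escape CSV missing columns: {sorted(missing)}")
        return cls(df)


def percent_change_map(phi_a: np.ndarray, phi_b: np.ndarray,
                       floor: float = 1e-8) -> np.ma.MaskedArray:
    """Voxel-wise percent change 100 * (phi_a - phi_b) / phi_b.

    Voxels where the reference ``phi_b`` does not exceed ``floor`` are
    masked invalid (unvisited voxels would otherwise blow up the ratio).
    """
    phi_a = np.asarray(phi_a, dtype=np.float64)
    phi_b = np.asarray(phi_b, dtype=np.float64)
    if phi_a.shape != phi_b.shape:
        raise ValueError("fluence maps must share one shape")
    valid = phi_b > floor
    out = np.zeros_like(phi_b)
    out[valid] = 100.0 * (phi_a[valid] - phi_b[valid]) / phi_b[valid]
    return np.ma.MaskedArray(out, mask=~valid)


# ---------------------------------------------------------------------------
# raw-binary + JSON sidecar I/O (x-fastest ordering on disk)

def _read_raw(path: str, shape: Sequence[int], dtype) -> np.ndarray:
    expected = int(np.prod(shape)) * np.dtype(dtype).itemsize
    actual = os.path.getsize(path)
    if actual != expected:
        raise ValueError(f"{path}: expected {expected} bytes for shape "
                         f"{tuple(shape)} {np.dtype(dtype).name}, found {actual}")
    flat = np.fromfile(path, dtype=dtype)
    return np.ascontiguousarray(flat.reshape(tuple(shape), order="F"))


def _write_sidecar(path: str, payload: dict) -> None:
    payload = dict(payload)
    payload["format_version"] = FORMAT_VERSION
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _read_sidecar(path: str) -> dict:
    with open(path) as fh:
        meta = json.load(fh)
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported format version {version!r}")
    if "dx" in meta and meta["dx"] <= 0:
        raise ValueError(f"{path}: sidecar dx must be positive")
    return meta


def write_volume(prefix: str, volume: LabeledVolume,
                 media: MediumTable | None = None) -> None:
    """Write ``prefix.labels.raw`` (uint8, x-fastest) + ``prefix.json``."""
    media = media if media is not None else volume.media
    arr = np.asfortranarray(volume.labels, dtype=np.uint8)
    arr.ravel(order="F").tofile(prefix + ".labels.raw")
    _write_sidecar(prefix + ".json", {
        "kind": "labeled_volume",
        "shape": list(volume.shape),
        "dx": volume.dx,
        "media": media.to_rows() if media is not None else None,
    })


def read_volume(prefix: str) -> LabeledVolume:
    meta = _read_sidecar(prefix + ".json")
    if meta.get("kind") != "labeled_volume":
        raise ValueError(f"{prefix}.json does not describe a labeled volume")
    labels = _read_raw(prefix + ".labels.raw", meta["shape"], np.uint8)
    media = (MediumTable.from_rows(meta["media"])
             if meta.get("media") is not None else None)
    return LabeledVolume(labels, meta["dx"], media)


def write_normals(prefix: str, normal_map, dx: float | None = None) -> None:
    """Write three float32 raw component files + sidecar."""
    for comp, name in ((normal_map.gx, "gx"), (normal_map.gy, "gy"),
                       (normal_map.gz, "gz")):
        np.asfortranarray(comp, dtype=np.float32).ravel(order="F").tofile(
            f"{prefix}.{name}.raw")
    _write_sidecar(prefix + ".json", {
        "kind": "normal_map",
        "shape": list(normal_map.shape),
        "dx": dx,
    })


def read_normals(prefix: str):
    from .normalmap import NormalMap
    meta = _read_sidecar(prefix + ".json")
    if meta.get("kind") != "normal_map":
        raise ValueError(f"{prefix}.json does not describe a normal map")
    comps = [_read_raw(f"{prefix}.{name}.raw", meta["shape"], np.float32)
             for name in ("gx", "gy", "gz")]
    return NormalMap(*comps)


def write_fluence(prefix: str, grid: FluenceGrid) -> None:
    np.asfortranarray(grid.values, dtype=np.float32).ravel(order="F").tofile(
        prefix + ".phi.raw")
    _write_sidecar(prefix + ".json", {
        "kind": "fluence",
        "shape": list(grid.values.shape),
        "dx": grid.dx,
        "n_photons": grid.n_photons,
        "seed": grid.seed,
        "mode": grid.mode,
        "units": "W/cm^2 per W delivered",
        "stats": {k: float(v) for k, v in grid.stats.items()},
    })


def read_fluence(prefix: str) -> FluenceGrid:
    meta = _read_sidecar(prefix + ".json")
    if meta.get("kind") != "fluence":
        raise ValueError(f"{prefix}.json does not describe a fluence grid")
    values = _read_raw(prefix + ".phi.raw", meta["shape"], np.float32)
    return FluenceGrid(values=values.astype(np.float64), dx=meta["dx"],
                       n_photons=meta["n_photons"], seed=meta["seed"],
                       mode=meta.get("mode", "unknown"),
                       stats=meta.get("stats", {}))


def export_tiff_stack(path: str, grid: FluenceGrid) -> None:
    """Optional float32 TIFF stack of phi slices for visual inspection."""
    import tifffile
    tifffile.imwrite(path, np.asarray(grid.values, dtype=np.float32))
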