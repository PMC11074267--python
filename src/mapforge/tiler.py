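"""Overlapping sub-grid tiling and core-based stitching.

Deep voxel classifiers consume fixed-size cubic blocks; full maps are too
large. ``divide`` cuts a volume into ``tile_size``-cubed blocks whose faces
overlap by ``overlap`` voxels, so that the *central cores* of the blocks
(edge ``tile_size - 2*overlap``) partition the volume exactly once.
``stitch`` reassembles per-voxel predictions by keeping only each block's
core, which avoids boundary artifacts in the overlapped margins.

With the defaults (32-voxel tiles, 6-voxel overlap) the core is 20 voxels
per edge.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gridio import DensityGrid


class CoverageError(ValueError):
    """The tile set does not form a complete core cover of the volume."""


@dataclass
class Tile:
    """One cubic block cut from a parent volume.

    ``core_offset`` locates the block's central core in the parent volume
    and is always a multiple of the stride; the data block itself starts at
    ``core_offset - overlap`` (negative on leading boundaries, where the
    margin is zero padding).
    """

    data: np.ndarray
    core_offset: tuple[int, int, int]
    overlap: int

    @property
    def block_offset(self) -> tuple[int, int, int]:
        return tuple(c - self.overlap for c in self.core_offset)


def _as_array(volume) -> np.ndarray:
    if isinstance(volume, DensityGrid):
        return volume.data
    if hasattr(volume, "data") and hasattr(volume, "scheme"):  # LabelMask
        return volume.data
    return np.asarray(volume)


def divide(volume, tile_size: int = 32, overlap: int = 6) -> list[Tile]:
    """Cut a volume into overlapping cubic tiles.

    The stride between tile cores is ``tile_size - 2*overlap``; each axis
    gets ``ceil(dim / stride)`` tiles. Tile data outside the volume is zero
    padding. The union of tile cores (clipped to the volume) covers every
    voxel exactly once.
    """
    data = _as_array(volume)
    if data.ndim != 3 or data.size == 0:
        raise ValueError("volume must be a non-empty 3D array")
    stride = tile_size - 2 * overlap
    if stride <= 0:
        raise ValueError(
            f"tile_size {tile_size} must exceed twice the overlap {overlap}")
    shape = data.shape
    n_tiles = [int(np.ceil(d / stride)) for d in shape]
    tiles: list[Tile] = []
    for mi in range(n_tiles[0]):
        for mj in range(n_tiles[1]):
            for mk in range(n_tiles[2]):
                m = (mi, mj, mk)
                block = np.zeros((tile_size,) * 3, dtype=data.dtype)
                lo = [mm * stride - overlap for mm in m]
                src = tuple(
                    slice(max(lo[a], 0), min(lo[a] + tile_size, shape[a]))
                    for a in range(3)
                )
                dst = tuple(
                    slice(src[a].start - lo[a], src[a].stop - lo[a])
                    for a in range(3)
                )
                block[dst] = data[src]
                tiles.append(Tile(
                    data=block,
                    core_offset=tuple(mm * stride for mm in m),
                    overlap=overlap,
                ))
    return tiles


def stitch(tiles: list[Tile], full_shape: tuple[int, int, int],
           tile_size: int = 32, overlap: int = 6) -> np.ndarray:
    """Reassemble a full volume from tile cores.

    Each output voxel takes its value from the unique tile whose central
    core contains it; core cells beyond ``full_shape`` are dropped.

    Raises
    ------
    CoverageError
        If some voxel of ``full_shape`` is covered by no tile core.
    """
    stride = tile_size - 2 * overlap
    if stride <= 0:
        raise ValueError(
            f"tile_size {tile_size} must exceed twice the overlap {overlap}")
    if not tiles:
        raise CoverageError("no tiles given")
    out = np.zeros(full_shape, dtype=tiles[0].data.dtype)
    covered = np.zeros(full_shape, dtype=bool)
    for tile in tiles:
        lo = tile.core_offset
        dst = tuple(
            slice(min(lo[a], full_shape[a]),
                  min(lo[a] + stride, full_shape[a]))
            for a in range(3)
        )
        if any(s.start >= s.stop for s in dst):
            continue
        src = tuple(
            slice(overlap + dst[a].start - lo[a],
                  overlap + dst[a].stop - lo[a])
            for a in range(3)
        )
        out[dst] = tile.data[src]
        covered[dst] = True
    if not covered.all():
        n_missing = int((~covered).sum())
        raise CoverageError(
            f"{n_missing} voxels of {full_shape} not covered by any tile core")
    return out


def save_tiles(tiles: list[Tile], path, full_shape=None,
               tile_size: int = 32, overlap: int = 6) -> None:
    """Serialize tiles as one zip archive of raw blocks plus a JSON manifest."""
    path = Path(path)
    manifest = {
        "tile_size": tile_size,
        "overlap": overlap,
        "full_shape": list(full_shape) if full_shape is not None else None,
        "dtype": str(tiles[0].data.dtype) if tiles else "float32",
        "tiles": [{"core_offset": list(t.core_offset)} for t in tiles],
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest))
        for n, tile in enumerate(tiles):
            zf.writestr(f"tile_{n:06d}.npy", tile.data.tobytes())


def load_tiles(path) -> tuple[list[Tile], dict]:
    """Inverse of :func:`save_tiles`; returns (tiles, manifest)."""
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        tile_size = manifest["tile_size"]
        dtype = np.dtype(manifest["dtype"])
        tiles = []
        for n, meta in enumerate(manifest["tiles"]):
            buf = zf.read(f"tile_{n:06d}.npy")
            data = np.frombuffer(buf, dtype=dtype).reshape((tile_size,) * 3)
            tiles.append(Tile(
                data=data.copy(),
                core_offset=tuple(meta["core_offset"]),
                overlap=manifest["overlap"],
            ))
    return tiles, manifest
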