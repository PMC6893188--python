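"""Deterministic image preparation for segmentation.

Raw microscopy images (RGB or grayscale, any size) are standardized to a
968 x 1292 grayscale float image in [0, 1], cropped to 960 x 960 from the
top-left corner, and split into four 480 x 480 tiles for the network.
Predicted tile masks are reassembled losslessly into the 960 x 960 map.

The crop anchor (top-left) and the ITU-R 601 luminance weights are fixed
design choices recorded in the tile metadata; crop_and_tile and
reassemble are exact inverses on the 960 x 960 domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize

STD_SHAPE = (968, 1292)
CROP_SIZE = 960
TILE_SIZE = 480
N_TILES = 4

#: Row-major quadrant offsets within the 960x960 crop: (row, col) of each
#: tile's top-left pixel, indexed by quadrant id 0..3.
QUADRANT_OFFSETS = tuple(
    (r * TILE_SIZE, c * TILE_SIZE) for r in range(2) for c in range(2)
)


@dataclass
class TileSet:
    """Four 480x480 tiles of one image plus reassembly bookkeeping."""

    tiles: list[np.ndarray]
    parent_id: str = ""
    crop_offset: tuple[int, int] = (0, 0)
    quadrants: tuple[int, ...] = (0, 1, 2, 3)
    offsets: tuple[tuple[int, int], ...] = field(default=QUADRANT_OFFSETS)

    def __post_init__(self):
        if len(self.tiles) != N_TILES:
            raise ValueError(f"a TileSet holds exactly {N_TILES} tiles, got {len(self.tiles)}")
        for t in self.tiles:
            if t.shape[:2] != (TILE_SIZE, TILE_SIZE):
                raise ValueError(f"tiles must be {TILE_SIZE}x{TILE_SIZE}, got {t.shape}")


def standardize(image: np.ndarray) -> np.ndarray:
    """Convert to a 968 x 1292 grayscale image with values in [0, 1].

    RGB input is collapsed with ITU-R 601 luminance weighting before the
    (anti-aliased) resize; integer input is rescaled by its dtype range.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = rgb2gray(arr)  # ITU-R 601 weights; also scales uint8 to [0,1]
    elif arr.ndim == 2:
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr / np.iinfo(arr.dtype).max
        arr = arr.astype(np.float64)
    else:
        raise ValueError(f"expected a 2-D or 3-D image, got shape {arr.shape}")
    arr = np.clip(arr, 0.0, 1.0)
    if arr.shape == STD_SHAPE:
        return arr
    return resize(arr, STD_SHAPE, order=1, anti_aliasing=True, preserve_range=True)


def crop_and_tile(image: np.ndarray, parent_id: str = "") -> TileSet:
    """Crop the standardized image to 960 x 960 (top-left anchor) and
    split it into four 480 x 480 quadrant tiles, row-major."""
    image = np.asarray(image)
    if image.shape != STD_SHAPE:
        raise ValueError(f"expected a standardized {STD_SHAPE} image, got {image.shape}")
    crop = image[:CROP_SIZE, :CROP_SIZE]
    tiles = [crop[r : r + TILE_SIZE, c : c + TILE_SIZE].copy() for r, c in QUADRANT_OFFSETS]
    return TileSet(tiles=tiles, parent_id=parent_id, crop_offset=(0, 0))


def reassemble(tileset: TileSet) -> np.ndarray:
    """Reassemble four quadrant tiles into the 960 x 960 map, bit-exact.

    Tiles may be stored in any order as long as ``quadrants`` records
    which quadrant each tile belongs to.
    """
    if len(tileset.tiles) != N_TILES:
        raise ValueError("missing tile(s): reassembly needs all four quadrants")
    if sorted(tileset.quadrants) != list(range(N_TILES)):
        raise ValueError(f"quadrant ids must be a permutation of 0..3, got {tileset.quadrants}")
    out = np.empty((CROP_SIZE, CROP_SIZE), dtype=tileset.tiles[0].dtype)
    for tile, q in zip(tileset.tiles, tileset.quadrants):
        r, c = QUADRANT_OFFSETS[q]
        out[r : r + TILE_SIZE, c : c + TILE_SIZE] = tile
    return out


def tile_count(n_images: int) -> int:
    """Number of 480x480 sub-images produced from ``n_images`` standardized
    images (each contributes one 960x960 crop = 4 quadrants)."""
    if n_images < 0:
        raise ValueError("n_images must be non-negative")
    return n_images * N_TILES
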