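"""Multi-channel image handling and window-based feature extraction.

An image is an M x N x K stack of non-negative intensity channels (K = 3
for RGB, K = 1 for grayscale).  Each pixel that admits a full
(2m+1) x (2m+1) neighbourhood inside the image is summarised, channel by
channel, by the Frobenius norm of its local window, yielding one length-K
feature vector per retained pixel.  Centers whose window would reach
beyond the image boundary are skipped, so with stride 1 a tile of side T
yields (T - 2m)^2 feature vectors.

Whole-slide style inputs are cut into non-overlapping square tiles first
(trailing partial tiles are dropped), and tiles that are mostly
background (near-white luminance) can be excluded before any network is
built.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyFeatureSetError, InvalidInputError, InvalidWindowError

__all__ = [
    "MultiChannelImage",
    "WindowConfig",
    "FeatureVectorSet",
    "TileSet",
    "frobenius_norm",
    "extract_features",
    "tile_image",
    "is_background",
    "read_image",
    "write_image",
    "write_features_csv",
]


@dataclass
class MultiChannelImage:
    """An M x N x K intensity raster with unit-scaled channels.

    Parameters
    ----------
    pixels
        Array of shape (M, N, K) (a 2-D array is promoted to K = 1).
        Intensities are expected on the [0, 1] scale; loaders normalise
        by the full scale of the source bit depth.
    channel_names
        K human-readable channel labels, e.g. ``["R", "G", "B"]``.
    bit_depth
        Bit depth of the source data (8 or 16 for typical scans); kept
        for provenance, the pixel data itself is already unit-scaled.
    """

    pixels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = px[:, :, np.newaxis]
        if px.ndim != 3:
            raise InvalidInputError(
                f"pixels must be 2-D or 3-D, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise InvalidInputError("pixel intensities must be finite")
        if np.any(px < 0):
            raise InvalidInputError("pixel intensities must be non-negative")
        self.pixels = px
        if not self.channel_names:
            k = px.shape[2]
            self.channel_names = (
                ["R", "G", "B"] if k == 3 else [f"ch{i}" for i in range(k)]
            )
        if len(self.channel_names) != px.shape[2]:
            raise InvalidInputError(
                f"{len(self.channel_names)} channel names for "
                f"{px.shape[2]} channels"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


@dataclass(frozen=True)
class WindowConfig:
    """Local-window geometry for feature extraction.

    ``m`` is the window half-width, so windows are (2m+1) x (2m+1);
    ``node_stride`` subsamples valid window centers every s-th row and
    column.  A stride above 1 keeps the node count of the downstream
    network tractable: a 150 x 150 tile at m = 3 has 144^2 = 20 736
    valid centers, and dense pairwise relations at that size are beyond
    routine memory budgets, while stride 4 gives a 36^2 = 1 296-node
    network that preserves the texture statistics.
    """

    m: int = 3
    node_stride: int = 4

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidInputError(f"window half-width m must be >= 1, got {self.m}")
        if self.node_stride < 1:
            raise InvalidInputError(
                f"node_stride must be >= 1, got {self.node_stride}"
            )

    @property
    def side(self) -> int:
        return 2 * self.m + 1


@dataclass
class FeatureVectorSet:
    """L feature vectors of length K with their source-pixel coordinates.

    ``vectors[l, k]`` is the Frobenius norm of the window centred at
    ``coords[l]`` in channel k.  Coordinates are 0-based (row, col)
    positions in the originating tile.  ``meta`` carries the extraction
    parameters (m, stride) for provenance.
    """

    vectors: np.ndarray
    coords: np.ndarray
    source_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.vectors.ndim != 2:
            raise InvalidInputError("vectors must be an L x K matrix")
        if self.coords.shape != (self.vectors.shape[0], 2):
            raise InvalidInputError("coords must be L pairs (row, col)")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_channels(self) -> int:
        return self.vectors.shape[1]


@dataclass
class TileSet:
    """Square tiles cut from one image, with per-tile keep/exclude flags."""

    tiles: list[MultiChannelImage]
    kept_flags: list[bool]
    tile_size: int
    source_id: str | None = None

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def kept_tiles(self) -> list[MultiChannelImage]:
        return [t for t, keep in zip(self.tiles, self.kept_flags) if keep]

    def filter_background(
        self,
        white_luminance_frac: float = 0.9,
        max_background_frac: float = 0.5,
    ) -> "TileSet":
        """Return a copy with mostly-background tiles flagged for exclusion."""
        flags = [
            not is_background(t, white_luminance_frac, max_background_frac)
            for t in self.tiles
        ]
        return TileSet(self.tiles, flags, self.tile_size, self.source_id)


def frobenius_norm(window: np.ndarray, squared: bool = False) -> float:
    """Frobenius norm of a square odd-sided local window.

    The norm is the square root of the sum of squared entries; it
    depends only on the multiset of intensities in the window and is
    therefore invariant under any right-angle rotation or flip.  With
    ``squared=True`` the radical is omitted and the raw sum of squares
    is returned instead.

    Raises
    ------
    InvalidWindowError
        If the window is not square with an odd side of at least 3.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidWindowError(f"window must be square, got shape {w.shape}")
    if w.shape[0] < 3 or w.shape[0] % 2 == 0:
        raise InvalidWindowError(
            f"window side must be odd and >= 3, got {w.shape[0]}"
        )
    if not np.all(np.isfinite(w)):
        raise InvalidInputError("window entries must be finite")
    ss = float(np.sum(w * w))
    return ss if squared else float(np.sqrt(ss))


def extract_features(
    image: MultiChannelImage,
    cfg: WindowConfig,
    squared_norm: bool = False,
    source_id: str | None = None,
) -> FeatureVectorSet:
    """Per-channel window Frobenius norms for every retained center pixel.

    Only pixels whose full (2m+1) x (2m+1) window lies inside the image
    are used; a center that would require out-of-bounds values is
    skipped.  With stride s, centers are taken every s-th valid row and
    column starting from the first valid position, so stride 1 yields
    L = (M - 2m)(N - 2m) vectors.

    Raises
    ------
    EmptyFeatureSetError
        If the image is smaller than the window in either dimension.
    """
    m = cfg.m
    M, N, K = image.shape
    side = 2 * m + 1
    if M < side or N < side:
        raise EmptyFeatureSetError(
            f"image of size {M}x{N} admits no {side}x{side} window"
        )
    px = image.pixels
    # sliding_window_view keeps memory flat (a view), the reduction below
    # materialises only the (M-2m) x (N-2m) norm map per channel
    sq = px * px
    windows = np.lib.stride_tricks.sliding_window_view(sq, (side, side), axis=(0, 1))
    sums = windows.sum(axis=(-2, -1))  # (M-2m, N-2m, K)
    norms = sums if squared_norm else np.sqrt(sums)

    s = cfg.node_stride
    norms = norms[::s, ::s, :]
    n_rows, n_cols = norms.shape[:2]
    rows = m + s * np.arange(n_rows)
    cols = m + s * np.arange(n_cols)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()])
    vectors = norms.reshape(-1, K)
    return FeatureVectorSet(
        vectors=vectors,
        coords=coords,
        source_id=source_id,
        meta={"m": m, "node_stride": s, "squared_norm": squared_norm},
    )


def tile_image(image: MultiChannelImage, tile_size: int) -> TileSet:
    """Cut an image into non-overlapping square tiles in row-major order.

    Trailing rows/columns that do not fill a whole tile are dropped.  A
    tile size exceeding the image in either dimension yields an empty
    TileSet with a warning.
    """
    if tile_size < 1:
        raise InvalidInputError(f"tile_size must be positive, got {tile_size}")
    M, N, _ = image.shape
    n_r, n_c = M // tile_size, N // tile_size
    if n_r == 0 or n_c == 0:
        warnings.warn(
            f"tile_size {tile_size} exceeds image {M}x{N}: no tiles produced",
            stacklevel=2,
        )
        return TileSet([], [], tile_size)
    tiles = []
    for r in range(n_r):
        for c in range(n_c):
            sub = image.pixels[
                r * tile_size : (r + 1) * tile_size,
                c * tile_size : (c + 1) * tile_size,
                :,
            ]
            tiles.append(
                MultiChannelImage(sub.copy(), list(image.channel_names), image.bit_depth)
            )
    return TileSet(tiles, [True] * len(tiles), tile_size)


def is_background(
    tile: MultiChannelImage,
    white_luminance_frac: float = 0.9,
    max_background_frac: float = 0.5,
) -> bool:
    """Whether a tile is mostly background (near-white) pixels.

    A pixel counts as background when its mean channel intensity exceeds
    ``white_luminance_frac`` of full scale; the tile is background when
    the fraction of such pixels exceeds ``max_background_frac``.
    """
    lum = tile.pixels.mean(axis=2)
    frac_white = float(np.mean(lum > white_luminance_frac))
    return frac_white > max_background_frac


# ---------------------------------------------------------------------------
# I/O


def read_image(path: str | Path) -> MultiChannelImage:
    """Read an 8- or 16-bit TIFF/PNG tile, normalised to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        depth, scale = 8, 255.0
    elif arr.dtype == np.uint16:
        depth, scale = 16, 65535.0
    else:
        depth, scale = 8, max(1.0, float(np.max(arr)))
    return MultiChannelImage(arr.astype(float) / scale, bit_depth=depth)


def write_image(image: MultiChannelImage, path: str | Path) -> None:
    """Write a unit-scaled image as an 8-bit PNG or TIFF."""
    path = Path(path)
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)


def write_features_csv(features: FeatureVectorSet, path: str | Path) -> None:
    """Write a feature set as CSV: tile_id, i, j, norm_1..norm_K."""
    k = features.n_channels
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tile_id", "i", "j"] + [f"norm_{c + 1}" for c in range(k)])
        for (i, j), vec in zip(features.coords, features.vectors):
            writer.writerow(
                [features.source_id or "", int(i), int(j)] + [repr(float(v)) for v in vec]
            )
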