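"""Image and decay-stack containers plus basic raster operations.

All image operations in the package work on :class:`ImageGrid`, a 2-D grid
of non-negative scalar intensities with an isotropic physical pixel size.
TCSPC photon-count histograms live in :class:`DecayStack`, a
rows x cols x time-bin cube of integer counts.

Coordinates are 0-based, row-major, with the pixel-center convention;
physical distances are derived via ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageGrid",
    "DecayStack",
    "read_image",
    "write_image",
    "to_grayscale",
    "downsample",
    "read_decay_stack",
    "write_decay_stack",
]

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class ImageGrid:
    """A single-channel 2-D image with physical pixel-size metadata.

    Parameters
    ----------
    values
        2-D array of finite, non-negative intensities (rows x cols).
    pixel_size_um
        Physical size of one pixel in micrometres (isotropic), > 0.
    channel_name
        Free-text channel label, e.g. ``"CD80"`` or ``"NADH"``.
    bit_depth
        Nominal bit depth of the source data: 8, 16, or 0 for float.
    """

    values: np.ndarray
    pixel_size_um: float
    channel_name: str = "gray"
    bit_depth: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("ImageGrid requires a 2-D array with at least one pixel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageGrid values must be finite")
        if np.any(self.values < 0):
            raise ValueError("ImageGrid values must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class DecayStack:
    """Per-pixel TCSPC photon-count histograms.

    ``counts`` is ordered (rows, cols, nbins); the time axis of bin *j*
    spans ``[j * bin_width_ns, (j + 1) * bin_width_ns)``.
    """

    counts: np.ndarray
    bin_width_ns: float
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("DecayStack counts must be 3-D (rows, cols, nbins)")
        if counts.shape[2] < 8:
            raise ValueError("DecayStack needs at least 8 time bins")
        as_int = np.asarray(counts)
        if not np.issubdtype(as_int.dtype, np.integer):
            rounded = np.rint(as_int)
            if not np.allclose(as_int, rounded):
                raise ValueError("DecayStack counts must be integers")
            as_int = rounded.astype(np.int64)
        if np.any(as_int < 0):
            raise ValueError("DecayStack counts must be non-negative")
        self.counts = as_int.astype(np.int64)
        if not (self.bin_width_ns > 0):
            raise ValueError("bin_width_ns must be > 0")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")

    @property
    def nbins(self) -> int:
        return self.counts.shape[2]

    @property
    def time_axis_ns(self) -> np.ndarray:
        """Left edge of each time bin, in ns."""
        return np.arange(self.nbins) * self.bin_width_ns


def read_image(path, pixel_size_um: float, channel_name: str = "gray"):
    """Read a TIFF raster into one :class:`ImageGrid` per channel.

    Single-channel files return one ``ImageGrid``; multi-channel files
    return a list of single-channel grids in file channel order.
    """
    if not (pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    bit_depth = {np.dtype("uint8"): 8, np.dtype("uint16"): 16}.get(arr.dtype, 0)
    if arr.ndim == 2:
        return ImageGrid(arr, pixel_size_um, channel_name, bit_depth)
    if arr.ndim == 3:
        # channel axis: whichever axis is smallest and <= 4 (RGB etc.),
        # preferring the trailing axis (H x W x C convention)
        if arr.shape[2] <= 4:
            channels = [arr[:, :, i] for i in range(arr.shape[2])]
        elif arr.shape[0] <= 4:
            channels = [arr[i] for i in range(arr.shape[0])]
        else:
            raise IOError(f"cannot infer channel axis of {path} with shape {arr.shape}")
        return [
            ImageGrid(c, pixel_size_um, f"{channel_name}[{i}]", bit_depth)
            for i, c in enumerate(channels)
        ]
    raise IOError(f"unsupported image dimensionality {arr.ndim} in {path}")


def write_image(image: ImageGrid, path) -> None:
    """Write an :class:`ImageGrid` to TIFF, preserving its bit depth."""
    dtype = {8: np.uint8, 16: np.uint16}.get(image.bit_depth, np.float32)
    tifffile.imwrite(str(path), image.values.astype(dtype))


def to_grayscale(channels, weights=BT601_WEIGHTS) -> ImageGrid:
    """Combine 1 or 3 channels into a grayscale image.

    Three channels are combined with the BT.601 luma weights
    (0.299 R + 0.587 G + 0.114 B); a single channel is returned unchanged.
    Pass ``weights=None`` for a plain channel mean.
    """
    if isinstance(channels, ImageGrid):
        channels = [channels]
    if len(channels) == 1:
        return channels[0]
    if len(channels) != 3:
        raise ValueError(f"to_grayscale expects 1 or 3 channels, got {len(channels)}")
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValueError("channels must share a shape")
    if weights is None:
        weights = (1 / 3, 1 / 3, 1 / 3)
    gray = sum(w * c.values for w, c in zip(weights, channels))
    return ImageGrid(gray, channels[0].pixel_size_um, "gray", channels[0].bit_depth)


def _overlap_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix of fractional interval overlaps.

    Entry (i, j) is the fraction of output cell i's footprint
    [i*s, (i+1)*s), s = n_in/n_out, covered by input cell [j, j+1).
    Exact area averaging: every row sums to 1 and every column sums to
    n_out/n_in, so constant images and the global mean are preserved.
    """
    s = n_in / n_out
    out_edges = np.arange(n_out + 1) * s
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = out_edges[i], out_edges[i + 1]
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = max(0.0, min(hi, j + 1) - max(lo, j)) / s
    return w


def downsample(image: ImageGrid, target: int = 200) -> ImageGrid:
    """Resample to a ``target x target`` grid by exact area averaging.

    Area averaging is anti-aliased by construction and conserves the
    global mean. When the two axes scale unequally (non-square input),
    the output pixel size is the geometric mean of the per-axis sizes.
    Returns the input object unchanged if it is already target x target.
    """
    if target < 2:
        raise ValueError("downsample target must be >= 2")
    rows, cols = image.shape
    if (rows, cols) == (target, target):
        return image
    wr = _overlap_matrix(rows, target)
    wc = _overlap_matrix(cols, target)
    out = wr @ image.values @ wc.T
    out = np.clip(out, 0.0, None)
    scale = np.sqrt((rows / target) * (cols / target))
    return ImageGrid(out, image.pixel_size_um * scale, image.channel_name, 0)


def read_decay_stack(path, bin_width_ns: float, pixel_size_um: float = 1.0,
                     time_axis: int | None = None) -> DecayStack:
    """Read a TCSPC decay stack from multi-page TIFF or a CSV table.

    TIFF stacks are ordered (time-bin, row, col), one page per bin. CSV
    tables carry columns ``row,col,bin,count``; absent cells default to 0.
    """
    if not (bin_width_ns > 0):
        raise ValueError("bin_width_ns must be > 0")
    path = Path(path)
    if not path.exists():
        raise IOError(f"decay stack file not found: {path}")
    if path.suffix.lower() == ".csv":
        table = pd.read_csv(path)
        required = {"row", "col", "bin", "count"}
        if not required.issubset(table.columns):
            raise IOError(f"decay CSV {path} must have columns {sorted(required)}")
        if np.any(table["count"].to_numpy() < 0):
            raise ValueError("decay CSV contains negative counts")
        nrows = int(table["row"].max()) + 1
        ncols = int(table["col"].max()) + 1
        nbins = max(int(table["bin"].max()) + 1, 8)
        counts = np.zeros((nrows, ncols, nbins), dtype=np.int64)
        counts[table["row"], table["col"], table["bin"]] = table["count"]
        return DecayStack(counts, bin_width_ns, pixel_size_um)
    try:
        cube = tifffile.imread(str(path))
    except Exception as exc:
        raise IOError(f"could not read decay stack {path}: {exc}") from exc
    if cube.ndim != 3:
        raise IOError(f"decay stack {path} must be a 3-D TIFF, got ndim={cube.ndim}")
    if time_axis is None:
        if cube.shape[0] == cube.shape[1] == cube.shape[2]:
            raise ValueError(
                "decay stack axes are ambiguous (equal dimensions); "
                "pass time_axis explicitly"
            )
        time_axis = 0
    cube = np.moveaxis(cube, time_axis, 0)
    return DecayStack(np.moveaxis(cube, 0, 2), bin_width_ns, pixel_size_um)


def write_decay_stack(stack: DecayStack, path) -> None:
    """Write a decay stack as a multi-page TIFF, one page per time bin."""
    pages = np.moveaxis(stack.counts, 2, 0).astype(np.uint32)
    tifffile.imwrite(str(path), pages)
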