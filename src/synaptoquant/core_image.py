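"""Image data model, voxel geometry and TIFF/CSV I/O shared by all pipelines.

Conventions
-----------
Axis order is ``[channel, z, y, x]``, coordinates are 0-based and regions
of interest are half-open intervals.  All physical lengths are micrometres.
Pixel intensities are carried as floating point internally after load
(background subtraction produces non-integers); the dtype the pixels were
stored with is remembered so integer data round-trips bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "LabelVolume",
    "read_stack",
    "write_stack",
    "max_intensity_projection",
    "crop_roi",
    "voxel_volume",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of one voxel.

    Parameters
    ----------
    pixel_size_xy : float
        Lateral sampling in µm per pixel (e.g. 0.21 for a 63x confocal
        objective with an EMCCD camera).
    z_step : float
        Axial spacing between consecutive slices in µm (e.g. 0.24).
    """

    pixel_size_xy: float
    z_step: float

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy > 0 and np.isfinite(self.pixel_size_xy)):
            raise ValueError(f"pixel_size_xy must be positive, got {self.pixel_size_xy}")
        if not (self.z_step > 0 and np.isfinite(self.z_step)):
            raise ValueError(f"z_step must be positive, got {self.z_step}")

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_xy ** 2 * self.z_step

    @property
    def sampling_zyx(self) -> tuple[float, float, float]:
        """Per-axis spacing (z, y, x) in µm, e.g. for distance transforms."""
        return (self.z_step, self.pixel_size_xy, self.pixel_size_xy)


def voxel_volume(geometry: VoxelGeometry) -> float:
    """Volume of one voxel in µm³ (= pixel_size_xy² × z_step)."""
    return geometry.voxel_volume_um3


@dataclass
class ImageStack:
    """Multichannel 3D intensity stack.

    ``data`` is indexed ``[channel, z, y, x]``; channels are addressed by the
    names in ``channel_names`` ("HRP", "GluRIIC", "BRP", ...).
    """

    data: np.ndarray
    geometry: VoxelGeometry
    channel_names: list[str]
    source_dtype: np.dtype | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be [channel, z, y, x], got ndim={self.data.ndim}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("need at least one channel and one slice")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    def channel(self, channel: str | int) -> np.ndarray:
        """3D [z, y, x] view of one channel."""
        return self.data[self.channel_index(channel)]


@dataclass
class LabelVolume:
    """Integer-labelled 3D segmentation sharing an ImageStack's geometry.

    Label 0 is background; positive labels are objects.  After
    ``relabel`` the label set is {0..L} with no gaps.
    """

    labels: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be [z, y, x]")
        if not np.issubdtype(self.labels.dtype, np.integer) and self.labels.dtype != bool:
            raise ValueError("labels must be an integer (or boolean) array")
        if self.labels.dtype != bool and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0 if self.labels.dtype != bool else self.labels

    @property
    def n_labels(self) -> int:
        return len(np.setdiff1d(np.unique(self.labels), [0]))

    def relabel(self) -> "LabelVolume":
        """Return a copy with labels renumbered consecutively from 1."""
        old = np.setdiff1d(np.unique(self.labels), [0])
        out = np.zeros_like(self.labels, dtype=np.int32)
        for new, lab in enumerate(old, start=1):
            out[self.labels == lab] = new
        return LabelVolume(out, self.geometry)


def read_stack(
    path: str | Path,
    geometry: VoxelGeometry,
    channel_names: list[str],
    interleaved: bool = False,
) -> ImageStack:
    """Read a multipage TIFF into an ImageStack.

    The page layout must be declared: ``interleaved=False`` means all z
    slices of channel 0 come first (contiguous-z-within-channel),
    ``interleaved=True`` means channels alternate within each z slice.
    Geometry is supplied here, not parsed from TIFF tags — tag dialects
    vary; if resolution tags are present and disagree, a warning is
    emitted and the supplied geometry wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        _warn_on_tag_mismatch(tf, geometry)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2D pages, got shape {pages.shape}")
    if not np.issubdtype(pages.dtype, np.number):
        raise ValueError(f"non-numeric pixel data of dtype {pages.dtype}")
    n_chan = len(channel_names)
    if pages.shape[0] % n_chan != 0:
        raise ValueError(
            f"{pages.shape[0]} pages not divisible by {n_chan} channels"
        )
    n_z = pages.shape[0] // n_chan
    if interleaved:
        data = pages.reshape(n_z, n_chan, *pages.shape[1:]).transpose(1, 0, 2, 3)
    else:
        data = pages.reshape(n_chan, n_z, *pages.shape[1:])
    return ImageStack(
        data.astype(np.float64),
        geometry,
        list(channel_names),
        source_dtype=pages.dtype,
    )


def _warn_on_tag_mismatch(tf: "tifffile.TiffFile", geometry: VoxelGeometry) -> None:
    try:
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        if res is None:
            return
        num, den = res.value
        if num == 0 or num == den:  # (1, 1) is the uncalibrated default
            return
        tag_px_um = den / num  # XResolution is pixels per unit
        if tag_px_um > 0 and abs(tag_px_um - geometry.pixel_size_xy) / geometry.pixel_size_xy > 0.01:
            warnings.warn(
                f"TIFF resolution tag implies {tag_px_um:.4g} µm/px but geometry "
                f"declares {geometry.pixel_size_xy:.4g} µm/px; using the declared value",
                stacklevel=3,
            )
    except Exception:
        pass


def write_stack(path: str | Path, stack: ImageStack, interleaved: bool = False) -> None:
    """Write an ImageStack as a multipage TIFF.

    If the stack remembers an integer source dtype and the data are still
    integral, pixels are written back in that dtype so the payload
    round-trips bit-exactly; otherwise float32 is used.
    """
    data = stack.data
    if stack.source_dtype is not None:
        candidate = data.astype(stack.source_dtype)
        if np.array_equal(candidate.astype(np.float64), data):
            data = candidate
        else:
            data = data.astype(np.float32)
    else:
        data = data.astype(np.float32)
    if interleaved:
        pages = data.transpose(1, 0, 2, 3).reshape(-1, *data.shape[2:])
    else:
        pages = data.reshape(-1, *data.shape[2:])
    tifffile.imwrite(Path(path), pages)


def max_intensity_projection(stack: ImageStack, channel: str | int) -> np.ndarray:
    """Maximum-intensity projection over z of one channel; shape [y, x]."""
    return stack.channel(channel).max(axis=0)


def crop_roi(stack: ImageStack, center_yx: tuple[int, int], size_px: int) -> ImageStack:
    """Crop a size_px × size_px square (all channels, all slices).

    The square is centred at ``center_yx``; for even ``size_px`` the
    centre rounds toward the origin.  The ROI must lie fully inside the
    image — there is no silent clipping.
    """
    if size_px < 1:
        raise ValueError("size_px must be >= 1")
    cy, cx = (int(center_yx[0]), int(center_yx[1]))
    y0 = cy - size_px // 2
    x0 = cx - size_px // 2
    y1, x1 = y0 + size_px, x0 + size_px
    ny, nx = stack.data.shape[2], stack.data.shape[3]
    if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
        raise ValueError(
            f"ROI [{y0}:{y1}, {x0}:{x1}] exceeds image bounds {ny}x{nx}"
        )
    return ImageStack(
        stack.data[:, :, y0:y1, x0:x1].copy(),
        stack.geometry,
        list(stack.channel_names),
        source_dtype=stack.source_dtype,
    )
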