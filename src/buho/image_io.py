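"""Channel containers and intensity preprocessing.

Micrographs are handled as plain 2-D intensity fields with a recorded bit
depth and physical pixel size.  The preprocessing operators here mirror the
classic toolbox steps used for confocal foci analysis: hard intensity
clipping of rare hot pixels, quantile contrast stretching, locally adaptive
(Wiener) denoising, a 3x3 unsharp sharpening pass for faint granules, and
bicubic downscaling that preserves the physical field size.

All operators are deterministic and shape-preserving (except resizing) and
use replicate-border handling so that no artificial structure is created at
the field edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import tifffile
from scipy import ndimage
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

ChannelRole = Literal["nuclear", "foci", "object"]

_VALID_ROLES = ("nuclear", "foci", "object")


class InputError(ValueError):
    """Raised for unreadable or malformed input files."""


@dataclass
class ChannelImage:
    """A single-channel 2-D intensity field.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (stored as float64).
    bit_depth
        8 or 16; intensities must lie in [0, 2**bit_depth - 1].
    pixel_size_um
        Physical size of one pixel edge in micrometres (> 0).
    role
        One of ``"nuclear"``, ``"foci"``, ``"object"``.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float
    role: ChannelRole = "foci"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InputError(f"channel image must be 2-D, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.role not in _VALID_ROLES:
            raise ValueError(f"role must be one of {_VALID_ROLES}, got {self.role!r}")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel intensities must be non-negative")
        if self.pixels.size and self.pixels.max() > self.max_intensity:
            raise ValueError(
                f"pixel intensities exceed 2**{self.bit_depth} - 1 = {self.max_intensity}"
            )

    @property
    def max_intensity(self) -> float:
        """Largest representable intensity, 2**bit_depth - 1."""
        return float(2**self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Copy of this channel carrying new pixel data."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


@dataclass
class ImageSet:
    """The channels of one imaged field.

    All channels must share dimensions and pixel size.  ``object_channel``
    holds an optional third stain (e.g. a synapse marker) used for
    inter-object distance analysis.
    """

    nuclear: ChannelImage
    foci: ChannelImage
    object_channel: Optional[ChannelImage] = None
    field_id: str = "field"
    well_id: Optional[str] = None

    def __post_init__(self) -> None:
        channels = [self.nuclear, self.foci]
        if self.object_channel is not None:
            channels.append(self.object_channel)
        shapes = {c.shape for c in channels}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        sizes = {c.pixel_size_um for c in channels}
        if len(sizes) != 1:
            raise ValueError(f"channel pixel sizes differ: {sizes}")

    @property
    def pixel_size_um(self) -> float:
        return self.nuclear.pixel_size_um


def load_channel(
    path: str | Path,
    role: ChannelRole,
    pixel_size_um: float,
    page: int = 0,
) -> ChannelImage:
    """Read one grayscale plane from a TIFF (or TIFF-dialect LSM) file.

    No rescaling is applied: raw stored intensities are preserved.  Files
    holding multiple planes are addressed with ``page``.  PNG files are
    accepted for convenience when working with exported fixtures.

    Raises
    ------
    InputError
        If the file is missing, unreadable, or the selected plane is not a
        single 2-D grayscale image.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff", ".lsm"):
            with tifffile.TiffFile(path) as tf:
                if page >= len(tf.pages):
                    raise InputError(
                        f"page {page} out of range for {path} ({len(tf.pages)} pages)"
                    )
                arr = tf.pages[page].asarray()
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except InputError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap all reader failures
        raise InputError(f"could not read image {path}: {exc}") from exc

    arr = np.squeeze(np.asarray(arr))
    if arr.ndim != 2:
        raise InputError(f"expected a 2-D grayscale plane in {path}, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number):
        raise InputError(f"unsupported sample format {arr.dtype} in {path}")
    bit_depth = 16 if arr.dtype.itemsize > 1 or arr.max(initial=0) > 255 else 8
    return ChannelImage(
        pixels=arr.astype(np.float64),
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        role=role,
    )


def save_channel(img: ChannelImage, path: str | Path) -> None:
    """Write a channel to TIFF at its native bit depth (for audit dumps)."""
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    data = np.clip(np.rint(img.pixels), 0, img.max_intensity).astype(dtype)
    tifffile.imwrite(Path(path), data)


def clip_intensity(img: ChannelImage, cap: float = 255.0) -> ChannelImage:
    """Clip intensities above ``cap``.

    In 16-bit confocal data only a tiny fraction of pixels (hot pixels,
    saturated nuclei) exceed the working range; clipping them to a common
    cap stabilises all later max-relative thresholds.  The fraction of
    clipped pixels is logged since the appropriate cap is data dependent.
    """
    if not cap > 0:
        raise ValueError(f"cap must be > 0, got {cap}")
    clipped = np.minimum(img.pixels, cap)
    n_clipped = int(np.count_nonzero(img.pixels > cap))
    if n_clipped:
        logger.info(
            "clip_intensity: %.4f%% of pixels clipped to %g",
            100.0 * n_clipped / img.pixels.size,
            cap,
        )
    return img.with_pixels(clipped)


def contrast_stretch(
    img: ChannelImage, low_frac: float = 0.01, high_frac: float = 0.99
) -> ChannelImage:
    """Linearly remap the [low_frac, high_frac] quantile range to full range.

    Intensities below the low quantile map to 0 and above the high quantile
    to the channel's maximum representable intensity.  A constant image is
    returned unchanged (with a log warning) since it has no contrast to
    stretch.
    """
    if not (0 <= low_frac < high_frac <= 1):
        raise ValueError(f"need 0 <= low_frac < high_frac <= 1, got {low_frac}, {high_frac}")
    lo = float(np.quantile(img.pixels, low_frac))
    hi = float(np.quantile(img.pixels, high_frac))
    if hi <= lo:
        logger.warning("contrast_stretch: constant (or degenerate) image left unchanged")
        return img.with_pixels(img.pixels.copy())
    out = (img.pixels - lo) / (hi - lo)
    np.clip(out, 0.0, 1.0, out=out)
    return img.with_pixels(out * img.max_intensity)


def wiener_denoise(img: ChannelImage, window: int = 3) -> ChannelImage:
    """Locally adaptive 2-D Wiener denoising.

    With local window mean ``mu`` and variance ``s2``, and the noise power
    ``nu`` estimated as the mean of all local variances, each pixel becomes

        out = mu + max(s2 - nu, 0) / max(s2, nu) * (in - mu)

    so flat regions collapse to their local mean while high-variance
    structure is preserved.  Borders are replicated.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    x = img.pixels
    mu = ndimage.uniform_filter(x, size=window, mode="nearest")
    mu2 = ndimage.uniform_filter(x * x, size=window, mode="nearest")
    s2 = np.maximum(mu2 - mu * mu, 0.0)
    nu = float(s2.mean())
    denom = np.maximum(s2, nu)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(denom > 0, np.maximum(s2 - nu, 0.0) / denom, 0.0)
    out = mu + gain * (x - mu)
    return img.with_pixels(np.clip(out, 0.0, img.max_intensity))


def unsharp_kernel(alpha: float) -> np.ndarray:
    """The classic 3x3 unsharp (negative-Laplacian) sharpening kernel."""
    if not (0 <= alpha <= 1):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    a = alpha
    return (
        np.array(
            [
                [-a, a - 1.0, -a],
                [a - 1.0, a + 5.0, a - 1.0],
                [-a, a - 1.0, -a],
            ]
        )
        / (a + 1.0)
    )


def unsharp_filter(img: ChannelImage, alpha: float = 0.2) -> ChannelImage:
    """Sharpen with the 3x3 unsharp kernel (sum 1, so flat areas are fixed).

    Faint or blurry granules gain contrast relative to their surround,
    which lets a second correlation pass pick up foci that fall just below
    a prototype's similarity threshold in the raw image.  Output is clamped
    to the valid intensity range; borders are replicated.
    """
    kernel = unsharp_kernel(alpha)
    out = ndimage.correlate(img.pixels, kernel, mode="nearest")
    return img.with_pixels(np.clip(out, 0.0, img.max_intensity))


def resize_image(img: ChannelImage, target_side: int) -> ChannelImage:
    """Bicubic resize to a square ``target_side`` x ``target_side`` field.

    The pixel size is rescaled by the geometric factor so physical lengths
    and areas are preserved.  Upscaling is allowed but warned about, since
    it cannot add information.
    """
    if target_side < 64:
        raise ValueError(f"target_side must be >= 64, got {target_side}")
    h, w = img.shape
    if (h, w) == (target_side, target_side):
        return img.with_pixels(img.pixels.copy())
    if target_side > max(h, w):
        warnings.warn("resize_image: upscaling requested", stacklevel=2)
    factor = h / target_side
    out = _sk_resize(
        img.pixels,
        (target_side, target_side),
        order=3,
        mode="edge",
        anti_aliasing=factor > 1,
        preserve_range=True,
    )
    return replace(
        img,
        pixels=np.clip(out, 0.0, img.max_intensity),
        pixel_size_um=img.pixel_size_um * factor,
    )
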