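"""Loading and canonicalization of lateral-flow strip photographs.

A strip photo shows two printed lines — the test line (tl) and the control
line (cl), 5 mm apart on the membrane — photographed either with a benchtop
imager or a smartphone in a darkbox.  Everything downstream assumes a
*canonical* raster: a single-channel image whose values encode band
**darkness** (colored bands are maxima), with the flow axis along axis 0 and
the test line upstream (lower row index) of the control line.

The three steps are :func:`load_strip_image` (decode + scale to [0, 1]),
:func:`to_signal_channel` (channel selection + polarity inversion) and
:func:`canonicalize_orientation` (flow axis / band order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from PIL import Image

from .errors import (
    ConfigurationError,
    DecodeError,
    InvalidInputError,
    OrientationAmbiguousError,
)

__all__ = [
    "StripImage",
    "LaneGeometry",
    "load_strip_image",
    "write_strip_image",
    "to_signal_channel",
    "canonicalize_orientation",
]

#: Rec.601 luma weights, used by the ``luminance`` channel policy.
_LUMA = np.array([0.299, 0.587, 0.114])

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass
class StripImage:
    """Pixel raster of one strip plus acquisition metadata.

    ``pixels`` is a float array scaled to [0, 1]; 2-D for single-channel
    images, 3-D ``(rows, cols, 3)`` for RGB.  ``flow_axis`` is the axis
    along which the sample migrated (0 after canonicalization).
    ``px_per_mm`` is the spatial resolution if known; it is otherwise
    estimated later from the detected line separation and the printed
    5 mm line spacing.  ``is_signal`` records whether polarity has been
    inverted so that darkness (band signal) is a maximum.
    """

    pixels: np.ndarray
    px_per_mm: float | None = None
    source_label: str = ""
    flow_axis: int = 0
    is_signal: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass(frozen=True)
class LaneGeometry:
    """Printed geometry of the strip.

    ``line_spacing_mm`` is the tl–cl distance (5 mm for the digoxigenin
    strips), ``band_width_mm`` the nominal printed line width and
    ``roi_width_fraction`` the central fraction of the strip width that
    is averaged into the flow-axis profile (edges are excluded because
    membrane borders and shadows concentrate there).
    """

    line_spacing_mm: float = 5.0
    band_width_mm: float = 1.0
    roi_width_fraction: float = 0.6

    def __post_init__(self):
        if self.line_spacing_mm <= 0:
            raise ValueError("line_spacing_mm must be positive")
        if not (0 < self.roi_width_fraction <= 1):
            raise ValueError("roi_width_fraction must be in (0, 1]")
        if self.band_width_mm <= 0:
            raise ValueError("band_width_mm must be positive")


def _scale_to_unit(arr: np.ndarray) -> np.ndarray:
    """Scale an integer raster to [0, 1] by its dtype's full range."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return (arr.astype(np.float64) - info.min) / (info.max - info.min)
    # float input: trust it is already normalized, clip defensively
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def load_strip_image(path: str | Path, source_label: str = "") -> StripImage:
    """Decode a JPEG/PNG/TIFF strip photo into a [0, 1]-scaled raster.

    8-bit inputs are divided by 255, 16-bit by 65535.  An alpha channel,
    if present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps decoder errors variously
        raise DecodeError(f"cannot decode image {path}: {exc}") from exc
    if arr.size == 0:
        raise InvalidInputError(f"zero-area image: {path}")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3):
        raise InvalidInputError(f"unsupported raster shape {arr.shape}: {path}")
    return StripImage(pixels=_scale_to_unit(arr), source_label=source_label or path.name)


def write_strip_image(img: StripImage, path: str | Path, jpeg_quality: int = 85) -> Path:
    """Write a strip raster as 8-bit PNG (lossless, default) or JPEG.

    Format follows the file extension.  Values are quantized to 8 bit, so
    a PNG round trip reproduces pixels to within 1/255.
    """
    path = Path(path)
    arr8 = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    pil = Image.fromarray(arr8)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        pil.save(path, quality=jpeg_quality)
    else:
        pil.save(path)
    return path


def to_signal_channel(img: StripImage, policy: str = "green") -> StripImage:
    """Reduce to one channel and invert polarity so band darkness is a peak.

    The gold-nanoparticle bands are red/pink on a light membrane, so the
    green channel carries the strongest absorbance contrast and is the
    default.  ``luminance`` (Rec.601 luma) suits grayscale imagers;
    ``red``/``blue`` are offered for unusual chemistries.  The output value
    is ``1 - channel_value``: white membrane maps to 0, a saturated dark
    band to 1.  Grayscale input passes through the same inversion.
    """
    if policy not in ("green", "luminance", "red", "blue"):
        raise ConfigurationError(f"unknown channel policy: {policy!r}")
    px = img.pixels
    if px.ndim == 2:
        chan = px
    elif px.shape[2] == 1:
        chan = px[:, :, 0]
    elif px.shape[2] == 3:
        if policy == "luminance":
            chan = px @ _LUMA
        else:
            chan = px[:, :, _CHANNEL_INDEX[policy]]
    else:
        raise InvalidInputError(f"expected 1 or 3 channels, got {px.shape[2]}")
    return replace(img, pixels=1.0 - chan, is_signal=True)


def _band_midpoint(img: StripImage, geom: LaneGeometry) -> float | None:
    """Midpoint (px, along axis 0) of the two most prominent bands, or None."""
    # local import: densitometry depends on the types defined here
    from .densitometry import extract_profile, correct_baseline, _top_two_peaks

    profile = extract_profile(img, geom)
    corrected = correct_baseline(profile, method="flank_linear", window_px=5)
    peaks = _top_two_peaks(corrected.corrected_values())
    if peaks is None:
        return None
    return float(np.mean(peaks))


def canonicalize_orientation(
    img: StripImage,
    geom: LaneGeometry | None = None,
    flow_direction_hint: str = "auto",
) -> StripImage:
    """Rotate/flip a signal image into canonical orientation.

    Canonical means: flow axis is axis 0 (the longer image axis) and the
    test line sits upstream (lower row index) of the control line.  With
    ``flow_direction_hint='auto'`` the band pair is located and the image
    flipped so that the pair's midpoint lies in the downstream half —
    strips are cut with more free membrane on the sample-pad side, so the
    printed lines sit past the middle of the cut strip.  With explicit
    hints (``tl_first`` / ``cl_first``) no content-based guessing occurs.

    The operation is idempotent: a canonical image is returned unchanged.
    """
    if geom is None:
        geom = LaneGeometry()
    if flow_direction_hint not in ("auto", "tl_first", "cl_first"):
        raise ConfigurationError(f"unknown flow direction hint: {flow_direction_hint!r}")
    if not img.is_signal or img.pixels.ndim != 2:
        raise InvalidInputError("canonicalize_orientation expects a single-channel signal image")

    px = img.pixels
    if px.shape[0] < px.shape[1]:
        px = px.T
    elif px.shape[0] == px.shape[1] and flow_direction_hint == "auto":
        raise OrientationAmbiguousError(
            "square image: flow axis indeterminate; pass flow_direction_hint="
            "'tl_first' or 'cl_first'"
        )
    out = replace(img, pixels=px, flow_axis=0)

    if flow_direction_hint == "tl_first":
        return out
    if flow_direction_hint == "cl_first":
        return replace(out, pixels=out.pixels[::-1].copy())

    mid = _band_midpoint(out, geom)
    if mid is None:
        raise OrientationAmbiguousError(
            "bands not found; cannot infer flow direction — pass "
            "flow_direction_hint='tl_first' or 'cl_first'"
        )
    center = (out.pixels.shape[0] - 1) / 2.0
    tol = max(1.0, 0.02 * out.pixels.shape[0])
    if abs(mid - center) <= tol:
        raise OrientationAmbiguousError(
            "band pair centered on the strip; flow direction indeterminate — "
            "pass flow_direction_hint='tl_first' or 'cl_first'"
        )
    if mid < center:
        return replace(out, pixels=out.pixels[::-1].copy())
    return out
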