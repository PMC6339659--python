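"""Strip densitometry: from a canonical strip raster to band intensities.

The chain is: average the central region of interest into a 1-D darkness
profile along the flow axis (:func:`extract_profile`), remove the smooth
membrane background (:func:`correct_baseline`), locate the test and
control lines using the printed 5 mm spacing as a prior
(:func:`detect_bands`), and integrate each band window.
:func:`quantify_strip` composes the chain and reports the background-
corrected test-line (tl) and control-line (cl) intensities together with
the normalized (cl/tl) and standardized (tl/cl) ratios used for
calibration.

Band quantity is integrated area (sum of corrected signal over the band
window) rather than peak height: area is robust to the focus/sharpness
differences between a benchtop imager and a smartphone photo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .errors import (
    AmbiguousBandsError,
    BandNotFoundError,
    ConfigurationError,
    InvalidGeometryError,
    OrientationAmbiguousError,
    ParameterError,
)
from .io import LaneGeometry, StripImage, canonicalize_orientation, to_signal_channel

__all__ = [
    "IntensityProfile",
    "BandCall",
    "StripMeasurement",
    "QuantifySettings",
    "extract_profile",
    "correct_baseline",
    "detect_bands",
    "quantify_strip",
    "measurements_to_frame",
    "frame_to_measurements",
]

MEASUREMENT_COLUMNS = [
    "sample_id",
    "device",
    "concentration_nM",
    "replicate",
    "tl",
    "cl",
    "normalized",
    "standardized",
    "flags",
]


@dataclass
class IntensityProfile:
    """1-D mean darkness along the flow axis.

    ``baseline`` is absent (None) until :func:`correct_baseline` populates
    it; corrected values are ``values - baseline`` floored at 0.
    """

    values: np.ndarray
    positions_px: np.ndarray
    baseline: np.ndarray | None = None

    def corrected_values(self) -> np.ndarray:
        if self.baseline is None:
            raise ValueError("profile has no baseline yet; run correct_baseline first")
        return np.clip(self.values - self.baseline, 0.0, None)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BandCall:
    """One detected band: center, integration window and intensities."""

    label: str  # 'tl' or 'cl'
    center_px: int
    window_px: tuple[int, int]  # half-open [start, stop)
    raw_area: float
    corrected_intensity: float  # floored at 0
    prominence: float = float("nan")


@dataclass
class StripMeasurement:
    """Background-corrected intensities and ratios for one strip.

    ``normalized`` (cl/tl) is the primary calibration response of the
    competitive assay and is defined only when ``tl_intensity > 0``;
    ``standardized`` (tl/cl) is the reciprocal alternative.
    """

    tl_intensity: float
    cl_intensity: float
    normalized: float | None
    standardized: float | None
    concentration_nM: float | None = None
    replicate: int = 0
    device: str = ""
    sample_id: str = ""
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class QuantifySettings:
    """Tunable knobs of the densitometry chain (all defaults documented).

    ``baseline_window_mm`` is the structuring window of the rolling-minimum
    baseline, expressed physically; 3 mm = 3x the nominal band width.
    ``saturation_fraction`` is the tolerated fraction of ROI pixels at the
    0/1 rails before the measurement is flagged 'saturated'.
    """

    channel: str = "green"
    baseline_method: str = "flank_linear"
    baseline_window_mm: float = 3.0
    orientation_hint: str = "auto"
    saturation_fraction: float = 0.01


def _roi_slice(n_cols: int, roi_width_fraction: float) -> slice:
    """Central columns used for profiling; at least 3 px wide."""
    if n_cols < 3:
        raise InvalidGeometryError(
            f"image only {n_cols} px wide after ROI trim; need at least 3"
        )
    keep = max(3, int(round(n_cols * roi_width_fraction)))
    keep = min(keep, n_cols)
    start = (n_cols - keep) // 2
    return slice(start, start + keep)


def extract_profile(img: StripImage, geom: LaneGeometry) -> IntensityProfile:
    """Mean signal over the central ROI columns, per flow-axis row."""
    if img.pixels.ndim != 2:
        raise InvalidGeometryError("extract_profile expects a single-channel image")
    cols = _roi_slice(img.pixels.shape[1], geom.roi_width_fraction)
    values = img.pixels[:, cols].mean(axis=1)
    return IntensityProfile(values=values, positions_px=np.arange(len(values)))


def _flank_linear_baseline(values: np.ndarray) -> np.ndarray:
    """Straight line through band-free points, found by iterative trimming.

    Fit a line to all points, then discard points lying more than 3 robust
    sigma *above* the line (the bands) and refit, until the support set is
    stable.  A profile with no bands reproduces itself exactly.
    """
    x = np.arange(len(values), dtype=float)
    mask = np.ones(len(values), dtype=bool)
    coef = np.polyfit(x, values, 1)
    for _ in range(50):
        coef = np.polyfit(x[mask], values[mask], 1)
        resid = values - np.polyval(coef, x)
        r = resid[mask]
        scale = 1.4826 * np.median(np.abs(r - np.median(r)))
        thr = max(3.0 * scale, 1e-12)
        new_mask = resid <= thr
        if new_mask.sum() < 4 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return np.polyval(coef, x)


def _rolling_min_baseline(values: np.ndarray, window_px: int) -> np.ndarray:
    """Morphological opening: rolling minimum followed by equal smoothing."""
    if window_px % 2 == 0:
        window_px += 1
    floor = minimum_filter1d(values, size=window_px, mode="reflect")
    return uniform_filter1d(floor, size=window_px, mode="reflect")


def correct_baseline(
    p: IntensityProfile, method: str = "flank_linear", window_px: int = 30
) -> IntensityProfile:
    """Estimate and attach the background baseline.

    ``flank_linear`` (default) fits a straight line through the band-free
    flanks and the inter-band valley floor; ``rolling_min`` uses a rolling
    minimum of ``window_px`` (which must span at least ~3 band widths so
    bands do not survive the opening).
    """
    if window_px < 3:
        raise ParameterError(f"window_px must be >= 3, got {window_px}")
    if method == "flank_linear":
        baseline = _flank_linear_baseline(p.values)
    elif method == "rolling_min":
        baseline = _rolling_min_baseline(p.values, int(window_px))
    else:
        raise ConfigurationError(f"unknown baseline method: {method!r}")
    return replace(p, baseline=baseline)


#: Absolute peak-prominence floor on the darkness scale.  Bands shallower
#: than ~2-3 gray levels of an 8-bit camera are indistinguishable from the
#: sensor noise/quantization floor and are not treated as lines.
MIN_PROMINENCE = 0.01


def _smooth(values: np.ndarray, width_px: float) -> np.ndarray:
    """Moving average with reflected boundaries; width forced odd so
    symmetric peaks keep their center."""
    w = max(1, int(round(width_px)))
    if w % 2 == 0:
        w += 1
    return uniform_filter1d(values, size=w, mode="reflect")


def _top_two_peaks(corrected: np.ndarray, smooth_px: float = 5) -> np.ndarray | None:
    """Indices of the two most prominent peaks, sorted, or None."""
    smoothed = _smooth(corrected, smooth_px)
    floor = max(MIN_PROMINENCE, 0.05 * float(smoothed.max(initial=0.0)))
    peaks, props = find_peaks(smoothed, prominence=floor)
    if len(peaks) < 2:
        return None
    order = np.argsort(props["prominences"])[::-1][:2]
    return np.sort(peaks[order])


def estimate_px_per_mm(p: IntensityProfile, geom: LaneGeometry) -> float:
    """Resolution from the detected tl-cl separation and the printed spacing."""
    peaks = _top_two_peaks(p.corrected_values())
    if peaks is None:
        raise BandNotFoundError(
            "cannot estimate px/mm: fewer than two bands found", missing="tl+cl"
        )
    return float(peaks[1] - peaks[0]) / geom.line_spacing_mm


def detect_bands(
    p: IntensityProfile, geom: LaneGeometry, px_per_mm: float
) -> tuple[BandCall, BandCall]:
    """Locate the test and control lines on a baseline-corrected profile.

    Candidate peaks are local maxima of the profile smoothed with a moving
    average one band-width wide.  Peak pairs whose separation is within
    +-25% of the expected ``line_spacing_mm * px_per_mm`` qualify; among
    them the pair maximizing summed prominence wins.  The upstream peak is
    labelled tl, the downstream one cl.  Integration windows span
    center +- 1.5 x band width / 2, clipped to the profile bounds.
    """
    corrected = p.corrected_values()
    band_w_px = geom.band_width_mm * px_per_mm
    smoothed = _smooth(corrected, band_w_px)
    floor = max(MIN_PROMINENCE, 0.05 * float(smoothed.max(initial=0.0)))
    peaks, props = find_peaks(smoothed, prominence=floor)
    prominences = props["prominences"]

    expected = geom.line_spacing_mm * px_per_mm
    pairs = []
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            sep = peaks[j] - peaks[i]
            if abs(sep - expected) <= 0.25 * expected:
                pairs.append((prominences[i] + prominences[j], peaks[i], peaks[j]))
    if not pairs:
        if len(peaks) == 0:
            raise BandNotFoundError("no bands found on strip", missing="tl+cl")
        best = int(peaks[int(np.argmax(prominences))])
        # one usable peak: name the absent partner by expected position
        if best < len(corrected) / 2:
            missing, where = "cl", best + expected
        else:
            missing, where = "tl", best - expected
        raise BandNotFoundError(
            f"only one band found at {best} px; {missing} line missing "
            f"(expected near {where:.0f} px)",
            missing=missing,
        )
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    if len(pairs) > 1 and abs(pairs[0][0] - pairs[1][0]) < 1e-9 and (
        pairs[0][1:] != pairs[1][1:]
    ):
        raise AmbiguousBandsError(
            f"band pairs {pairs[0][1:]} and {pairs[1][1:]} tie in prominence"
        )
    _, tl_center, cl_center = pairs[0]

    half = 1.5 * band_w_px / 2.0
    calls = []
    for label, center in (("tl", int(tl_center)), ("cl", int(cl_center))):
        start = max(0, int(round(center - half)))
        stop = min(len(corrected), int(round(center + half)) + 1)
        idx = peaks.tolist().index(center)
        calls.append(
            BandCall(
                label=label,
                center_px=center,
                window_px=(start, stop),
                raw_area=float(p.values[start:stop].sum()),
                corrected_intensity=max(0.0, float(corrected[start:stop].sum())),
                prominence=float(prominences[idx]),
            )
        )
    return calls[0], calls[1]


def _saturation_flag(img: StripImage, geom: LaneGeometry, threshold: float) -> bool:
    """True if >threshold of ROI pixels sit at the 0/1 rails before inversion."""
    px = img.pixels
    if px.ndim == 3:
        px = px.reshape(px.shape[0], px.shape[1], -1)
        cols = _roi_slice(px.shape[1], geom.roi_width_fraction)
        roi = px[:, cols, :]
    else:
        cols = _roi_slice(px.shape[1], geom.roi_width_fraction)
        roi = px[:, cols]
    railed = np.mean((roi <= 0.0) | (roi >= 1.0))
    return bool(railed > threshold)


def quantify_strip(
    img: StripImage,
    geom: LaneGeometry | None = None,
    settings: QuantifySettings | None = None,
) -> StripMeasurement:
    """Full chain: channel -> orientation -> profile -> baseline -> bands -> ratios.

    If the image resolution is unknown it is estimated from the detected
    band separation and the printed line spacing.  A measurement with
    ``tl_intensity == 0`` is flagged ``tl_zero`` and has no normalized
    ratio; saturated images are flagged but still quantified.
    """
    geom = geom or LaneGeometry()
    settings = settings or QuantifySettings()

    flags = list(img.flags)
    if _saturation_flag(img, geom, settings.saturation_fraction):
        flags.append("saturated")

    signal = img if (img.is_signal and img.pixels.ndim == 2) else to_signal_channel(
        img, settings.channel
    )
    try:
        signal = canonicalize_orientation(signal, geom, settings.orientation_hint)
    except OrientationAmbiguousError:
        if signal.pixels.shape[0] == signal.pixels.shape[1]:
            raise  # square raster: not even the flow axis is known
        # proceed as-given so band detection can name what is missing
        signal = canonicalize_orientation(signal, geom, "tl_first")
        flags.append("orientation_assumed")

    profile = extract_profile(signal, geom)
    px_per_mm = signal.px_per_mm
    if px_per_mm is None:
        provisional = correct_baseline(profile, method="flank_linear", window_px=5)
        px_per_mm = estimate_px_per_mm(provisional, geom)

    window_px = max(3, int(round(settings.baseline_window_mm * px_per_mm)))
    corrected = correct_baseline(profile, settings.baseline_method, window_px)
    tl, cl = detect_bands(corrected, geom, px_per_mm)

    tl_i, cl_i = tl.corrected_intensity, cl.corrected_intensity
    if tl_i <= 0:
        flags.append("tl_zero")
    if cl_i <= 0:
        flags.append("cl_zero")
    return StripMeasurement(
        tl_intensity=tl_i,
        cl_intensity=cl_i,
        normalized=(cl_i / tl_i) if tl_i > 0 else None,
        standardized=(tl_i / cl_i) if cl_i > 0 else None,
        device=img.source_label,
        flags=flags,
    )


def measurements_to_frame(measurements: list[StripMeasurement]) -> pd.DataFrame:
    """Tabulate measurements in the interchange CSV layout."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "sample_id": m.sample_id,
                "device": m.device,
                "concentration_nM": m.concentration_nM,
                "replicate": m.replicate,
                "tl": m.tl_intensity,
                "cl": m.cl_intensity,
                "normalized": m.normalized,
                "standardized": m.standardized,
                "flags": ";".join(m.flags),
            }
        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def frame_to_measurements(df: pd.DataFrame) -> list[StripMeasurement]:
    """Inverse of :func:`measurements_to_frame`; accepts ImageJ-style CSVs.

    Only ``concentration_nM`` plus either intensities (``tl``, ``cl``) or
    precomputed ratios are required; missing ratio cells are derived from
    the intensities when possible.
    """
    out = []
    for _, row in df.iterrows():
        tl = float(row["tl"]) if "tl" in df.columns and pd.notna(row.get("tl")) else 0.0
        cl = float(row["cl"]) if "cl" in df.columns and pd.notna(row.get("cl")) else 0.0
        norm = row.get("normalized")
        std = row.get("standardized")
        norm = float(norm) if pd.notna(norm) else (cl / tl if tl > 0 else None)
        std = float(std) if pd.notna(std) else (tl / cl if cl > 0 else None)
        conc = row.get("concentration_nM")
        flags = row.get("flags", "")
        out.append(
            StripMeasurement(
                tl_intensity=tl,
                cl_intensity=cl,
                normalized=norm,
                standardized=std,
                concentration_nM=float(conc) if pd.notna(conc) else None,
                replicate=int(row.get("replicate", 0) or 0),
                device=str(row.get("device", "") or ""),
                sample_id=str(row.get("sample_id", "") or ""),
                flags=[f for f in str(flags or "").split(";") if f],
            )
        )
    return out
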