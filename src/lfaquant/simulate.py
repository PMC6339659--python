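"""Seeded synthetic strip images with exact ground truth.

The generator emulates what the densitometry chain actually sees on a
photographed gold-nanoparticle strip: two absorbing Gaussian bands 5 mm
apart on a light membrane, a smooth background gradient, and i.i.d. pixel
noise.  The darkness field along the flow position ``x`` (in px) is

    darkness(x) = offset + slope * x + sum_k A_k * exp(-(x - mu_k)^2 / (2 sigma^2))

replicated across the strip width; the rendered image is the pinkish-band
photo this implies (green channel = 1 - darkness).  Each band's analytic
area is ``A_k * sigma_px * sqrt(2*pi)``, so amplitude ratios translate
exactly into the area ratios the pipeline integrates.

:func:`generate_calibration_set` builds a whole dilution-series
experiment: per strip the target cl/tl ratio is drawn from the
ground-truth line ``r = beta0 + beta1 * c + eps`` and the two band
amplitudes are set to ``A_cl = A_ref * r / (1 + r)`` and
``A_tl = A_ref / (1 + r)``, making the analytic area ratio equal ``r`` by
construction — ground truth for the calibration line is exact without a
mechanistic binding model.  Every output is a pure function of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, ScenarioError
from .io import StripImage, write_strip_image

__all__ = [
    "SyntheticStripSpec",
    "CalibrationScenario",
    "CalibrationSet",
    "generate_strip",
    "generate_calibration_set",
    "write_calibration_set",
    "PAPER_CALIBRATION_DESIGN",
    "SERUM_DESIGN",
]

#: Dilution series of the pure-standard calibration: 0..100 nM, 5 replicates.
PAPER_CALIBRATION_DESIGN = (0.0, 1.0, 20.0, 40.0, 60.0, 80.0, 100.0)

#: Denser series used for spiked-serum samples, 3 replicates.
SERUM_DESIGN = (0.0, 1.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class SyntheticStripSpec:
    """Parameters of one synthetic strip image.

    Defaults: a 12 x 3 mm strip at 10 px/mm with the test line at 4 mm and
    the control line at 9 mm (the printed 5 mm spacing), band sigma 0.4 mm,
    and a mild upward background gradient.
    """

    length_px: int = 120
    width_px: int = 30
    px_per_mm: float = 10.0
    band_centers_mm: tuple[float, float] = (4.0, 9.0)  # (tl, cl)
    band_sigma_mm: float = 0.4
    band_amplitudes: tuple[float, float] = (0.3, 0.3)  # (tl, cl) darkness
    background: tuple[float, float] = (0.08, 0.0005)  # (offset, slope per px)
    noise_sd: float = 0.01
    seed: int = 0
    rgb: bool = True


def generate_strip(spec: SyntheticStripSpec) -> tuple[StripImage, dict]:
    """Render one strip and its ground-truth manifest.

    The manifest carries the band centers (px), the analytic band areas
    ``A_k * sigma_px * sqrt(2*pi)`` and the noiseless darkness profile.
    Identical spec (including seed) gives a bit-identical image.
    """
    offset, slope = spec.background
    bg_peak = offset + slope * max(spec.length_px - 1, 0)
    if max(spec.band_amplitudes) + max(offset, bg_peak) > 1.0:
        raise GenerationError(
            "band amplitude plus background exceeds 1: the image would clip"
        )
    x = np.arange(spec.length_px, dtype=float)
    sigma_px = spec.band_sigma_mm * spec.px_per_mm
    centers_px = tuple(c * spec.px_per_mm for c in spec.band_centers_mm)
    profile = offset + slope * x
    for amp, mu in zip(spec.band_amplitudes, centers_px):
        profile = profile + amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma_px**2))

    field2d = np.repeat(profile[:, None], spec.width_px, axis=1)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        field2d = field2d + rng.normal(0.0, spec.noise_sd, size=field2d.shape)
    field2d = np.clip(field2d, 0.0, 1.0)

    if spec.rgb:
        # pink/red bands on white membrane: green absorbs fully, red barely
        pixels = np.stack(
            [1.0 - 0.25 * field2d, 1.0 - field2d, 1.0 - 0.9 * field2d], axis=2
        )
    else:
        pixels = 1.0 - field2d

    img = StripImage(
        pixels=pixels, px_per_mm=spec.px_per_mm, source_label="synthetic"
    )
    manifest = {
        "tl_center_px": centers_px[0],
        "cl_center_px": centers_px[1],
        "band_sigma_px": sigma_px,
        "tl_area": spec.band_amplitudes[0] * sigma_px * np.sqrt(2.0 * np.pi),
        "cl_area": spec.band_amplitudes[1] * sigma_px * np.sqrt(2.0 * np.pi),
        "noiseless_profile": profile,
        "background": spec.background,
        "seed": spec.seed,
    }
    return img, manifest


@dataclass(frozen=True)
class CalibrationScenario:
    """A whole simulated dilution-series experiment.

    ``true_beta0``/``true_beta1`` define the ground-truth normalized
    (cl/tl) response line; ``ratio_noise_sd`` is the between-strip spread
    of the realized ratio around that line and is the scenario's
    stochastic element.  ``image_noise_sd`` optionally adds per-pixel
    noise to each rendered strip (off by default; note that pixel noise
    perturbs the densitometry itself, beyond the ratio-noise model).
    ``amplitude_ref`` is the summed band amplitude budget split between
    tl and cl.
    """

    concentrations_nM: tuple[float, ...] = PAPER_CALIBRATION_DESIGN
    replicates: int = 5
    true_beta0: float = 0.5
    true_beta1: float = 0.02
    ratio_noise_sd: float = 0.01
    device_label: str = "synthetic"
    seed: int = 0
    amplitude_ref: float = 0.6
    image_noise_sd: float = 0.0
    base_spec: SyntheticStripSpec = field(default_factory=SyntheticStripSpec)


@dataclass
class CalibrationSet:
    """In-memory result of :func:`generate_calibration_set`."""

    strips: list[tuple[StripImage, dict]]
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame


def generate_calibration_set(scn: CalibrationScenario) -> CalibrationSet:
    """Simulate every (concentration, replicate) strip of a scenario.

    Per strip the target ratio ``r`` is drawn from the ground-truth line;
    amplitudes ``A_cl = A_ref * r/(1+r)``, ``A_tl = A_ref/(1+r)`` make the
    analytic cl/tl area ratio exactly ``r``.  A non-positive target ratio
    (possible when beta0 is small and noise large) aborts the scenario.
    """
    rng = np.random.default_rng(scn.seed)
    strips, sheet_rows, truth_rows = [], [], []
    for conc in scn.concentrations_nM:
        for rep in range(1, scn.replicates + 1):
            eps = rng.normal(0.0, scn.ratio_noise_sd) if scn.ratio_noise_sd > 0 else 0.0
            r = scn.true_beta0 + scn.true_beta1 * conc + eps
            if r <= 0:
                raise ScenarioError(
                    f"target cl/tl ratio {r:.4g} <= 0 at {conc} nM; "
                    "adjust beta0/beta1 or ratio_noise_sd"
                )
            a_cl = scn.amplitude_ref * r / (1.0 + r)
            a_tl = scn.amplitude_ref / (1.0 + r)
            strip_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                scn.base_spec,
                band_amplitudes=(a_tl, a_cl),
                noise_sd=scn.image_noise_sd,
                seed=strip_seed,
            )
            img, manifest = generate_strip(spec)
            img.source_label = scn.device_label
            sample_id = f"c{conc:g}_r{rep}"
            strips.append((img, manifest))
            sheet_rows.append(
                {
                    "image_path": f"{sample_id}.png",
                    "concentration_nM": conc,
                    "replicate": rep,
                    "device": scn.device_label,
                }
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "concentration_nM": conc,
                    "replicate": rep,
                    "true_ratio": r,
                    "tl_amplitude": a_tl,
                    "cl_amplitude": a_cl,
                    "tl_area": manifest["tl_area"],
                    "cl_area": manifest["cl_area"],
                    "tl_center_px": manifest["tl_center_px"],
                    "cl_center_px": manifest["cl_center_px"],
                    "strip_seed": strip_seed,
                }
            )
    return CalibrationSet(
        strips=strips,
        sample_sheet=pd.DataFrame(sheet_rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_calibration_set(
    cal: CalibrationSet, out_dir: str | Path, fmt: str = "png"
) -> Path:
    """Write images plus ``sample_sheet.csv`` and ``truth.csv`` to a directory.

    PNG (lossless) is the default; ``fmt='jpeg'`` writes quality-85 JPEGs,
    adding realistic compression noise.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = cal.sample_sheet.copy()
    ext = "jpg" if fmt.lower() in ("jpg", "jpeg") else "png"
    paths = []
    for (img, _), stem in zip(cal.strips, cal.truth["sample_id"]):
        path = out_dir / f"{stem}.{ext}"
        write_strip_image(img, path)
        paths.append(path.name)  # relative to the sheet's own directory
    sheet["image_path"] = paths
    sheet.to_csv(out_dir / "sample_sheet.csv", index=False)
    cal.truth.to_csv(out_dir / "truth.csv", index=False)
    return out_dir / "sample_sheet.csv"
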