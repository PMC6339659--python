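import numpy as np
import pytest

from lfaquant import (
    LaneGeometry,
    StripMeasurement,
    SyntheticStripSpec,
    generate_strip,
)


@pytest.fixture
def geom():
    return LaneGeometry()


@pytest.fixture
def noiseless_strip():
    """Default synthetic strip with no pixel noise, plus its manifest."""
    return generate_strip(SyntheticStripSpec(noise_sd=0.0))


def make_measurements(concentrations, ratios, mode="normalized"):
    """Measurement list whose chosen ratio takes the given values.

    Intensities are chosen consistently (tl=1, cl=ratio for normalized),
    so both ratios stay defined and reciprocal.
    """
    out = []
    for i, (c, r) in enumerate(zip(concentrations, ratios)):
        if mode == "normalized":
            tl, cl = 1.0, float(r)
        else:
            tl, cl = float(r), 1.0
        out.append(
            StripMeasurement(
                tl_intensity=tl,
                cl_intensity=cl,
                normalized=cl / tl,
                standardized=tl / cl if cl > 0 else None,
                concentration_nM=float(c),
                replicate=i,
                sample_id=f"s{i}",
            )
        )
    return out


@pytest.fixture
def toy_line_measurements():
    """Exact line: ratio = 1 + 2*conc at conc 0, 1, 2."""
    return make_measurements([0, 1, 2], [1, 3, 5])
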