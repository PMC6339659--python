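"""Linear calibration of band-intensity ratios and LOB/LOD/LOQ statistics.

The competitive assay's response is the background-corrected control-line
over test-line intensity ratio, cl/tl ("normalized intensity"), which
rises with analyte concentration because the test line fades; the
reciprocal tl/cl ("standardized intensity") is supported as an
alternative response.  Over the assay's working range the response is
treated as a straight line,

    ratio = beta0 + beta1 * concentration + error,

fitted by ordinary least squares on individual replicates (not on
per-concentration means).  Concentrations are inverse-predicted as
``(ratio - beta0) / beta1``.

Two blank-statistic conventions for assay sensitivity are implemented,
both computed on the ratio scale and mapped to nmol/L through the inverse
fitted line:

method 1
    LOD = mean(blank) + 3 * sd(blank)
    LOQ = mean(blank) + 10 * sd(blank)

method 2
    LOB = mean(blank) + 1.645 * sd(blank)
    LOD = LOB + 1.645 * sd(1 nM replicates)
    LOQ = mean(blank) + 10 * sd(blank)

where sd is the sample standard deviation (n-1 denominator) within
replicates and "blank" means the chosen ratio at 0 nM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .densitometry import StripMeasurement, frame_to_measurements
from .errors import (
    DesignError,
    InsufficientBlanksError,
    InvalidInputError,
    Method2UnavailableError,
    NonInvertibleModelError,
    UndefinedCorrelationError,
)

__all__ = [
    "CalibrationModel",
    "CalibrationResult",
    "DetectionLimits",
    "fit_calibration",
    "replicate_stats",
    "predict_concentration",
    "limits_method1",
    "limits_method2",
    "pearson_vs_predicted",
]

MODES = ("normalized", "standardized")


def replicate_stats(
    values, confidence: float = 0.95
) -> tuple[float, float, float, float]:
    """Mean, sample SD and Student-t confidence interval of replicates.

    Returns ``(mean, sd, ci_low, ci_high)``.  The SD uses the n-1
    denominator and the CI is ``mean +- t_{1-alpha/2, n-1} * sd / sqrt(n)``.
    A single replicate yields its mean with sd/CI undefined (NaN).
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise InvalidInputError("replicate_stats: empty input")
    mean = float(values.mean())
    if values.size == 1:
        return mean, float("nan"), float("nan"), float("nan")
    sd = float(values.std(ddof=1))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, values.size - 1))
    half = tcrit * sd / math.sqrt(values.size)
    return mean, sd, mean - half, mean + half


@dataclass
class DetectionLimits:
    """LOB/LOD/LOQ on the ratio (intensity) scale and in nmol/L.

    ``lob_intensity``/``lob_nM`` are None for method 1, which defines no
    limit of blank.  ``scale_note`` records how the concentration-scale
    values were obtained (inverse fitted line).
    """

    method: int
    scale_note: str
    lod_intensity: float
    loq_intensity: float
    lob_intensity: float | None = None
    lod_nM: float | None = None
    loq_nM: float | None = None
    lob_nM: float | None = None


class CalibrationModel:
    """Straight-line calibration of an intensity ratio against concentration.

    Parameters
    ----------
    concentrations, ratios:
        Paired arrays over all replicates.
    mode:
        'normalized' (cl/tl, default) or 'standardized' (tl/cl); recorded
        for bookkeeping and used to pick the ratio column in the
        dataframe/measurement constructors.

    Use :meth:`from_measurements` or :meth:`from_dataframe` to build a
    model from pipeline output; measurements whose chosen ratio is
    undefined are collected in ``rejects`` and excluded from the fit.
    """

    def __init__(self, concentrations, ratios, mode: str = "normalized"):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        conc = np.asarray(list(concentrations), dtype=float)
        resp = np.asarray(list(ratios), dtype=float)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise InvalidInputError("concentrations and ratios must be equal-length 1-D")
        if np.unique(conc).size < 2:
            raise DesignError(
                "calibration needs at least 2 distinct concentrations, got "
                f"{np.unique(conc).size}"
            )
        self.concentrations = conc
        self.ratios = resp
        self.mode = mode
        self.rejects: list[StripMeasurement] = []

    @classmethod
    def from_measurements(
        cls, measurements: list[StripMeasurement], mode: str = "normalized"
    ) -> "CalibrationModel":
        attr = mode  # 'normalized' / 'standardized' are attribute names
        kept, rejects = [], []
        for m in measurements:
            ratio = getattr(m, attr, None)
            if ratio is None or m.concentration_nM is None or not np.isfinite(ratio):
                rejects.append(m)
            else:
                kept.append((m.concentration_nM, ratio))
        if len({c for c, _ in kept}) < 2:
            raise DesignError(
                "fewer than 2 distinct concentrations with a defined "
                f"{mode} ratio ({len(rejects)} measurement(s) rejected)"
            )
        model = cls([c for c, _ in kept], [r for _, r in kept], mode=mode)
        model.rejects = rejects
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mode: str = "normalized") -> "CalibrationModel":
        """Build from a measurement table (pipeline or ImageJ-exported CSV)."""
        return cls.from_measurements(frame_to_measurements(df), mode=mode)

    def fit(self, confidence: float = 0.95) -> "CalibrationResult":
        """Ordinary least squares of ratio on concentration."""
        X = sm.add_constant(self.concentrations)
        ols = sm.OLS(self.ratios, X).fit()
        return CalibrationResult(self, ols, confidence)


class CalibrationResult:
    """Fitted calibration line with replicate statistics and limit methods.

    Attributes
    ----------
    slope, intercept : float
        Line coefficients (ratio units per nM; ratio units).
    r_squared : float
        Coefficient of determination of the OLS fit.
    pearson_r : float
        Pearson correlation between observed ratios and fitted values.
    per_concentration : pandas.DataFrame
        mean / sd / CI of the ratio within each replicate group.
    """

    def __init__(self, model: CalibrationModel, ols_results, confidence: float = 0.95):
        self.model = model
        self.mode = model.mode
        self._ols = ols_results
        self.confidence = confidence
        self.intercept = float(ols_results.params[0])
        self.slope = float(ols_results.params[1])
        self.slope_se = float(ols_results.bse[1])
        ci = ols_results.conf_int(alpha=1 - confidence)
        self.slope_ci = (float(ci[1][0]), float(ci[1][1]))
        self.r_squared = float(ols_results.rsquared)
        self.n_points = int(ols_results.nobs)
        try:
            self.pearson_r = pearson_vs_predicted(self)
        except (UndefinedCorrelationError, InvalidInputError):
            # flat fit, flat data or < 3 points: correlation undefined
            self.pearson_r = float("nan")
        self.per_concentration = self._replicate_table(confidence)

    # -- construction helpers -------------------------------------------------
    def _replicate_table(self, confidence: float) -> pd.DataFrame:
        rows = []
        for conc in np.unique(self.model.concentrations):
            vals = self.model.ratios[self.model.concentrations == conc]
            mean, sd, lo, hi = replicate_stats(vals, confidence)
            rows.append(
                {
                    "concentration_nM": float(conc),
                    "n": int(vals.size),
                    "mean": mean,
                    "sd": sd,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)

    # -- prediction -----------------------------------------------------------
    def predict(self, concentrations) -> np.ndarray:
        """Ratio predicted by the fitted line."""
        c = np.asarray(concentrations, dtype=float)
        return self.intercept + self.slope * c

    def predict_concentration(self, ratio: float) -> float:
        """Inverse calibration: concentration (nM) for an observed ratio.

        Negative results are returned as-is; they indicate a response below
        the fitted blank level (below-range).
        """
        return predict_concentration(self, ratio)

    def group_ratios(self, concentration: float) -> np.ndarray:
        """All replicate ratios observed at one concentration."""
        return self.model.ratios[np.isclose(self.model.concentrations, concentration)]

    # -- detection limits -----------------------------------------------------
    def detection_limits(
        self, method: int = 1, blank_ratios=None, one_nM_ratios=None
    ) -> DetectionLimits:
        """LOB/LOD/LOQ by blank-statistic method 1 or 2.

        Blank (0 nM) and 1 nM replicate groups default to the model's own
        data; pass them explicitly to use external blank series.
        """
        if blank_ratios is None:
            blank_ratios = self.group_ratios(0.0)
        if method == 1:
            return limits_method1(blank_ratios, self)
        if method == 2:
            if one_nM_ratios is None:
                one_nM_ratios = self.group_ratios(1.0)
            return limits_method2(blank_ratios, one_nM_ratios, self)
        raise ValueError(f"method must be 1 or 2, got {method!r}")

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fit and replicate statistics."""
        lines = [
            f"Calibration fit ({self.mode} intensity, {self.n_points} points)",
            "-" * 58,
            f"  slope      {self.slope: .6g}  per nM   "
            f"[{self.slope_ci[0]:.6g}, {self.slope_ci[1]:.6g}] "
            f"{self.confidence:.0%} CI",
            f"  intercept  {self.intercept: .6g}",
            f"  R^2        {self.r_squared: .4f}",
            f"  Pearson r  {self.pearson_r: .4f} (observed vs predicted)",
            "",
            "Per-concentration replicate statistics:",
            self.per_concentration.to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
        ]
        if self.model.rejects:
            lines.append("")
            lines.append(f"Rejected measurements (undefined ratio): {len(self.model.rejects)}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One-row fit summary in the interchange CSV layout."""
        return pd.DataFrame(
            [
                {
                    "mode": self.mode,
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "pearson_r": self.pearson_r,
                    "n": self.n_points,
                }
            ]
        )

    def plot(self, ax=None):
        """Calibration scatter with the fitted line and replicate error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.model.concentrations, self.model.ratios, "o", ms=4, alpha=0.6,
                label="replicates")
        tab = self.per_concentration
        ax.errorbar(tab["concentration_nM"], tab["mean"], yerr=tab["sd"],
                    fmt="s", ms=4, capsize=3, color="k", label="mean +- SD")
        grid = np.linspace(self.model.concentrations.min(),
                           self.model.concentrations.max(), 50)
        ax.plot(grid, self.predict(grid), "-", color="C3",
                label=f"fit (R$^2$={self.r_squared:.3f})")
        ax.set_xlabel("concentration (nM)")
        ylabel = "cl/tl" if self.mode == "normalized" else "tl/cl"
        ax.set_ylabel(f"{self.mode} intensity ({ylabel})")
        ax.legend(fontsize=8)
        return ax


def fit_calibration(
    measurements: list[StripMeasurement], mode: str = "normalized"
) -> CalibrationResult:
    """OLS calibration fit over all replicates; see :class:`CalibrationModel`."""
    return CalibrationModel.from_measurements(measurements, mode=mode).fit()


def predict_concentration(fit: CalibrationResult, ratio: float) -> float:
    """Invert the fitted line: ``(ratio - intercept) / slope`` in nM."""
    if fit.slope == 0:
        raise NonInvertibleModelError("calibration slope is zero; cannot invert")
    return (float(ratio) - fit.intercept) / fit.slope


def pearson_vs_predicted(fit: CalibrationResult, measurements=None) -> float:
    """Pearson r between observed ratios and model-predicted ratios.

    By default uses the fit's own data; pass a measurement list to
    correlate an external set against its predictions.  For a simple OLS
    fit on its own data, ``r**2`` equals the fit's R-squared.
    """
    if measurements is None:
        observed = fit.model.ratios
        predicted = fit.predict(fit.model.concentrations)
    else:
        attr = fit.mode
        pairs = [
            (getattr(m, attr), m.concentration_nM)
            for m in measurements
            if getattr(m, attr) is not None and m.concentration_nM is not None
        ]
        observed = np.array([p[0] for p in pairs], dtype=float)
        predicted = fit.predict([p[1] for p in pairs])
    if observed.size < 3:
        raise InvalidInputError("pearson_vs_predicted needs at least 3 measurements")
    if np.std(observed) == 0 or np.std(predicted) == 0:
        raise UndefinedCorrelationError(
            "zero variance in observed or predicted ratios"
        )
    return float(np.corrcoef(observed, predicted)[0, 1])


def _limits_common(blank_ratios) -> tuple[float, float]:
    blanks = np.asarray(list(blank_ratios), dtype=float)
    if blanks.size < 2:
        raise InsufficientBlanksError(
            f"need >= 2 blank (0 nM) ratios, got {blanks.size}"
        )
    return float(blanks.mean()), float(blanks.std(ddof=1))


_SCALE_NOTE = (
    "concentration-scale limits via inverse fitted line (ratio - intercept)/slope"
)


def limits_method1(blank_ratios, fit: CalibrationResult | None = None) -> DetectionLimits:
    """LOD/LOQ from blank mean + 3 / + 10 blank SDs (no LOB defined)."""
    mean, sd = _limits_common(blank_ratios)
    lod_i = mean + 3.0 * sd
    loq_i = mean + 10.0 * sd
    lim = DetectionLimits(
        method=1, scale_note=_SCALE_NOTE, lod_intensity=lod_i, loq_intensity=loq_i
    )
    if fit is not None:
        lim.lod_nM = predict_concentration(fit, lod_i)
        lim.loq_nM = predict_concentration(fit, loq_i)
    return lim


def limits_method2(
    blank_ratios, one_nM_ratios, fit: CalibrationResult | None = None
) -> DetectionLimits:
    """LOB from blank statistics; LOD adds 1.645 SDs of the 1 nM group."""
    mean, sd = _limits_common(blank_ratios)
    ones = np.asarray(list(one_nM_ratios), dtype=float)
    if ones.size < 2:
        raise Method2UnavailableError(
            "method 2 needs >= 2 replicates at 1 nM to estimate sd(1 nM); "
            f"got {ones.size}"
        )
    lob_i = mean + 1.645 * sd
    lod_i = lob_i + 1.645 * float(ones.std(ddof=1))
    loq_i = mean + 10.0 * sd
    lim = DetectionLimits(
        method=2,
        scale_note=_SCALE_NOTE,
        lod_intensity=lod_i,
        loq_intensity=loq_i,
        lob_intensity=lob_i,
    )
    if fit is not None:
        lim.lob_nM = predict_concentration(fit, lob_i)
        lim.lod_nM = predict_concentration(fit, lod_i)
        lim.loq_nM = predict_concentration(fit, loq_i)
    return lim


def limits_to_frame(limits: list[DetectionLimits]) -> pd.DataFrame:
    """Tabulate limits on both scales in the interchange CSV layout."""
    rows = []
    for lim in limits:
        rows.append(
            {
                "method": lim.method,
                "scale": "intensity",
                "lob": lim.lob_intensity,
                "lod": lim.lod_intensity,
                "loq": lim.loq_intensity,
            }
        )
        rows.append(
            {
                "method": lim.method,
                "scale": "nM",
                "lob": lim.lob_nM,
                "lod": lim.lod_nM,
                "loq": lim.loq_nM,
            }
        )
    return pd.DataFrame(rows, columns=["method", "scale", "lob", "lod", "loq"])
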