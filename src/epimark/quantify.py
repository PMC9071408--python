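"""Peak integration and the normalization ladder for MRM nucleoside data.

The ladder has three relative stages plus an absolute branch:

1. **SILIS ratio** — per modification, the ratio of light (12C) to heavy
   (13C) peak area.  The co-injected stable-isotope-labelled internal
   standard gives every analyte a reference channel, cancelling injection
   and ionisation variability.  Modifications without a heavy partner keep
   their raw light-channel area.
2. **UV normalization** — division by the mean 254 nm UV area of the four
   canonical nucleosides, after subtracting the UV contribution attributed
   to the internal standard itself (its per-ng UV response times the
   nominal 50 ng added per injection).  This corrects for the amount of
   RNA actually injected.
3. **Mean scaling** — each modification row divided by its own mean across
   samples, putting all modifications on a common relative scale for
   heatmaps and PCA.

Absolute quantification converts a SILIS ratio through an external
calibration line into an injected amount, expressed as a percentage of the
adenosine UV signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .iodata import NormalizedMatrix, PeakTable, SampleMeta, TransitionTable, UVRecord

logger = logging.getLogger(__name__)

__all__ = [
    "QuantificationError",
    "Chromatogram",
    "CalibrationCurve",
    "ISTDSpec",
    "integrate_peak",
    "silis_ratio",
    "uv_normalizer",
    "normalize_sample",
    "build_matrix",
    "mean_scale",
    "fit_calibration",
    "absolute_percent_A",
    "AbsoluteResult",
]


class QuantificationError(ValueError):
    """Raised when a quantification step cannot proceed for a sample."""


@dataclass(frozen=True)
class Chromatogram:
    """An extracted-ion trace on a uniform time grid (minutes vs counts)."""

    times: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, float)
        y = np.asarray(self.intensity, float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and intensity must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class ISTDSpec:
    """Internal-standard settings for the UV normaliser.

    ``nominal_mass_per_injection`` is the mass of internal standard added per
    injection (ng; 50 by default).  ``uv_response_per_ng`` is the UV area the
    standard contributes per ng per canonical nucleoside; the default of 0
    makes the ISTD correction term explicit but inactive.
    """

    nominal_mass_per_injection: float = 50.0
    uv_response_per_ng: float = 0.0

    def __post_init__(self):
        if self.nominal_mass_per_injection <= 0:
            raise ValueError("nominal_mass_per_injection must be > 0")
        if self.uv_response_per_ng < 0:
            raise ValueError("uv_response_per_ng must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """External calibration line ratio = slope * ng + intercept."""

    modification: str
    slope: float
    intercept: float
    valid_range: tuple[float, float]
    r_squared: float = float("nan")

    def __post_init__(self):
        if self.slope <= 0:
            raise QuantificationError(f"{self.modification}: calibration slope must be > 0")
        if not self.valid_range[1] > self.valid_range[0] >= 0:
            raise QuantificationError(f"{self.modification}: empty calibration range")


def integrate_peak(
    chrom: Chromatogram, center: float, window: float
) -> tuple[float, float]:
    """Integrate a chromatographic peak and estimate its signal-to-noise.

    The AUC is the trapezoidal integral of the baseline-subtracted intensity
    within ``[center - window/2, center + window/2]``; the baseline is the
    median intensity outside the window.  S/N is the baseline-subtracted peak
    apex divided by a robust (MAD-based) SD of the out-of-window residuals;
    a flat zero trace yields (0, 0).
    """
    t, y = chrom.times, chrom.intensity
    lo, hi = center - window / 2.0, center + window / 2.0
    if lo < t[0] or hi > t[-1]:
        raise ValueError(
            f"integration window [{lo:g}, {hi:g}] outside trace span [{t[0]:g}, {t[-1]:g}]"
        )
    inside = (t >= lo) & (t <= hi)
    outside = ~inside
    if not inside.any() or not outside.any():
        raise ValueError("integration window must leave points on both sides")
    baseline = float(np.median(y[outside]))
    resid = y[inside] - baseline
    auc = float(np.trapezoid(np.clip(resid, 0.0, None), t[inside]))
    apex = float(resid.max(initial=0.0))
    out_resid = y[outside] - baseline
    mad = float(np.median(np.abs(out_resid - np.median(out_resid))))
    noise_sd = 1.4826 * mad
    if noise_sd == 0.0:
        snr = 0.0 if apex == 0.0 else float("inf")
    else:
        snr = apex / noise_sd
    return auc, max(snr, 0.0)


def silis_ratio(auc12: float, auc13: float, compound: str = "?", sample: str = "?") -> float:
    """Light/heavy area ratio; the heavy channel must carry signal."""
    if auc13 <= 0:
        raise QuantificationError(
            f"zero 13C internal-standard area for {compound} in sample {sample}"
        )
    return auc12 / auc13


def uv_normalizer(uv: UVRecord, istd: ISTDSpec = ISTDSpec()) -> float:
    """Sample loading normaliser from canonical UV areas.

    mean(C, U, G, A areas) minus the internal standard's attributed UV
    contribution (per-ng response x nominal ng per injection).  A
    non-positive corrected normaliser marks the sample unusable.
    """
    correction = istd.uv_response_per_ng * istd.nominal_mass_per_injection
    norm = uv.average - correction
    if norm <= 0:
        raise QuantificationError(
            f"sample {uv.sample_id}: UV normaliser non-positive after ISTD "
            f"correction ({uv.average:g} - {correction:g})"
        )
    return norm


def normalize_sample(
    peaks: PeakTable,
    uv: UVRecord,
    table: TransitionTable,
    istd: ISTDSpec = ISTDSpec(),
    sample: SampleMeta | str | None = None,
) -> pd.Series:
    """One sample's UV-normalised abundance column over the whole panel.

    SILIS members: (12C/13C area ratio) / UV normaliser.  Modifications
    without a heavy channel: raw 12C area / UV normaliser (these are in
    area-per-UV units rather than ratio-per-UV units and are excluded from
    absolute quantification downstream).
    """
    sample_id = sample.sample_id if isinstance(sample, SampleMeta) else (sample or uv.sample_id)
    norm = uv_normalizer(uv, istd)
    values = {}
    for mod in table.modifications:
        rec12 = peaks.get(sample_id, mod, "C12")
        if mod in table.silis_members:
            rec13 = peaks.get(sample_id, mod, "C13")
            values[mod] = silis_ratio(rec12.auc, rec13.auc, mod, sample_id) / norm
        else:
            values[mod] = rec12.auc / norm
    return pd.Series(values, name=sample_id)


def build_matrix(
    columns: Iterable[pd.Series],
    provenance: Iterable[str] = (),
) -> NormalizedMatrix:
    """Assemble per-sample columns from :func:`normalize_sample` into a matrix."""
    df = pd.concat(list(columns), axis=1)
    return NormalizedMatrix(df.fillna(0.0), "uv_normalized", provenance)


def mean_scale(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Divide each modification row by its own mean across samples.

    Output row means are 1 except for all-zero rows, which pass through
    unchanged with a warning.  Idempotent, and invariant to rescaling a
    row's raw inputs by a positive constant.
    """
    values = matrix.values.copy()
    means = values.mean(axis=1)
    zero_rows = means == 0
    if zero_rows.any():
        warnings.warn(
            f"mean_scale: all-zero rows pass through unchanged: "
            f"{list(values.index[zero_rows])}",
            stacklevel=2,
        )
    safe = means.where(~zero_rows, 1.0)
    scaled = values.div(safe, axis=0)
    return matrix.advance("mean_scaled", scaled, "row mean scaling (row / row mean)")


def fit_calibration(
    points: Sequence[tuple[float, float]], modification: str = "?"
) -> CalibrationCurve:
    """Ordinary least-squares line through (amount ng, SILIS ratio) points.

    Needs at least 3 points at 2 distinct amounts; the valid range is the
    span of calibrated amounts, and extrapolation beyond it is flagged by
    :func:`absolute_percent_A`.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise QuantificationError(f"{modification}: need >= 3 calibration points")
    ng, ratio = pts[:, 0], pts[:, 1]
    if len(np.unique(ng)) < 2:
        raise QuantificationError(f"{modification}: need >= 2 distinct calibration amounts")
    res = sp_stats.linregress(ng, ratio)
    if not np.isfinite(res.slope) or res.slope <= 0:
        raise QuantificationError(f"{modification}: degenerate calibration fit")
    return CalibrationCurve(
        modification=modification,
        slope=float(res.slope),
        intercept=float(res.intercept),
        valid_range=(float(ng.min()), float(ng.max())),
        r_squared=float(res.rvalue) ** 2,
    )


@dataclass(frozen=True)
class AbsoluteResult:
    """Absolute quantification outcome in % of the adenosine UV signal.

    ``flag`` is ``ok``, ``bdl`` (ratio at or below the calibration
    intercept: below detection limit, value 0) or ``above_range`` /
    ``below_range`` (amount outside the calibrated span; the value is still
    computed but must be interpreted with care).
    """

    modification: str
    value: float
    amount_ng: float
    flag: str


def absolute_percent_A(
    value: float,
    curve: CalibrationCurve,
    uv: UVRecord,
    uv_response_per_ng: float = 1.0,
) -> AbsoluteResult:
    """Convert a SILIS ratio to an absolute amount in % of adenosine UV.

    The ratio is inverted through the calibration line into ng, converted to
    a UV-area equivalent via the configured per-ng UV response, and expressed
    as a percentage of the sample's adenosine UV area.
    """
    if uv.area_A <= 0:
        raise QuantificationError(f"sample {uv.sample_id}: adenosine UV area must be > 0")
    if uv_response_per_ng <= 0:
        raise QuantificationError("uv_response_per_ng must be > 0 for absolute quantification")
    amount_ng = (value - curve.intercept) / curve.slope
    if amount_ng <= 0:
        return AbsoluteResult(curve.modification, 0.0, 0.0, "bdl")
    flag = "ok"
    if amount_ng > curve.valid_range[1]:
        flag = "above_range"
    elif amount_ng < curve.valid_range[0]:
        flag = "below_range"
    percent = 100.0 * (amount_ng * uv_response_per_ng) / uv.area_A
    return AbsoluteResult(curve.modification, percent, amount_ng, flag)
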