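"""Band-intensity readout, methylation calibration and group comparison.

The intensity readout reproduces the vendor "R-method": a straight chord is
drawn between the spectrum's values at two fixed frequency limits and the
peak height above that chord is read. Plotting those intensities against
the nominal methylation percentage of a mixture series gives a univariate
linear calibration whose inverse predicts the methylation fraction of an
unknown sample. Group comparison applies the same readout at the cellular
CH3 marker bands and reports per-marker differences with Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.signal import argrelextrema

from .spectrum import Spectrum


@dataclass(frozen=True)
class BandWindow:
    """A marker band plus the chord limits used to read its intensity."""

    label: str
    target: float
    hi_limit: float
    lo_limit: float

    def __post_init__(self) -> None:
        if self.hi_limit <= self.lo_limit:
            raise ValueError(f"window {self.label!r}: hi_limit must exceed lo_limit")
        if not self.lo_limit < self.target < self.hi_limit:
            raise ValueError(f"window {self.label!r}: target outside (lo, hi)")


# Chord limits for the synthetic-oligo CH3 markers: the stretches share one
# window (3012-2865 cm^-1), the bends have their own.
DEFAULT_SYNTHETIC_WINDOWS = (
    BandWindow("2984", 2984.0, 3012.0, 2865.0),
    BandWindow("2883", 2883.0, 3012.0, 2865.0),
    BandWindow("1478", 1478.0, 1513.0, 1437.0),
    BandWindow("1363", 1363.0, 1436.0, 1344.0),
)

# Cellular total-RNA CH3 markers, same chord-limit scheme.
DEFAULT_CELLULAR_WINDOWS = (
    BandWindow("2949", 2949.0, 3012.0, 2865.0),
    BandWindow("2883", 2883.0, 3012.0, 2865.0),
    BandWindow("1488", 1488.0, 1513.0, 1437.0),
    BandWindow("1359", 1359.0, 1436.0, 1344.0),
)


@dataclass
class PeakMeasurement:
    window: BandWindow
    apex_position: float
    intensity: float
    chord_endpoints: tuple[tuple[float, float], tuple[float, float]]
    below_baseline: bool = False


@dataclass
class CalibrationModel:
    """OLS fit of R-method intensity on methylation percentage."""

    marker: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residual_sd: float
    x_mean: float = 0.0
    x_ssq: float = 0.0  # sum of squared deviations of x (Sxx)


@dataclass
class PredictedFraction:
    """Inverse prediction: methylation percentage for a measured intensity."""

    fraction_pct: float
    se_pct: float
    out_of_range: bool


@dataclass
class MarkerComparison:
    window: BandWindow
    mean_a: float
    mean_b: float
    abs_difference: float
    rel_difference: float
    p_value: float | None
    direction: str  # "increase" | "decrease" | "no-change"


@dataclass
class ComparisonReport:
    markers: list[MarkerComparison]
    direction: str  # majority call across markers
    n_a: int
    n_b: int
    multiple_testing_correction: str = "none"


def _window_slice(s: Spectrum, w: BandWindow) -> np.ndarray:
    mask = (s.axis >= w.lo_limit - 1e-9) & (s.axis <= w.hi_limit + 1e-9)
    if mask.sum() < 3:
        raise ValueError(f"window {w.label!r} empty or outside the spectrum axis")
    return np.flatnonzero(mask)


#: Default half-width (cm^-1) of the apex search around a window's target.
APEX_SEARCH_RADIUS = 8.0


def band_intensity(
    s: Spectrum,
    w: BandWindow,
    mode: str = "auto",
    apex_radius: float = APEX_SEARCH_RADIUS,
) -> PeakMeasurement:
    """Read the R-method intensity of a marker band.

    A chord is drawn between the spectrum values at the grid points nearest
    the two frequency limits; the intensity is the absorbance above that
    chord at the apex. Apex selection modes:

    * ``"auto"`` (default): the local maximum within ``apex_radius`` of
      ``w.target`` nearest to it — emulating a peak pick at the defined
      marker position, and robust when two markers share one chord window —
      falling back to the grid point nearest the target when no local
      maximum is that close (flat spectra, or a marker band that is absent,
      then read only the chord-relative background).
    * ``"max"``: global maximum inside the open window.
    * ``"fixed"``: always read at the grid point nearest ``w.target``.
    """
    s.require_state("normalized")
    idx = _window_slice(s, w)
    i_hi = s.nearest_index(w.hi_limit)
    i_lo = s.nearest_index(w.lo_limit)
    x_hi, y_hi = float(s.axis[i_hi]), float(s.values[i_hi])
    x_lo, y_lo = float(s.axis[i_lo]), float(s.values[i_lo])
    chord_slope = (y_hi - y_lo) / (x_hi - x_lo)

    interior = idx[(idx != i_hi) & (idx != i_lo)]
    if interior.size == 0:
        raise ValueError(f"window {w.label!r} has no interior grid points")

    if mode == "fixed":
        apex_i = s.nearest_index(w.target)
    elif mode == "max":
        apex_i = int(interior[np.argmax(s.values[interior])])
    elif mode == "auto":
        sub = s.values[idx]
        rel = argrelextrema(sub, np.greater_equal, order=1)[0]
        # strict local maxima only (greater_equal + plateau dedup keeps flats out)
        rel = np.array([
            r for r in rel
            if 0 < r < sub.size - 1 and sub[r] > sub[r - 1] and sub[r] >= sub[r + 1]
        ], dtype=int)
        if rel.size:
            cand = idx[rel]
            dist = np.abs(s.axis[cand] - w.target)
            cand = cand[dist <= apex_radius]
        else:
            cand = np.array([], dtype=int)
        if cand.size:
            apex_i = int(cand[np.argmin(np.abs(s.axis[cand] - w.target))])
        else:
            apex_i = s.nearest_index(w.target)
    else:
        raise ValueError(f"unknown apex mode {mode!r}")

    x_apex = float(s.axis[apex_i])
    chord_at_apex = y_lo + chord_slope * (x_apex - x_lo)
    intensity = float(s.values[apex_i] - chord_at_apex)
    return PeakMeasurement(
        window=w,
        apex_position=x_apex,
        intensity=intensity,
        chord_endpoints=((x_hi, y_hi), (x_lo, y_lo)),
        below_baseline=intensity < 0,
    )


def find_band_position(s2: Spectrum, w: BandWindow) -> float:
    """Marker-band position from the second-derivative spectrum.

    Overlapped absorbance bands separate into distinct negative lobes in
    the 2nd derivative; the band position is the wavenumber of the most
    negative local minimum inside the window (ties break toward the lower
    wavenumber), reported at grid resolution.
    """
    s2.require_state("derivative2")
    idx = _window_slice(s2, w)
    sub = s2.values[idx]
    # a band is a *negative* lobe; the floor rejects floating-point dust on
    # featureless (e.g. exactly linear) segments
    floor = -1e-15 * max(1.0, float(np.max(np.abs(s2.values))))
    minima = [
        i for i in range(1, sub.size - 1)
        if sub[i] < sub[i - 1] and sub[i] <= sub[i + 1] and sub[i] < floor
    ]
    if not minima:
        raise ValueError(f"absent band: no local minimum inside window {w.label!r}")
    best = min(minima, key=lambda i: (sub[i], s2.axis[idx[i]]))
    return float(s2.axis[idx[best]])


def fit_calibration(
    points: Sequence[tuple[float, float]], marker: str = ""
) -> CalibrationModel:
    """OLS of intensity on methylation percentage.

    ``r_squared`` is the squared Pearson correlation of the fit;
    ``residual_sd`` uses n - 2 degrees of freedom. Zero intensity variance
    yields slope 0 with ``r_squared`` NaN (flagged, not an error).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (fraction, intensity) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all fractions equal")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if np.ptp(y) == 0:
        slope, intercept, r2 = 0.0, float(y[0]), float("nan")
        resid_sd = 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue) ** 2
        resid = y - (intercept + slope * x)
        resid_sd = float(np.sqrt(np.sum(resid**2) / (x.size - 2)))
    return CalibrationModel(
        marker=marker,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=int(x.size),
        residual_sd=resid_sd,
        x_mean=float(x.mean()),
        x_ssq=sxx,
    )


def predict_methylation(m: CalibrationModel, intensity: float) -> PredictedFraction:
    """Invert the calibration: fraction % = (intensity - intercept) / slope.

    The first-order inverse-prediction standard error is
    ``(residual_sd/|slope|) * sqrt(1 + 1/n + (x0 - x_mean)^2 / Sxx)``.
    Values outside [0, 100] are returned unclipped with ``out_of_range``.
    """
    if m.slope == 0:
        raise ValueError("zero slope: calibration cannot be inverted")
    x0 = (intensity - m.intercept) / m.slope
    if m.x_ssq > 0 and m.n_points > 0:
        se = (m.residual_sd / abs(m.slope)) * np.sqrt(
            1.0 + 1.0 / m.n_points + (x0 - m.x_mean) ** 2 / m.x_ssq
        )
    else:
        se = float("nan")
    return PredictedFraction(
        fraction_pct=float(x0),
        se_pct=float(se),
        out_of_range=not 0.0 <= x0 <= 100.0,
    )


def compare_groups(
    group_a: Sequence[Spectrum],
    group_b: Sequence[Spectrum],
    markers: Sequence[BandWindow] = DEFAULT_CELLULAR_WINDOWS,
    mode: str = "auto",
) -> ComparisonReport:
    """Compare two groups of normalised spectra at the CH3 marker bands.

    Group A is the control: relative difference = (B - A) / A. A two-tailed
    Welch t-test is reported per marker when both groups have >= 3
    replicates (unequal variances assumed; no multiple-testing correction
    is applied across markers). The overall direction is the majority call
    across markers.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must contain at least one spectrum")
    if not markers:
        raise ValueError("markers must be nonempty")
    results = []
    votes = {"increase": 0, "decrease": 0, "no-change": 0}
    for w in markers:
        ia = np.array([band_intensity(s, w, mode).intensity for s in group_a])
        ib = np.array([band_intensity(s, w, mode).intensity for s in group_b])
        mean_a, mean_b = float(ia.mean()), float(ib.mean())
        diff = mean_b - mean_a
        rel = diff / mean_a if mean_a != 0 else float("nan")
        if len(ia) >= 3 and len(ib) >= 3:
            if np.ptp(ia) == 0 and np.ptp(ib) == 0:
                # degenerate variances: a t-test is undefined, so report
                # p=1 for identical readings and no p at all otherwise
                p = 1.0 if mean_a == mean_b else None
            else:
                p = float(stats.ttest_ind(ia, ib, equal_var=False).pvalue)
        else:
            p = None
        if diff > 0:
            direction = "increase"
        elif diff < 0:
            direction = "decrease"
        else:
            direction = "no-change"
        votes[direction] += 1
        results.append(
            MarkerComparison(
                window=w,
                mean_a=mean_a,
                mean_b=mean_b,
                abs_difference=diff,
                rel_difference=rel,
                p_value=p,
                direction=direction,
            )
        )
    best = max(votes.values())
    winners = [k for k, v in votes.items() if v == best]
    overall = winners[0] if len(winners) == 1 else "no-change"
    return ComparisonReport(
        markers=results,
        direction=overall,
        n_a=len(group_a),
        n_b=len(group_b),
    )
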