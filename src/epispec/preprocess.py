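"""FT-IR preprocessing chain.

The chain mirrors routine ATR-FTIR practice for dried RNA films:

1. anchor-point baseline correction — straight lines interpolated between
   the spectrum's values at a fixed list of anchor wavenumbers are
   subtracted;
2. equal-area normalisation over 1750-1513 cm^-1, a base-vibration region
   free of CH3 contributions, so samples become comparable;
3. replicate averaging;
4. Savitzky-Golay second derivative (9-point window, quadratic polynomial)
   to resolve overlapped bands as separated minima;
5. a dryness QC metric: the integrated O-H stretching envelope
   (4000-3000 cm^-1), which stops changing once the film is dry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectrum import Spectrum

DEFAULT_ANCHORS = (
    3970.0, 3715.0, 2800.0, 2500.0, 1800.0, 1750.0, 1510.0,
    1438.0, 1315.0, 946.0, 895.0, 835.0, 801.0,
)


@dataclass(frozen=True)
class PreprocessConfig:
    anchors: tuple[float, ...] = DEFAULT_ANCHORS
    norm_range: tuple[float, float] = (1750.0, 1513.0)
    norm_target_area: float = 1.0
    sg_points: int = 9
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        a = np.asarray(self.anchors, dtype=float)
        if a.size < 2 or not np.all(np.diff(a) < 0):
            raise ValueError("anchors must be >= 2 strictly decreasing wavenumbers")
        if self.norm_target_area <= 0:
            raise ValueError("norm_target_area must be > 0")
        if self.sg_points < 5 or self.sg_points % 2 == 0:
            raise ValueError("sg_points must be an odd integer >= 5")
        if self.sg_polyorder >= self.sg_points:
            raise ValueError("sg_polyorder must be < sg_points")


def baseline_correct(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Subtract the piecewise-linear baseline through the spectrum's values
    at the anchor wavenumbers.

    Anchors snap to the nearest grid point. Outside the outermost anchors
    the nearest baseline segment is extended linearly. The corrected value
    at every anchor grid point is 0 (to machine precision), which also
    makes the operation idempotent.
    """
    cfg = cfg or PreprocessConfig()
    s.require_state("raw")
    lo, hi = float(np.min(s.axis)), float(np.max(s.axis))
    a = np.asarray(cfg.anchors, dtype=float)
    if a.min() < lo - 1e-9 or a.max() > hi + 1e-9:
        raise ValueError("anchor wavenumbers fall outside the spectrum axis span")

    idx = np.array([int(np.argmin(np.abs(s.axis - x))) for x in a])
    ax = s.axis[idx]  # descending, like the anchors
    ay = s.values[idx]
    # np.interp needs ascending x; extend the end segments linearly.
    xs, ys = ax[::-1], ay[::-1]
    baseline = np.interp(s.axis, xs, ys)
    below = s.axis < xs[0]
    if below.any():
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        baseline[below] = ys[0] + slope * (s.axis[below] - xs[0])
    above = s.axis > xs[-1]
    if above.any():
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        baseline[above] = ys[-1] + slope * (s.axis[above] - xs[-1])

    out = s.copy()
    out.values = s.values - baseline
    out.advance_state("baseline_corrected")
    return out


def _range_mask(axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    lo, hi = min(lo, hi), max(lo, hi)
    return (axis >= lo - 1e-9) & (axis <= hi + 1e-9)


def region_area(s: Spectrum, lo: float, hi: float, absolute: bool = True) -> float:
    """Trapezoid area of the spectrum over [lo, hi] on the stored grid."""
    mask = _range_mask(s.axis, lo, hi)
    if mask.sum() < 2:
        raise ValueError(f"axis does not cover [{lo}, {hi}]")
    x = s.axis[mask]
    y = s.values[mask]
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return float(np.trapezoid(np.abs(y) if absolute else y, x))


def normalize_area(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Scale the spectrum so the |absorbance| area over the base-vibration
    normalisation range equals ``norm_target_area``."""
    cfg = cfg or PreprocessConfig()
    s.require_state("baseline_corrected")
    hi, lo = cfg.norm_range
    area = region_area(s, lo, hi, absolute=True)
    if area <= 1e-300:
        raise ValueError("nonpositive area in the normalisation range")
    out = s.copy()
    out.values = s.values * (cfg.norm_target_area / area)
    out.advance_state("normalized")
    return out


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra sharing axis and state."""
    if not spectra:
        raise ValueError("empty spectrum collection")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.axis, first.axis):
            raise ValueError("spectra must share an identical axis")
        if s.state != first.state:
            raise ValueError("spectra must share the same processing_state")
    values = np.mean([s.values for s in spectra], axis=0)
    out = first.copy()
    out.values = values
    out.meta["source_ids"] = [s.meta.get("sample_id") for s in spectra]
    out.meta["n_averaged"] = len(spectra)
    return out


def sg_derivative(
    s: Spectrum, cfg: PreprocessConfig | None = None, order: int = 2
) -> Spectrum:
    """Savitzky-Golay derivative of the requested order.

    Units are per (cm^-1)^order regardless of storage direction (the filter
    runs over the stored array; odd-order results are sign-corrected for
    descending axes). Edges use a polynomial fit on the truncated window.
    """
    cfg = cfg or PreprocessConfig()
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    steps = np.diff(s.axis)
    if s.axis.size < cfg.sg_points:
        raise ValueError("spectrum shorter than the smoothing window")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("sg_derivative requires a uniform axis")
    step = float(steps[0])
    deriv = savgol_filter(
        s.values, cfg.sg_points, cfg.sg_polyorder, deriv=order,
        delta=abs(step), mode="interp",
    )
    if step < 0 and order % 2 == 1:
        deriv = -deriv
    out = s.copy()
    out.values = deriv
    if order == 2:
        out.advance_state("derivative2")
    else:
        out.meta["derivative_order"] = 1
    return out


def oh_stretch_area(s: Spectrum) -> float:
    """Integrated O-H stretching envelope (4000-3000 cm^-1), the dryness
    tracker: it plateaus once residual water has evaporated."""
    return region_area(s, 3000.0, 4000.0, absolute=False)


def is_dry(areas: Sequence[float], rel_tol: float = 0.02) -> bool:
    """True when the last four sequential O-H areas vary by less than
    ``rel_tol`` relative to their mean."""
    if len(areas) < 4:
        return False
    last = np.asarray(areas[-4:], dtype=float)
    mean = float(np.mean(np.abs(last)))
    if mean == 0.0:
        return True
    return float(np.ptp(last)) / mean < rel_tol


def preprocess_replicates(
    spectra: Sequence[Spectrum], cfg: PreprocessConfig | None = None
) -> tuple[Spectrum, Spectrum]:
    """Full chain on a replicate set: baseline-correct and normalise each,
    average, then second-differentiate the average.

    Returns ``(average_normalized, second_derivative)``.
    """
    cfg = cfg or PreprocessConfig()
    processed = [normalize_area(baseline_correct(s, cfg), cfg) for s in spectra]
    avg = average_spectra(processed)
    return avg, sg_derivative(avg, cfg, order=2)
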