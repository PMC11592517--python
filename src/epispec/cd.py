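"""Circular dichroism analysis: derivative, signed peak inventory,
condition-to-condition comparison.

For RNA the 200-300 nm CD pattern reports base stacking and helix
handedness; the A-form signature is a strong positive band near 265-267 nm
and a negative band near 209-210 nm. Peaks of both signs are inventoried
with their prominence, positions refined by the first-derivative zero
crossing, and two conditions are compared by nearest-position matching of
their inventories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .spectrum import CDSpectrum

#: Fraction of max |ellipticity| used as the automatic prominence floor.
AUTO_PROMINENCE_FRACTION = 0.02

#: Peak-matching radius (nm) for condition comparisons: larger than any
#: reported methylation-induced shift, smaller than inter-peak spacing.
DEFAULT_MATCH_RADIUS = 6.0

SG_POINTS = 9
SG_POLYORDER = 2


@dataclass
class CDPeak:
    position: float  # nm
    amplitude: float  # mdeg, signed
    sign: str  # "positive" | "negative"
    prominence: float  # mdeg, >= 0


@dataclass
class MatchedPeakPair:
    reference: CDPeak
    test: CDPeak
    d_position: float  # nm, test - reference
    d_amplitude: float  # mdeg, test - reference
    d_amplitude_pct: float  # % of reference amplitude


@dataclass
class CDComparison:
    matched: list[MatchedPeakPair]
    unmatched_reference: list[CDPeak]
    unmatched_test: list[CDPeak]


def cd_first_derivative(c: CDSpectrum) -> CDSpectrum:
    """Savitzky-Golay first derivative (9-point window, quadratic), per nm."""
    if c.derivative_order != 0:
        raise ValueError("input is already a derivative spectrum")
    steps = np.diff(c.axis)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        raise ValueError("cd_first_derivative requires a uniform axis")
    if c.axis.size < SG_POINTS:
        raise ValueError("spectrum shorter than the smoothing window")
    deriv = savgol_filter(
        c.values, SG_POINTS, SG_POLYORDER, deriv=1, delta=float(steps[0]),
        mode="interp",
    )
    out = c.copy()
    out.values = deriv
    out.meta["derivative_order"] = 1
    return out


def _refine_position(c: CDSpectrum, deriv: np.ndarray, i: int, is_max: bool) -> float:
    """Refine a grid extremum by the first-derivative zero crossing.

    Looks for a sign change of the derivative across the extremum within
    one grid step on each side; linear interpolation locates the root. If
    no clean crossing exists the grid position is kept.
    """
    sign = 1.0 if is_max else -1.0
    d = sign * deriv
    for j in (i - 1, i):
        if 0 <= j < d.size - 1 and d[j] >= 0.0 >= d[j + 1] and d[j] != d[j + 1]:
            t = d[j] / (d[j] - d[j + 1])
            pos = c.axis[j] + t * (c.axis[j + 1] - c.axis[j])
            if abs(pos - c.axis[i]) <= abs(c.axis[1] - c.axis[0]):
                return float(pos)
    return float(c.axis[i])


def find_cd_peaks(c: CDSpectrum, min_prominence: float | None = None) -> list[CDPeak]:
    """Inventory the signed extrema of a CD spectrum.

    Positive peaks are local maxima with positive ellipticity, negative
    peaks local minima with negative ellipticity; both must exceed
    ``min_prominence`` (default: 2% of max |ellipticity|). Positions are
    refined by the first-derivative zero crossing. Sorted by wavelength.
    An empty inventory is a valid result.
    """
    if c.derivative_order != 0:
        raise ValueError("find_cd_peaks expects an underivatised spectrum")
    v = c.values
    if not np.any(v):
        return []
    if min_prominence is None:
        min_prominence = AUTO_PROMINENCE_FRACTION * float(np.max(np.abs(v)))
    deriv = savgol_filter(
        v, SG_POINTS, SG_POLYORDER, deriv=1,
        delta=float(c.axis[1] - c.axis[0]), mode="interp",
    ) if c.axis.size >= SG_POINTS else np.gradient(v, c.axis)

    peaks: list[CDPeak] = []
    pos_idx, pos_props = find_peaks(v, prominence=min_prominence)
    for i, prom in zip(pos_idx, pos_props["prominences"]):
        if v[i] > 0:
            peaks.append(CDPeak(
                position=_refine_position(c, deriv, int(i), is_max=True),
                amplitude=float(v[i]),
                sign="positive",
                prominence=float(prom),
            ))
    neg_idx, neg_props = find_peaks(-v, prominence=min_prominence)
    for i, prom in zip(neg_idx, neg_props["prominences"]):
        if v[i] < 0:
            peaks.append(CDPeak(
                position=_refine_position(c, deriv, int(i), is_max=False),
                amplitude=float(v[i]),
                sign="negative",
                prominence=float(prom),
            ))
    peaks.sort(key=lambda p: p.position)
    return peaks


def compare_cd(
    reference: CDSpectrum,
    test: CDSpectrum,
    min_prominence: float | None = None,
    match_radius: float = DEFAULT_MATCH_RADIUS,
) -> CDComparison:
    """Match the peak inventories of two conditions and report the shifts.

    Pairs are formed greedily by smallest position distance within
    ``match_radius``; each peak enters at most one pair. Delta quantities
    are test minus reference, so swapping the arguments negates them.
    """
    if abs(reference.axis[0] - test.axis[0]) > 1e-9 or abs(
        reference.axis[-1] - test.axis[-1]
    ) > 1e-9:
        raise ValueError("reference and test spectra must share the axis span")
    ref_peaks = find_cd_peaks(reference, min_prominence)
    test_peaks = find_cd_peaks(test, min_prominence)

    pairs = sorted(
        (
            (abs(t.position - r.position), ri, ti)
            for ri, r in enumerate(ref_peaks)
            for ti, t in enumerate(test_peaks)
            if abs(t.position - r.position) <= match_radius
        ),
    )
    used_r: set[int] = set()
    used_t: set[int] = set()
    matched: list[MatchedPeakPair] = []
    for _, ri, ti in pairs:
        if ri in used_r or ti in used_t:
            continue
        used_r.add(ri)
        used_t.add(ti)
        r, t = ref_peaks[ri], test_peaks[ti]
        d_amp = t.amplitude - r.amplitude
        matched.append(MatchedPeakPair(
            reference=r,
            test=t,
            d_position=t.position - r.position,
            d_amplitude=d_amp,
            d_amplitude_pct=100.0 * d_amp / r.amplitude if r.amplitude else float("nan"),
        ))
    matched.sort(key=lambda p: p.reference.position)
    return CDComparison(
        matched=matched,
        unmatched_reference=[p for i, p in enumerate(ref_peaks) if i not in used_r],
        unmatched_test=[p for i, p in enumerate(test_peaks) if i not in used_t],
    )
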