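"""In-memory spectrum containers.

Two containers cover the whole pipeline: :class:`Spectrum` for FT-IR
absorbance traces (wavenumber domain, stored high-to-low following the
plotting convention of the field) and :class:`CDSpectrum` for circular
dichroism ellipticity traces (wavelength domain, ascending).

Every FT-IR processing stage stamps its output with a ``processing_state``
so that stages can refuse out-of-order application (e.g. normalising a
spectrum that was never baseline-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Forward-only processing states for FT-IR spectra, in pipeline order.
PROCESSING_STATES = ("raw", "baseline_corrected", "normalized", "derivative2")


def _state_rank(state: str) -> int:
    try:
        return PROCESSING_STATES.index(state)
    except ValueError:
        raise ValueError(f"unknown processing_state {state!r}") from None


@dataclass
class Spectrum:
    """An FT-IR absorbance spectrum on a strictly monotone wavenumber grid.

    Parameters
    ----------
    axis
        Wavenumbers in cm^-1, strictly monotone (conventionally descending,
        4000 -> 800).
    values
        Absorbance in arbitrary units, same length as ``axis``.
    meta
        Free-form metadata. Recognised keys: ``sample_id``, ``replicate``,
        ``f`` (nominal methylation fraction in [0, 1], or ``None`` for
        unknown), ``processing_state`` (defaults to ``"raw"``),
        ``source_ids`` (for averaged spectra), ``config_hash``.
    """

    axis: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.ndim != 1 or self.values.ndim != 1:
            raise ValueError("axis and values must be 1-D")
        if self.axis.shape != self.values.shape:
            raise ValueError(
                f"axis and values lengths differ: {self.axis.size} vs {self.values.size}"
            )
        d = np.diff(self.axis)
        if self.axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        self.meta.setdefault("processing_state", "raw")
        _state_rank(self.meta["processing_state"])

    # -- convenience ------------------------------------------------------

    @property
    def state(self) -> str:
        return self.meta["processing_state"]

    @property
    def f(self) -> float | None:
        """Nominal methylation fraction in [0, 1], or None if unknown."""
        return self.meta.get("f")

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis.copy(), self.values.copy(), dict(self.meta))

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.axis - wavenumber)))

    def value_at(self, wavenumber: float) -> float:
        """Absorbance at the grid point nearest to ``wavenumber``."""
        return float(self.values[self.nearest_index(wavenumber)])

    def advance_state(self, new_state: str) -> None:
        """Move the processing state forward; refuse to go backwards."""
        if _state_rank(new_state) <= _state_rank(self.state):
            raise ValueError(
                f"cannot move processing_state from {self.state!r} to {new_state!r}: "
                "states only advance forward"
            )
        self.meta["processing_state"] = new_state

    def require_state(self, expected: str) -> None:
        if self.state != expected:
            raise ValueError(
                f"expected a {expected!r} spectrum, got {self.state!r}"
            )


@dataclass
class CDSpectrum:
    """A circular dichroism spectrum: ellipticity (mdeg) vs wavelength (nm).

    The axis is ascending and must lie within the acquisition window of
    190-350 nm. ``meta['derivative_order']`` is 0 for a recorded spectrum
    and 1 after Savitzky-Golay first differentiation.
    """

    axis: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.ndim != 1 or self.values.ndim != 1:
            raise ValueError("axis and values must be 1-D")
        if self.axis.shape != self.values.shape:
            raise ValueError("axis and values lengths differ")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("CD axis must be strictly ascending")
        if self.axis.size and (self.axis[0] < 190.0 - 1e-9 or self.axis[-1] > 350.0 + 1e-9):
            raise ValueError("CD axis must lie within [190, 350] nm")
        self.meta.setdefault("derivative_order", 0)
        if self.meta["derivative_order"] not in (0, 1):
            raise ValueError("derivative_order must be 0 or 1")

    @property
    def derivative_order(self) -> int:
        return self.meta["derivative_order"]

    @property
    def condition(self) -> str | None:
        return self.meta.get("condition")

    def copy(self) -> "CDSpectrum":
        return CDSpectrum(self.axis.copy(), self.values.copy(), dict(self.meta))
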