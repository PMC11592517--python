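"""Synthetic spectrum generation.

Emulates the study's four data families without any instrument: (a) 30-nt
synthetic oligo FT-IR spectra with and without m6A, (b) v/v mixtures of the
0% and 100% methylated stocks, (c) cellular total-RNA spectra with a
reduced effective methylation range, and (d) CD spectra carrying the
A-form signature peaks under various conditions.

A spectrum is the signed sum of pseudo-Voigt bands (amplitudes scaled by
the methylation fraction according to each band's ``methyl_dependence``),
plus a low-order polynomial baseline drift and i.i.d. Gaussian noise whose
SD is a fraction of the largest catalogue amplitude. The band model is
linear in ``f``, which is what makes the downstream univariate calibration
well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bands import BandCatalog, cd_catalog
from .spectrum import CDSpectrum, Spectrum


@dataclass(frozen=True)
class BaselineDrift:
    """Polynomial drift (coefficients of t^0, t^1, ... on t in [0, 1] across
    the grid) plus an optional broad Gaussian hump (center, fwhm, amplitude)."""

    coeffs: tuple[float, ...] = ()
    hump: tuple[float, float, float] | None = None

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        out = np.zeros_like(axis, dtype=float)
        if self.coeffs:
            lo, hi = float(axis.min()), float(axis.max())
            t = (axis - lo) / (hi - lo) if hi > lo else np.zeros_like(axis)
            out += np.polynomial.polynomial.polyval(t, np.asarray(self.coeffs))
        if self.hump is not None:
            c, w, a = self.hump
            out += a * np.exp(-4.0 * np.log(2.0) * ((axis - c) / w) ** 2)
        return out


#: Default drift: quadratic, peaking at 5% of the strongest default band.
DEFAULT_FTIR_DRIFT = BaselineDrift(coeffs=(0.02, 0.015, 0.015))


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition-window and noise settings for the generator.

    Defaults follow the acquisition described for the study system:
    FT-IR 4000-800 cm^-1 at 2 cm^-1 resolution (stored descending), CD
    190-350 nm at 0.1 nm pitch (ascending). ``noise_sd_rel`` is the noise
    SD as a fraction of the largest band amplitude in the catalogue.
    """

    grid_start: float = 4000.0
    grid_end: float = 800.0
    grid_step: float = 2.0
    noise_sd_rel: float = 0.005
    baseline: BaselineDrift = field(default_factory=lambda: DEFAULT_FTIR_DRIFT)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if self.noise_sd_rel > 0 and self.seed is None:
            raise ValueError("a seed is required whenever noise_sd_rel > 0")

    @classmethod
    def ftir(cls, **kw) -> "GeneratorConfig":
        return cls(**kw)

    @classmethod
    def cd(cls, **kw) -> "GeneratorConfig":
        kw.setdefault("grid_start", 190.0)
        kw.setdefault("grid_end", 350.0)
        kw.setdefault("grid_step", 0.1)
        kw.setdefault("baseline", BaselineDrift())
        return cls(**kw)

    def grid(self) -> np.ndarray:
        """The acquisition grid, including both endpoints.

        Descending when ``grid_start > grid_end`` (FT-IR convention),
        ascending otherwise (CD convention).
        """
        n = int(round(abs(self.grid_start - self.grid_end) / self.grid_step)) + 1
        return np.linspace(self.grid_start, self.grid_end, n)


NOISE_FREE_FTIR = GeneratorConfig(noise_sd_rel=0.0, baseline=BaselineDrift())


def _band_sum(catalog: BandCatalog, f: float, axis: np.ndarray) -> np.ndarray:
    values = np.zeros_like(axis, dtype=float)
    for band in catalog:
        s = band.scale(f)
        if s == 0.0:
            continue
        values += band.sign * band.amplitude * s * band.profile(axis)
    return values


def generate_ftir(
    catalog: BandCatalog,
    f: float,
    config: GeneratorConfig | None = None,
    sample_id: str | None = None,
) -> Spectrum:
    """Generate one raw FT-IR spectrum at methylation fraction ``f``.

    Deterministic: identical (catalog, f, config incl. seed) reproduce the
    output bit-identically.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"methylation fraction f={f} outside [0, 1]")
    if catalog.domain != "ftir":
        raise ValueError("generate_ftir requires an FT-IR catalog")
    if not len(catalog):
        raise ValueError("empty catalog")
    cfg = config if config is not None else GeneratorConfig.ftir(seed=0)
    axis = cfg.grid()
    values = _band_sum(catalog, f, axis)
    values += cfg.baseline.evaluate(axis)
    if cfg.noise_sd_rel > 0:
        rng = np.random.default_rng(cfg.seed)
        values += rng.normal(0.0, cfg.noise_sd_rel * catalog.max_amplitude, axis.size)
    meta = {
        "f": float(f),
        "processing_state": "raw",
        "variant": catalog.variant,
    }
    if sample_id is not None:
        meta["sample_id"] = sample_id
    if cfg.seed is not None:
        meta["seed"] = cfg.seed
    return Spectrum(axis, values, meta)


def mix_spectra(
    s_meth: Spectrum,
    s_unmeth: Spectrum,
    parts_meth: int,
    parts_unmeth: int,
) -> Spectrum:
    """Volume-mix two raw stock spectra, e.g. 3:1 of the 100% and 0% stocks.

    Absorbance is additive in concentration, so an integer v/v mix of two
    stocks is the parts-weighted mean of their spectra; the nominal
    methylation label follows the same weighting.
    """
    if parts_meth < 0 or parts_unmeth < 0:
        raise ValueError("parts must be nonnegative")
    if parts_meth + parts_unmeth == 0:
        raise ValueError("parts must not both be zero")
    s_meth.require_state("raw")
    s_unmeth.require_state("raw")
    if s_meth.axis.shape != s_unmeth.axis.shape or not np.array_equal(
        s_meth.axis, s_unmeth.axis
    ):
        raise ValueError("stock spectra must share an identical axis")
    p, q = float(parts_meth), float(parts_unmeth)
    total = p + q
    values = (p * s_meth.values + q * s_unmeth.values) / total
    f_m = s_meth.f if s_meth.f is not None else 1.0
    f_u = s_unmeth.f if s_unmeth.f is not None else 0.0
    meta = {
        "f": (p * f_m + q * f_u) / total,
        "processing_state": "raw",
        "mix_parts": (parts_meth, parts_unmeth),
    }
    return Spectrum(s_meth.axis.copy(), values, meta)


def generate_cd(
    condition: str,
    config: GeneratorConfig | None = None,
    catalog: BandCatalog | None = None,
) -> CDSpectrum:
    """Generate one CD spectrum for a named condition.

    ``condition`` selects a default catalogue variant (see
    :data:`epispec.bands.CD_CONDITIONS`) unless an explicit CD ``catalog``
    is supplied.
    """
    cat = catalog if catalog is not None else cd_catalog(condition)
    if cat.domain != "cd":
        raise ValueError("generate_cd requires a CD catalog")
    cfg = config if config is not None else GeneratorConfig.cd(noise_sd_rel=0.0)
    axis = cfg.grid()
    if axis[0] > axis[-1]:
        raise ValueError("CD grid must be ascending (grid_start < grid_end)")
    values = np.zeros_like(axis)
    for band in cat:
        values += band.sign * band.amplitude * band.profile(axis)
    values += cfg.baseline.evaluate(axis)
    if cfg.noise_sd_rel > 0:
        rng = np.random.default_rng(cfg.seed)
        values += rng.normal(0.0, cfg.noise_sd_rel * cat.max_amplitude, axis.size)
    meta = {"condition": condition, "derivative_order": 0}
    if cfg.seed is not None:
        meta["seed"] = cfg.seed
    return CDSpectrum(axis, values, meta)


def generate_replicates(
    catalog: BandCatalog,
    f: float,
    config: GeneratorConfig,
    n: int,
    base_seed: int,
    sample_id: str | None = None,
) -> list[Spectrum]:
    """Generate ``n`` technical replicates with seeds base_seed + 0..n-1.

    Emulates repeated acquisition of the same dried sample: identical
    nominal ``f``, independent noise realisations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        cfg = replace(config, seed=base_seed + i)
        sid = f"{sample_id}_rep{i}" if sample_id is not None else None
        s = generate_ftir(catalog, f, cfg, sample_id=sid)
        s.meta["replicate"] = i
        out.append(s)
    return out


def mixture_series() -> list[tuple[int, int]]:
    """The v/v mixing design of the calibration experiment: 0:4, 1:3, 1:1,
    3:1, 4:0 parts of (methylated, unmethylated) stock -> 0/25/50/75/100%."""
    return [(0, 4), (1, 3), (1, 1), (3, 1), (4, 0)]


def mixture_fractions(design: Sequence[tuple[int, int]] | None = None) -> list[float]:
    design = design if design is not None else mixture_series()
    return [p / (p + q) for p, q in design]
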