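"""Band catalogues: the spectral ground truth behind the synthetic generator.

Each band is a pseudo-Voigt line whose amplitude may depend on the global
methylation fraction ``f`` of the sample:

* ``constant`` bands come from groups every RNA has (bases, phosphate,
  sugar, CH2) and ignore ``f``;
* ``proportional`` bands are the CH3 marker bands introduced by the methyl
  moiety of m6A/m1A and scale linearly with ``f``;
* ``complement`` bands scale with ``1 - f`` (e.g. the N-H stretching
  envelope, attenuated when N6 methylation converts NH2 to NH).

Band *positions* are empirical constants for RNA vibrational and electronic
transitions; widths and amplitudes are engineering choices documented in
``docs/methods.md`` (no instrument-resolved widths are available for this
system).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

METHYL_DEPENDENCES = ("constant", "proportional", "complement")


@dataclass(frozen=True)
class BandDefinition:
    """One pseudo-Voigt band.

    ``center`` and ``fwhm`` share units: cm^-1 for FT-IR, nm for CD.
    ``amplitude`` is the (nonnegative) peak height in absorbance units or
    mdeg; ``sign`` may be -1 only for CD bands (negative Cotton effects).
    ``shape_eta`` is the Lorentzian fraction of the pseudo-Voigt.
    """

    label: str
    center: float
    fwhm: float
    amplitude: float
    methyl_dependence: str = "constant"
    shape_eta: float = 0.1
    sign: int = 1

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band {self.label!r}: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band {self.label!r}: amplitude must be >= 0")
        if not 0.0 <= self.shape_eta <= 1.0:
            raise ValueError(f"band {self.label!r}: shape_eta must be in [0, 1]")
        if self.methyl_dependence not in METHYL_DEPENDENCES:
            raise ValueError(
                f"band {self.label!r}: methyl_dependence must be one of {METHYL_DEPENDENCES}"
            )
        if self.sign not in (-1, 1):
            raise ValueError(f"band {self.label!r}: sign must be +1 or -1")

    def scale(self, f: float) -> float:
        """Amplitude multiplier for methylation fraction ``f``."""
        if self.methyl_dependence == "proportional":
            return f
        if self.methyl_dependence == "complement":
            return 1.0 - f
        return 1.0

    def profile(self, x: np.ndarray) -> np.ndarray:
        """Unit-independent pseudo-Voigt profile evaluated on ``x``."""
        return pseudo_voigt(x, self.center, self.fwhm, self.shape_eta)


@dataclass
class BandCatalog:
    """An ordered collection of bands plus its domain and sample variant."""

    bands: list[BandDefinition]
    domain: str  # "ftir" | "cd"
    variant: str  # "synthetic_oligo" | "cellular" | a CD condition label

    def __post_init__(self) -> None:
        if self.domain not in ("ftir", "cd"):
            raise ValueError("domain must be 'ftir' or 'cd'")
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError("band labels must be unique")
        if self.domain == "ftir":
            for b in self.bands:
                if b.sign != 1:
                    raise ValueError(
                        f"absorbance band {b.label!r} cannot have negative sign"
                    )
                if not 800.0 <= b.center <= 4000.0:
                    raise ValueError(
                        f"FT-IR band {b.label!r} center outside 800-4000 cm^-1"
                    )
        else:
            for b in self.bands:
                if not 190.0 <= b.center <= 350.0:
                    raise ValueError(f"CD band {b.label!r} center outside 190-350 nm")

    @property
    def max_amplitude(self) -> float:
        if not self.bands:
            raise ValueError("empty catalog")
        return max(b.amplitude for b in self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Pseudo-Voigt profile: eta * Lorentzian + (1 - eta) * Gaussian.

    Both components are normalised to unit peak height, so the returned
    profile peaks at 1 at ``center``.
    """
    u = (np.asarray(x, dtype=float) - center) / fwhm
    lorentz = 1.0 / (1.0 + 4.0 * u * u)
    gauss = np.exp(-4.0 * np.log(2.0) * u * u)
    return eta * lorentz + (1.0 - eta) * gauss


# ---------------------------------------------------------------------------
# Default FT-IR catalogues
# ---------------------------------------------------------------------------

# Width classes (cm^-1). The CH bending bands use a narrower width so the
# CH2 bend at 1468 and the CH3 bend at 1478 overlap in absorbance yet
# resolve as two minima in the Savitzky-Golay 2nd derivative, and the
# sugar-backbone triplet (880/865/811) keeps distinct maxima.
_W_CH = 25.0        # C-H stretching region
_W_FINGER = 20.0    # generic fingerprint bands
_W_BEND = 10.0      # CH2/CH3 bending bands
_W_SUGAR = 10.0     # sugar-backbone marker bands
_W_ENVELOPE = 250.0  # broad O-H/N-H envelope

_B = BandDefinition


def _ftir_scaffold() -> list[BandDefinition]:
    """Bands common to every RNA sample (methylation independent except
    where noted).

    The O-H/N-H stretching envelope is split into a constant component and
    a co-centred complement component: N6 methylation converts the NH2 of
    adenine to NH, attenuating the N-H contribution as f grows.
    """
    return [
        _B("oh_nh_envelope", 3350.0, _W_ENVELOPE, 0.38),
        _B("nh_envelope", 3350.0, _W_ENVELOPE, 0.07, "complement", shape_eta=0.0),
        _B("ch2_asym_stretch_a", 2955.0, _W_CH, 0.10),
        _B("ch2_asym_stretch_b", 2920.0, _W_CH, 0.10),
        _B("ch2_sym_stretch", 2850.0, _W_CH, 0.08),
        _B("guanine_co", 1691.0, _W_FINGER, 0.85),
        _B("base_envelope", 1650.0, 35.0, 1.00),
        _B("adenine_ring_a", 1605.0, _W_FINGER, 0.55),
        _B("adenine_ring_b", 1573.0, _W_FINGER, 0.45),
        _B("ch2_bend", 1468.0, _W_BEND, 0.12),
        _B("backbone_def", 1340.0, _W_FINGER, 0.12),
        _B("po2_antisym", 1224.0, _W_FINGER, 0.60),
        _B("po2_sym", 1065.0, _W_FINGER, 0.70),
        _B("ribose_ring", 912.0, _W_SUGAR, 0.10),
    ]


def ftir_catalog(variant: str = "synthetic_oligo") -> BandCatalog:
    """Default FT-IR band catalogue.

    ``synthetic_oligo`` carries the CH3 markers of the 30-nt oligo system
    (2984/2883 cm^-1 stretches, 1478/1363 cm^-1 bends); ``cellular``
    shifts them to the total-RNA positions 2949 (broad)/2883/1488/1359
    cm^-1 and adds the N-type sugar markers at 861/810 cm^-1.
    """
    scaffold = _ftir_scaffold()
    if variant == "synthetic_oligo":
        markers = [
            _B("ch3_asym_stretch", 2984.0, _W_CH, 0.30, "proportional", shape_eta=0.0),
            _B("ch3_sym_stretch", 2883.0, _W_CH, 0.10, "proportional", shape_eta=0.0),
            _B("ch3_asym_bend", 1478.0, _W_BEND, 0.24, "proportional", shape_eta=0.0),
            _B("ch3_sym_bend", 1363.0, _W_BEND, 0.08, "proportional", shape_eta=0.0),
        ]
        sugars = [
            _B("sugar_n_type_880", 880.0, _W_SUGAR, 0.10),
            _B("sugar_n_type_865", 865.0, _W_SUGAR, 0.08),
            _B("sugar_n_type_811", 811.0, _W_SUGAR, 0.08),
        ]
    elif variant == "cellular":
        markers = [
            _B("ch3_asym_stretch", 2949.0, 35.0, 0.25, "proportional", shape_eta=0.0),
            _B("ch3_sym_stretch", 2883.0, _W_CH, 0.10, "proportional", shape_eta=0.0),
            _B("ch3_asym_bend", 1488.0, _W_BEND, 0.22, "proportional", shape_eta=0.0),
            _B("ch3_sym_bend", 1359.0, _W_BEND, 0.08, "proportional", shape_eta=0.0),
        ]
        sugars = [
            _B("sugar_n_type_880", 880.0, _W_SUGAR, 0.10),
            _B("sugar_n_type_861", 861.0, _W_SUGAR, 0.08),
            _B("sugar_n_type_810", 810.0, _W_SUGAR, 0.08),
        ]
    else:
        raise ValueError(f"unknown FT-IR catalog variant {variant!r}")
    return BandCatalog(scaffold + markers + sugars, domain="ftir", variant=variant)


# ---------------------------------------------------------------------------
# Default CD catalogues, one per experimental condition
# ---------------------------------------------------------------------------

_W_CD = 8.0  # nm

# A-form RNA signature: strong positive band near 265-267 nm, negative band
# near 209-210 nm, weak positive band near 222-224 nm (helical twisting);
# cellular total RNA adds a positive band near 198.7 nm.
_CD_VARIANTS: dict[str, list[BandDefinition]] = {
    # 30-nt synthetic oligos
    "synthetic_unmethylated": [
        _B("trough_209", 209.0, _W_CD, 5.0, sign=-1),
        _B("twist_222", 222.0, _W_CD, 1.0),
        _B("stack_267", 267.0, _W_CD, 6.0),
    ],
    # methylation deepens the 209 nm trough and shifts/strengthens 267 -> 266
    "synthetic_methylated": [
        _B("trough_209", 209.0, _W_CD, 6.5, sign=-1),
        _B("twist_222", 222.0, _W_CD, 1.0),
        _B("stack_266", 266.0, _W_CD, 7.2),
    ],
    # HeLa total RNA, negative-control siRNA
    "cellular_control": [
        _B("peak_198", 198.7, 6.0, 4.0),
        _B("trough_209", 209.7, _W_CD, 5.0, sign=-1),
        _B("twist_224", 224.0, _W_CD, 0.8),
        _B("stack_265", 265.8, 10.0, 6.0),
    ],
    # METTL3 knockdown: 209.7 trough about halved, 198.7 shifted down and
    # reduced, 224 reduced to a shoulder, 265.8 -> 265.6 with lower amplitude
    "cellular_mettl3_kd": [
        _B("peak_198", 198.0, 6.0, 2.5),
        _B("trough_209", 209.7, _W_CD, 2.5, sign=-1),
        _B("twist_224", 224.0, _W_CD, 0.4),
        _B("stack_265", 265.6, 10.0, 4.5),
    ],
    # TRMT61A knockdown: stronger perturbation, 265.8 -> 265.2 about halved
    "cellular_trmt61a_kd": [
        _B("peak_198", 197.8, 6.0, 2.0),
        _B("trough_209", 209.7, _W_CD, 2.2, sign=-1),
        _B("twist_224", 224.0, _W_CD, 0.3),
        _B("stack_265", 265.2, 10.0, 3.0),
    ],
    # cycloheximide control for the TNF-alpha stimulus experiment
    "cellular_chx": [
        _B("peak_198", 198.7, 6.0, 4.0),
        _B("trough_209", 209.6, _W_CD, 5.0, sign=-1),
        _B("twist_224", 224.0, _W_CD, 0.8),
        _B("stack_265", 265.5, 10.0, 6.0),
    ],
    # TNF-alpha treatment: 209.6 and 265.5 amplitudes reduced
    "cellular_tnfa": [
        _B("peak_198", 198.5, 6.0, 3.2),
        _B("trough_209", 209.6, _W_CD, 3.5, sign=-1),
        _B("twist_224", 224.0, _W_CD, 0.6),
        _B("stack_265", 265.5, 10.0, 4.5),
    ],
}

CD_CONDITIONS = tuple(_CD_VARIANTS)


def cd_catalog(condition: str) -> BandCatalog:
    """CD band catalogue for a named experimental condition."""
    try:
        bands = _CD_VARIANTS[condition]
    except KeyError:
        raise ValueError(
            f"unknown CD condition {condition!r}; known: {', '.join(CD_CONDITIONS)}"
        ) from None
    return BandCatalog(list(bands), domain="cd", variant=condition)
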