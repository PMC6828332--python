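"""Emission-spectrum registry and shape model for luciferase colour mutants.

The registry holds one entry per (enzyme, substrate) pair: three stabilised
firefly-luciferase colour mutants (``FLuc_green``, ``FLuc_natural``,
``FLuc_red``) crossed with four luciferin substrates (``LH2``, ``iLH2``,
``CycLuc1``, ``AkaLumine``).  Peak emission wavelengths are the in vitro
values characterised for these pairs; spectral widths and asymmetries are
shape-model parameters (luminometer-grade emission curves are not available
for every pair), documented as calibration choices in the package docs.

Spectra are rendered as skew-normal bells on a shared 1 nm wavelength grid
spanning 400-900 nm and normalised to unit area, so that downstream filter
integrals are directly comparable across reporters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import skewnorm

__all__ = [
    "WAVELENGTH_GRID",
    "ReporterPair",
    "EmissionSpectrum",
    "UnknownReporterError",
    "load_registry",
    "registry_pairs",
    "registry_lookup",
    "make_spectrum",
    "red_shift",
]

#: Shared wavelength grid (nm), 1 nm spacing over 400-900, used by every module.
WAVELENGTH_GRID: np.ndarray = np.arange(400.0, 900.0 + 0.5, 1.0)
WAVELENGTH_GRID.setflags(write=False)

ENZYMES = ("FLuc_green", "FLuc_natural", "FLuc_red")
SUBSTRATES = ("LH2", "iLH2", "CycLuc1", "AkaLumine")


class UnknownReporterError(KeyError):
    """Raised when an (enzyme, substrate) pair is not in the registry."""


@dataclass(frozen=True)
class ReporterPair:
    """One enzyme-substrate pair and its spectral/brightness parameters.

    Parameters
    ----------
    enzyme, substrate
        Names of the luciferase mutant and the luciferin.
    peak_nm
        In vitro peak emission wavelength (nm).
    fwhm_nm
        Full width at half maximum of the emission bell (nm).
    skew
        Dimensionless red-tail weight; 0 gives a symmetric bell.
    photon_yield
        Relative photons per cell per second, FLuc_natural-LH2 = 1.
    """

    enzyme: str
    substrate: str
    peak_nm: float
    fwhm_nm: float
    skew: float
    photon_yield: float

    def __post_init__(self) -> None:
        if not 500.0 <= self.peak_nm <= 800.0:
            raise ValueError(f"peak_nm {self.peak_nm} outside [500, 800]")
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.photon_yield <= 0:
            raise ValueError("photon_yield must be positive")

    @property
    def key(self) -> tuple[str, str]:
        return (self.enzyme, self.substrate)


@dataclass
class EmissionSpectrum:
    """Relative photon density per nm on the shared wavelength grid."""

    wavelength: np.ndarray
    density: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.wavelength.shape != self.density.shape:
            raise ValueError("wavelength and density must have the same shape")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    def total(self) -> float:
        """Trapezoidal integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.wavelength))

    def normalized(self) -> "EmissionSpectrum":
        """Return a copy scaled to unit area (idempotent)."""
        area = self.total()
        if area <= 0:
            raise ValueError("cannot normalise an all-zero spectrum")
        return EmissionSpectrum(self.wavelength, self.density / area, self.source)

    def peak_wavelength(self) -> float:
        return float(self.wavelength[int(np.argmax(self.density))])


def load_registry(path: "str | None" = None) -> dict[tuple[str, str], ReporterPair]:
    """Load a reporter registry from a JSON table.

    With no ``path``, loads the packaged default.  Custom registries use the
    same schema (a ``pairs`` list of entries) and can be swapped in anywhere
    a :class:`ReporterPair` is accepted.
    """
    if path is None:
        text = resources.files("glowmix.data").joinpath("reporter_registry.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = json.loads(text)
    registry: dict[tuple[str, str], ReporterPair] = {}
    for row in table["pairs"]:
        pair = ReporterPair(**row)
        if pair.key in registry:
            raise ValueError(f"duplicate registry entry {pair.key}")
        registry[pair.key] = pair
    return registry


_REGISTRY = load_registry()


def registry_pairs() -> tuple[ReporterPair, ...]:
    """All registry entries, in file order."""
    return tuple(_REGISTRY.values())


def registry_lookup(enzyme: str, substrate: str) -> ReporterPair:
    """Return the immutable registry entry for an (enzyme, substrate) pair."""
    try:
        return _REGISTRY[(enzyme, substrate)]
    except KeyError:
        raise UnknownReporterError(
            f"no registry entry for enzyme={enzyme!r}, substrate={substrate!r}; "
            f"known enzymes {ENZYMES}, substrates {SUBSTRATES}"
        ) from None


@lru_cache(maxsize=None)
def _standard_shape(a: float) -> tuple[float, float]:
    """Mode and half-max width of the standard skew-normal with shape ``a``."""
    res = minimize_scalar(lambda z: -skewnorm.pdf(z, a), bounds=(-3.0, 3.0), method="bounded")
    mode = float(res.x)
    half = skewnorm.pdf(mode, a) / 2.0
    left = brentq(lambda z: skewnorm.pdf(z, a) - half, mode - 12.0, mode)
    right = brentq(lambda z: skewnorm.pdf(z, a) - half, mode, mode + 12.0)
    return mode, float(right - left)


def make_spectrum(pair: ReporterPair) -> EmissionSpectrum:
    """Render the unit-area emission spectrum of a reporter pair.

    The curve is a skew-normal bell whose mode sits at ``pair.peak_nm`` and
    whose full width at half maximum equals ``pair.fwhm_nm``; ``pair.skew``
    sets the red-tail weight through the skew-normal shape parameter
    (``alpha = 4 * skew``).  Deterministic: equal pairs give identical arrays.
    """
    alpha = 4.0 * pair.skew
    mode0, width0 = _standard_shape(alpha)
    scale = pair.fwhm_nm / width0
    loc = pair.peak_nm - mode0 * scale
    density = skewnorm.pdf((WAVELENGTH_GRID - loc) / scale, alpha) / scale
    spec = EmissionSpectrum(
        WAVELENGTH_GRID.copy(), density, source=f"{pair.enzyme}+{pair.substrate}"
    )
    return spec.normalized()


def red_shift(pair_a: ReporterPair, pair_b: ReporterPair) -> float:
    """Peak-wavelength shift (nm) from ``pair_a`` to ``pair_b``, same enzyme.

    Positive when ``pair_b`` emits further into the red.
    """
    if pair_a.enzyme != pair_b.enzyme:
        raise ValueError(
            f"red_shift compares substrates for one enzyme; got "
            f"{pair_a.enzyme!r} vs {pair_b.enzyme!r}"
        )
    return float(pair_b.peak_nm - pair_a.peak_nm)
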