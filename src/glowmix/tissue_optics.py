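"""Depth- and wavelength-dependent tissue attenuation forward model.

A single effective attenuation coefficient mu_eff(lambda) (mm^-1) summarises
absorption and scattering; spectra are attenuated by the Beer-Lambert factor
exp(-mu_eff * depth).  The packaged default curve is synthetic, shaped by the
main features of mammalian soft tissue: strong haemoglobin absorption below
600 nm with the oxy-haemoglobin Q bands near 542 and 576 nm (leaving a local
transparency notch near 560 nm), a steep fall across 600-650 nm, and the low
near-infrared plateau of the 650-900 nm bio-optical window.  Its values are
calibration constants of this package, not measurements.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_model import WAVELENGTH_GRID, EmissionSpectrum

__all__ = [
    "AttenuationTable",
    "TissueContext",
    "CONTEXTS",
    "default_attenuation_table",
    "transmission",
    "apply_attenuation",
]


@dataclass
class AttenuationTable:
    """Effective attenuation coefficient (mm^-1) on the shared grid."""

    wavelength: np.ndarray
    mu_eff: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.mu_eff = np.asarray(self.mu_eff, dtype=float)
        if self.wavelength.shape != self.mu_eff.shape:
            raise ValueError("wavelength and mu_eff must have the same shape")
        if np.any(self.mu_eff <= 0):
            raise ValueError("mu_eff must be strictly positive everywhere")

    @classmethod
    def from_csv(cls, path: str | Path | io.IOBase) -> "AttenuationTable":
        """Load a two-column CSV (wavelength_nm, mu_eff_per_mm).

        Knot values are linearly interpolated onto the shared 1 nm grid.
        """
        frame = pd.read_csv(path)
        wl = frame["wavelength_nm"].to_numpy(float)
        mu = frame["mu_eff_per_mm"].to_numpy(float)
        order = np.argsort(wl)
        mu_grid = np.interp(WAVELENGTH_GRID, wl[order], mu[order])
        return cls(WAVELENGTH_GRID.copy(), mu_grid)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelength, "mu_eff_per_mm": self.mu_eff}
        ).to_csv(path, index=False)

    def mu_at(self, wavelength_nm: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated mu_eff; errors outside the table range."""
        wl = np.asarray(wavelength_nm, dtype=float)
        if np.any(wl < self.wavelength[0]) or np.any(wl > self.wavelength[-1]):
            raise ValueError(
                f"wavelength outside table range "
                f"[{self.wavelength[0]}, {self.wavelength[-1]}] nm"
            )
        return np.interp(wl, self.wavelength, self.mu_eff)


@dataclass(frozen=True)
class TissueContext:
    """Named imaging context: mean source depth and per-animal variability."""

    name: str
    depth_mm: float
    depth_sd_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_mm < 0:
            raise ValueError("depth_mm must be nonnegative")
        if self.name == "in_vitro" and self.depth_mm != 0:
            raise ValueError("in_vitro context must have depth 0")


#: Default contexts.  Depths are nominal source depths for the three tumour
#: models (superficial / intermediate / deep); they are config values, not
#: measured anatomy.
CONTEXTS: dict[str, TissueContext] = {
    "in_vitro": TissueContext("in_vitro", 0.0, 0.0),
    "subcutaneous": TissueContext("subcutaneous", 1.0, 0.5),
    "systemic": TissueContext("systemic", 4.0, 0.5),
    "intracranial": TissueContext("intracranial", 6.0, 0.5),
}


def default_attenuation_table() -> AttenuationTable:
    """The packaged synthetic mu_eff curve (see module docstring)."""
    text = resources.files("glowmix.data").joinpath("mu_eff_default.csv").read_text()
    return AttenuationTable.from_csv(io.StringIO(text))


def transmission(
    wavelength_nm: float | np.ndarray, depth_mm: float, table: AttenuationTable
) -> np.ndarray:
    """Beer-Lambert transmitted fraction exp(-mu_eff(lambda) * depth)."""
    if depth_mm < 0:
        raise ValueError("depth must be nonnegative")
    return np.exp(-table.mu_at(wavelength_nm) * depth_mm)


def apply_attenuation(
    spectrum: EmissionSpectrum, depth_mm: float, table: AttenuationTable
) -> EmissionSpectrum:
    """Attenuate a spectrum through ``depth_mm`` of tissue.

    The result is NOT renormalised: total photons decrease with depth, which
    is what makes deep sources dim as well as colour-shifted.
    """
    if spectrum.wavelength.shape != table.wavelength.shape or not np.allclose(
        spectrum.wavelength, table.wavelength
    ):
        raise ValueError("spectrum and attenuation table are on different grids")
    factor = np.exp(-table.mu_eff * depth_mm)
    return EmissionSpectrum(
        spectrum.wavelength.copy(), spectrum.density * factor, spectrum.source
    )
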