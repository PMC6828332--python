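"""Synthetic measurement generator for mixing plates, animal cohorts and the
tumour / engineered-T-cell time-course demo.

The generator realises the statistical structure the unmixing analysis
assumes: per-filter expectations are exactly linear in the green/red cell
fractions, depth attenuation acts on the emission spectra before the filter
bank, and counting noise is Poisson with additive Gaussian read noise.
A ``noise_free`` flag returns exact expectations (not a large-budget
approximation) so deterministic checks are float-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from .instrument import FilterBank, SpectralMeasurement, band_integral, full_bank
from .spectral_model import make_spectrum, registry_lookup
from .tissue_optics import (
    CONTEXTS,
    AttenuationTable,
    TissueContext,
    apply_attenuation,
    default_attenuation_table,
)

__all__ = [
    "MixtureDesign",
    "NoiseModel",
    "CarTKinetics",
    "simulate_sample",
    "simulate_plate",
    "simulate_cohort",
    "simulate_cart_timecourse",
]

#: Default cell load per well/animal; also the reference for the photon budget.
DEFAULT_CELLS = 1e6


@dataclass(frozen=True)
class MixtureDesign:
    """A mixing experiment: which green:red fractions, how many replicates.

    Defaults mirror the two validation designs: in vitro plates titrate the
    green population 0-100% with six replicate wells; in vivo cohorts engraft
    90:10 through 10:90 mixtures with four animals per condition.
    """

    fractions: tuple[float, ...]
    replicates: int
    cells: float = DEFAULT_CELLS
    substrate: str = "iLH2"
    context: TissueContext = CONTEXTS["in_vitro"]
    enzymes: tuple[str, str] = ("FLuc_green", "FLuc_red")

    def __post_init__(self) -> None:
        if len(self.fractions) == 0:
            raise ValueError("design needs at least one fraction")
        if any(not 0 <= f <= 100 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 100] percent")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def in_vitro_default(cls, substrate: str = "iLH2") -> "MixtureDesign":
        return cls((0, 10, 25, 50, 75, 90, 100), 6, substrate=substrate)

    @classmethod
    def in_vivo_default(
        cls, substrate: str = "iLH2", context: TissueContext | None = None
    ) -> "MixtureDesign":
        return cls(
            (90, 75, 50, 25, 10),
            4,
            substrate=substrate,
            context=context or CONTEXTS["systemic"],
        )


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise model for the simulated camera.

    ``photon_budget`` is the expected total count for a pure LH2 well of the
    default cell load at depth 0; iLH2 wells inherit their ~100x lower yield
    from the registry.  ``noise_free`` bypasses sampling and returns exact
    expectations.
    """

    photon_budget: float = 1e6
    read_noise_sd: float = 5.0
    seed: int = 0
    noise_free: bool = False

    def __post_init__(self) -> None:
        if self.photon_budget < 0:
            raise ValueError("photon_budget must be nonnegative")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@lru_cache(maxsize=64)
def _band_vector_cached(
    enzyme: str, substrate: str, depth_mm: float, centers: tuple[float, ...],
    bandwidth: float, transmission: float,
) -> np.ndarray:
    """Per-filter integrals of the attenuated unit-area spectrum."""
    bank = FilterBank(centers, bandwidth, transmission)
    spec = make_spectrum(registry_lookup(enzyme, substrate))
    spec = apply_attenuation(spec, depth_mm, _default_table())
    v = np.array([band_integral(spec, c, bank) for c in centers])
    v.setflags(write=False)
    return v


@lru_cache(maxsize=1)
def _default_table() -> AttenuationTable:
    return default_attenuation_table()


@lru_cache(maxsize=8)
def _reference_band_total(substrate_ref: str = "LH2") -> float:
    """Full-bank total for a pure FLuc_green-LH2 source at depth 0.

    Anchors the photon budget: expected counts scale so this source at the
    default cell load produces ``photon_budget`` counts in total.
    """
    bank = full_bank()
    v = _band_vector_cached(
        "FLuc_green", substrate_ref, 0.0, bank.centers, bank.bandwidth, bank.transmission
    )
    return float(v.sum())


def _expected_counts(
    green_cells: float,
    red_cells: float,
    substrate: str,
    depth_mm: float,
    bank: FilterBank,
    noise: NoiseModel,
    enzymes: tuple[str, str] = ("FLuc_green", "FLuc_red"),
) -> np.ndarray:
    yg = registry_lookup(enzymes[0], substrate).photon_yield
    yr = registry_lookup(enzymes[1], substrate).photon_yield
    vg = _band_vector_cached(
        enzymes[0], substrate, depth_mm, bank.centers, bank.bandwidth, bank.transmission
    )
    vr = _band_vector_cached(
        enzymes[1], substrate, depth_mm, bank.centers, bank.bandwidth, bank.transmission
    )
    scale = noise.photon_budget / _reference_band_total()
    return scale * (
        (green_cells / DEFAULT_CELLS) * yg * vg + (red_cells / DEFAULT_CELLS) * yr * vr
    )


def _sample_counts(expected: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.noise_free:
        return expected.copy()
    counts = rng.poisson(expected).astype(float)
    counts += rng.normal(0.0, noise.read_noise_sd, size=counts.shape)
    return np.clip(counts, 0.0, None)


def simulate_sample(
    green_fraction: float,
    design: MixtureDesign,
    noise: NoiseModel,
    depth_mm: float | None = None,
    bank: FilterBank | None = None,
    sample_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> SpectralMeasurement:
    """Simulate one well/animal at a given green-cell fraction.

    The expectation is linear in the fraction: ``f`` of the cells carry the
    green enzyme, ``1 - f`` the red one, each contributing its attenuated,
    filter-integrated, yield-weighted spectrum.
    """
    if not 0 <= green_fraction <= 100:
        raise ValueError("green_fraction must be in [0, 100]")
    bank = bank or full_bank()
    depth = design.context.depth_mm if depth_mm is None else depth_mm
    f = green_fraction / 100.0
    expected = _expected_counts(
        f * design.cells,
        (1.0 - f) * design.cells,
        design.substrate,
        depth,
        bank,
        noise,
        design.enzymes,
    )
    rng = rng if rng is not None else noise.rng()
    counts = _sample_counts(expected, noise, rng)
    return SpectralMeasurement(
        sample_id or f"sample_f{green_fraction:g}",
        bank.centers,
        counts,
        design.context.name,
        truth=float(green_fraction),
        depth_mm=depth,
    )


def simulate_plate(
    design: MixtureDesign, noise: NoiseModel, bank: FilterBank | None = None
) -> list[SpectralMeasurement]:
    """One measurement per (fraction, replicate); deterministic given the seed."""
    rng = noise.rng()
    out: list[SpectralMeasurement] = []
    for frac in design.fractions:
        for rep in range(design.replicates):
            out.append(
                simulate_sample(
                    frac,
                    design,
                    noise,
                    bank=bank,
                    sample_id=f"well_f{frac:g}_r{rep}",
                    rng=rng,
                )
            )
    return out


def simulate_cohort(
    design: MixtureDesign, noise: NoiseModel, bank: FilterBank | None = None
) -> list[SpectralMeasurement]:
    """Simulate an animal cohort with per-animal source-depth jitter.

    Each animal's depth is drawn Normal(depth_mm, depth_sd_mm), truncated
    below at 0.1 mm, then passed through the same forward model as a well.
    """
    if design.context.name == "in_vitro":
        raise ValueError("cohorts require an in vivo context")
    rng = noise.rng()
    out: list[SpectralMeasurement] = []
    for frac in design.fractions:
        for rep in range(design.replicates):
            depth = max(
                0.1,
                float(rng.normal(design.context.depth_mm, design.context.depth_sd_mm)),
            )
            out.append(
                simulate_sample(
                    frac,
                    design,
                    noise,
                    depth_mm=depth,
                    bank=bank,
                    sample_id=f"animal_f{frac:g}_r{rep}",
                    rng=rng,
                )
            )
    return out


@dataclass(frozen=True)
class CarTKinetics:
    """Demonstration kinetics for the tumour / engineered-T-cell time-course.

    Tumour (green reporter) grows exponentially; T cells (red reporter)
    expand logistically after dosing and suppress tumour signal through a
    Hill-type kill term.  Parameters are demo defaults in units of cells and
    per-day rates.
    """

    days: tuple[float, ...] = (3.0, 4.0, 6.0)
    tumour_cells0: float = 1e5
    tumour_growth: float = 0.3
    t_cell_dose: float = 1e3
    t_cell_growth: float = 1.2
    t_cell_capacity: float = 5e5
    kill_ec50: float = 1e5
    kill_hill: float = 2.0
    substrate: str = "iLH2"
    context: TissueContext = CONTEXTS["systemic"]

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise ValueError("days must be non-empty")
        for name in ("tumour_cells0", "tumour_growth", "t_cell_growth",
                     "t_cell_capacity", "kill_ec50", "kill_hill"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_cell_dose < 0:
            raise ValueError("t_cell_dose must be nonnegative")

    def t_cells(self, day: float) -> float:
        if self.t_cell_dose == 0:
            return 0.0
        grown = self.t_cell_dose * np.exp(self.t_cell_growth * day)
        return float(
            grown / (1.0 + self.t_cell_dose * (np.exp(self.t_cell_growth * day) - 1.0)
                     / self.t_cell_capacity)
        )

    def tumour(self, day: float, treated: bool) -> float:
        unchecked = self.tumour_cells0 * np.exp(self.tumour_growth * day)
        if not treated or self.t_cell_dose == 0:
            return float(unchecked)
        suppression = 1.0 + (self.t_cells(day) / self.kill_ec50) ** self.kill_hill
        return float(unchecked / suppression)


def simulate_cart_timecourse(
    params: CarTKinetics, noise: NoiseModel, bank: FilterBank | None = None
) -> list[SpectralMeasurement]:
    """Longitudinal measurements for a control and a treated animal.

    Sample ids are ``{control|treated}_d{day}``.  The control animal carries
    tumour only (green); the treated animal carries tumour plus red-labelled
    T cells.  ``truth`` records the true green percentage of total cells.
    """
    bank = bank or full_bank()
    rng = noise.rng()
    out: list[SpectralMeasurement] = []
    for arm, treated in (("control", False), ("treated", True)):
        for day in params.days:
            green = params.tumour(day, treated)
            red = params.t_cells(day) if treated else 0.0
            expected = _expected_counts(
                green, red, params.substrate, params.context.depth_mm, bank, noise
            )
            counts = _sample_counts(expected, noise, rng)
            total = green + red
            out.append(
                SpectralMeasurement(
                    f"{arm}_d{day:g}",
                    bank.centers,
                    counts,
                    params.context.name,
                    truth=100.0 * green / total if total > 0 else None,
                    depth_mm=params.context.depth_mm,
                )
            )
    return out
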