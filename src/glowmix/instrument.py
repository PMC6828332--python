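"""Bandpass-filter camera model: spectra -> per-filter radiance vectors.

Models a small-animal optical imager that acquires one image per bandpass
filter and reduces each to a region-of-interest (ROI) total.  The default
bank is 18 top-hat filters, 20 nm wide, centred 500-840 nm in 20 nm steps,
tiling 490-850 nm without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectral_model import EmissionSpectrum

__all__ = [
    "FilterBank",
    "SpectralMeasurement",
    "full_bank",
    "in_vivo_bank",
    "band_integral",
    "measure",
    "subset",
    "peak_filter",
    "measurements_to_frame",
    "measurements_to_csv",
    "measurements_from_csv",
    "read_tiff_measurement",
    "write_phantom_tiff",
]


@dataclass(frozen=True)
class FilterBank:
    """Top-hat bandpass filter set."""

    centers: tuple[float, ...]
    bandwidth: float = 20.0
    transmission: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, float)
        if c.size == 0:
            raise ValueError("filter bank needs at least one center")
        if np.any(np.diff(c) <= 0):
            raise ValueError("filter centers must be strictly increasing")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    def __len__(self) -> int:
        return len(self.centers)

    def index_of(self, center: float) -> int:
        try:
            return self.centers.index(center)
        except ValueError:
            raise KeyError(f"filter center {center} nm not in bank") from None


def full_bank() -> FilterBank:
    """The default 18-filter bank: 500, 520, ..., 840 nm, 20 nm wide."""
    return FilterBank(tuple(np.arange(500.0, 841.0, 20.0)))


def in_vivo_bank(substrate: str) -> FilterBank:
    """Acquisition presets for in vivo imaging.

    Shorter-wavelength filters carry no signal in vivo and are skipped:
    540-820 nm for LH2 and 600-820 nm for iLH2.
    """
    if substrate == "LH2":
        return FilterBank(tuple(np.arange(540.0, 821.0, 20.0)))
    if substrate == "iLH2":
        return FilterBank(tuple(np.arange(600.0, 821.0, 20.0)))
    raise ValueError(f"no in vivo acquisition preset for substrate {substrate!r}")


@dataclass
class SpectralMeasurement:
    """Per-filter ROI radiance vector for one sample (well or animal).

    ``truth`` optionally records the known green-cell fraction in percent;
    ``depth_mm`` the simulated source depth when applicable.
    """

    sample_id: str
    filter_centers: tuple[float, ...]
    radiance: np.ndarray
    context: str = "in_vitro"
    truth: float | None = None
    depth_mm: float | None = None

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=float)
        if len(self.filter_centers) != self.radiance.size:
            raise ValueError("radiance length must match filter count")
        if np.any(self.radiance < 0):
            raise ValueError("radiance must be nonnegative")

    def restricted(self, centers: Sequence[float]) -> "SpectralMeasurement":
        """The same sample seen through a subset of its filters."""
        idx = [self.filter_centers.index(c) for c in centers]
        return SpectralMeasurement(
            self.sample_id,
            tuple(centers),
            self.radiance[idx],
            self.context,
            self.truth,
            self.depth_mm,
        )


def band_integral(spectrum: EmissionSpectrum, center: float, bank: FilterBank) -> float:
    """Radiance through one top-hat filter: trapezoidal in-band integral."""
    bank.index_of(center)
    lo, hi = center - bank.bandwidth / 2.0, center + bank.bandwidth / 2.0
    wl, dens = spectrum.wavelength, spectrum.density
    mask = (wl >= lo) & (wl <= hi)
    if not np.any(mask):
        return 0.0
    return float(bank.transmission * np.trapezoid(dens[mask], wl[mask]))


def measure(
    spectrum: EmissionSpectrum,
    bank: FilterBank,
    flux: float = 1.0,
    sample_id: str = "sample",
    context: str = "in_vitro",
) -> SpectralMeasurement:
    """Noise-free camera reading: flux times each filter's band integral."""
    if flux < 0:
        raise ValueError("flux must be nonnegative")
    radiance = np.array([flux * band_integral(spectrum, c, bank) for c in bank.centers])
    return SpectralMeasurement(sample_id, bank.centers, radiance, context)


def subset(bank: FilterBank, centers: Iterable[float]) -> FilterBank:
    """Restrict a bank to the requested centers (returned in ascending order)."""
    wanted = list(centers)
    missing = [c for c in wanted if c not in bank.centers]
    if missing:
        raise KeyError(f"centers not in bank: {missing}")
    kept = tuple(c for c in bank.centers if c in set(wanted))
    return FilterBank(kept, bank.bandwidth, bank.transmission)


def peak_filter(measurement: SpectralMeasurement) -> float:
    """Center of the brightest filter; ties resolve to the longer wavelength."""
    r = measurement.radiance
    if not np.any(r > 0):
        raise ValueError("peak_filter undefined for an all-zero measurement")
    idx = r.size - 1 - int(np.argmax(r[::-1]))
    return float(measurement.filter_centers[idx])


# ---------------------------------------------------------------------------
# Tabular I/O (long format, one row per sample x filter)

def measurements_to_frame(measurements: Sequence[SpectralMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for c, r in zip(m.filter_centers, m.radiance):
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "context": m.context,
                    "filter_center_nm": c,
                    "radiance": r,
                    "truth_green_pct": m.truth,
                    "depth_mm": m.depth_mm,
                }
            )
    return pd.DataFrame(rows)


def measurements_to_csv(measurements: Sequence[SpectralMeasurement], path: str | Path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)


def measurements_from_csv(path: str | Path) -> list[SpectralMeasurement]:
    frame = pd.read_csv(path)
    out: list[SpectralMeasurement] = []
    for sid, grp in frame.groupby("sample_id", sort=False):
        grp = grp.sort_values("filter_center_nm")
        truth = grp["truth_green_pct"].iloc[0] if "truth_green_pct" in grp else None
        depth = grp["depth_mm"].iloc[0] if "depth_mm" in grp else None
        out.append(
            SpectralMeasurement(
                str(sid),
                tuple(grp["filter_center_nm"].astype(float)),
                grp["radiance"].to_numpy(float),
                str(grp["context"].iloc[0]),
                None if pd.isna(truth) else float(truth),
                None if depth is None or pd.isna(depth) else float(depth),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Optional image pathway: multi-page TIFF stacks reduced to ROI sums

def read_tiff_measurement(
    path: str | Path,
    centers: Sequence[float],
    roi: tuple[int, int, int, int],
    sample_id: str = "roi",
    context: str = "in_vitro",
) -> SpectralMeasurement:
    """Reduce a multi-page TIFF (one page per filter) to an ROI-total vector.

    ``roi`` is (row_start, row_stop, col_start, col_stop) in pixel indices.
    """
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.shape[0] != len(centers):
        raise ValueError(
            f"TIFF has {stack.shape[0]} pages but {len(centers)} centers given"
        )
    r0, r1, c0, c1 = roi
    sums = stack[:, r0:r1, c0:c1].reshape(stack.shape[0], -1).sum(axis=1)
    return SpectralMeasurement(
        sample_id, tuple(centers), np.clip(sums.astype(float), 0, None), context
    )


def write_phantom_tiff(
    path: str | Path,
    measurement: SpectralMeasurement,
    shape: tuple[int, int] = (32, 32),
    radius: int = 10,
) -> None:
    """Write a synthetic uniform-disc phantom stack for one measurement.

    Each page holds the sample's per-filter radiance spread uniformly over a
    centred disc; ROI sums over the disc recover the radiance vector.
    """
    import tifffile

    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    disc = ((yy - rows // 2) ** 2 + (xx - cols // 2) ** 2) <= radius**2
    n_pix = int(disc.sum())
    pages = np.zeros((len(measurement.filter_centers), rows, cols), dtype=np.float32)
    for i, r in enumerate(measurement.radiance):
        pages[i][disc] = r / n_pix
    tifffile.imwrite(path, pages)
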