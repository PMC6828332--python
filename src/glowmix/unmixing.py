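"""Library-based non-negative spectral unmixing.

The analysis core: build two-column library signatures from pure-population
measurements, decompose mixed measurements into nonnegative green/red
abundances by least squares, convert abundances into brightness-adjusted
percentages, and rank filter subsets by unmixing accuracy.

The central object is :class:`SpectralUnmixer`, a scikit-learn style
estimator: ``fit`` on pure-population radiance vectors labelled by reporter,
``transform`` mixed vectors into abundances, ``predict`` green percentages.
The module-level functions (`build_library`, `nnls_unmix`, `percent_unmixed`,
`subset_search`) are thin wrappers kept for pipeline-free use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .instrument import SpectralMeasurement

__all__ = [
    "LibrarySpectra",
    "Abundances",
    "SpectralUnmixer",
    "RankDeficientLibraryError",
    "build_library",
    "nnls_unmix",
    "percent_unmixed",
    "subset_search",
    "SubsetResult",
]

#: Condition numbers above this mark a signature pair as effectively collinear.
CONDITION_THRESHOLD = 1e6

GREEN_LABELS = {"green", "FLuc_green"}
RED_LABELS = {"red", "FLuc_red"}


class RankDeficientLibraryError(ValueError):
    """Signature matrix too ill-conditioned to unmix."""


@dataclass
class LibrarySpectra:
    """Unit-sum per-filter signatures of the two reporters.

    ``reference_radiance`` holds the mean total radiance of the pure
    populations the library was built from, used for brightness adjustment
    of unmixed percentages.
    """

    filter_centers: tuple[float, ...]
    signature_green: np.ndarray
    signature_red: np.ndarray
    substrate: str = ""
    context: str = ""
    condition_number: float = np.nan
    reference_radiance: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.signature_green = np.asarray(self.signature_green, float)
        self.signature_red = np.asarray(self.signature_red, float)
        for sig in (self.signature_green, self.signature_red):
            if sig.size != len(self.filter_centers):
                raise ValueError("signature length must match filter count")
            if np.any(sig < 0):
                raise ValueError("signatures must be nonnegative")
            if abs(sig.sum() - 1.0) > 1e-9:
                raise ValueError("signatures must sum to 1")

    @property
    def matrix(self) -> np.ndarray:
        """(n_filters, 2) signature matrix, columns green then red."""
        return np.column_stack([self.signature_green, self.signature_red])

    def restricted(self, centers: Sequence[float]) -> "LibrarySpectra":
        """Library renormalised onto a subset of its filters."""
        idx = [self.filter_centers.index(c) for c in centers]
        g = self.signature_green[idx]
        r = self.signature_red[idx]
        if g.sum() <= 0 or r.sum() <= 0:
            raise ValueError("restricted signature has zero total")
        g, r = g / g.sum(), r / r.sum()
        cond = float(np.linalg.cond(np.column_stack([g, r])))
        ref = None
        if self.reference_radiance is not None:
            # reference totals shrink by the fraction of signal the subset keeps
            keep_g = self.signature_green[idx].sum()
            keep_r = self.signature_red[idx].sum()
            ref = (
                self.reference_radiance[0] * keep_g,
                self.reference_radiance[1] * keep_r,
            )
        return LibrarySpectra(
            tuple(centers), g, r, self.substrate, self.context, cond, ref
        )

    def to_files(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        pd.DataFrame(
            {
                "filter_center_nm": self.filter_centers,
                "signature_green": self.signature_green,
                "signature_red": self.signature_red,
            }
        ).to_csv(csv_path, index=False)
        meta = {
            "substrate": self.substrate,
            "context": self.context,
            "condition_number": self.condition_number,
            "reference_radiance": self.reference_radiance,
        }
        sidecar = Path(json_path) if json_path else Path(csv_path).with_suffix(".json")
        sidecar.write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_files(cls, csv_path: str | Path, json_path: str | Path | None = None) -> "LibrarySpectra":
        frame = pd.read_csv(csv_path)
        sidecar = Path(json_path) if json_path else Path(csv_path).with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        ref = meta.get("reference_radiance")
        return cls(
            tuple(frame["filter_center_nm"].astype(float)),
            frame["signature_green"].to_numpy(float),
            frame["signature_red"].to_numpy(float),
            meta.get("substrate", ""),
            meta.get("context", ""),
            float(meta.get("condition_number", np.nan)),
            tuple(ref) if ref else None,
        )


@dataclass
class Abundances:
    """Nonnegative unmixing result for one measurement."""

    a_green: float
    a_red: float
    residual_norm: float
    pct_green: float | None = None
    pct_red: float | None = None


class SpectralUnmixer(BaseEstimator, TransformerMixin):
    """Two-endmember nonnegative spectral unmixer (scikit-learn API).

    Fit on pure-population per-filter radiance vectors ``X`` with labels
    ``y`` in {"green", "red"} (reporter names are accepted too).  Each class
    signature is the mean of its samples' unit-sum normalisations.

    Parameters
    ----------
    condition_threshold : float
        Condition number of the 2-column signature matrix above which the
        library is rejected as rank-deficient.

    Attributes
    ----------
    signatures_ : ndarray of shape (n_filters, 2)
        Columns are the green and red unit-sum signatures.
    condition_number_ : float
    reference_radiance_ : ndarray of shape (2,)
        Mean total radiance of the pure training samples per class; the
        brightness reference for percentage adjustment.
    """

    def __init__(self, condition_threshold: float = CONDITION_THRESHOLD):
        self.condition_threshold = condition_threshold

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y):
        X = check_array(X, ensure_min_features=2)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        sigs, refs = [], []
        for labels in (GREEN_LABELS, RED_LABELS):
            mask = np.isin(y, list(labels))
            if not mask.any():
                raise ValueError(f"no pure samples labelled {sorted(labels)}")
            block = X[mask]
            totals = block.sum(axis=1)
            if np.any(totals <= 0):
                raise ValueError("pure sample with zero total radiance")
            sigs.append((block / totals[:, None]).mean(axis=0))
            refs.append(totals.mean())
        self.signatures_ = np.column_stack(sigs)
        self.reference_radiance_ = np.asarray(refs)
        self.condition_number_ = float(np.linalg.cond(self.signatures_))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Nonnegative abundances, shape (n_samples, 2): green, red."""
        check_is_fitted(self, "signatures_")
        X = check_array(X)
        self._check_rank()
        out = np.empty((X.shape[0], 2))
        for i, row in enumerate(X):
            out[i], _ = self._solve(row)
        return out

    def predict(self, X) -> np.ndarray:
        """Brightness-adjusted green percentage per sample."""
        ab = self.transform(X)
        shares = ab / self.reference_radiance_[None, :]
        denom = shares.sum(axis=1)
        pct = np.full(ab.shape[0], np.nan)  # NaN where both abundances are 0
        ok = denom > 0
        pct[ok] = 100.0 * shares[ok, 0] / denom[ok]
        return pct

    def score(self, X, y) -> float:
        """Squared Pearson correlation between known and predicted percentages."""
        from .experiments import r_squared

        return r_squared(np.asarray(y, float), self.predict(X))

    # -- internals ----------------------------------------------------------
    def _check_rank(self) -> None:
        if not np.isfinite(self.condition_number_) or (
            self.condition_number_ > self.condition_threshold
        ):
            raise RankDeficientLibraryError(
                f"signature condition number {self.condition_number_:.3g} exceeds "
                f"threshold {self.condition_threshold:.3g}"
            )

    def _solve(self, v: np.ndarray) -> tuple[np.ndarray, float]:
        coef, resid = _scipy_nnls(self.signatures_, v)
        return coef, resid


def build_library(
    pure_measurements: Sequence[SpectralMeasurement],
    labels: Sequence[str],
    substrate: str = "",
    context: str = "",
) -> LibrarySpectra:
    """Average pure-population measurements into a two-signature library."""
    if len(pure_measurements) == 0:
        raise ValueError("no pure measurements given")
    centers = pure_measurements[0].filter_centers
    for m in pure_measurements:
        if m.filter_centers != centers:
            raise ValueError("pure measurements use different filter sets")
    X = np.vstack([m.radiance for m in pure_measurements])
    est = SpectralUnmixer().fit(X, np.asarray(labels))
    return LibrarySpectra(
        centers,
        est.signatures_[:, 0],
        est.signatures_[:, 1],
        substrate,
        context or pure_measurements[0].context,
        est.condition_number_,
        tuple(est.reference_radiance_),
    )


def _estimator_from_library(
    library: LibrarySpectra, condition_threshold: float = CONDITION_THRESHOLD
) -> SpectralUnmixer:
    est = SpectralUnmixer(condition_threshold)
    est.signatures_ = library.matrix
    est.condition_number_ = (
        library.condition_number
        if np.isfinite(library.condition_number)
        else float(np.linalg.cond(est.signatures_))
    )
    ref = library.reference_radiance or (1.0, 1.0)
    est.reference_radiance_ = np.asarray(ref, float)
    est.n_features_in_ = len(library.filter_centers)
    return est


def nnls_unmix(measurement: SpectralMeasurement, library: LibrarySpectra) -> Abundances:
    """Nonnegative least-squares decomposition of one measurement.

    Minimises the per-filter squared residual between the measurement and
    ``a_green * signature_green + a_red * signature_red`` over a_green,
    a_red >= 0.
    """
    if measurement.filter_centers != library.filter_centers:
        raise ValueError("measurement and library filter centers differ")
    est = _estimator_from_library(library)
    est._check_rank()
    coef, resid = est._solve(measurement.radiance)
    return Abundances(float(coef[0]), float(coef[1]), float(resid))


def percent_unmixed(
    abundances: Abundances, reference: tuple[float, float]
) -> tuple[float, float]:
    """Brightness-adjusted green/red percentages.

    Abundances are divided by the pure-population reference radiances so a
    50:50 cell mixture reads 50:50 even when the reporters differ in
    brightness; the two shares are then rescaled to sum to 100.
    """
    ref_g, ref_r = reference
    if ref_g <= 0 or ref_r <= 0:
        raise ValueError("reference radiances must be positive")
    share_g = abundances.a_green / ref_g
    share_r = abundances.a_red / ref_r
    if share_g + share_r <= 0:
        raise ValueError("both abundances are zero; percentages undefined")
    pct_green = 100.0 * share_g / (share_g + share_r)
    abundances.pct_green = pct_green
    abundances.pct_red = 100.0 - pct_green
    return pct_green, 100.0 - pct_green


@dataclass
class SubsetResult:
    centers: tuple[float, ...]
    r_squared: float
    condition_number: float
    ok: bool


def subset_search(
    plate: Sequence[SpectralMeasurement],
    library: LibrarySpectra,
    k: int,
    condition_threshold: float = CONDITION_THRESHOLD,
) -> list[SubsetResult]:
    """Exhaustively rank all k-filter subsets by unmixing accuracy.

    For every k-subset of the library's filters the library and the plate
    are restricted to those filters, every sample is unmixed, and the squared
    Pearson correlation between known and recovered green percentages is
    recorded.  Subsets whose restricted signatures are close to collinear
    (condition number above threshold) are flagged failed and sort last.
    Ties in accuracy resolve to lexicographically smaller center tuples.
    """
    from .experiments import r_squared

    n = len(library.filter_centers)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    truths = [m.truth for m in plate]
    if any(t is None for t in truths):
        raise ValueError("subset_search requires measurements with known truth")
    results: list[SubsetResult] = []
    for centers in combinations(library.filter_centers, k):
        try:
            lib_k = library.restricted(centers)
        except ValueError:
            results.append(SubsetResult(centers, np.nan, np.inf, False))
            continue
        if not np.isfinite(lib_k.condition_number) or (
            lib_k.condition_number > condition_threshold
        ):
            results.append(SubsetResult(centers, np.nan, lib_k.condition_number, False))
            continue
        est = _estimator_from_library(lib_k, condition_threshold)
        idx = [plate[0].filter_centers.index(c) for c in centers]
        X = np.vstack([m.radiance for m in plate])[:, idx]
        pct = est.predict(X)
        r2 = r_squared(np.asarray(truths, float), pct)
        results.append(SubsetResult(centers, r2, lib_k.condition_number, True))
    results.sort(key=lambda s: (not s.ok, -(s.r_squared if s.ok else 0.0), s.centers))
    return results
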