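import numpy as np
import pytest

from glowmix import (
    MixtureDesign,
    NoiseModel,
    RankDeficientLibraryError,
    SpectralMeasurement,
    SpectralUnmixer,
    build_library,
    nnls_unmix,
    percent_unmixed,
    simulate_cohort,
    simulate_plate,
    subset_search,
)
from glowmix.tissue_optics import TissueContext
from glowmix.unmixing import Abundances, LibrarySpectra

from conftest import grid_nnls


def _plate_and_library(substrate="iLH2", noise=None):
    noise = noise or NoiseModel(noise_free=True)
    plate = simulate_plate(MixtureDesign.in_vitro_default(substrate), noise)
    pure = [m for m in plate if m.truth in (0.0, 100.0)]
    labels = ["green" if m.truth == 100.0 else "red" for m in pure]
    return plate, build_library(pure, labels, substrate=substrate)


class TestBuildLibrary:
    def test_single_sample_signature_is_its_unit_normalisation(self):
        m_g = SpectralMeasurement("g", (600.0, 700.0), np.array([1.0, 3.0]))
        m_r = SpectralMeasurement("r", (600.0, 700.0), np.array([4.0, 1.0]))
        lib = build_library([m_g, m_r], ["green", "red"])
        assert np.allclose(lib.signature_green, [0.25, 0.75])
        assert np.allclose(lib.signature_red, [0.8, 0.2])

    def test_duplicate_replicates_do_not_change_signature(self):
        m_g = SpectralMeasurement("g", (600.0, 700.0), np.array([1.0, 3.0]))
        m_r = SpectralMeasurement("r", (600.0, 700.0), np.array([4.0, 1.0]))
        one = build_library([m_g, m_r], ["green", "red"])
        two = build_library([m_g, m_g, m_r], ["green", "green", "red"])
        assert np.allclose(one.signature_green, two.signature_green)

    def test_systemic_infra_green_signature_peaks_at_700(self, bank):
        ctx = TissueContext("systemic", 4.0, 0.0)
        design = MixtureDesign((100.0, 0.0), 2, substrate="iLH2", context=ctx)
        cohort = simulate_cohort(design, NoiseModel(noise_free=True))
        labels = ["green" if m.truth == 100.0 else "red" for m in cohort]
        lib = build_library(cohort, labels)
        i = lib.filter_centers.index(
            lib.filter_centers[int(np.argmax(lib.signature_green))]
        )
        assert lib.filter_centers[i] == 700.0

    def test_missing_class_rejected(self):
        m = SpectralMeasurement("g", (600.0, 700.0), np.array([1.0, 3.0]))
        with pytest.raises(ValueError, match="red"):
            build_library([m], ["green"])

    def test_zero_total_sample_rejected(self):
        m_g = SpectralMeasurement("g", (600.0, 700.0), np.zeros(2))
        m_r = SpectralMeasurement("r", (600.0, 700.0), np.array([4.0, 1.0]))
        with pytest.raises(ValueError, match="zero"):
            build_library([m_g, m_r], ["green", "red"])

    def test_signatures_sum_to_one(self):
        _, lib = _plate_and_library()
        assert lib.signature_green.sum() == pytest.approx(1.0, abs=1e-12)
        assert lib.signature_red.sum() == pytest.approx(1.0, abs=1e-12)


class TestNnlsUnmix:
    def test_scaled_pure_column_recovered_exactly(self):
        _, lib = _plate_and_library()
        m = SpectralMeasurement("x", lib.filter_centers, 5.0 * lib.signature_green)
        ab = nnls_unmix(m, lib)
        assert ab.a_green == pytest.approx(5.0, abs=1e-9)
        assert ab.a_red == pytest.approx(0.0, abs=1e-9)

    def test_zero_measurement_gives_zero_abundances(self):
        _, lib = _plate_and_library()
        m = SpectralMeasurement("x", lib.filter_centers, np.zeros(len(lib.filter_centers)))
        ab = nnls_unmix(m, lib)
        assert ab.a_green == 0.0 and ab.a_red == 0.0

    def test_perturbed_mixture_matches_grid_search_oracle(self):
        _, lib = _plate_and_library()
        rng = np.random.default_rng(7)
        v = 0.3 * lib.signature_green + 0.7 * lib.signature_red
        v = np.clip(v + rng.normal(0, 0.002, v.size), 0, None)
        ab = nnls_unmix(SpectralMeasurement("x", lib.filter_centers, v), lib)
        best, best_resid = grid_nnls(lib.matrix, v, upper=2.0, step=1e-3)
        assert ab.a_green == pytest.approx(best[0], abs=2e-3)
        assert ab.a_red == pytest.approx(best[1], abs=2e-3)
        assert ab.residual_norm <= best_resid + 1e-9

    def test_oracle_equivalence_on_randomised_instances(self):
        # solver vs exhaustive nonnegative grid search on random 2-column
        # problems: the solver's residual can never exceed the grid's
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = rng.integers(3, 10)
            A = rng.random((n, 2))
            A /= A.sum(axis=0)
            v = np.clip(
                A @ (2.0 * rng.random(2)) + rng.normal(0, 0.01, n), 0, None
            )
            est = SpectralUnmixer()
            est.signatures_ = A
            est.condition_number_ = np.linalg.cond(A)
            est.reference_radiance_ = np.ones(2)
            est.n_features_in_ = n
            coef, resid = est._solve(v)
            _, grid_resid = grid_nnls(A, v, upper=3.0, step=1e-3)
            assert resid <= grid_resid + 1e-9
            assert resid >= (grid_resid - 1e-3) * (1 - 1e-6) - 1e-9

    def test_filter_mismatch_rejected(self):
        _, lib = _plate_and_library()
        m = SpectralMeasurement("x", (600.0, 700.0), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="filter"):
            nnls_unmix(m, lib)

    def test_collinear_library_rejected(self):
        sig = np.array([0.2, 0.8])
        lib = LibrarySpectra((600.0, 700.0), sig, sig.copy(), condition_number=np.inf)
        m = SpectralMeasurement("x", (600.0, 700.0), np.array([1.0, 1.0]))
        with pytest.raises(RankDeficientLibraryError):
            nnls_unmix(m, lib)

    def test_scale_invariance(self):
        _, lib = _plate_and_library()
        v = 0.4 * lib.signature_green + 0.6 * lib.signature_red
        a1 = nnls_unmix(SpectralMeasurement("x", lib.filter_centers, v), lib)
        a2 = nnls_unmix(SpectralMeasurement("x", lib.filter_centers, 37.0 * v), lib)
        assert a2.a_green == pytest.approx(37.0 * a1.a_green, rel=1e-9)
        assert a2.a_red == pytest.approx(37.0 * a1.a_red, rel=1e-9)
        ref = lib.reference_radiance
        p1 = percent_unmixed(a1, ref)
        p2 = percent_unmixed(a2, ref)
        assert p1[0] == pytest.approx(p2[0], abs=1e-9)


class TestPercentUnmixed:
    def test_pure_green_is_100(self):
        ab = Abundances(3.0, 0.0, 0.0)
        assert percent_unmixed(ab, (1.0, 1.0)) == (100.0, 0.0)

    def test_brightness_correction_formula(self):
        # hand evaluation: (1/2) / (1/2 + 1/1) = 1/3
        ab = Abundances(1.0, 1.0, 0.0)
        pct_green, pct_red = percent_unmixed(ab, (2.0, 1.0))
        assert pct_green == pytest.approx(100.0 / 3.0)
        assert pct_green + pct_red == pytest.approx(100.0)

    def test_end_to_end_half_mixture_reads_fifty(self):
        plate, lib = _plate_and_library("iLH2")
        m50 = next(m for m in plate if m.truth == 50.0)
        ab = nnls_unmix(m50, lib)
        pct_green, _ = percent_unmixed(ab, lib.reference_radiance)
        assert pct_green == pytest.approx(50.0, abs=1e-6)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            percent_unmixed(Abundances(0.0, 0.0, 0.0), (1.0, 1.0))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_unmixed(Abundances(1.0, 0.0, 0.0), (0.0, 1.0))


class TestSubsetSearch:
    def test_full_bank_subset_equals_full_result(self):
        plate, lib = _plate_and_library("iLH2")
        full = subset_search(plate, lib, k=len(lib.filter_centers))
        assert len(full) == 1
        assert full[0].r_squared == pytest.approx(1.0, abs=1e-9)

    def test_every_admissible_pair_recovers_noise_free_truth(self):
        plate, lib = _plate_and_library("LH2")
        ranked = subset_search(plate, lib, k=2)
        ok = [s for s in ranked if s.ok]
        assert ok, "no full-rank 2-filter subsets found"
        assert all(s.r_squared == pytest.approx(1.0, abs=1e-6) for s in ok)

    def test_collinear_subset_flagged_and_excluded(self):
        g = np.array([0.5, 0.25, 0.25])
        r = np.array([0.1, 0.45, 0.45])  # proportional on the last two filters
        lib = LibrarySpectra((600.0, 700.0, 720.0), g, r, condition_number=1.0,
                             reference_radiance=(1.0, 1.0))
        plate = [
            SpectralMeasurement(f"s{f}", lib.filter_centers,
                                f / 100 * g + (1 - f / 100) * r, truth=float(f))
            for f in (0, 25, 50, 75, 100)
        ]
        ranked = subset_search(plate, lib, k=2)
        bad = next(s for s in ranked if s.centers == (700.0, 720.0))
        assert not bad.ok
        assert not np.isfinite(bad.r_squared) or np.isnan(bad.r_squared)
        assert ranked[-1] is bad

    def test_k_out_of_range_rejected(self):
        plate, lib = _plate_and_library("iLH2")
        with pytest.raises(ValueError):
            subset_search(plate, lib, k=1)
        with pytest.raises(ValueError):
            subset_search(plate, lib, k=99)


class TestEstimatorInterface:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = SpectralUnmixer(condition_threshold=1e5)
        cloned = clone(est)
        assert cloned.get_params()["condition_threshold"] == 1e5

    def test_fit_predict_recovers_fractions(self):
        plate, _ = _plate_and_library("LH2")
        pure = [m for m in plate if m.truth in (0.0, 100.0)]
        X_pure = np.vstack([m.radiance for m in pure])
        y = ["green" if m.truth == 100.0 else "red" for m in pure]
        est = SpectralUnmixer().fit(X_pure, y)
        X = np.vstack([m.radiance for m in plate])
        pct = est.predict(X)
        truth = np.array([m.truth for m in plate])
        assert np.max(np.abs(pct - truth)) < 1e-6

    def test_score_is_squared_correlation(self):
        plate, _ = _plate_and_library("iLH2")
        pure = [m for m in plate if m.truth in (0.0, 100.0)]
        est = SpectralUnmixer().fit(
            np.vstack([m.radiance for m in pure]),
            ["green" if m.truth == 100.0 else "red" for m in pure],
        )
        X = np.vstack([m.radiance for m in plate])
        truth = [m.truth for m in plate]
        assert est.score(X, truth) == pytest.approx(1.0, abs=1e-9)


def test_library_file_roundtrip(tmp_path):
    _, lib = _plate_and_library("iLH2")
    path = tmp_path / "library.csv"
    lib.to_files(path)
    back = LibrarySpectra.from_files(path)
    assert back.filter_centers == lib.filter_centers
    assert np.allclose(back.signature_green, lib.signature_green)
    assert back.reference_radiance == pytest.approx(lib.reference_radiance)
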