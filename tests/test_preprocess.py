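"""Preprocessing contracts: referencing, exclusion, RSPA, normalization, scaling."""

import numpy as np
import pandas as pd
import pytest

import nmrmet as nm
from nmrmet.preprocess import PipelineOrderError, SpectralMatrix


def _singlet_spectrum(center, n=4096, gamma=0.004, amp=1.0, noise=0.0, seed=0,
                      meta=None):
    ppm = np.linspace(10.0, -1.0, n)
    rng = np.random.default_rng(seed)
    inten = amp * gamma / (np.pi * (gamma**2 + (ppm - center) ** 2))
    inten += rng.normal(0, noise, n) if noise else 0.0
    return nm.Spectrum1D(ppm, inten, meta or {})


class TestReferencing:
    def test_tsp_peak_at_0p05_shifted_to_zero(self):
        s = _singlet_spectrum(0.05, noise=1e-4, seed=1, meta={"phase": "aqueous"})
        out = nm.reference_axis(s, "TSP")
        assert out.meta["reference_shift_ppm"] == pytest.approx(-0.05, abs=s.step)
        peak = out.ppm[np.argmax(out.intensity)]
        assert abs(peak) < s.step

    def test_already_referenced_shift_zero(self):
        s = _singlet_spectrum(0.0, noise=1e-4, seed=2)
        out = nm.reference_axis(s, "TSP")
        assert abs(out.meta["reference_shift_ppm"]) <= s.step

    def test_pyrazine_at_8p57_shifted_up(self):
        s = _singlet_spectrum(8.57, noise=1e-4, seed=3)
        # independent check: argmax in the window before shifting
        win = s.window_slice(8.4, 8.8)
        manual = s.ppm[win][np.argmax(s.intensity[win])]
        out = nm.reference_axis(s, "pyrazine")
        assert out.meta["reference_shift_ppm"] == pytest.approx(8.6 - manual)
        assert out.meta["reference_shift_ppm"] == pytest.approx(0.03, abs=2 * s.step)

    def test_no_peak_flags_sample(self):
        ppm = np.linspace(10.0, -1.0, 2048)
        rng = np.random.default_rng(0)
        s = nm.Spectrum1D(ppm, rng.normal(0, 1.0, 2048), {"sample_id": "x"})
        out = nm.reference_axis(s, "TSP")
        assert out.meta.get("reference_failed") is True

    def test_unknown_standard_rejected(self):
        s = _singlet_spectrum(0.0)
        with pytest.raises(ValueError):
            nm.reference_axis(s, "DSS")


class TestExclusion:
    def test_defaults_remove_solvent_columns(self, normalized_matrix):
        ppm = normalized_matrix.ppm
        for lo, hi in [(4.70, 5.00), (3.34, 3.37)]:
            assert not ((ppm >= lo) & (ppm <= hi)).any()

    def test_empty_set_unchanged(self, small_cohort):
        spectra, _ = small_cohort
        m = nm.build_matrix([nm.reference_axis(s) for s in spectra])
        out = nm.exclude_regions(m, nm.ExclusionSet([]))
        assert out.data.shape == m.data.shape
        assert out.flags["excluded"]

    def test_whole_axis_exclusion_rejected(self, small_cohort):
        spectra, _ = small_cohort
        m = nm.build_matrix([nm.reference_axis(s) for s in spectra])
        with pytest.raises(ValueError, match="entire axis"):
            nm.exclude_regions(m, nm.ExclusionSet([(-10, 20)]))

    def test_canonicalization_merges_overlaps(self):
        ex = nm.ExclusionSet([(1.0, 2.0), (1.5, 3.0), (5.0, 6.0)])
        assert ex.intervals == ((1.0, 3.0), (5.0, 6.0))
        with pytest.raises(ValueError):
            nm.ExclusionSet([(2.0, 1.0)])


class TestPipelineOrder:
    def test_align_requires_exclusion(self, small_cohort):
        spectra, _ = small_cohort
        m = nm.build_matrix([nm.reference_axis(s) for s in spectra])
        with pytest.raises(PipelineOrderError):
            nm.align_rspa(m)

    def test_normalize_requires_exclusion(self, small_cohort):
        spectra, _ = small_cohort
        m = nm.build_matrix([nm.reference_axis(s) for s in spectra])
        with pytest.raises(PipelineOrderError):
            nm.normalize_total_area(m)

    def test_scale_requires_normalized(self, small_cohort):
        spectra, _ = small_cohort
        m = nm.build_matrix([nm.reference_axis(s) for s in spectra])
        m = nm.exclude_regions(m, nm.default_exclusions("aqueous"))
        with pytest.raises(PipelineOrderError):
            nm.scale_columns(m, "uv")

    def test_exclude_after_normalize_rejected(self, normalized_matrix):
        with pytest.raises(PipelineOrderError):
            nm.exclude_regions(normalized_matrix, nm.ExclusionSet([(1, 2)]))


class TestNormalization:
    def test_row_sums_one(self, normalized_matrix):
        np.testing.assert_allclose(
            normalized_matrix.data.sum(axis=1), 1.0, atol=1e-9
        )

    def test_scale_invariance(self, small_cohort):
        spectra, _ = small_cohort
        refd = [nm.reference_axis(s) for s in spectra]
        m = nm.exclude_regions(nm.build_matrix(refd), nm.default_exclusions("aqueous"))
        m7 = SpectralMatrix(m.data * 7.0, m.groups, dict(m.flags))
        a = nm.normalize_total_area(m)
        b = nm.normalize_total_area(m7)
        np.testing.assert_allclose(a.data.to_numpy(), b.data.to_numpy(), atol=1e-12)

    def test_hand_arithmetic_two_samples(self):
        data = pd.DataFrame([[1.0, 1.0], [3.0, 1.0]], index=["a", "b"],
                            columns=[2.0, 1.0])
        m = SpectralMatrix(data, pd.Series(["SC", "HF"], index=["a", "b"]),
                           {"referenced": True, "excluded": True})
        out = nm.normalize_total_area(m)
        np.testing.assert_allclose(out.data.loc["a"], [0.5, 0.5])
        np.testing.assert_allclose(out.data.loc["b"], [0.75, 0.25])

    def test_non_positive_row_rejected(self):
        data = pd.DataFrame([[1.0, -2.0]], index=["a"], columns=[2.0, 1.0])
        m = SpectralMatrix(data, pd.Series(["SC"], index=["a"]),
                           {"referenced": True, "excluded": True})
        with pytest.raises(ValueError, match="non-positive"):
            nm.normalize_total_area(m)


class TestScaling:
    def test_uv_unit_variance(self, uv_matrix):
        np.testing.assert_allclose(uv_matrix.data.std(axis=0, ddof=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(uv_matrix.data.mean(axis=0), 0.0, atol=1e-9)

    def test_center_zero_mean(self, normalized_matrix):
        out = nm.scale_columns(normalized_matrix, "center")
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_pareto_hand_arithmetic(self):
        col = np.array([0.0, 4.0, 8.0, 4.0, 0.0, 8.0])  # SD = 4 -> divide by 2
        data = pd.DataFrame({1.0: col / col.sum(), 2.0: [1 / 6] * 6},
                            index=list("abcdef"))
        data = data.div(data.sum(axis=1), axis=0)
        m = SpectralMatrix(data, pd.Series(["SC"] * 3 + ["HF"] * 3, index=list("abcdef")),
                           {"referenced": True, "excluded": True, "normalized": True})
        out = nm.scale_columns(m, "pareto")
        sd = data[1.0].std(ddof=1)
        expected = (data[1.0] - data[1.0].mean()) / np.sqrt(sd)
        np.testing.assert_allclose(out.data[1.0], expected, atol=1e-12)

    def test_zero_variance_columns_dropped(self):
        data = pd.DataFrame({1.0: [0.4, 0.5, 0.6, 0.5], 2.0: [0.1] * 4})
        data.index = list("abcd")
        data = data.div(data.sum(axis=1), axis=0)
        # column 2 becomes non-constant after row normalization; make one constant
        data[2.0] = 0.25
        m = SpectralMatrix(data, pd.Series(["SC", "SC", "HF", "HF"], index=list("abcd")),
                           {"referenced": True, "excluded": True, "normalized": True})
        out = nm.scale_columns(m, "uv")
        assert 2.0 not in out.data.columns

    def test_unknown_mode_rejected(self, normalized_matrix):
        with pytest.raises(ValueError, match="unknown scaling"):
            nm.scale_columns(normalized_matrix, "vast")


class TestAlignment:
    def test_no_jitter_identity(self, aqueous_library):
        d = nm.CohortDesign(phase="aqueous", n_SC=3, n_HF=3, n_points=4096,
                            jitter_sd_ppm=0.0, noise_sd=0.0, seed=4)
        spectra, _ = nm.simulate_cohort(d, aqueous_library, seed=4)
        refd = [nm.reference_axis(s) for s in spectra]
        m = nm.exclude_regions(nm.build_matrix(refd, axis=d.axis),
                               nm.default_exclusions("aqueous"))
        out = nm.align_rspa(m)
        np.testing.assert_allclose(out.data.to_numpy(), m.data.to_numpy(), atol=1e-12)

    def test_global_shift_recovered(self):
        ppm = np.linspace(10.0, 0.0, 2048)
        gamma = 0.02
        base = sum(
            a * gamma / (np.pi * (gamma**2 + (ppm - c) ** 2))
            for c, a in [(2.0, 1.0), (5.0, 2.0), (8.0, 1.5)]
        )
        shifted = np.roll(base, 5)
        data = pd.DataFrame([base, shifted, base], index=["r", "s", "r2"], columns=ppm)
        m = SpectralMatrix(data, pd.Series(["SC", "HF", "HF"], index=data.index),
                           {"referenced": True, "excluded": True})
        out = nm.align_rspa(m, max_shift_ppm=0.1, min_seg_points=64)
        for c in (2.0, 5.0, 8.0):
            win = (ppm <= c + 0.5) & (ppm >= c - 0.5)
            ref_peak = np.argmax(out.data.loc["r"].to_numpy()[win])
            mov_peak = np.argmax(out.data.loc["s"].to_numpy()[win])
            assert abs(int(ref_peak) - int(mov_peak)) <= 1

    def test_jittered_cohort_correlation_increases_area_preserved(
        self, aqueous_library
    ):
        d = nm.CohortDesign(phase="aqueous", n_SC=4, n_HF=4, n_points=8192,
                            jitter_sd_ppm=0.005, noise_sd=0.001, seed=9)
        spectra, _ = nm.simulate_cohort(d, aqueous_library, seed=9)
        refd = [nm.reference_axis(s) for s in spectra]
        m = nm.exclude_regions(nm.build_matrix(refd, axis=d.axis),
                               nm.default_exclusions("aqueous"))
        X = m.data.to_numpy()
        out = nm.align_rspa(m)
        Xa = out.data.to_numpy()

        def mean_corr(M):
            C = np.corrcoef(M)
            n = M.shape[0]
            return (C.sum() - n) / (n * (n - 1))

        assert mean_corr(Xa) > mean_corr(X)
        areas_before = X.sum(axis=1)
        areas_after = Xa.sum(axis=1)
        np.testing.assert_allclose(areas_after, areas_before, rtol=5e-3)

    def test_max_shift_exceeding_segment_rejected(self, normalized_matrix):
        m = normalized_matrix
        fresh = SpectralMatrix(m.data, m.groups,
                               {"referenced": True, "excluded": True})
        with pytest.raises(ValueError, match="max_shift"):
            nm.align_rspa(fresh, max_shift_ppm=1.0, min_seg_points=16)


def test_matrix_tsv_round_trip(tmp_path, normalized_matrix):
    p = tmp_path / "m.tsv"
    normalized_matrix.to_tsv(p)
    back = SpectralMatrix.from_tsv(p)
    assert back.flags["normalized"] is True
    assert back.flags["scaling"] == "none"
    np.testing.assert_allclose(
        back.data.to_numpy(), normalized_matrix.data.to_numpy(), rtol=1e-9
    )
    assert list(back.groups) == list(normalized_matrix.groups)
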