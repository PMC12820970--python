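"""Window integration, normality-gated tests, effect sizes, FDR, heatmaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nmrmet as nm
from nmrmet.univariate import (
    PeakWindow,
    analyze_windows,
    bh_fdr,
    effect_size_with_error,
    es_error_half_width,
    fold_change_matrix,
    integrate_windows,
    significance_marks,
)
from nmrmet.univariate import test_diet_effect as diet_effect


def brute_force_bh(p):
    """Definitional step-up oracle: p_adj_(i) = min_{j>=i} min(1, p_(j)*m/j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(i, m)
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestIntegration:
    def test_isolated_singlet_tracks_truth(self, aqueous_library):
        """Normalized integral ∝ true concentration / total spectral mass."""
        d = nm.CohortDesign(phase="aqueous", n_SC=8, n_HF=8, n_points=4096,
                            noise_sd=5e-4, jitter_sd_ppm=0.0, seed=21)
        spectra, gt = nm.simulate_cohort(d, aqueous_library, seed=21)
        m = nm.build_matrix([nm.reference_axis(s) for s in spectra])
        m = nm.exclude_regions(m, nm.default_exclusions("aqueous"))
        m = nm.normalize_total_area(nm.align_rspa(m))
        table = integrate_windows(m, [PeakWindow("glycine", 3.53, 3.59)])
        protons = {met.name: sum(s.n_protons for s in met.signals)
                   for met in aqueous_library}
        total_mass = sum(gt.concentrations[n] * p for n, p in protons.items())
        total_mass = total_mass + 0.1 * 9  # TSP reference contribution
        truth = (gt.concentrations["glycine"] / total_mass).loc[table.index]
        r = np.corrcoef(table["glycine"], truth)[0, 1]
        assert r > 0.99

    def test_adjacent_windows_partition_region(self, normalized_matrix):
        full = [PeakWindow("all", 1.0, 3.0)]
        # halves share no column: split at an inter-column boundary
        ppm = normalized_matrix.ppm
        mid = ppm[(ppm >= 1.0) & (ppm <= 3.0)]
        cut = (mid[len(mid) // 2] + mid[len(mid) // 2 + 1]) / 2
        parts = [PeakWindow("lo", 1.0, cut), PeakWindow("hi", cut, 3.0)]
        t_full = integrate_windows(normalized_matrix, full)
        t_parts = integrate_windows(normalized_matrix, parts)
        np.testing.assert_allclose(
            t_parts.sum(axis=1), t_full["all"], rtol=1e-12
        )

    def test_window_outside_axis_rejected(self, normalized_matrix):
        with pytest.raises(ValueError, match="outside the axis"):
            integrate_windows(normalized_matrix, [PeakWindow("x", 20.0, 21.0)])

    def test_window_in_excluded_region_rejected(self, normalized_matrix):
        with pytest.raises(ValueError, match="no retained columns"):
            integrate_windows(normalized_matrix, [PeakWindow("water", 4.80, 4.90)])

    def test_requires_normalized_unscaled(self, uv_matrix, small_cohort):
        with pytest.raises(ValueError, match="unscaled"):
            integrate_windows(uv_matrix, [PeakWindow("x", 1.0, 2.0)])


class TestDietEffect:
    def test_identical_groups_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        test_used, p, *_ = diet_effect(x, x.copy())
        assert test_used == "welch_t"
        assert p == pytest.approx(1.0)

    def test_separated_groups_welch_matches_closed_form(self):
        sc = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        hf = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        test_used, p, *_ = diet_effect(sc, hf)
        assert test_used == "welch_t"
        assert p < 0.001
        # closed-form Welch t and Welch-Satterthwaite df oracle
        v1, v2 = sc.var(ddof=1) / 5, hf.var(ddof=1) / 5
        t = (hf.mean() - sc.mean()) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / 4 + v2**2 / 4)
        p_oracle = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        sc = np.exp(rng.normal(0, 2.5, 12))  # heavy log-normal skew
        hf = np.exp(rng.normal(1, 2.5, 11))
        test_used, p, sw_sc, sw_hf = diet_effect(sc, hf)
        assert min(sw_sc, sw_hf) < 0.05
        assert test_used == "mann_whitney"

    def test_mann_whitney_exact_u_hand_example(self):
        # U statistic by hand: sc={1,2,3}, hf={4,5,6} -> U(hf over sc) = 9
        sc = np.array([1.0, 2.0, 3.0])
        hf = np.array([4.0, 5.0, 6.0])
        u = stats.mannwhitneyu(hf, sc, alternative="two-sided", method="exact")
        assert u.statistic == 9
        assert u.pvalue == pytest.approx(0.1, abs=1e-12)  # 2 * 1/20

    def test_constant_data_p_undefined(self):
        x = np.ones(5)
        _, p, *_ = diet_effect(x, np.ones(4))
        assert np.isnan(p)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            diet_effect([1.0, 2.0], [1.0, 2.0, 3.0])


class TestEffectSize:
    def test_printed_error_for_tma_row(self):
        """ES −2.09 at n=12/11 carries a 1.02 error (95% CI half-width)."""
        assert round(es_error_half_width(-2.09, 12, 11), 2) == 1.02

    def test_equal_means_error_closed_form(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 1, 12)
        sc = base
        hf = rng.normal(10, 1, 11)
        es, err = effect_size_with_error(sc, hf)
        expected = 1.96 * np.sqrt(23 / 132 + es**2 / 46)
        assert err == pytest.approx(expected, abs=1e-12)
        assert es_error_half_width(0.0, 12, 11) == pytest.approx(
            1.96 * np.sqrt(23 / 132)
        )
        assert round(es_error_half_width(0.0, 12, 11), 2) == 0.82

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        sc, hf = rng.normal(5, 1, 12), rng.normal(7, 1, 11)
        es1, err1 = effect_size_with_error(sc, hf)
        es2, err2 = effect_size_with_error(2 * sc, 2 * hf)
        assert es1 == pytest.approx(es2, abs=1e-12)
        assert err1 == pytest.approx(err2, abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            effect_size_with_error(np.ones(5), np.ones(5) * 2)


class TestBHFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_four_rank_example(self):
        """p=(0.01,0.02,0.03,0.04): step-up gives 0.04 for every rank."""
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        # confirmed by the brute-force definition
        np.testing.assert_allclose(
            brute_force_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_monotone_in_rank_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestAnalyzeAndHeatmap:
    def test_analyze_windows_full_table(self, normalized_matrix):
        windows = [w for w in nm.default_windows("aqueous")]
        table = integrate_windows(normalized_matrix, windows)
        res = analyze_windows(table, normalized_matrix.groups)
        assert {"ES", "ES_err", "p_raw", "p_fdr", "test_used",
                "fold_change"} <= set(res.columns)
        valid = res["p_raw"].notna()
        assert (res.loc[valid, "p_fdr"] >= res.loc[valid, "p_raw"] - 1e-12).all()
        assert (res.loc[valid, "fold_change"] > 0).all()

    def test_fdr_false_positive_rate_under_null(self):
        """All effect sizes zero: average FDR-significant fraction <= 5%."""
        lib = [
            nm.MetaboliteSpec(f"m{k}", (nm.SignalSpec(f"m{k}", 1.0 + k, "s", 2),),
                              1.0, 0.0)
            for k in range(8)
        ]
        d = nm.CohortDesign(phase="aqueous", n_SC=12, n_HF=11, n_points=1024,
                            linewidth_ppm=0.004)
        fracs = []
        for seed in range(60):
            _, gt = nm.simulate_cohort(d, lib, seed=seed)
            res = analyze_windows(gt.concentrations, gt.groups)
            fracs.append((res["p_fdr"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_fold_change_and_annotations(self):
        df = pd.DataFrame(
            {
                "fold_change": [2.0, 0.5],
                "p_raw": [0.004, 0.2],
                "p_fdr": [0.03, 0.6],
            },
            index=["up", "down"],
        )
        out = fold_change_matrix({"kidney": df, "heart": df.iloc[:1]})
        assert out.loc["up", "kidney"] == "2.00**#"
        assert out.loc["down", "kidney"] == "0.50"
        assert out.loc["down", "heart"] == "N.D."

    def test_significance_mark_levels(self):
        assert significance_marks(0.04, "*") == "*"
        assert significance_marks(0.004, "*") == "**"
        assert significance_marks(0.0004, "*") == "***"
        assert significance_marks(0.5, "*") == ""
        assert significance_marks(float("nan"), "#") == ""


def test_default_windows_skip_overlapped_cluster():
    names = {w.name for w in nm.default_windows("aqueous")}
    assert "trimethylamine" in names
    assert "trimethylamine-N-oxide" not in names  # handled by overlap model
    u = next(w for w in nm.default_windows("aqueous") if w.name.startswith("U_"))
    assert u.assignment_status == "unassigned"
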