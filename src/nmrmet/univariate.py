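"""Signal integration and per-signal group statistics.

Assigned signals are integrated over ppm windows on the aligned, total-area
normalized (but unscaled) matrix. Per window the diet effect is tested with
a normality gate: if Shapiro–Wilk p ≥ 0.05 in both groups a two-sided Welch
t-test is used, otherwise a two-sided Mann–Whitney test. Effect sizes are
pooled-SD standardized mean differences (HF − SC) and their error is the
95% CI half-width

    ES_err = 1.96 * sqrt( (n1+n2)/(n1*n2) + ES^2 / (2*(n1+n2)) ),

the standard large-sample variance of a standardized mean difference.
Raw p-values are adjusted by Benjamini–Hochberg FDR within each tissue ×
phase family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import SpectralMatrix
from .signals import DEFAULT_J_PPM, build_default_library

__all__ = [
    "PeakWindow",
    "default_windows",
    "integrate_windows",
    "test_diet_effect",
    "effect_size_with_error",
    "es_error_half_width",
    "bh_fdr",
    "analyze_windows",
    "fold_change_matrix",
    "significance_marks",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class PeakWindow:
    """A named ppm integration window for one assigned (or unassigned) signal."""

    name: str
    lo_ppm: float
    hi_ppm: float
    multiplicity: str = "s"
    assignment_status: str = "assigned"

    def __post_init__(self) -> None:
        if not self.lo_ppm < self.hi_ppm:
            raise ValueError(f"window {self.name}: lo must be < hi")
        if self.assignment_status not in ("assigned", "unassigned"):
            raise ValueError("assignment_status must be assigned|unassigned")


# half-widths by multiplicity: multiplets need wider windows than singlets
_HALF_WIDTH = {"s": 0.02, "d": 0.03, "t": 0.03, "q": 0.035, "m": 0.04}
# crowded regions where neighbouring signals force narrower windows
# (pyruvate 2.37 / succinate 2.40; MUFA-allylic 2.00 / PUFA-allylic 2.04)
_NARROW = {"pyruvate": 0.014, "succinate": 0.014,
           "MUFA_allylic": 0.019, "PUFA_allylic": 0.019}


def default_windows(phase: str) -> list[PeakWindow]:
    """Integration windows centered on the default library's signals.

    One window per metabolite, centered on its first (reporting) signal;
    overlapped signals that cannot be integrated directly (the TMAO/taurine/
    glucose cluster near δ 3.26) are left out — they are handled by the
    overlap-subtracting quantification instead.
    """
    skip = {"trimethylamine-N-oxide", "taurine", "glucose"}
    windows = []
    for met in build_default_library(phase):
        if met.name in skip:
            continue
        sig = met.signals[0]
        half = _NARROW.get(met.name, _HALF_WIDTH[sig.multiplicity])
        spread = sig.j_spacing_ppm * (len(sig.line_offsets_weights) - 1) / 2
        status = "unassigned" if met.name.startswith("U_") else "assigned"
        windows.append(
            PeakWindow(met.name, sig.center_ppm - half - spread,
                       sig.center_ppm + half + spread, sig.multiplicity, status)
        )
    return windows


def integrate_windows(m: SpectralMatrix, windows: list[PeakWindow]) -> pd.DataFrame:
    """Sum column intensities per window; rows are samples, columns windows.

    Requires a normalized, unscaled matrix (integrals feed ratio statistics,
    not latent-variable models). A window with no retained columns — e.g.
    one falling inside an excluded solvent region — is an error naming it.
    """
    if not m.flags["normalized"]:
        raise ValueError("integrate_windows expects a total-area normalized matrix")
    if m.flags["scaling"] != "none":
        raise ValueError("integrate_windows expects an unscaled matrix")
    ppm = m.ppm
    out = {}
    for w in windows:
        if w.lo_ppm > ppm.max() or w.hi_ppm < ppm.min():
            raise ValueError(f"window {w.name!r} ({w.lo_ppm}-{w.hi_ppm}) outside the axis")
        mask = (ppm >= w.lo_ppm) & (ppm <= w.hi_ppm)
        if not mask.any():
            raise ValueError(
                f"window {w.name!r} has no retained columns (excluded region?)"
            )
        out[w.name] = m.data.loc[:, mask].sum(axis=1)
    return pd.DataFrame(out)


def test_diet_effect(x_sc: np.ndarray, x_hf: np.ndarray
                     ) -> tuple[str, float, float, float]:
    """Normality-gated two-sided group test.

    Returns ``(test_used, p_raw, shapiro_p_SC, shapiro_p_HF)``. Welch's t is
    used when both groups pass Shapiro–Wilk at α=0.05, otherwise
    Mann–Whitney (exact for small samples, normal approximation with tie
    correction above n=8).
    """
    x_sc = np.asarray(x_sc, dtype=float)
    x_hf = np.asarray(x_hf, dtype=float)
    if min(x_sc.size, x_hf.size) < 3:
        raise ValueError("each group needs n >= 3")
    if np.ptp(x_sc) == 0 and np.ptp(x_hf) == 0:
        return "welch_t", np.nan, np.nan, np.nan  # constant data: p undefined
    sw_sc = float(stats.shapiro(x_sc).pvalue) if np.ptp(x_sc) > 0 else 0.0
    sw_hf = float(stats.shapiro(x_hf).pvalue) if np.ptp(x_hf) > 0 else 0.0
    if sw_sc >= NORMALITY_ALPHA and sw_hf >= NORMALITY_ALPHA:
        t = stats.ttest_ind(x_hf, x_sc, equal_var=False)
        return "welch_t", float(t.pvalue), sw_sc, sw_hf
    method = "exact" if max(x_sc.size, x_hf.size) <= 8 else "asymptotic"
    u = stats.mannwhitneyu(x_hf, x_sc, alternative="two-sided", method=method)
    return "mann_whitney", float(u.pvalue), sw_sc, sw_hf


def es_error_half_width(es: float, n1: int, n2: int) -> float:
    """95% CI half-width of a standardized mean difference."""
    var = (n1 + n2) / (n1 * n2) + es**2 / (2.0 * (n1 + n2))
    return 1.96 * float(np.sqrt(var))


def effect_size_with_error(x_sc: np.ndarray, x_hf: np.ndarray
                           ) -> tuple[float, float]:
    """Pooled-SD standardized mean difference (HF − SC) and its 95% half-width."""
    x_sc = np.asarray(x_sc, dtype=float)
    x_hf = np.asarray(x_hf, dtype=float)
    n1, n2 = x_sc.size, x_hf.size
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n1 - 1) * x_sc.var(ddof=1) + (n2 - 1) * x_hf.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled SD is zero: effect size undefined")
    es = float((x_hf.mean() - x_sc.mean()) / np.sqrt(sp2))
    return es, es_error_half_width(es, n1, n2)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def analyze_windows(integrals: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Full univariate table for one tissue × phase integral table.

    Columns: ES, ES_err, p_raw, p_fdr, test_used, shapiro_p_SC/HF,
    fold_change (mean HF / mean SC). The FDR family is all windows in the
    table.
    """
    groups = groups.loc[integrals.index]
    sc = integrals[groups == "SC"]
    hf = integrals[groups == "HF"]
    rows = []
    for name in integrals.columns:
        test_used, p_raw, sw_sc, sw_hf = test_diet_effect(sc[name], hf[name])
        es, es_err = effect_size_with_error(sc[name], hf[name])
        mean_sc = float(sc[name].mean())
        rows.append(
            {
                "window": name,
                "ES": es,
                "ES_err": es_err,
                "p_raw": p_raw,
                "test_used": test_used,
                "shapiro_p_SC": sw_sc,
                "shapiro_p_HF": sw_hf,
                "fold_change": float(hf[name].mean()) / mean_sc if mean_sc != 0 else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("window")
    valid = df["p_raw"].notna()
    df["p_fdr"] = np.nan
    df.loc[valid, "p_fdr"] = bh_fdr(df.loc[valid, "p_raw"].to_numpy())
    return df


def significance_marks(p: float, symbol: str) -> str:
    """'*'-style marks: one below 0.05, two below 0.01, three below 0.001."""
    if not np.isfinite(p) or p >= 0.05:
        return ""
    if p < 0.001:
        return symbol * 3
    if p < 0.01:
        return symbol * 2
    return symbol


def fold_change_matrix(results_by_tissue: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Tissue × signal fold-change table with significance annotations.

    Cells hold ``fold_change`` plus raw-p stars and FDR-p hashes; signals
    absent from a tissue are marked ``N.D.``.
    """
    all_windows: list[str] = []
    for df in results_by_tissue.values():
        for w in df.index:
            if w not in all_windows:
                all_windows.append(w)
    out = pd.DataFrame(index=all_windows, columns=list(results_by_tissue), dtype=object)
    for tissue, df in results_by_tissue.items():
        for w in all_windows:
            if w not in df.index:
                out.loc[w, tissue] = "N.D."
                continue
            row = df.loc[w]
            marks = significance_marks(row["p_raw"], "*") + significance_marks(
                row["p_fdr"], "#"
            )
            out.loc[w, tissue] = f"{row['fold_change']:.2f}{marks}"
    return out
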