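"""Spectral preprocessing: referencing, exclusion, alignment, normalization.

The stages run in a fixed order mirroring routine NMR metabolomics practice:

1. chemical-shift referencing of each spectrum (TSP δ 0.0 aqueous,
   pyrazine δ 8.6 lipophilic),
2. assembly into a samples × ppm matrix on a common axis,
3. exclusion of solvent/reference regions (water δ 4.70–5.00, residual
   methanol δ 3.34–3.37 for aqueous; chloroform δ 7.03–7.49 and pyrazine
   δ 8.50–8.80 for lipophilic),
4. recursive segment-wise peak alignment (RSPA) against the most
   representative sample,
5. total-area normalization per sample,
6. column scaling (mean-centering, Pareto, or unit-variance) for
   multivariate modelling.

Calling a stage out of order raises :class:`PipelineOrderError`; the
provenance flags carried by :class:`SpectralMatrix` are append-only and
serialized with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectrum import Spectrum1D

__all__ = [
    "ExclusionSet",
    "SpectralMatrix",
    "PipelineOrderError",
    "default_exclusions",
    "reference_axis",
    "build_matrix",
    "exclude_regions",
    "align_rspa",
    "normalize_total_area",
    "scale_columns",
]

log = logging.getLogger(__name__)

REFERENCE_WINDOWS = {"TSP": (-0.2, 0.2), "pyrazine": (8.4, 8.8)}
REFERENCE_TARGETS = {"TSP": 0.0, "pyrazine": 8.6}

#: solvent / reference exclusion intervals per phase (lo_ppm, hi_ppm)
DEFAULT_EXCLUSIONS = {
    "aqueous": [(4.70, 5.00), (3.34, 3.37)],
    "lipophilic": [(7.03, 7.49), (8.50, 8.80)],
}


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was invoked out of its mandated order."""


@dataclass(frozen=True)
class ExclusionSet:
    """Canonicalized, non-overlapping closed ppm intervals to drop."""

    intervals: tuple[tuple[float, float], ...]

    def __init__(self, intervals) -> None:
        ivs = sorted((float(lo), float(hi)) for lo, hi in intervals)
        for lo, hi in ivs:
            if not lo < hi:
                raise ValueError(f"interval ({lo}, {hi}) must have lo < hi")
        merged: list[tuple[float, float]] = []
        for lo, hi in ivs:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
            else:
                merged.append((lo, hi))
        object.__setattr__(self, "intervals", tuple(merged))

    def contains(self, ppm: np.ndarray) -> np.ndarray:
        """Boolean mask: True where a ppm value falls inside any interval."""
        ppm = np.asarray(ppm)
        mask = np.zeros(ppm.shape, dtype=bool)
        for lo, hi in self.intervals:
            mask |= (ppm >= lo) & (ppm <= hi)
        return mask


def default_exclusions(phase: str) -> ExclusionSet:
    """The standard solvent/reference exclusion set for a phase."""
    try:
        return ExclusionSet(DEFAULT_EXCLUSIONS[phase])
    except KeyError:
        raise ValueError(f"unknown phase {phase!r}") from None


@dataclass
class SpectralMatrix:
    """Samples × ppm-bins intensity table with group labels and provenance.

    ``data`` rows are sample ids, columns are ppm bin centers (descending).
    ``flags`` records which stages have been applied; ``col_stats`` keeps the
    pre-scaling column means/SDs so model loadings can be back-scaled.
    """

    data: pd.DataFrame
    groups: pd.Series
    flags: dict = field(default_factory=dict)
    col_stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.groups = self.groups.loc[self.data.index]
        defaults = {
            "referenced": False,
            "excluded": False,
            "aligned": False,
            "normalized": False,
            "scaling": "none",
        }
        self.flags = {**defaults, **self.flags}

    @property
    def ppm(self) -> np.ndarray:
        return self.data.columns.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """0/1 class coding (SC=0, HF=1)."""
        return (self.groups == "HF").to_numpy(dtype=float)

    def _evolve(self, data: pd.DataFrame, **flag_updates) -> "SpectralMatrix":
        return SpectralMatrix(
            data, self.groups.copy(), {**self.flags, **flag_updates}, self.col_stats
        )

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        flagline = ";".join(f"{k}={v}" for k, v in self.flags.items())
        with open(path, "w") as fh:
            fh.write(f"#flags: {flagline}\n")
            df = self.data.copy()
            df.insert(0, "group", self.groups)
            df.to_csv(fh, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpectralMatrix":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline().strip()
            flags: dict = {}
            if first.startswith("#flags:"):
                for kv in first.removeprefix("#flags:").strip().split(";"):
                    k, v = kv.split("=")
                    flags[k] = {"True": True, "False": False}.get(v, v)
            df = pd.read_csv(fh, sep="\t", index_col="sample_id")
        groups = df.pop("group")
        df.columns = df.columns.astype(float)
        return cls(df, groups, flags)


def _noise_floor(intensity: np.ndarray) -> float:
    """Robust noise estimate: scaled MAD (most points are baseline)."""
    med = np.median(intensity)
    return float(1.4826 * np.median(np.abs(intensity - med)))


def reference_axis(s: Spectrum1D, standard: str = None) -> Spectrum1D:
    """Shift the ppm axis so the reference peak sits exactly at its δ.

    The maximum-intensity point inside the search window (TSP: −0.2…0.2;
    pyrazine: 8.4…8.8 ppm) is moved to δ 0.0 / δ 8.6. If no point in the
    window rises 5× above the noise floor the sample is flagged
    (``meta['reference_failed'] = True``) and returned unshifted.
    """
    if standard is None:
        standard = "TSP" if s.meta.get("phase", "aqueous") == "aqueous" else "pyrazine"
    if standard not in REFERENCE_WINDOWS:
        raise ValueError(f"unknown reference standard {standard!r}")
    lo, hi = REFERENCE_WINDOWS[standard]
    target = REFERENCE_TARGETS[standard]
    mask = s.window_slice(lo, hi)
    if not mask.any():
        raise ValueError(f"axis has no points in the {standard} window ({lo}, {hi})")
    window_int = s.intensity[mask]
    window_ppm = s.ppm[mask]
    floor = _noise_floor(s.intensity)
    peak_idx = int(np.argmax(window_int))
    if window_int[peak_idx] - np.median(s.intensity) < 5 * floor:
        log.warning("referencing failed for %s: no peak above 5x noise floor",
                    s.meta.get("sample_id", "<sample>"))
        return s.copy(reference_failed=True)
    shift = target - float(window_ppm[peak_idx])
    out = s.copy(reference_shift_ppm=shift)
    out.ppm = out.ppm + shift
    return out


def build_matrix(
    spectra: list[Spectrum1D],
    axis: np.ndarray | None = None,
    bucket_ppm: float | None = None,
) -> SpectralMatrix:
    """Interpolate referenced spectra onto a common descending axis.

    With ``bucket_ppm`` set, intensities are additionally summed into uniform
    buckets of that width (default is full resolution, no bucketing).
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    if axis is None:
        axis = spectra[0].ppm
    axis = np.asarray(axis, dtype=float)
    asc = axis[::-1]
    rows, ids, groups = [], [], []
    for s in spectra:
        rows.append(np.interp(asc, s.ppm[::-1], s.intensity[::-1])[::-1])
        ids.append(s.meta.get("sample_id", f"S{len(ids):02d}"))
        groups.append(s.meta.get("group", "SC"))
    data = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=axis)
    if bucket_ppm is not None:
        edges = np.arange(axis.min(), axis.max() + bucket_ppm, bucket_ppm)
        centers = (edges[:-1] + edges[1:]) / 2.0
        idx = np.clip(np.digitize(axis, edges) - 1, 0, centers.size - 1)
        bucketed = np.zeros((len(rows), centers.size))
        np.add.at(bucketed.T, idx, data.to_numpy().T)
        keep = np.sort(np.unique(idx))[::-1]
        data = pd.DataFrame(
            bucketed[:, keep], index=data.index, columns=centers[keep]
        )
    referenced = all("reference_shift_ppm" in s.meta for s in spectra)
    return SpectralMatrix(
        data, pd.Series(groups, index=data.index, name="group"),
        {"referenced": referenced},
    )


def exclude_regions(m: SpectralMatrix, ex: ExclusionSet) -> SpectralMatrix:
    """Drop every column whose center lies inside an exclusion interval."""
    if m.flags["normalized"]:
        raise PipelineOrderError("exclusion must run before normalization")
    mask = ex.contains(m.ppm)
    if mask.all():
        raise ValueError("exclusion set covers the entire axis")
    if mask.mean() > 0.5:
        log.warning("exclusion removes %.0f%% of columns — likely misconfigured",
                    100 * mask.mean())
    return m._evolve(m.data.loc[:, ~mask], excluded=True)


# ---------------------------------------------------------------------------
# Recursive segment-wise peak alignment (RSPA)

def _shift_fill(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift a segment by ``lag`` points, filling edges with boundary values."""
    if lag == 0:
        return x
    out = np.empty_like(x)
    if lag > 0:
        out[lag:] = x[:-lag]
        out[:lag] = x[0]
    else:
        out[:lag] = x[-lag:]
        out[lag:] = x[-1]
    return out


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if sa == sb == 0 else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _best_lag(test: np.ndarray, ref: np.ndarray, max_lag: int) -> int:
    """Lag maximizing cross-correlation with the reference, |lag| <= max_lag."""
    tc = test - test.mean()
    rc = ref - ref.mean()
    full = np.correlate(rc, tc, mode="full")  # index n-1+lag corresponds to shift by lag
    n = test.size
    lags = np.arange(-max_lag, max_lag + 1)
    valid = lags[(lags > -n) & (lags < n)]
    # prefer the smallest displacement among (near-)ties: scan by |lag|
    order = np.lexsort((valid, np.abs(valid)))
    scores = full[n - 1 + valid]
    best = order[0]
    for j in order[1:]:
        if scores[j] > scores[best]:
            best = j
    return int(valid[best])


def _align_segment(
    test: np.ndarray, ref: np.ndarray, max_lag: int, min_seg: int, corr_stop: float
) -> np.ndarray:
    if test.size < min_seg:
        return test
    lag = _best_lag(test, ref, min(max_lag, test.size - 1))
    shifted = _shift_fill(test, lag)
    if _corr(shifted, ref) <= _corr(test, ref):
        shifted = test
    if _corr(shifted, ref) >= corr_stop or test.size < 2 * min_seg:
        return shifted
    # split at the intensity minimum of the reference in the middle half
    a, b = test.size // 4, 3 * test.size // 4
    split = a + int(np.argmin(ref[a:b]))
    left = _align_segment(shifted[:split], ref[:split], max_lag, min_seg, corr_stop)
    right = _align_segment(shifted[split:], ref[split:], max_lag, min_seg, corr_stop)
    return np.concatenate([left, right])


def align_rspa(
    m: SpectralMatrix,
    max_shift_ppm: float = 0.02,
    min_seg_points: int = 64,
    corr_stop: float = 0.98,
) -> SpectralMatrix:
    """Recursive segment-wise peak alignment against a reference sample.

    The reference is the sample with the highest mean Pearson correlation to
    all others. Each other sample is recursively segmented (split points at
    reference-intensity minima) and each segment shifted by the
    cross-correlation-maximizing lag, bounded by ``max_shift_ppm``; recursion
    stops when a segment is shorter than ``min_seg_points`` or already
    correlates at ``corr_stop`` with the reference. A sample whose overall
    correlation to the reference would decrease is left untouched, so the
    mean correlation never drops.
    """
    if not (m.flags["referenced"] and m.flags["excluded"]):
        raise PipelineOrderError("alignment requires referenced, region-excluded data")
    if m.flags["normalized"]:
        raise PipelineOrderError("alignment must run before normalization")
    X = m.data.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("alignment needs at least 2 samples")
    step = float(np.median(np.abs(np.diff(m.ppm))))
    max_lag = max(1, int(round(max_shift_ppm / step)))
    if max_lag >= min_seg_points:
        raise ValueError(
            f"max_shift ({max_lag} points) must be smaller than min_seg_points "
            f"({min_seg_points})"
        )
    C = np.corrcoef(X)
    ref_idx = int(np.argmax((C.sum(axis=1) - 1.0) / (n - 1)))
    ref = X[ref_idx]
    out = X.copy()
    for i in range(n):
        if i == ref_idx:
            continue
        aligned = _align_segment(X[i], ref, max_lag, min_seg_points, corr_stop)
        if _corr(aligned, ref) >= _corr(X[i], ref):
            out[i] = aligned
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return m._evolve(data, aligned=True)


def normalize_total_area(m: SpectralMatrix) -> SpectralMatrix:
    """Divide each sample row by its total intensity over retained columns."""
    if not m.flags["excluded"]:
        raise PipelineOrderError("normalize after exclusion (denominator uses retained columns)")
    sums = m.data.sum(axis=1)
    bad = sums[sums <= 0]
    if len(bad):
        raise ValueError(f"non-positive total area for samples: {list(bad.index)}")
    return m._evolve(m.data.div(sums, axis=0), normalized=True)


def scale_columns(m: SpectralMatrix, mode: str) -> SpectralMatrix:
    """Mean-center columns, optionally dividing by SD (uv) or √SD (pareto).

    Zero-variance columns are dropped (with a log entry) rather than left as
    zeros, so they cannot contribute spurious loadings. The pre-scaling
    column means and SDs are retained for back-scaling loading weights.
    """
    if not m.flags["normalized"]:
        raise PipelineOrderError("scaling requires a normalized matrix")
    if mode not in ("center", "pareto", "uv"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    means = m.data.mean(axis=0)
    sds = m.data.std(axis=0, ddof=1)
    if mode == "center":
        keep = m.data.columns
    else:
        keep = m.data.columns[sds > 0]
        dropped = len(m.data.columns) - len(keep)
        if dropped:
            log.info("dropped %d zero-variance columns under %s scaling", dropped, mode)
    centered = m.data[keep] - means[keep]
    if mode == "center":
        data = centered
    elif mode == "uv":
        data = centered / sds[keep]
    else:  # pareto
        data = centered / np.sqrt(sds[keep])
    out = m._evolve(data, scaling=mode)
    out.col_stats = pd.DataFrame({"mean": means[keep], "sd": sds[keep]})
    return out
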