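"""Multi-layer validation of PLS-DA models.

Four complementary layers, all seeded for bit-reproducibility:

* ``cv_q2`` — stratified 7-fold cross-validated predictive power,
  Q² = 1 − PRESS/TSS with TSS about the overall class-vector mean;
* ``permutation_test`` — the Q² null distribution under label permutation,
  with the +1 small-sample-corrected empirical p-value;
* ``mccv`` — Monte-Carlo cross-validation: repeatedly withhold a stratified
  1/n_blocks of samples, refit, predict; yields the Q² distribution,
  classification rate, sensitivity (HF recall) and specificity (SC recall),
  plus a label-permuted parallel run for the true-vs-permuted plot;
* ``kfold_auroc`` — stratified k-fold AUROC of a random-forest classifier
  with per-fold label-permutation null bands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .chemometrics import PLSDA, _as_xy

__all__ = [
    "cv_q2",
    "permutation_test",
    "mccv",
    "kfold_auroc",
    "validate",
    "MCCVReport",
    "AUROCReport",
    "ValidationReport",
]

log = logging.getLogger(__name__)


def _xy(m, y):
    X, y_m, _ = _as_xy(m)
    if y is None:
        y = y_m
    if y is None:
        raise ValueError("class vector y required")
    return X, np.asarray(y, dtype=float).ravel()


def stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator
                     ) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (round-robin within class)."""
    assign = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % n_folds
    return [np.flatnonzero(assign == f) for f in range(n_folds)]


def cv_q2(m, A: int = 2, n_folds: int = 7, seed: int = 0,
          y: np.ndarray | None = None) -> np.ndarray:
    """Cross-validated Q² per cumulative component (stratified folds)."""
    X, y = _xy(m, y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    folds = stratified_folds(y, n_folds, rng)
    tss = float(((y - y.mean()) ** 2).sum())
    press = np.zeros(A)
    for test_idx in folds:
        if test_idx.size == 0:
            continue
        train = np.setdiff1d(np.arange(y.size), test_idx)
        if np.unique(y[train]).size < 2:
            raise ValueError("a fold left the training set single-class")
        res = PLSDA(X[train], y[train]).fit(A)
        Xc = X[test_idx] - res.x_mean
        # cumulative-component predictions via successive deflation
        Xd = Xc.copy()
        y_hat = np.full(test_idx.size, res.y_mean)
        for a in range(A):
            t = Xd @ res.W[:, a]
            y_hat = y_hat + t * res.q[a]
            Xd = Xd - np.outer(t, res.P[:, a])
            press[a] += float(((y[test_idx] - y_hat) ** 2).sum())
    return 1.0 - press / tss


def permutation_test(m, A: int = 2, n_perm: int = 500, seed: int = 0,
                     n_folds: int = 7, y: np.ndarray | None = None
                     ) -> tuple[float, np.ndarray, float]:
    """Label-permutation test of Q².

    Returns ``(perm_p, q2_null_distribution, q2_observed)`` with
    perm_p = (1 + #{Q²_perm >= Q²_obs}) / (1 + n_perm).
    """
    X, y = _xy(m, y)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    q2_obs = float(cv_q2(X, A, n_folds, seed=seed, y=y)[-1])
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        null[i] = cv_q2(X, A, n_folds, seed=seed, y=yp)[-1]
    p = (1.0 + float((null >= q2_obs).sum())) / (1.0 + n_perm)
    return p, null, q2_obs


@dataclass
class MCCVReport:
    q2_distribution: np.ndarray
    q2_median: float
    classification_rate: float
    sensitivity: float
    specificity: float
    null_q2_distribution: np.ndarray
    null_classification_rate: float
    true_records: list = field(repr=False, default_factory=list)
    permuted_records: list = field(repr=False, default_factory=list)
    seed: int = 0


def _stratified_holdout(y: np.ndarray, frac_blocks: int, rng: np.random.Generator
                        ) -> np.ndarray:
    """Withhold a stratified 1/n_blocks of samples, at least one per class."""
    test = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        k = max(1, int(round(idx.size / frac_blocks)))
        test.append(rng.choice(idx, size=k, replace=False))
    return np.concatenate(test)


def mccv(m, A: int = 2, n_blocks: int = 7, n_iter: int = 500, seed: int = 0,
         y: np.ndarray | None = None) -> MCCVReport:
    """Monte-Carlo cross-validation with a label-permuted parallel run."""
    X, y = _xy(m, y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("both classes must have more than 1 sample")
    rng = np.random.default_rng(seed)
    q2s, null_q2s = np.empty(n_iter), np.empty(n_iter)
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    null_correct = 0
    null_total = 0
    true_records, perm_records = [], []
    for it in range(n_iter):
        for _attempt in range(100):
            test_idx = _stratified_holdout(y, n_blocks, rng)
            train = np.setdiff1d(np.arange(y.size), test_idx)
            if np.unique(y[train]).size == 2 and np.unique(y[test_idx]).size == 2:
                break
            log.info("mccv iteration %d: degenerate split, resampled", it)
        res = PLSDA(X[train], y[train]).fit(A)
        y_hat = res.decision_function(X[test_idx])
        y_true = y[test_idx]
        tss = float(((y_true - res.y_mean) ** 2).sum())
        q2s[it] = 1.0 - float(((y_true - y_hat) ** 2).sum()) / tss if tss > 0 else 0.0
        pred = (y_hat >= 0.5).astype(int)
        counts["tp"] += int(((pred == 1) & (y_true == 1)).sum())
        counts["tn"] += int(((pred == 0) & (y_true == 0)).sum())
        counts["fp"] += int(((pred == 1) & (y_true == 0)).sum())
        counts["fn"] += int(((pred == 0) & (y_true == 1)).sum())
        true_records.append((y_true.tolist(), y_hat.tolist()))
        # permuted-label parallel run, scored against the true labels
        yp = y.copy()
        yp[train] = rng.permutation(yp[train])
        if np.unique(yp[train]).size == 2:
            resp = PLSDA(X[train], yp[train]).fit(A)
            yp_hat = resp.decision_function(X[test_idx])
            tssp = float(((y_true - resp.y_mean) ** 2).sum())
            null_q2s[it] = 1.0 - float(((y_true - yp_hat) ** 2).sum()) / tssp \
                if tssp > 0 else 0.0
            null_correct += int(((yp_hat >= 0.5).astype(int) == y_true).sum())
            null_total += y_true.size
            perm_records.append((y_true.tolist(), yp_hat.tolist()))
        else:
            null_q2s[it] = np.nan
    sens_den = counts["tp"] + counts["fn"]
    spec_den = counts["tn"] + counts["fp"]
    total = sens_den + spec_den
    return MCCVReport(
        q2_distribution=q2s,
        q2_median=float(np.median(q2s)),
        classification_rate=(counts["tp"] + counts["tn"]) / total,
        sensitivity=counts["tp"] / sens_den if sens_den else np.nan,
        specificity=counts["tn"] / spec_den if spec_den else np.nan,
        null_q2_distribution=null_q2s[~np.isnan(null_q2s)],
        null_classification_rate=null_correct / null_total if null_total else np.nan,
        true_records=true_records,
        permuted_records=perm_records,
        seed=seed,
    )


@dataclass
class AUROCReport:
    fold_aurocs: np.ndarray
    mean_auroc: float
    ci95: tuple[float, float]
    null_aurocs: np.ndarray
    n_estimators: int
    seed: int = 0


def kfold_auroc(m, k: int = 5, n_perm_per_fold: int = 100, seed: int = 0,
                n_estimators: int = 500, y: np.ndarray | None = None
                ) -> AUROCReport:
    """Stratified k-fold AUROC of a random-forest classifier with null band.

    The 95% CI is mean ± 1.96·SD/√k across folds; the null band comes from
    refitting on label-permuted training sets ``n_perm_per_fold`` times per
    fold (set to 0 to skip).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    X, y = _xy(m, y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if min((y == 0).sum(), (y == 1).sum()) < k:
        raise ValueError("stratification failure: a class is smaller than k")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    aurocs, null = [], []
    for train, test in skf.split(X, y):
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31))
        )
        clf.fit(X[train], y[train])
        scores = clf.predict_proba(X[test])[:, 1]
        aurocs.append(roc_auc_score(y[test], scores))
        for _ in range(n_perm_per_fold):
            yp = rng.permutation(y[train])
            if np.unique(yp).size < 2:
                continue
            clfp = RandomForestClassifier(
                n_estimators=n_estimators, random_state=int(rng.integers(2**31))
            )
            clfp.fit(X[train], yp)
            null.append(roc_auc_score(y[test], clfp.predict_proba(X[test])[:, 1]))
    aurocs = np.asarray(aurocs)
    half = 1.96 * aurocs.std(ddof=1) / np.sqrt(k) if k > 1 else 0.0
    mean = float(aurocs.mean())
    return AUROCReport(
        fold_aurocs=aurocs,
        mean_auroc=mean,
        ci95=(mean - half, mean + half),
        null_aurocs=np.asarray(null),
        n_estimators=n_estimators,
        seed=seed,
    )


@dataclass
class ValidationReport:
    """Full validation stack for one PLS-DA model."""

    r2x: float
    r2y: float
    q2: float
    q2_per_component: np.ndarray
    perm_p: float
    q2_perm_distribution: np.ndarray
    mccv: MCCVReport | None
    auroc: AUROCReport | None
    n_components: int
    seed: int

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        d = {
            "r2x": self.r2x, "r2y": self.r2y, "q2": self.q2,
            "q2_per_component": self.q2_per_component,
            "perm_p": self.perm_p,
            "q2_perm_distribution": self.q2_perm_distribution,
            "n_components": self.n_components, "seed": self.seed,
        }
        if self.mccv is not None:
            d["mccv"] = {k: v for k, v in asdict(self.mccv).items()
                         if k not in ("true_records", "permuted_records")}
        if self.auroc is not None:
            d["auroc"] = asdict(self.auroc)
        return clean(d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary(self) -> str:
        lines = [
            f"PLS-DA validation (A={self.n_components}, seed={self.seed})",
            f"  R2X={self.r2x:.3f}  R2Y={self.r2y:.3f}  Q2={self.q2:.3f}",
            f"  permutation p={self.perm_p:.4g} "
            f"({self.q2_perm_distribution.size} permutations)",
        ]
        if self.mccv is not None:
            lines.append(
                f"  MCCV: Q2_median={self.mccv.q2_median:.3f} "
                f"CR={self.mccv.classification_rate:.3f} "
                f"sens={self.mccv.sensitivity:.3f} spec={self.mccv.specificity:.3f}"
            )
        if self.auroc is not None:
            lo, hi = self.auroc.ci95
            lines.append(f"  AUROC={self.auroc.mean_auroc:.3f} (95% CI {lo:.3f}-{hi:.3f})")
        return "\n".join(lines)


def validate(m, A: int = 2, n_folds: int = 7, n_perm: int = 500,
             mccv_blocks: int = 7, mccv_iter: int = 500,
             auroc_k: int = 5, auroc_perms: int = 100,
             rf_estimators: int = 500,
             seed: int = 0, y: np.ndarray | None = None,
             run_mccv: bool = True, run_auroc: bool = True) -> ValidationReport:
    """Fit diagnostics plus the full resampling validation stack."""
    X, y = _xy(m, y)
    res = PLSDA(X, y).fit(A)
    q2s = cv_q2(X, A, n_folds, seed=seed, y=y)
    perm_p, q2_null, q2_obs = permutation_test(X, A, n_perm, seed=seed,
                                               n_folds=n_folds, y=y)
    mccv_rep = mccv(X, A, mccv_blocks, mccv_iter, seed=seed, y=y) if run_mccv else None
    auroc_rep = (
        kfold_auroc(X, auroc_k, auroc_perms, seed=seed,
                    n_estimators=rf_estimators, y=y)
        if run_auroc else None
    )
    return ValidationReport(
        r2x=res.r2x, r2y=res.r2y, q2=float(q2s[-1]), q2_per_component=q2s,
        perm_p=perm_p, q2_perm_distribution=q2_null,
        mccv=mccv_rep, auroc=auroc_rep, n_components=A, seed=seed,
    )
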