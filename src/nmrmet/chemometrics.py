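"""Latent-variable models for spectral class discrimination.

The module follows the model/results idiom: :class:`PCA` and :class:`PLSDA`
are built from a data matrix (or a preprocessed :class:`~nmrmet.preprocess.
SpectralMatrix`), their ``fit`` returns a results object carrying scores,
loadings, explained variance, VIP scores and a ``summary()`` table, and
resampling-based validation hangs off the results object (see
:mod:`nmrmet.validation`).

PLS-DA is PLS1 regression of the 0/1 class vector (SC=0, HF=1) on the
spectral matrix, fitted by the classical NIPALS sequence with deflation of X
per component; class prediction thresholds the linear predictor at 0.5.
Variable importance to projection is

    VIP_j = sqrt( p * sum_a [ SSY_a (w_aj/||w_a||)^2 ] / sum_a SSY_a ),

with SSY_a = q_a^2 t_a' t_a, so the mean of VIP^2 over the p variables is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SpectralMatrix

__all__ = ["PCA", "PCAResults", "PLSDA", "PLSDAResults", "fit_pca", "fit_plsda"]


def _as_xy(m) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Accept a SpectralMatrix or a plain array; return (X, y, columns)."""
    if isinstance(m, SpectralMatrix):
        return m.data.to_numpy(dtype=float), m.y, m.ppm
    return np.asarray(m, dtype=float), None, None


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude element of each column positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return signs


class PCA:
    """Principal component analysis of a (scaled) spectral matrix."""

    def __init__(self, data, columns: np.ndarray | None = None):
        X, _, cols = _as_xy(data)
        self.X = X
        self.columns = columns if columns is not None else cols
        self.rank = int(np.linalg.matrix_rank(X)) if X.size else 0

    def fit(self, n_components: int = 2) -> "PCAResults":
        if n_components > self.rank:
            raise ValueError(f"n_components={n_components} exceeds matrix rank {self.rank}")
        U, s, Vt = np.linalg.svd(self.X, full_matrices=False)
        signs = _fix_sign(Vt.T[:, :n_components])
        loadings = Vt.T[:, :n_components] * signs
        scores = (U[:, :n_components] * s[:n_components]) * signs
        total = float((s**2).sum())
        r2x = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
        return PCAResults(self, scores, loadings, r2x, s**2 / total if total else s * 0)


@dataclass
class PCAResults:
    model: PCA
    scores: np.ndarray          # n x A
    loadings: np.ndarray        # p x A, orthonormal
    r2x: np.ndarray             # per-component explained variance fraction
    full_spectrum: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"R2X": self.r2x, "R2X_cum": np.cumsum(self.r2x)},
            index=[f"PC{i+1}" for i in range(self.n_components)],
        )


class PLSDA:
    """PLS-DA model of a two-class spectral matrix (NIPALS PLS1).

    The constructor accepts either a scaled :class:`SpectralMatrix` (class
    labels taken from its group column) or a raw array plus 0/1 ``y``. X and
    y are mean-centered internally with the training means, so resampling
    refits behave correctly on subsets.
    """

    def __init__(self, data, y: np.ndarray | None = None,
                 columns: np.ndarray | None = None,
                 col_sds: np.ndarray | None = None):
        X, y_m, cols = _as_xy(data)
        if y is None:
            y = y_m
        if y is None:
            raise ValueError("class vector y is required")
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y have different numbers of samples")
        if np.unique(y).size < 2:
            raise ValueError("PLS-DA needs both classes present")
        self.X = X
        self.y = y
        self.columns = columns if columns is not None else cols
        if col_sds is None and isinstance(data, SpectralMatrix) and data.col_stats is not None:
            col_sds = data.col_stats["sd"].to_numpy()
        self.col_sds = col_sds

    def fit(self, n_components: int = 2, max_iter: int = 500, tol: float = 1e-12
            ) -> "PLSDAResults":
        X = self.X - self.X.mean(axis=0)
        y = self.y - self.y.mean()
        n, p = X.shape
        A = int(n_components)
        if A < 1:
            raise ValueError("n_components must be >= 1")
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        T = np.zeros((n, A))
        q = np.zeros(A)
        Xd = X.copy()
        for a in range(A):
            # NIPALS for a single y reduces to one pass, but iterate anyway to
            # keep the classical u/w/t/q loop explicit
            u = y.copy()
            w = np.zeros(p)
            for _ in range(max_iter):
                w_new = Xd.T @ u
                nrm = np.linalg.norm(w_new)
                if nrm == 0:
                    break
                w_new /= nrm
                t = Xd @ w_new
                tt = t @ t
                if tt == 0:
                    break
                qa = (y @ t) / tt
                u_new = y * qa
                if np.linalg.norm(w_new - w) < tol:
                    w = w_new
                    break
                w, u = w_new, u_new
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                raise ValueError(f"component {a+1}: degenerate scores (rank exhausted)")
            pa = Xd.T @ t / tt
            qa = (y @ t) / tt
            Xd -= np.outer(t, pa)
            W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        y_hat = T @ q
        tss = float(y @ y)
        r2y = 1.0 - float((y - y_hat) @ (y - y_hat)) / tss if tss > 0 else 0.0
        xss = float((X * X).sum())
        r2x = float(sum((T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a]) for a in range(A))) / xss \
            if xss > 0 else 0.0
        return PLSDAResults(self, W, P, T, q, r2y, r2x,
                            self.X.mean(axis=0), float(self.y.mean()))


@dataclass
class PLSDAResults:
    """Fitted PLS-DA model: weights, loadings, scores and fit diagnostics."""

    model: PLSDA
    W: np.ndarray               # p x A weight vectors
    P: np.ndarray               # p x A x-loadings
    T: np.ndarray               # n x A x-scores (mutually orthogonal)
    q: np.ndarray               # A y-loadings
    r2y: float
    r2x: float
    x_mean: np.ndarray
    y_mean: float

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def coef_(self) -> np.ndarray:
        """Regression vector B with y_hat = y_mean + (X - x_mean) @ B."""
        PtW = self.P.T @ self.W
        return self.W @ np.linalg.solve(PtW, self.q)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean + (X - self.x_mean) @ self.coef_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class (0=SC, 1=HF): linear predictor thresholded at 0.5."""
        return (self.decision_function(X) >= 0.5).astype(int)

    def vip(self) -> np.ndarray:
        p = self.W.shape[0]
        ssy = self.q**2 * np.einsum("ia,ia->a", self.T, self.T)
        wnorm2 = np.einsum("ja,ja->a", self.W, self.W)
        wnorm2[wnorm2 == 0] = 1.0
        contrib = (self.W**2 / wnorm2) @ ssy
        total = ssy.sum()
        if total == 0:
            return np.zeros(p)
        return np.sqrt(p * contrib / total)

    def scaled_loading_weights(self, col_sds: np.ndarray | None = None) -> pd.DataFrame:
        """LV1 loading-weight profile back-scaled by column SD, with VIP.

        Multiplying each weight by its variable's pre-scaling SD restores the
        raw-intensity scale of the loading profile for display; VIP supplies
        the color dimension.
        """
        if col_sds is None:
            col_sds = self.model.col_sds
        if col_sds is None:
            raise ValueError("column SDs unavailable: fit from a scaled SpectralMatrix "
                             "or pass col_sds")
        col_sds = np.asarray(col_sds, dtype=float)
        idx = self.model.columns if self.model.columns is not None \
            else np.arange(self.W.shape[0])
        return pd.DataFrame(
            {"w1_sd": self.W[:, 0] * col_sds, "vip": self.vip()},
            index=pd.Index(idx, name="ppm"),
        )

    def summary(self) -> pd.DataFrame:
        rows = {
            "n_components": self.n_components,
            "R2X": self.r2x,
            "R2Y": self.r2y,
            "n_samples": self.T.shape[0],
            "n_variables": self.W.shape[0],
        }
        return pd.DataFrame({"value": rows})

    def validate(self, **kwargs):
        """Run the full validation stack; see :func:`nmrmet.validation.validate`."""
        from .validation import validate

        return validate(self.model.X, self.model.y, A=self.n_components, **kwargs)


def fit_pca(m, n_components: int = 2) -> PCAResults:
    """Fit a PCA on a scaled matrix (components ordered by explained variance)."""
    return PCA(m).fit(n_components)


def fit_plsda(m, n_components: int = 2, y: np.ndarray | None = None) -> PLSDAResults:
    """Fit a PLS-DA on a scaled matrix against the SC/HF class vector."""
    return PLSDA(m, y=y).fit(n_components)
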