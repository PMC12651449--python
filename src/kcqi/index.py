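"""Construction of the kiwifruit comprehensive quality index (KCQI).

The index integrates five quality parameters selected by factor analysis —
soluble solids content (SSC), firmness F, lightness L*, yellowness b* and
chroma C — into a single scalar:

    KCQI = ln( 1000 * F * L* * b* * C / SSC )

Parameters with positive rotated loadings enter the numerator and the
negatively loaded SSC the denominator, so the index decreases as fruit ripen
(softening, darkening, sugar accumulation).  The module provides the full
selection workflow: Pearson screening, Kaiser-Meyer-Olkin (KMO) sampling
adequacy, Bartlett's sphericity test, principal-component factor extraction
with varimax rotation, and the loading-threshold / cross-loading selection
rule, wrapped in a scikit-learn style estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .simulate import QUALITY_PARAMETERS

__all__ = [
    "pearson_matrix",
    "zscore_normalize",
    "kmo",
    "bartlett_sphericity",
    "varimax",
    "QualityFactorAnalysis",
    "select_parameters",
    "compute_kcqi",
    "add_kcqi_column",
]


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        cols = [c for c in QUALITY_PARAMETERS if c in table.columns]
        if not cols:
            cols = list(table.columns)
        return table[cols].to_numpy(dtype=float), cols
    X = np.asarray(table, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def pearson_matrix(table) -> pd.DataFrame:
    """Pearson correlation matrix of the quality parameters.

    Constant columns are flagged: their rows/columns are NaN (undefined
    correlation) and a warning names them.
    """
    X, names = _as_matrix(table)
    sd = X.std(axis=0)
    constant = [n for n, s in zip(names, sd) if s == 0]
    if constant:
        warnings.warn(
            f"constant columns have undefined correlations: {constant}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(R, index=names, columns=names)


def zscore_normalize(table):
    """Column-wise z-scores (mean 0, SD 1, population denominator).

    Idempotent up to floating error; constant columns raise.
    """
    X, names = _as_matrix(table)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [n for n, s in zip(names, sd) if s == 0]
        raise ValueError(f"cannot z-score constant columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(Z, index=table.index, columns=names)
    return Z


def kmo(corr) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are the
    anti-image partial correlations obtained from the inverse correlation
    matrix.  Values above 0.5 conventionally gate factor analysis.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular correlation matrix; using pseudo-inverse for KMO",
            stacklevel=2,
        )
        Rinv = np.linalg.pinv(R)
    d = 1.0 / np.sqrt(np.diag(Rinv))
    Q = -Rinv * np.outer(d, d)  # partial correlations (off-diagonal)
    off = ~np.eye(p, dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(corr, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: (chi2, df, p).

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2.  Small p-values
    reject the hypothesis that the correlation matrix is the identity.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        logdet = -np.inf  # singular: chi2 -> infinity
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Orthogonal varimax rotation (SVD algorithm, gamma = 1)."""
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy()
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return L @ R


@dataclass
class ParameterSelection:
    selected: list[str]
    dominant_factor: dict[str, int]
    dominant_sign: dict[str, float]
    cross_loaded: list[str]
    kept_factors: list[int]


def select_parameters(
    loadings,
    names: list[str] | None = None,
    retained: list[int] | None = None,
    loading_threshold: float = 0.5,
    cross_secondary: float = 0.4,
    cross_margin: float = 0.2,
) -> ParameterSelection:
    """Loading-based selection of index parameters.

    A parameter is selected when its largest |loading| over the *retained*
    factors exceeds ``loading_threshold`` and it is not cross-loaded.  It is
    cross-loaded when, over *all* factor columns, its second-largest |loading|
    is at least ``cross_secondary`` and within ``cross_margin`` of the
    largest.  Factors on which no selected parameter is dominant are dropped.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if retained is None:
        retained = list(range(k))

    selected, cross_loaded = [], []
    dominant_factor, dominant_sign = {}, {}
    for i, name in enumerate(names):
        absrow = np.abs(L[i])
        order = np.argsort(absrow)[::-1]
        largest, second = absrow[order[0]], (absrow[order[1]] if k > 1 else 0.0)
        is_cross = second >= cross_secondary and (largest - second) < cross_margin
        max_retained = max(abs(L[i, j]) for j in retained)
        if is_cross:
            cross_loaded.append(name)
            continue
        if max_retained > loading_threshold:
            jdom = retained[int(np.argmax([abs(L[i, j]) for j in retained]))]
            selected.append(name)
            dominant_factor[name] = jdom
            dominant_sign[name] = float(np.sign(L[i, jdom]))
    kept = sorted({dominant_factor[n] for n in selected})
    if not selected:
        warnings.warn(
            "no parameter exceeds the loading threshold; empty selection",
            stacklevel=2,
        )
    return ParameterSelection(selected, dominant_factor, dominant_sign,
                              cross_loaded, kept)


class QualityFactorAnalysis(BaseEstimator):
    """Principal-component factor analysis of the quality-parameter table.

    Extraction is the eigendecomposition of the Pearson correlation matrix;
    factors are retained up to ``variance_threshold`` percent cumulative
    variance, loading columns are scaled by sqrt(eigenvalue), varimax-rotated
    over the retained block, and sign-fixed so each factor's largest-|loading|
    variable loads positively.

    Attributes (after ``fit``)
    --------------------------
    correlation_ : DataFrame, p x p Pearson matrix
    kmo_ : float
    bartlett_chi2_, bartlett_df_, bartlett_p_ : sphericity test
    eigenvalues_ : ndarray, descending
    cumulative_variance_ : ndarray, percent
    retained_k_ : int
    loadings_ : DataFrame, p x retained_k rotated loadings
    selection_ : ParameterSelection
    """

    def __init__(self, variance_threshold: float = 80.0,
                 loading_threshold: float = 0.5):
        self.variance_threshold = variance_threshold
        self.loading_threshold = loading_threshold

    def fit(self, table, y=None):
        X, names = _as_matrix(table)
        n, p = X.shape
        R = pearson_matrix(pd.DataFrame(X, columns=names))
        Rv = R.to_numpy()
        if np.isnan(Rv).any():
            raise ValueError("correlation matrix contains undefined entries")
        eigval = np.linalg.eigvalsh(Rv)
        if eigval.min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")

        self.correlation_ = R
        self.kmo_ = kmo(Rv)
        self.bartlett_chi2_, self.bartlett_df_, self.bartlett_p_ = (
            bartlett_sphericity(Rv, n)
        )
        w, V = np.linalg.eigh(Rv)
        w, V = w[::-1], V[:, ::-1]
        w = np.clip(w, 0.0, None)
        self.eigenvalues_ = w
        self.cumulative_variance_ = np.cumsum(w) / p * 100.0
        k = int(np.searchsorted(self.cumulative_variance_,
                                self.variance_threshold) + 1)
        k = min(k, p)
        self.retained_k_ = k
        L = V[:, :k] * np.sqrt(w[:k])
        Lr = varimax(L)
        for j in range(k):
            i = int(np.argmax(np.abs(Lr[:, j])))
            if Lr[i, j] < 0:
                Lr[:, j] = -Lr[:, j]
        self.loadings_ = pd.DataFrame(
            Lr, index=names, columns=[f"factor{j + 1}" for j in range(k)]
        )
        self.selection_ = select_parameters(
            Lr, names=names, loading_threshold=self.loading_threshold
        )
        self.n_samples_ = n
        return self

    def report(self) -> dict:
        """JSON-serializable summary of the fitted analysis."""
        return {
            "kmo": self.kmo_,
            "bartlett": {
                "chi2": self.bartlett_chi2_,
                "df": self.bartlett_df_,
                "p": self.bartlett_p_,
            },
            "eigenvalues": self.eigenvalues_.tolist(),
            "cumulative_variance_pct": self.cumulative_variance_.tolist(),
            "retained_factors": self.retained_k_,
            "rotated_loadings": self.loadings_.round(4).to_dict(),
            "selected_parameters": self.selection_.selected,
            "cross_loaded": self.selection_.cross_loaded,
        }


def compute_kcqi(record) -> float:
    """KCQI = ln(1000 * F * L* * b* * C / SSC) for one fruit.

    All five inputs must be strictly positive; the offending field is named
    otherwise.
    """
    fields = {
        "firmness": float(record["firmness"]),
        "L": float(record["L"]),
        "b": float(record["b"]),
        "chroma": float(record["chroma"]),
        "ssc": float(record["ssc"]),
    }
    for name, value in fields.items():
        if not value > 0:
            raise ValueError(f"KCQI requires {name} > 0, got {value}")
    return float(np.log(
        1000.0 * fields["firmness"] * fields["L"] * fields["b"]
        * fields["chroma"] / fields["ssc"]
    ))


def add_kcqi_column(table: pd.DataFrame) -> pd.DataFrame:
    """Copy of ``table`` with a ``kcqi`` column appended."""
    out = table.copy()
    out["kcqi"] = np.log(
        1000.0 * out["firmness"] * out["L"] * out["b"] * out["chroma"]
        / out["ssc"]
    )
    if not np.isfinite(out["kcqi"]).all():
        raise ValueError("KCQI undefined for some rows (nonpositive inputs)")
    return out
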