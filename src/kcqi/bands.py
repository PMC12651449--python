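"""Calibration/prediction partitioning and characteristic-band selection.

Implements the chemometric variable-selection workflow used for spectral
regression:

* SPXY — Kennard-Stone-style max-min sample partitioning on a joint,
  normalized predictor (X) + response (y) distance, so calibration and
  prediction sets cover both spaces;
* SPA — successive projections algorithm: forward selection of minimally
  collinear bands by orthogonal-projection residual norms, stopped by an
  F-test against the minimum-RMSE chain;
* CARS — competitive adaptive reweighted sampling: Monte-Carlo PLS runs with
  an exponentially decaying forced-retention schedule and adaptive reweighted
  sampling on |PLS coefficient| weights, returning the subset with minimal
  cross-validated RMSE;
* random frog — an MCMC-flavoured subset sampler whose per-band inclusion
  frequency is thresholded.

Selectors are scikit-learn transformers (``fit(X, y)`` on calibration data
only, ``transform`` restricts columns) exposing ``indices_``, ``support_``
and a ``diagnostics_`` trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .hsi import SpectralAxis

__all__ = [
    "spxy_split",
    "BandSubset",
    "SPASelector",
    "CARSSelector",
    "RandomFrogSelector",
]


# ---------------------------------------------------------------------------
# SPXY sample partitioning
# ---------------------------------------------------------------------------

def spxy_split(
    X, y, calibration_fraction: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """SPXY partition into (calibration_indices, prediction_indices).

    Joint distance d(i,j) = dX(i,j)/max dX + dy(i,j)/max dy (Euclidean both),
    followed by Kennard-Stone greedy max-min selection of the calibration
    set.  Deterministic; max-min ties break to the lowest sample index.
    Calibration size is round(fraction * n).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 5:
        raise ValueError("SPXY requires at least 5 samples")
    if not (0.0 < calibration_fraction < 1.0):
        raise ValueError("calibration_fraction must be in (0, 1)")
    n_cal = int(round(calibration_fraction * n))
    n_cal = min(max(n_cal, 2), n - 1)

    dX = squareform(pdist(X))
    dY = np.abs(y[:, None] - y[None, :])
    D = np.zeros((n, n))
    if dX.max() > 0:
        D += dX / dX.max()
    if dY.max() > 0:
        D += dY / dY.max()

    # seed with the most distant pair (lowest indices on ties)
    flat = np.argmax(D)  # argmax returns first occurrence = lowest index pair
    i0, j0 = np.unravel_index(flat, D.shape)
    selected = [min(i0, j0), max(i0, j0)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_cal:
        md = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(md))  # first max = lowest index tie-break
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    cal = np.sort(np.array(selected))
    pred = np.sort(np.nonzero(remaining)[0])
    return cal, pred


# ---------------------------------------------------------------------------
# Band subsets
# ---------------------------------------------------------------------------

@dataclass
class BandSubset:
    """Selected band positions, their wavelengths and the selection trace."""

    method: str
    indices: np.ndarray
    wavelengths: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0)):
            idx = np.unique(idx)
        self.indices = idx
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)

    @classmethod
    def full(cls, axis: SpectralAxis) -> "BandSubset":
        idx = np.arange(axis.n_bands)
        return cls("full", idx, axis.wavelengths[idx])


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((np.asarray(y).ravel() - np.asarray(yhat).ravel()) ** 2)))


def _pls_truncated_coefs(Xtr, ytr, amax):
    """Regression vectors B_a (and intercepts) for every LV truncation
    a = 1..amax, from a single NIPALS fit: B_a = W_a (P_a^T W_a)^{-1} q_a."""
    import warnings

    pls = PLSRegression(n_components=amax, scale=False)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls.fit(Xtr, ytr)
    W, P = pls.x_weights_, pls.x_loadings_
    q = pls.y_loadings_.ravel()
    x_mean, y_mean = Xtr.mean(axis=0), float(np.mean(ytr))
    PtW = P.T @ W
    coefs = np.empty((Xtr.shape[1], amax))
    icepts = np.empty(amax)
    for a in range(1, amax + 1):
        beta = W[:, :a] @ np.linalg.solve(PtW[:a, :a], q[:a])
        coefs[:, a - 1] = beta
        icepts[a - 1] = y_mean - x_mean @ beta
    return coefs, icepts


def _pls_rmsecv(X, y, bands, cv_folds=5, max_components=10, seed=0) -> float:
    """Cross-validated RMSE of a PLS model on the given bands, minimized
    over the number of latent variables (capped at ``max_components``)."""
    Xb = X[:, np.asarray(bands, dtype=int)]
    n, p = Xb.shape
    amax = max(1, min(max_components, p, n - int(np.ceil(n / cv_folds)) - 1))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    press = np.zeros(amax)
    for tr, te in kf.split(Xb):
        coefs, icepts = _pls_truncated_coefs(Xb[tr], y[tr], amax)
        preds = Xb[te] @ coefs + icepts  # (n_te, amax)
        press += np.sum((y[te, None] - preds) ** 2, axis=0)
    return float(np.sqrt(press.min() / n))


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

class SPASelector(SelectorMixin, BaseEstimator):
    """Successive projections algorithm.

    For every starting band a chain is grown by repeatedly adding the band
    whose column has the largest norm after projection onto the orthogonal
    complement of the already-selected columns.  Each (start, length) chain
    is scored by the calibration RMSE of an ordinary least-squares fit; the
    returned subset is the shortest chain whose RMSE is not significantly
    worse than the global minimum under an F-test at ``alpha``
    (F = RMSE_k^2 / RMSE_min^2, n_cal - k degrees of freedom each side).
    """

    def __init__(self, max_bands: int = 25, alpha: float = 0.25):
        self.max_bands = max_bands
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        kmax = min(self.max_bands, p)
        if kmax >= n:
            raise ValueError(
                f"max_bands={self.max_bands} must be < n_calibration={n}"
            )
        Xc = X - X.mean(axis=0)
        chains = np.empty((p, kmax), dtype=int)
        for j0 in range(p):
            chains[j0] = self._chain(Xc, j0, kmax)

        # score every chain prefix by OLS calibration RMSE
        rmse = np.full((p, kmax), np.inf)
        ones = np.ones((n, 1))
        for j0 in range(p):
            for k in range(1, kmax + 1):
                cols = chains[j0, :k]
                A = np.hstack([ones, X[:, cols]])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                rmse[j0, k - 1] = _rmse(y, A @ coef)
        best_per_k = rmse.min(axis=0)
        best_start_per_k = rmse.argmin(axis=0)
        kmin = int(np.argmin(best_per_k)) + 1
        rmse_min = best_per_k[kmin - 1]

        chosen_k = kmin
        for k in range(1, kmax + 1):
            f_obs = (best_per_k[k - 1] / rmse_min) ** 2 if rmse_min > 0 else np.inf
            if rmse_min == 0 and best_per_k[k - 1] == 0:
                f_obs = 1.0
            f_crit = stats.f.ppf(1.0 - self.alpha, n - k, n - kmin)
            if f_obs < f_crit:
                chosen_k = k
                break
        start = best_start_per_k[chosen_k - 1]
        idx = np.sort(chains[start, :chosen_k])
        self.n_features_in_ = p
        self.indices_ = idx
        self.diagnostics_ = {
            "rmse_path": best_per_k.tolist(),
            "k_min": kmin,
            "rmse_min": float(rmse_min),
            "chosen_k": int(chosen_k),
        }
        return self

    @staticmethod
    def _chain(Xc: np.ndarray, start: int, kmax: int) -> np.ndarray:
        P = Xc.copy()
        chain = [start]
        for _ in range(kmax - 1):
            v = P[:, chain[-1]].copy()
            vv = v @ v
            if vv > 0:
                P -= np.outer(v, v @ P) / vv
            P[:, chain] = 0.0
            norms = np.einsum("ij,ij->j", P, P)
            chain.append(int(np.argmax(norms)))
        return np.array(chain, dtype=int)

    def _get_support_mask(self):
        check_is_fitted(self, "indices_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.indices_] = True
        return mask

    def subset(self, axis: SpectralAxis) -> BandSubset:
        check_is_fitted(self, "indices_")
        return BandSubset("SPA", self.indices_, axis.wavelengths[self.indices_],
                          dict(self.diagnostics_))


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

class CARSSelector(SelectorMixin, BaseEstimator):
    """Competitive adaptive reweighted sampling.

    ``n_runs`` Monte-Carlo iterations; run i fits a PLS model on a random
    ``mc_fraction`` of the calibration samples, weights bands by |PLS
    regression coefficient|, enforces the exponentially decaying retention
    ratio r(i) = a * exp(-k i) (a, k fixed by r(1) = 1 and r(n_runs) = 2/p),
    then applies adaptive reweighted sampling among the survivors.  The run
    whose retained set minimizes 5-fold RMSECV is returned.
    """

    def __init__(self, n_runs: int = 50, mc_fraction: float = 0.8,
                 cv_folds: int = 5, max_components: int = 10,
                 random_state: int = 0):
        self.n_runs = n_runs
        self.mc_fraction = mc_fraction
        self.cv_folds = cv_folds
        self.max_components = max_components
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        N = self.n_runs
        kdec = np.log(p / 2.0) / (N - 1)
        a = np.exp(kdec)

        survivors = np.arange(p)
        rmsecv_path, count_path, subsets = [], [], []
        n_sub = max(4, int(round(self.mc_fraction * n)))
        for i in range(1, N + 1):
            if survivors.size < 2:
                self.diagnostics_ = {
                    "truncated_at_run": i,
                    "rmsecv_path": rmsecv_path,
                    "count_path": count_path,
                }
                break
            idx = rng.choice(n, size=n_sub, replace=False)
            amax = max(1, min(self.max_components, survivors.size, n_sub - 1))
            pls = PLSRegression(n_components=amax, scale=False)
            pls.fit(X[np.ix_(idx, survivors)], y[idx])
            w = np.abs(np.asarray(pls.coef_).reshape(-1))
            # forced retention by the decay schedule
            n_keep = max(2, int(round(a * np.exp(-kdec * i) * p)))
            n_keep = min(n_keep, survivors.size)
            top = np.argsort(w)[::-1][:n_keep]
            forced = survivors[np.sort(top)]
            wf = w[np.sort(top)]
            # adaptive reweighted sampling (weighted, with replacement)
            if wf.sum() > 0:
                draw = rng.choice(forced.size, size=n_keep, replace=True,
                                  p=wf / wf.sum())
                survivors = np.unique(forced[draw])
            else:  # pragma: no cover - degenerate all-zero weights
                survivors = forced
            rmsecv = _pls_rmsecv(X, y, survivors, self.cv_folds,
                                 self.max_components, seed=self.random_state)
            rmsecv_path.append(rmsecv)
            count_path.append(int(survivors.size))
            subsets.append(survivors.copy())
        if not subsets:
            raise ValueError("CARS produced no candidate subsets")
        best = int(np.argmin(rmsecv_path))
        self.n_features_in_ = p
        self.indices_ = np.sort(subsets[best])
        self.diagnostics_ = {
            "rmsecv_path": rmsecv_path,
            "count_path": count_path,
            "best_run": best + 1,
            "rmsecv_min": float(rmsecv_path[best]),
        }
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "indices_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.indices_] = True
        return mask

    def subset(self, axis: SpectralAxis) -> BandSubset:
        check_is_fitted(self, "indices_")
        return BandSubset("CARS", self.indices_,
                          axis.wavelengths[self.indices_],
                          dict(self.diagnostics_))


# ---------------------------------------------------------------------------
# Random frog
# ---------------------------------------------------------------------------

class RandomFrogSelector(SelectorMixin, BaseEstimator):
    """Random-frog band selection.

    A chain over band subsets: each iteration proposes a new subset size from
    a normal distribution around the current size (SD = ``proposal_sd_frac``
    times the current size), adds/removes uniformly random bands to reach it,
    and accepts the candidate when its 5-fold PLS RMSECV improves — otherwise
    with probability ``accept_eta`` * (current error / candidate error).  A
    band's selection probability is the fraction of iterations whose subset
    contains it; bands at or above ``threshold`` are returned.
    """

    def __init__(self, n_iterations: int = 1000, threshold: float = 0.40,
                 init_size: int = 10, proposal_sd_frac: float = 0.3,
                 accept_eta: float = 0.1, cv_folds: int = 5,
                 max_components: int = 10, random_state: int = 0):
        self.n_iterations = n_iterations
        self.threshold = threshold
        self.init_size = init_size
        self.proposal_sd_frac = proposal_sd_frac
        self.accept_eta = accept_eta
        self.cv_folds = cv_folds
        self.max_components = max_components
        self.random_state = random_state

    def fit(self, X, y):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly inside (0, 1)")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)

        current = np.sort(rng.choice(p, size=min(self.init_size, p),
                                     replace=False))
        err_cur = _pls_rmsecv(X, y, current, self.cv_folds,
                              self.max_components, seed=self.random_state)
        counts = np.zeros(p)
        err_path = []
        for _ in range(self.n_iterations):
            m = current.size
            m_new = int(round(rng.normal(m, self.proposal_sd_frac * m)))
            m_new = min(max(m_new, 1), p)
            if m_new > m:
                pool = np.setdiff1d(np.arange(p), current)
                add = rng.choice(pool, size=m_new - m, replace=False)
                cand = np.sort(np.concatenate([current, add]))
            elif m_new < m:
                keep = rng.choice(m, size=m_new, replace=False)
                cand = np.sort(current[keep])
            else:
                swap_out = rng.integers(m)
                pool = np.setdiff1d(np.arange(p), current)
                cand = current.copy()
                if pool.size:
                    cand[swap_out] = rng.choice(pool)
                cand = np.sort(cand)
            err_cand = _pls_rmsecv(X, y, cand, self.cv_folds,
                                   self.max_components, seed=self.random_state)
            if err_cand <= err_cur or (
                rng.random() < self.accept_eta * err_cur / err_cand
            ):
                current, err_cur = cand, err_cand
            counts[current] += 1
            err_path.append(err_cur)
        probs = counts / self.n_iterations
        idx = np.sort(np.nonzero(probs >= self.threshold)[0])
        if idx.size == 0:
            import warnings

            warnings.warn(
                f"no band reaches selection probability {self.threshold} "
                f"(max = {probs.max():.3f}); empty subset",
                stacklevel=2,
            )
        self.n_features_in_ = p
        self.indices_ = idx
        self.selection_probabilities_ = probs
        self.diagnostics_ = {
            "selection_probabilities": probs.tolist(),
            "rmsecv_path": err_path,
            "rmsecv_final": float(err_cur),
        }
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "indices_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.indices_] = True
        return mask

    def subset(self, axis: SpectralAxis) -> BandSubset:
        check_is_fitted(self, "indices_")
        return BandSubset("RFrog", self.indices_,
                          axis.wavelengths[self.indices_],
                          {"selection_probabilities":
                           self.selection_probabilities_.tolist()})
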