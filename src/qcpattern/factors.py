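"""Latent-factor reduction of the colour-pattern statistic table.

The raw table (one row per individual x viewing distance, 157 statistic
columns) is reduced in four steps:

1. rows with any non-finite statistic are dropped (patterns with fewer than
   two elements produce NaNs by design);
2. highly collinear statistics are pruned with a greedy Pearson filter
   (|r| < 0.6 against every previously kept column, scanned in a fixed,
   documented column order);
3. the number of latent factors is chosen by parallel analysis: observed
   correlation-matrix eigenvalues must exceed the rank-wise *median*
   eigenvalues of 10 000 standard-normal datasets of the same shape;
4. an ordinary-least-squares (minres) exploratory factor analysis with
   varimax rotation is fitted, with bootstrap percentile confidence
   intervals on the loadings and regression-method factor scores.

`ExploratoryFactorAnalysis` is a scikit-learn style estimator (fit /
transform / get_params); the module-level functions are thin wrappers.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

FAMILY_ORDER = ("CAA", "VCA", "BSA", "LEIA")


# ---------------------------------------------------------------------------
# filtering

def drop_invalid(df: pd.DataFrame, metric_cols=None):
    """Remove rows containing any NaN/Inf metric; report removals per species.

    Returns (filtered table, report dict with 'removed_ids' and
    'removed_per_species').
    """
    if metric_cols is None:
        metric_cols = [c for c in df.columns
                       if c.split(".")[0] in FAMILY_ORDER]
    vals = df[metric_cols].to_numpy(dtype=float)
    ok = np.isfinite(vals).all(axis=1)
    removed = df.loc[~ok]
    report = {
        "n_removed": int((~ok).sum()),
        "removed_ids": list(removed.get("id", removed.index).astype(str)),
        "removed_per_species": (
            removed["species"].value_counts().to_dict() if "species" in df else {}
        ),
    }
    kept = df.loc[ok].copy()
    if len(kept) == 0:
        raise ValueError("all rows removed by the missing-value filter")
    if report["n_removed"]:
        logger.info("dropped %d invalid rows: %s", report["n_removed"],
                    report["removed_ids"])
    return kept, report


def _ordered_columns(cols):
    def key(c):
        fam = c.split(".")[0]
        fam_i = FAMILY_ORDER.index(fam) if fam in FAMILY_ORDER else len(FAMILY_ORDER)
        return (fam_i, c)
    return sorted(cols, key=key)


def correlation_filter(df: pd.DataFrame, r_max: float = 0.6, metric_cols=None):
    """Greedy decorrelation of metric columns.

    Columns are scanned in a fixed order (statistic family CAA, VCA, BSA,
    LEIA, then name); a column is kept iff its absolute Pearson correlation
    with every previously kept column is < r_max. Constant columns are
    dropped with a warning. Deterministic and idempotent.
    """
    if metric_cols is None:
        metric_cols = [c for c in df.columns if c.split(".")[0] in FAMILY_ORDER]
    order = _ordered_columns(metric_cols)
    X = df[order].to_numpy(dtype=float)
    sd = X.std(axis=0)
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    kept = []
    for j, col in enumerate(order):
        if not np.isfinite(sd[j]) or sd[j] < 1e-9 * scale[j]:
            warnings.warn(f"constant column {col} dropped by correlation filter")
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(X[:, j], X[:, order.index(k)])[0, 1]
            if not np.isfinite(r) or abs(r) >= r_max:
                ok = False
                break
        if ok:
            kept.append(col)
    return df[[c for c in df.columns if c not in metric_cols] + kept], kept


# ---------------------------------------------------------------------------
# parallel analysis

def _corr_eigs_random(n, p, n_random, rng, batch=256):
    """Rank-wise median correlation eigenvalues of standard-normal datasets."""
    eigs = np.empty((n_random, p))
    done = 0
    while done < n_random:
        b = min(batch, n_random - done)
        X = rng.standard_normal((b, n, p))
        X -= X.mean(axis=1, keepdims=True)
        X /= X.std(axis=1, keepdims=True)
        R = np.einsum("bni,bnj->bij", X, X) / n
        eigs[done:done + b] = np.linalg.eigvalsh(R)[:, ::-1]
        done += b
    return np.median(eigs, axis=0)


def parallel_analysis(X, n_random: int = 10000, seed=None) -> int:
    """Number of factors whose eigenvalues beat the random-data medians.

    Observed correlation-matrix eigenvalues are compared rank-wise with the
    median eigenvalues of ``n_random`` i.i.d. standard-normal datasets of the
    same shape; retention stops at the first rank that fails.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_random < 100:
        warnings.warn("parallel analysis with n_random < 100 is unreliable")
    R = np.corrcoef(X, rowvar=False)
    obs = np.sort(np.linalg.eigvalsh(R))[::-1]
    rng = np.random.default_rng(seed)
    med = _corr_eigs_random(n, p, n_random, rng)
    k = 0
    for j in range(p):
        if obs[j] > med[j]:
            k += 1
        else:
            break
    return k


# ---------------------------------------------------------------------------
# minres EFA + varimax

def _minres_loadings(R, n_factors, max_iter=200):
    """OLS/minres factor extraction on a correlation matrix.

    The uniquenesses psi are optimised so the off-diagonal residuals of
    R - Lambda Lambda' are minimal in least squares; Lambda comes from the
    top-k eigenpairs of R - diag(psi).
    """
    p = R.shape[0]
    offmask = ~np.eye(p, dtype=bool)

    def loadings_for(psi):
        e, V = linalg.eigh(R - np.diag(psi))
        idx = np.argsort(e)[::-1][:n_factors]
        lam = V[:, idx] * np.sqrt(np.clip(e[idx], 0, None))
        return lam

    def objective(psi):
        lam = loadings_for(psi)
        resid = R - lam @ lam.T
        return float(np.sum(resid[offmask] ** 2))

    # start at 1 - squared multiple correlation
    try:
        smc = 1.0 - 1.0 / np.diag(linalg.inv(R))
    except linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(objective, psi0, method="L-BFGS-B",
                            bounds=[(1e-3, 1 - 1e-3)] * p,
                            options={"maxiter": max_iter})
    if not (res.success or res.status == 1):
        raise RuntimeError(
            f"minres factor extraction did not converge: {res.message} "
            f"(nit={res.nit}, fun={res.fun:.3g})"
        )
    return loadings_for(res.x), res.x


def varimax(L, gamma=1.0, tol=1e-8, max_iter=500):
    """Varimax rotation with Kaiser normalisation; returns (rotated, R)."""
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1)
    h = np.sqrt(np.sum(L ** 2, axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = A @ R
        G = A.T @ (B ** 3 - (gamma / p) * B @ np.diag(np.sum(B ** 2, axis=0)))
        U, s, Vt = np.linalg.svd(G)
        R = U @ Vt
        d = np.sum(s)
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return (A @ R) * h[:, None], R


def tucker_congruence(a, b):
    """Tucker's congruence coefficient between two loading vectors."""
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def _order_and_sign(L):
    """Factors sorted by explained SS descending; largest |loading| positive."""
    ss = np.sum(L ** 2, axis=0)
    order = np.argsort(ss)[::-1]
    L = L[:, order]
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def align_loadings(L, ref):
    """Permute and sign-flip factors of L to best match a reference solution."""
    from scipy.optimize import linear_sum_assignment
    k = L.shape[1]
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            C[i, j] = abs(tucker_congruence(ref[:, i], L[:, j]))
    ri, cj = linear_sum_assignment(-C)
    out = np.empty_like(L)
    for i, j in zip(ri, cj):
        col = L[:, j]
        if tucker_congruence(ref[:, i], col) < 0:
            col = -col
        out[:, i] = col
    return out


class ExploratoryFactorAnalysis(BaseEstimator, TransformerMixin):
    """Minres (OLS) exploratory factor analysis with varimax rotation.

    Parameters
    ----------
    n_factors : int or None
        Number of factors; when None it is chosen by parallel analysis
        against the median eigenvalues of ``n_random`` random datasets.
    n_random : int
        Random datasets for parallel analysis (default 10 000).
    random_state : int or None
        Seed for parallel analysis.

    Attributes (after fit)
    ----------------------
    loadings_ : (p, k) varimax-rotated loadings, factors ordered by explained
        variance, sign fixed so each factor's largest loading is positive.
    uniquenesses_, eigenvalues_, explained_variance_ratio_, rotation_,
    mean_, scale_, n_factors_, feature_names_in_
    """

    def __init__(self, n_factors=None, n_random=10000, max_iter=200,
                 random_state=None):
        self.n_factors = n_factors
        self.n_random = n_random
        self.max_iter = max_iter
        self.random_state = random_state

    def _validate(self, X):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("EFA input contains non-finite values; run drop_invalid first")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        if np.any(self.scale_ == 0):
            raise ValueError("constant column passed to EFA; run correlation_filter first")
        Z = (X - self.mean_) / self.scale_
        R = np.corrcoef(Z, rowvar=False)
        self.correlation_ = R
        self.eigenvalues_ = np.sort(np.linalg.eigvalsh(R))[::-1]
        k = self.n_factors
        if k is None:
            k = parallel_analysis(Z, n_random=self.n_random, seed=self.random_state)
            k = max(k, 1)
        self.n_factors_ = int(k)
        L0, psi = _minres_loadings(R, self.n_factors_, self.max_iter)
        Lr, rot = varimax(L0)
        self.unrotated_loadings_ = L0
        self.rotation_ = rot
        self.loadings_ = _order_and_sign(Lr)
        self.uniquenesses_ = psi
        self.explained_variance_ratio_ = np.sum(self.loadings_ ** 2, axis=0) / R.shape[0]
        return self

    def transform(self, X):
        """Regression-method factor scores for (possibly new) rows."""
        check_is_fitted(self, "loadings_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        W = linalg.solve(self.correlation_, self.loadings_, assume_a="pos")
        return Z @ W

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def efa(X, n_factors: int) -> ExploratoryFactorAnalysis:
    """Fit a varimax-rotated minres EFA with a fixed factor count."""
    return ExploratoryFactorAnalysis(n_factors=n_factors).fit(X)


def bootstrap_loadings(X, n_factors: int, n_boot: int = 1000, seed=None,
                       reference: ExploratoryFactorAnalysis | None = None):
    """Bootstrap percentile CIs (2.5/97.5%) for varimax-rotated loadings.

    Rows are resampled with replacement; each replicate is refitted and
    aligned to the reference solution by factor permutation and sign before
    the percentiles are taken. Replicates that fail to converge are skipped
    (an error is raised if more than 10% fail).
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if reference is None:
        reference = efa(X, n_factors)
    ref = reference.loadings_
    rng = np.random.default_rng(seed)
    reps, skipped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            m = ExploratoryFactorAnalysis(n_factors=n_factors).fit(X[idx])
            reps.append(align_loadings(m.loadings_, ref))
        except (RuntimeError, ValueError):
            skipped += 1
    if skipped > 0.1 * n_boot:
        raise RuntimeError(f"{skipped}/{n_boot} bootstrap replicates failed to converge")
    reps = np.stack(reps)
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    return lo, hi, skipped
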