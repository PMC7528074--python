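"""Phylogenetic comparative statistics.

The statistical core is exposed two ways:

* sklearn-style estimators — :class:`PhylogeneticSignal`, :class:`PGLS`,
  :class:`TwoBlockPLS` — with ``fit``/``get_params`` conventions and fitted
  attributes ending in an underscore, so they compose with sklearn tooling;
* thin module-level functions (:func:`blomberg_k`, :func:`phylosig_test`,
  :func:`pgls_fit`, :func:`rrpp_significance`, :func:`two_block_pls`,
  :func:`phylo_pls`, :func:`multi_tree_run`) returning small result
  dataclasses, for scripted pipelines.

All methods assume a Brownian-motion covariance structure ``C`` among tips
(see :func:`viperpcm.treeops.phylo_covariance`).  Significance is assessed by
permutation throughout: tip-label permutation of the trait for the signal
test, residual randomization (RRPP) for PGLS, and row permutation of one
block for PLS.  Observed statistics are always included in the permutation
reference set, so p-values are bounded below by ``1/(n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.linalg import LinAlgError
from scipy.linalg import cho_factor, cho_solve, eigh
from sklearn.base import BaseEstimator, RegressorMixin

from .treeops import Chronogram, PhyloCovariance

__all__ = [
    "PhyloSignalResult",
    "PGLSResult",
    "PLSResult",
    "MultiTreeSummary",
    "PhylogeneticSignal",
    "PGLS",
    "TwoBlockPLS",
    "phylo_gls_mean",
    "blomberg_k",
    "phylosig_test",
    "pgls_fit",
    "rrpp_significance",
    "two_block_pls",
    "phylo_pls",
    "pairwise_pgls",
    "multi_tree_run",
    "spawn_seeds",
]


# ---------------------------------------------------------------------------
# helpers


def _cov_matrix(C, labels: Sequence[str] | None = None) -> np.ndarray:
    """Accept a PhyloCovariance or a plain matrix; align to labels if given."""
    if isinstance(C, PhyloCovariance):
        if labels is not None and list(labels) != C.labels:
            C = C.reorder(list(labels))
        return C.matrix
    return np.asarray(C, dtype=float)


def _values_and_labels(x) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(x, pd.Series):
        return x.to_numpy(dtype=float), [str(i) for i in x.index]
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(i) for i in x.index]
    return np.asarray(x, dtype=float), None


def _chol(C: np.ndarray):
    try:
        return cho_factor(C, lower=True)
    except LinAlgError as exc:
        cond = np.linalg.cond(C)
        raise LinAlgError(
            f"phylogenetic covariance is singular or not PD (cond={cond:.3g})"
        ) from exc


def inv_sqrt_psd(C: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root ``C^{-1/2} = U W^{-1/2} U^T``."""
    w, U = eigh(C)
    wmax = w[-1]
    if wmax <= 0:
        raise LinAlgError("covariance has no positive eigenvalue")
    if w[0] < -rtol * wmax:
        raise LinAlgError("covariance is not positive semi-definite")
    w = np.clip(w, rtol * wmax, None)
    return (U / np.sqrt(w)) @ U.T


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(master_seed, n: int) -> list[np.random.SeedSequence]:
    """Independent counter-keyed substreams from one master seed.

    Stream *i* depends only on ``(master_seed, i)``, so consumers can be run
    in any order (or in parallel) and still reproduce bit-identical results.
    """
    if isinstance(master_seed, np.random.SeedSequence):
        base = master_seed
    else:
        base = np.random.SeedSequence(master_seed)
    return base.spawn(n)


def _perm_matrix(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """m random permutations of range(n), as an (m, n) index array."""
    return np.argsort(rng.random((m, n)), axis=1)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class PhyloSignalResult:
    """Blomberg's K with the components of its ratio and a permutation test."""

    K: float
    mse0: float
    mse: float
    expected_ratio: float
    p_value: float | None = None
    n_perm: int = 0


@dataclass
class PGLSResult:
    coefficients: np.ndarray
    df_model: int
    df_resid: int
    r2: float
    f: float
    z: float | None = None
    p_value: float | None = None


@dataclass
class PLSResult:
    r: float
    left_loadings: np.ndarray
    right_loadings: np.ndarray
    left_scores: np.ndarray
    right_scores: np.ndarray
    p_value: float | None
    mode: str


@dataclass
class MultiTreeSummary:
    """Across-tree mean and dispersion of per-tree statistics.

    ``dispersion`` is the standard deviation of the per-tree values (the
    "± SE" column of the report tables); ``se_of_mean`` additionally divides
    by sqrt(n_trees).  ``n_significant`` counts trees with p < alpha.
    """

    per_tree: pd.DataFrame
    mean: pd.Series
    dispersion: pd.Series
    se_of_mean: pd.Series
    n_trees: int
    n_significant: int
    n_failed: int
    alpha: float


# ---------------------------------------------------------------------------
# GLS mean and Blomberg's K


def phylo_gls_mean(x, C) -> float:
    """GLS estimate of the ancestral (root) state, â = (1'C⁻¹1)⁻¹ 1'C⁻¹x."""
    xv, labels = _values_and_labels(x)
    Cm = _cov_matrix(C, labels)
    factor = _chol(Cm)
    u = cho_solve(factor, np.ones(len(xv)))
    return float(u @ xv / u.sum())


def _k_statistics(X: np.ndarray, factor, trace: float) -> np.ndarray:
    """Blomberg's K for each column of X (n, m) given a Cholesky factor of C."""
    n = X.shape[0]
    one = np.ones(n)
    u = cho_solve(factor, one)
    s = float(u @ one)
    ahat = (u @ X) / s
    D = X - ahat  # (n, m)
    mse0 = np.einsum("ij,ij->j", D, D) / (n - 1)
    CinvD = cho_solve(factor, X) - np.outer(u, ahat)
    mse = np.einsum("ij,ij->j", D, CinvD) / (n - 1)
    expected = (trace - n / s) / (n - 1)
    return (mse0 / mse) / expected


class PhylogeneticSignal(BaseEstimator):
    """Blomberg's K phylogenetic-signal statistic with a permutation test.

    K compares the observed trait mean squared error (about the GLS root
    state) to its GLS counterpart, standardized by the Brownian expectation
    of that ratio on the given tree: K = 1 under pure Brownian motion, K < 1
    when close relatives resemble each other less than Brownian motion
    predicts.  Significance comes from permuting trait values across tips
    and counting permuted K values at least as large as the observed one.

    Parameters
    ----------
    cov : PhyloCovariance or (n, n) array
        Brownian covariance among tips.
    n_perm : int
        Number of random tip permutations (0 disables the test).
    random_state : int, Generator or SeedSequence, optional
    """

    def __init__(self, cov=None, n_perm: int = 999, random_state=None):
        self.cov = cov
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y=None):
        xv, labels = _values_and_labels(X)
        xv = xv.ravel()
        n = xv.size
        if n < 3:
            raise ValueError("phylogenetic signal needs at least 3 tips")
        if np.ptp(xv) == 0:
            raise ValueError("trait has zero variance; K is undefined")
        Cm = _cov_matrix(self.cov, labels)
        factor = _chol(Cm)
        trace = float(np.trace(Cm))

        one = np.ones(n)
        u = cho_solve(factor, one)
        s = float(u @ one)
        ahat = float(u @ xv) / s
        d = xv - ahat
        self.mse0_ = float(d @ d) / (n - 1)
        self.mse_ = float(d @ cho_solve(factor, d)) / (n - 1)
        self.expected_ratio_ = (trace - n / s) / (n - 1)
        self.k_ = (self.mse0_ / self.mse_) / self.expected_ratio_

        if self.n_perm:
            rng = _rng(self.random_state)
            perms = _perm_matrix(rng, n, self.n_perm)
            k_perm = _k_statistics(xv[perms].T, factor, trace)
            n_ge = int(np.sum(k_perm >= self.k_ - 1e-12))
            self.p_value_ = (1 + n_ge) / (self.n_perm + 1)
            self.null_distribution_ = k_perm
        else:
            self.p_value_ = None
        self.n_features_in_ = 1
        return self


def blomberg_k(x, C) -> PhyloSignalResult:
    """Blomberg's K statistic only (no permutation test)."""
    est = PhylogeneticSignal(cov=C, n_perm=0).fit(x)
    return PhyloSignalResult(est.k_, est.mse0_, est.mse_, est.expected_ratio_)


def phylosig_test(x, C, n_perm: int = 999, seed=None) -> PhyloSignalResult:
    """Blomberg's K with an upper-tail tip-permutation test."""
    est = PhylogeneticSignal(cov=C, n_perm=n_perm, random_state=seed).fit(x)
    return PhyloSignalResult(
        est.k_, est.mse0_, est.mse_, est.expected_ratio_, est.p_value_, n_perm
    )


# ---------------------------------------------------------------------------
# PGLS with RRPP


class PGLS(RegressorMixin, BaseEstimator):
    """Phylogenetic generalized least squares with RRPP significance.

    The model ``y = Xβ + ε`` with ``ε ~ N(0, σ²C)`` is fit by premultiplying
    the intercept-augmented design and response by the symmetric inverse
    square root of ``C`` and running OLS in that transformed space.  R² and F
    are computed there, against the GLS-mean (intercept-only) reduced model.
    Significance uses residual randomization (RRPP): reduced-model residuals
    are permuted, added back to reduced fitted values, and the full model is
    refit to each pseudo-dataset; the effect size Z is the standardized
    position of ln F among the permuted ln F values.

    With ``cov=None`` (identity covariance) this reduces exactly to OLS with
    a classical permutation F-test.
    """

    def __init__(self, cov=None, n_perm: int = 999, random_state=None):
        self.cov = cov
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y):
        Xv, xlabels = _values_and_labels(X)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        yv, ylabels = _values_and_labels(y)
        yv = yv.ravel()
        n, p = Xv.shape
        if n != yv.size:
            raise ValueError("X and y have different numbers of tips")
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 tips (n={n}, p={p})")
        labels = ylabels or xlabels
        if self.cov is None:
            P = np.eye(n)
        else:
            P = inv_sqrt_psd(_cov_matrix(self.cov, labels))

        design = np.column_stack([np.ones(n), Xv])
        if np.linalg.matrix_rank(design) < p + 1:
            raise ValueError("design matrix is rank deficient (collinearity)")
        Xs = P @ design
        ys = P @ yv

        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.df_model_ = p
        self.df_resid_ = n - p - 1

        # reduced (intercept-only) model in the transformed space
        x0 = P @ np.ones(n)
        q0 = x0 / np.linalg.norm(x0)
        fit0 = q0 * (q0 @ ys)
        e0 = ys - fit0
        sst = float(e0 @ e0)
        Q, _ = np.linalg.qr(Xs)
        resid = ys - Q @ (Q.T @ ys)
        sse = float(resid @ resid)
        ssr = max(sst - sse, 0.0)
        self.r2_ = ssr / sst if sst > 0 else 0.0
        if sse > 0:
            self.f_ = (ssr / p) / (sse / self.df_resid_)
        else:
            self.f_ = np.inf

        self._Q = Q
        self._q0 = q0
        self._fit0 = fit0
        self._e0 = e0

        if self.n_perm:
            self.p_value_, self.z_ = self._rrpp()
        else:
            self.p_value_ = self.z_ = None
        self.n_features_in_ = p
        return self

    def _rrpp(self) -> tuple[float, float]:
        rng = _rng(self.random_state)
        n = self._e0.size
        perms = _perm_matrix(rng, n, self.n_perm)
        Yp = self._fit0[None, :] + self._e0[perms]  # (m, n)
        total = np.einsum("ij,ij->i", Yp, Yp)
        sst_p = total - (Yp @ self._q0) ** 2
        A = Yp @ self._Q
        sse_p = total - np.einsum("ij,ij->i", A, A)
        sse_p = np.maximum(sse_p, 1e-300)
        ssr_p = np.maximum(sst_p - sse_p, 0.0)
        f_perm = (ssr_p / self.df_model_) / (sse_p / self.df_resid_)
        n_ge = int(np.sum(f_perm >= self.f_ * (1 - 1e-12)))
        p_value = (1 + n_ge) / (self.n_perm + 1)
        log_all = np.log(np.append(f_perm, self.f_).clip(1e-300))
        sd = log_all.std(ddof=1)
        z = float((np.log(max(self.f_, 1e-300)) - log_all.mean()) / sd) if sd > 0 else 0.0
        self.null_distribution_ = f_perm
        return p_value, z

    def predict(self, X):
        Xv, _ = _values_and_labels(X)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        return Xv @ self.coef_ + self.intercept_

    def result(self) -> PGLSResult:
        return PGLSResult(
            coefficients=np.concatenate([[self.intercept_], self.coef_]),
            df_model=self.df_model_,
            df_resid=self.df_resid_,
            r2=self.r2_,
            f=self.f_,
            z=self.z_,
            p_value=self.p_value_,
        )


def pgls_fit(y, X, C) -> PGLSResult:
    """GLS fit and ANOVA statistics only (no permutation inference)."""
    return PGLS(cov=C, n_perm=0).fit(X, y).result()


def rrpp_significance(y, X, C, n_perm: int = 999, seed=None) -> tuple[float, float]:
    """RRPP permutation p-value and Z effect size for a PGLS model."""
    import warnings as _warnings

    if n_perm < 99:
        _warnings.warn(
            f"n_perm={n_perm} gives a coarse p-value resolution "
            f"(minimum attainable p = {1 / (n_perm + 1):.3g})",
            stacklevel=2,
        )
    est = PGLS(cov=C, n_perm=n_perm, random_state=seed).fit(X, y)
    return est.p_value_, est.z_


# ---------------------------------------------------------------------------
# two-block PLS


def _first_singular_pair(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    u, v = U[:, 0], Vt[0]
    # sign convention: only the joint (u, v) flip preserves R, so anchor the
    # largest-magnitude LEFT loading positive; right-block signs then carry
    # the direction of the association
    if u[np.argmax(np.abs(u))] < 0:
        u, v = -u, -v
    return u, v, float(s[0])


def _score_correlation(xs: np.ndarray, ys: np.ndarray) -> float:
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(abs(np.corrcoef(xs, ys)[0, 1]))


class TwoBlockPLS(BaseEstimator):
    """Two-block partial least squares, naive or phylogenetic.

    The first singular pair of the cross-covariance ``X'Y/(n-1)`` between two
    centered blocks gives one axis per block; ``r_`` is the absolute Pearson
    correlation of the paired scores, tested by permuting rows of the right
    block.  With ``cov`` given, both blocks are first centered on their GLS
    (phylogenetic) column means and premultiplied by the symmetric inverse
    square root of ``C``; permutation then shuffles the transformed rows.
    On an equal-depth star phylogeny this coincides with the naive analysis.
    """

    def __init__(self, cov=None, n_perm: int = 999, random_state=None):
        self.cov = cov
        self.n_perm = n_perm
        self.random_state = random_state

    def _transform_blocks(self, Xv, Yv, labels):
        if self.cov is None:
            self._P = None
            return Xv - Xv.mean(0), Yv - Yv.mean(0)
        Cm = _cov_matrix(self.cov, labels)
        factor = _chol(Cm)
        n = Xv.shape[0]
        u = cho_solve(factor, np.ones(n))
        s = u.sum()
        P = inv_sqrt_psd(Cm)
        self._P = P
        ax = (u @ Xv) / s
        ay = (u @ Yv) / s
        return P @ (Xv - ax), P @ (Yv - ay)

    def fit(self, X, Y):
        Xv, xlabels = _values_and_labels(X)
        Yv, ylabels = _values_and_labels(Y)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        if Yv.ndim == 1:
            Yv = Yv[:, None]
        if Xv.shape[0] != Yv.shape[0]:
            raise ValueError("blocks have different numbers of rows")
        n = Xv.shape[0]
        if n < 3:
            raise ValueError("two-block PLS needs at least 3 rows")
        for name, block in (("left", Xv), ("right", Yv)):
            if np.any(np.ptp(block, axis=0) == 0):
                import warnings as _warnings

                _warnings.warn(f"{name} block has constant column(s)", stacklevel=2)
        labels = xlabels or ylabels
        Xt, Yt = self._transform_blocks(Xv, Yv, labels)

        R = Xt.T @ Yt / (n - 1)
        u, v, _ = _first_singular_pair(R)
        xs, ys = Xt @ u, Yt @ v
        self.x_loadings_, self.y_loadings_ = u, v
        self.x_scores_, self.y_scores_ = xs, ys
        self.r_ = _score_correlation(xs, ys)
        self.mode_ = "phylogenetic" if self.cov is not None else "naive"

        if self.n_perm:
            rng = _rng(self.random_state)
            r_perm = np.empty(self.n_perm)
            for i in range(self.n_perm):
                Yp = Yt[rng.permutation(n)]
                up, vp, _ = _first_singular_pair(Xt.T @ Yp / (n - 1))
                r_perm[i] = _score_correlation(Xt @ up, Yp @ vp)
            n_ge = int(np.sum(r_perm >= self.r_ - 1e-12))
            self.p_value_ = (1 + n_ge) / (self.n_perm + 1)
            self.null_distribution_ = r_perm
        else:
            self.p_value_ = None
        self.n_features_in_ = Xv.shape[1]
        return self

    def result(self) -> PLSResult:
        return PLSResult(
            r=self.r_,
            left_loadings=self.x_loadings_,
            right_loadings=self.y_loadings_,
            left_scores=self.x_scores_,
            right_scores=self.y_scores_,
            p_value=self.p_value_,
            mode=self.mode_,
        )


def two_block_pls(X, Y, n_perm: int = 999, seed=None) -> PLSResult:
    """Phylogenetically naive two-block PLS (arithmetic centering)."""
    return TwoBlockPLS(cov=None, n_perm=n_perm, random_state=seed).fit(X, Y).result()


def phylo_pls(X, Y, C, n_perm: int = 999, seed=None) -> PLSResult:
    """Two-block PLS after GLS centering and C^{-1/2} whitening of both blocks."""
    return TwoBlockPLS(cov=C, n_perm=n_perm, random_state=seed).fit(X, Y).result()


# ---------------------------------------------------------------------------
# pairwise PGLS and multi-tree summaries


def pairwise_pgls(
    traits: pd.DataFrame,
    descriptors: pd.DataFrame,
    C,
    n_perm: int = 999,
    seed=None,
    holm: bool = False,
) -> pd.DataFrame:
    """PGLS of each trait column on each descriptor column.

    Returns a long table (trait, descriptor, coefficient, r2, f, z, p_value,
    significant) flagging raw p < 0.05; ``holm=True`` applies a Holm
    correction within each trait before flagging.
    """
    if list(traits.index) != list(descriptors.index):
        raise ValueError("trait and descriptor tables have different row labels")
    seeds = spawn_seeds(seed, traits.shape[1] * descriptors.shape[1])
    rows = []
    k = 0
    for trait in traits.columns:
        for desc in descriptors.columns:
            est = PGLS(cov=C, n_perm=n_perm, random_state=_rng(seeds[k])).fit(
                descriptors[[desc]], traits[trait]
            )
            rows.append(
                {
                    "trait": trait,
                    "descriptor": desc,
                    "coefficient": float(est.coef_[0]),
                    "r2": est.r2_,
                    "f": est.f_,
                    "z": est.z_,
                    "p_value": est.p_value_,
                }
            )
            k += 1
    out = pd.DataFrame(rows)
    if holm:
        adj = np.empty(len(out))
        for trait in traits.columns:
            sel = (out["trait"] == trait).to_numpy()
            adj[sel] = _holm_adjust(out.loc[sel, "p_value"].to_numpy())
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < 0.05
    else:
        out["significant"] = out["p_value"] < 0.05
    return out


def _holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def multi_tree_run(
    analysis: Callable[[Chronogram, np.random.SeedSequence], Mapping[str, float]],
    trees: Iterable[Chronogram],
    seed=None,
    alpha: float = 0.05,
    p_key: str = "p_value",
) -> MultiTreeSummary:
    """Repeat a per-tree analysis over a tree collection and summarize.

    ``analysis(tree, seed)`` must return a flat mapping of named statistics;
    the entry named ``p_key`` drives the count of significant iterations.
    Per-tree substreams are counter-keyed off the master seed, so results do
    not depend on iteration order.  A failing tree is recorded, warned about
    and excluded rather than aborting the whole run.
    """
    import warnings as _warnings

    trees = list(trees)
    seeds = spawn_seeds(seed, len(trees))
    records: list[dict[str, float]] = []
    n_failed = 0
    for i, (tree, sub) in enumerate(zip(trees, seeds)):
        try:
            stats = dict(analysis(tree, sub))
        except Exception as exc:
            n_failed += 1
            _warnings.warn(f"analysis failed on tree {i}: {exc}", stacklevel=2)
            continue
        stats["tree_index"] = i
        records.append(stats)
    if not records:
        raise ValueError("analysis failed on every tree")
    per_tree = pd.DataFrame.from_records(records).set_index("tree_index")
    mean = per_tree.mean()
    dispersion = per_tree.std(ddof=1) if len(per_tree) > 1 else per_tree.iloc[0] * 0.0
    se_of_mean = dispersion / np.sqrt(len(per_tree))
    n_significant = (
        int((per_tree[p_key] < alpha).sum()) if p_key in per_tree else 0
    )
    return MultiTreeSummary(
        per_tree=per_tree,
        mean=mean,
        dispersion=dispersion,
        se_of_mean=se_of_mean,
        n_trees=len(per_tree),
        n_significant=n_significant,
        n_failed=n_failed,
        alpha=alpha,
    )
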