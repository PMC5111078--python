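"""Supervised admixture estimation with fixed ancestral allele frequencies.

Given a K x L matrix F of ancestral allele frequencies (one row per ancestral
population, e.g. ancient Levantine / Armenian / Anatolian sources) and a
diploid genotype vector g over the same loci (dosages 0/1/2 of the counted
allele, missing allowed), the admixture proportions q on the K-simplex are
estimated by maximising the binomial likelihood

    l(q) = sum_j  log C(2, g_j) + g_j log p_j + (2 - g_j) log(1 - p_j),
    p_j = sum_k q_k F_kj,

over non-missing loci j (the binomial coefficient is constant in q, so it
does not affect the maximiser, but it makes l the genuine log-probability
of the genotypes). The optimiser is the classical multiplicative EM
update

    q_k <- q_k / (2 L') * sum_j [ g_j F_kj / p_j + (2 - g_j)(1 - F_kj) / (1 - p_j) ],

(L' = number of non-missing loci), which stays on the simplex and increases
the log-likelihood monotonically. Frequencies are clamped to [eps, 1 - eps]
before likelihood evaluation so fixed loci cannot produce infinite logs.

When all rows of F are identical the likelihood is flat in q; the estimate is
reported as the uniform vector with an ``unidentifiable`` flag rather than an
arbitrary interior point.

The module also implements the standard sliding-window LD input filter:
within windows of `window` SNPs (sliding by `step`), the later member of any
pair of retained loci with squared Pearson dosage correlation above `r2_max`
is removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InputError, ShapeError
from .world import MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "log_likelihood",
    "estimate_admixture",
    "ld_prune",
    "SupervisedAdmixture",
    "LDPruner",
    "AdmixtureFitResult",
]


def _as_float_genotypes(G) -> np.ndarray:
    """Genotypes as float with NaN for missing; accepts MISSING (-1) or NaN."""
    X = np.asarray(G, dtype=float)
    X = np.where(X == MISSING, np.nan, X)
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(X) & ~np.isin(X, (0.0, 1.0, 2.0))
    if np.any(bad):
        raise InputError("genotype values must be 0, 1, 2 or missing")
    return X


def _clamp(F, eps: float) -> np.ndarray:
    F = np.atleast_2d(np.asarray(F, dtype=float))
    return np.clip(F, eps, 1.0 - eps)


def log_likelihood(q, g, F, *, clamp: float = 1e-6) -> float:
    """Binomial log-likelihood of admixture vector q for one genotype vector."""
    q = np.asarray(q, dtype=float).ravel()
    F = _clamp(F, clamp)
    if q.size != F.shape[0]:
        raise ShapeError(f"q has K={q.size} but F has K={F.shape[0]} rows")
    g = _as_float_genotypes(g).ravel()
    if g.size != F.shape[1]:
        raise ShapeError(f"genotype length {g.size} != n_loci {F.shape[1]}")
    obs = ~np.isnan(g)
    if not obs.any():
        return 0.0
    g = g[obs]
    p = q @ F[:, obs]
    const = math.log(2.0) * float(np.sum(g == 1.0))  # binomial coefficient term
    return const + float(np.sum(g * np.log(p) + (2.0 - g) * np.log1p(-p)))


@dataclass
class AdmixtureFitResult:
    """Per-individual outcome of the EM maximisation."""

    Q: np.ndarray  # (n, K) estimated proportions
    log_likelihood: np.ndarray  # (n,) final log-likelihood
    converged: np.ndarray  # (n,) bool
    n_iter: np.ndarray  # (n,) iterations used
    unidentifiable: bool  # True when all F rows coincide (flat likelihood)


def _em_estimate(G: np.ndarray, F: np.ndarray, tol: float, max_iter: int) -> AdmixtureFitResult:
    """Vectorised EM over the rows of G (n individuals x L loci)."""
    n, L = G.shape
    K = F.shape[0]
    W = (~np.isnan(G)).astype(float)
    nonmiss = W.sum(axis=1)
    ll_const = math.log(2.0) * np.nansum(np.where(G == 1.0, 1.0, 0.0), axis=1)
    if np.any(nonmiss == 0):
        raise InputError("at least one individual has all loci missing")
    Gz = np.where(np.isnan(G), 0.0, G)

    if K == 1:
        Q = np.ones((n, 1))
        ll = ll_const + np.array([
            float(np.sum(W[i] * (Gz[i] * np.log(F[0]) + (2 - Gz[i]) * np.log1p(-F[0]))))
            for i in range(n)
        ])
        return AdmixtureFitResult(Q, ll, np.ones(n, bool), np.zeros(n, int), False)

    if float(np.max(F.max(axis=0) - F.min(axis=0))) < 1e-12:
        # every component has identical frequencies: likelihood flat in q
        Q = np.full((n, K), 1.0 / K)
        p = Q[0] @ F
        ll = ll_const + np.sum(W * (Gz * np.log(p) + (2 - Gz) * np.log1p(-p)), axis=1)
        return AdmixtureFitResult(Q, ll, np.ones(n, bool), np.zeros(n, int), True)

    Q = np.full((n, K), 1.0 / K)
    Fc = 1.0 - F

    def loglik(Q, rows):
        P = Q @ F
        return np.sum(W[rows] * (Gz[rows] * np.log(P) + (2 - Gz[rows]) * np.log1p(-P)), axis=1)

    ll = loglik(Q, np.arange(n))
    converged = np.zeros(n, bool)
    n_iter = np.zeros(n, int)
    active = np.arange(n)
    for it in range(1, max_iter + 1):
        Qa, Ga, Wa = Q[active], Gz[active], W[active]
        P = Qa @ F
        A = ((Wa * Ga) / P) @ F.T
        B = ((Wa * (2.0 - Ga)) / (1.0 - P)) @ Fc.T
        Qn = Qa * (A + B) / (2.0 * nonmiss[active])[:, None]
        Qn /= Qn.sum(axis=1, keepdims=True)  # guard fp drift
        Q[active] = Qn
        new_ll = loglik(Qn, active)
        rel = np.abs(new_ll - ll[active]) / (np.abs(ll[active]) + 1.0)
        ll[active] = new_ll
        n_iter[active] = it
        done = rel <= tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    return AdmixtureFitResult(Q, ll + ll_const, converged, n_iter, False)


def estimate_admixture(
    g, F, tol: float = 1e-7, max_iter: int = 2000, *, clamp: float = 1e-6
):
    """Maximum-likelihood admixture proportions for one genotype vector.

    Returns ``(q, converged, log_likelihood)``; with a flat likelihood (all
    F rows identical) q is the uniform vector and the result object's
    ``unidentifiable`` flag (available via :class:`SupervisedAdmixture`) is
    set. Non-convergence returns the best iterate with ``converged=False``.
    """
    F = _clamp(F, clamp)
    g = _as_float_genotypes(g).ravel()
    if g.size != F.shape[1]:
        raise ShapeError(f"genotype length {g.size} != n_loci {F.shape[1]}")
    res = _em_estimate(g[None, :], F, tol, max_iter)
    return res.Q[0], bool(res.converged[0]), float(res.log_likelihood[0])


class SupervisedAdmixture(BaseEstimator, TransformerMixin):
    """Supervised admixture estimator as a scikit-learn transformer.

    ``fit(F)`` fixes the ancestral components (rows of the K x L frequency
    matrix, clamped to [clamp, 1-clamp]); ``transform(G)`` maps an
    (n_individuals, L) genotype matrix to the (n, K) matrix of estimated
    admixture proportions. ``fit_result(G)`` exposes convergence diagnostics.

    Parameters
    ----------
    tol : float, default 1e-7
        Relative log-likelihood change declaring convergence.
    max_iter : int, default 2000
        EM iteration cap; past it the best iterate is returned un-converged.
    clamp : float, default 1e-6
        Frequency clamping bound avoiding infinite logs at fixed loci.
    """

    def __init__(self, tol: float = 1e-7, max_iter: int = 2000, clamp: float = 1e-6):
        self.tol = tol
        self.max_iter = max_iter
        self.clamp = clamp

    def fit(self, X, y=None, component_labels=None):
        F = _clamp(X, self.clamp)
        self.components_ = F
        self.n_components_ = F.shape[0]
        self.n_loci_ = F.shape[1]
        self.component_labels_ = (
            list(map(str, component_labels))
            if component_labels is not None
            else [f"C{k}" for k in range(F.shape[0])]
        )
        if len(self.component_labels_) != self.n_components_:
            raise ShapeError("component_labels length != K")
        return self

    def fit_result(self, G) -> AdmixtureFitResult:
        self._check_fitted()
        G = np.atleast_2d(_as_float_genotypes(G))
        if G.shape[1] != self.n_loci_:
            raise ShapeError(f"genotypes have {G.shape[1]} loci, model has {self.n_loci_}")
        return _em_estimate(G, self.components_, self.tol, self.max_iter)

    def transform(self, G) -> np.ndarray:
        """Estimated admixture proportions, one simplex row per individual."""
        return self.fit_result(G).Q

    def score(self, G) -> float:
        """Mean per-individual maximised log-likelihood."""
        return float(self.fit_result(G).log_likelihood.mean())

    def _check_fitted(self) -> None:
        if not hasattr(self, "components_"):
            raise InputError("SupervisedAdmixture instance is not fitted yet")


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(G, window: int = 50, step: int = 5, r2_max: float = 0.2) -> list[int]:
    """Sliding-window LD filter; returns indexes of the retained loci.

    Within each window of `window` consecutive loci (the window start sliding
    by `step`), every pair of still-retained loci is examined in index order
    and the later-indexed member of any pair with squared Pearson dosage
    correlation > `r2_max` is removed. Loci with zero variance (monomorphic)
    have undefined correlation and are never removed for LD.
    """
    X = _as_float_genotypes(np.atleast_2d(G))
    n, L = X.shape
    if n < 2:
        raise InputError("LD pruning needs at least two individuals")
    if window < 1 or step < 1:
        raise InputError("window and step must be positive")
    kept = np.ones(L, dtype=bool)
    if window == 1 or L < 2:
        return list(range(L))

    has_missing = np.isnan(X).any()
    starts = range(0, max(L - 1, 1), step)
    n_monomorphic = 0
    for start in starts:
        idx = [j for j in range(start, min(start + window, L)) if kept[j]]
        if len(idx) < 2:
            continue
        sub = X[:, idx]
        if has_missing:
            C = np.ma.corrcoef(np.ma.masked_invalid(sub), rowvar=False)
            C = np.asarray(C.filled(np.nan))
        else:
            sd = sub.std(axis=0)
            zero = sd == 0
            n_monomorphic += int(zero.sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                C = np.corrcoef(sub, rowvar=False)
            C[zero, :] = np.nan
            C[:, zero] = np.nan
        alive = [True] * len(idx)
        for a in range(len(idx)):
            if not alive[a]:
                continue
            for b in range(a + 1, len(idx)):
                if not alive[b]:
                    continue
                r = C[a, b]
                if np.isfinite(r) and r * r > r2_max:
                    alive[b] = False
                    kept[idx[b]] = False
    if n_monomorphic:
        logger.info("ld_prune: %d monomorphic window entries retained (undefined r)", n_monomorphic)
    return [int(j) for j in np.flatnonzero(kept)]


class LDPruner(BaseEstimator, TransformerMixin):
    """Sliding-window LD filter as a scikit-learn feature selector.

    ``fit(G)`` records the retained locus indexes in ``kept_indices_`` /
    boolean ``support_``; ``transform(G)`` keeps those columns.
    """

    def __init__(self, window: int = 50, step: int = 5, r2_max: float = 0.2):
        self.window = window
        self.step = step
        self.r2_max = r2_max

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X))
        self.n_features_in_ = X.shape[1]
        self.kept_indices_ = ld_prune(X, self.window, self.step, self.r2_max)
        self.support_ = np.zeros(self.n_features_in_, dtype=bool)
        self.support_[self.kept_indices_] = True
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "support_"):
            raise InputError("LDPruner instance is not fitted yet")
        X = np.atleast_2d(np.asarray(X))
        if X.shape[1] != self.n_features_in_:
            raise ShapeError("transform input has a different number of loci than fit")
        return X[:, self.support_]

    def get_support(self, indices: bool = False):
        if indices:
            return list(self.kept_indices_)
        return self.support_.copy()
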