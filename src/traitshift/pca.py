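"""Bayesian PCA with varimax rotation and credible intervals on loadings.

Mechanism: the posterior of the trait covariance matrix is sampled with the
conjugate inverse-Wishart Gibbs sampler; each covariance draw is converted
to a correlation matrix, eigendecomposed, the top-k components are scaled to
loadings (eigenvector times sqrt(eigenvalue), so squared loadings sum to the
eigenvalue and variance explained is well defined), varimax-rotated, and
then sign/permutation-aligned to a classical-PCA+varimax reference so that
elementwise quantiles over draws are meaningful.  Summaries are medians and
equal-tailed 50%/95% intervals; variance explained of a rotated component is
its sum of squared loadings divided by the number of traits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import StandardizedMatrix
from .mcmc import DrawMatrix, MCMCConfig, cov_draws_as_matrices, gelman_rubin, sample_mvnormal_cov

EIGEN_MULTIPLICITY_TOL = 1e-10


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax criterion: sum over columns of var of squared loadings."""
    sq = np.square(L)
    return float(np.sum(np.mean(sq**2, axis=0) - np.mean(sq, axis=0) ** 2))


def varimax(
    L: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
    kaiser: bool = False,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Varimax rotation maximizing the variance of squared loadings per column.

    Returns (rotated loadings, orthonormal rotation matrix T with
    L_rot = L @ T, converged flag).  ``kaiser`` applies Kaiser (communality)
    row normalization before rotating.  Iteration stops when the criterion
    gain drops below ``tol``; non-convergence returns the best iterate with a
    warning.
    """
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1), True
    W = L
    comm = None
    if kaiser:
        comm = np.sqrt(np.sum(L**2, axis=1))
        comm[comm == 0] = 1.0
        W = L / comm[:, None]
    T = np.eye(k)
    crit = varimax_criterion(W)
    converged = False
    for _ in range(max_iter):
        B = W @ T
        G = W.T @ (B**3 - B * (np.sum(B**2, axis=0) / p))
        U, _, Vt = np.linalg.svd(G)
        T = U @ Vt
        new_crit = varimax_criterion(W @ T)
        if new_crit - crit < tol:
            converged = True
            break
        crit = new_crit
    if not converged:
        warnings.warn(f"varimax did not converge in {max_iter} iterations")
    rotated = W @ T
    if comm is not None:
        rotated = rotated * comm[:, None]
    return rotated, T, converged


def _order_and_sign(L: np.ndarray) -> np.ndarray:
    """Deterministic convention: columns by variance explained (descending),
    each column oriented so its largest-magnitude element is positive."""
    order = np.argsort(-np.sum(L**2, axis=0), kind="stable")
    out = L[:, order].copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] *= -1
    return out


def pca_varimax_from_corr(R: np.ndarray, k: int, kaiser: bool = False) -> np.ndarray:
    """PCA + varimax of a given correlation matrix, with the deterministic
    column-order/sign convention.  Used for the alignment reference and as a
    population-truth oracle when the exact correlation matrix is known."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if not (1 <= k <= p):
        raise ValueError(f"k must be in [1, {p}]")
    lam, V = np.linalg.eigh(R)
    lam, V = lam[::-1], V[:, ::-1]
    gaps = np.abs(np.diff(lam[: min(k + 1, p)]))
    if gaps.size and gaps.min() < EIGEN_MULTIPLICITY_TOL:
        raise ValueError(
            "reference decomposition has (near-)repeated eigenvalues; rotation indeterminate"
        )
    L = V[:, :k] * np.sqrt(np.clip(lam[:k], 0, None))
    rotated, _, _ = varimax(L, kaiser=kaiser)
    return _order_and_sign(rotated)


def classical_pca_varimax(
    Z: np.ndarray, k: int, kaiser: bool = False
) -> np.ndarray:
    """Classical PCA of the sample correlation matrix, varimax-rotated.

    Serves both as the alignment reference and as the vague-prior large-n
    oracle for the Bayesian fit.  Loadings are eigenvector * sqrt(eigenvalue).
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    return pca_varimax_from_corr(np.corrcoef(Z, rowvar=False), k, kaiser=kaiser)


def align_draws(
    draws: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Align each rotated loading draw to a reference (sign + column permutation).

    For every draw the column permutation and per-column signs maximizing the
    total |correlation| between matched columns are chosen exhaustively
    (k! * 2^k options; exact for small k).  Returns the aligned draws and the
    (n_draws, k) integer array of source-column indices, so quantities
    ordered per component (e.g. variance explained) can be re-ordered
    identically.
    """
    draws = np.asarray(draws, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if draws.ndim != 3:
        raise ValueError("draws must be (n_draws, p, k)")
    m, p, k = draws.shape
    if reference.shape != (p, k):
        raise ValueError("reference shape mismatch")
    if k > 6:
        raise ValueError("exhaustive alignment supports k <= 6 only")
    if np.any(np.all(reference == 0, axis=0)):
        raise ValueError("reference columns must be nonzero")

    refc = reference - reference.mean(axis=0)
    ref_norm = np.linalg.norm(refc, axis=0)
    perms = list(itertools.permutations(range(k)))
    aligned = np.empty_like(draws)
    source = np.empty((m, k), dtype=int)
    for i in range(m):
        D = draws[i]
        Dc = D - D.mean(axis=0)
        dnorm = np.linalg.norm(Dc, axis=0)
        dnorm[dnorm == 0] = np.inf  # zero-variance column -> zero correlation
        C = (Dc.T @ refc) / np.outer(dnorm, ref_norm)
        best, best_perm = -np.inf, perms[0]
        for perm in perms:
            score = sum(abs(C[perm[j], j]) for j in range(k))
            if score > best:
                best, best_perm = score, perm
        for j in range(k):
            sgn = 1.0 if C[best_perm[j], j] >= 0 else -1.0
            aligned[i, :, j] = sgn * D[:, best_perm[j]]
            source[i, j] = best_perm[j]
    return aligned, source


@dataclass
class BPCAResult:
    """Posterior summaries of a varimax-rotated Bayesian PCA."""

    trait_names: tuple[str, ...]
    k: int
    loadings_median: np.ndarray
    loadings_ci50_low: np.ndarray
    loadings_ci50_high: np.ndarray
    loadings_ci95_low: np.ndarray
    loadings_ci95_high: np.ndarray
    varexp_median: np.ndarray
    varexp_ci_low: np.ndarray
    varexp_ci_high: np.ndarray
    scores: np.ndarray
    reference: np.ndarray
    n_draws: int
    n_populations: int
    rhat_varexp: np.ndarray
    varexp_draws_total: np.ndarray  # per-draw rotated k-subset totals (invariant check)
    unrotated_topk_total: np.ndarray  # per-draw top-k eigenvalue totals / p
    unrotated_total: np.ndarray  # per-draw sum over all p components (== 1)

    def loadings_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trait_names):
            for j in range(self.k):
                rows.append(
                    {
                        "trait": t,
                        "component": j + 1,
                        "median": self.loadings_median[i, j],
                        "ci50_low": self.loadings_ci50_low[i, j],
                        "ci50_high": self.loadings_ci50_high[i, j],
                        "ci95_low": self.loadings_ci95_low[i, j],
                        "ci95_high": self.loadings_ci95_high[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def varexp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.k + 1),
                "varexp_median": self.varexp_median,
                "varexp_ci_low": self.varexp_ci_low,
                "varexp_ci_high": self.varexp_ci_high,
                "rhat": self.rhat_varexp,
            }
        )

    def scores_frame(self, row_index) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=[f"PC{j+1}" for j in range(self.k)])
        df.insert(0, "stage", [r[2] for r in row_index])
        df.insert(0, "site_id", [r[1] for r in row_index])
        df.insert(0, "species_id", [r[0] for r in row_index])
        return df


def fit_bayes_pca(
    std: StandardizedMatrix,
    k: int,
    config: MCMCConfig,
    kaiser: bool = False,
) -> BPCAResult:
    """Bayesian PCA with varimax rotation on a complete-case standardized matrix.

    When rows from both stages are present the trait set must not include
    DA_pit (its seedling and adult measurements are not comparable, so it is
    excluded from combined-stage ordinations by contract).
    """
    Z = np.asarray(std.values, dtype=float)
    n, p = Z.shape
    if np.isnan(Z).any():
        raise ValueError("fit_bayes_pca requires complete cases (no missing cells)")
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    if not (1 <= k <= p):
        raise ValueError(f"k must be in [1, {p}]")
    stages = {r[2] for r in std.row_index}
    if len(stages) > 1 and "DA_pit" in std.trait_names:
        raise ValueError("combined-stage ordination must exclude DA_pit")

    reference = classical_pca_varimax(Z, k, kaiser=kaiser)
    cov_draws = sample_mvnormal_cov(Z, config, labels=std.trait_names)
    sigmas = cov_draws_as_matrices(cov_draws, p)
    m = sigmas.shape[0]

    # per-draw: correlation -> eigendecomposition -> loadings -> varimax
    d = 1.0 / np.sqrt(sigmas[:, np.arange(p), np.arange(p)])
    corr = sigmas * d[:, :, None] * d[:, None, :]
    rotated = np.empty((m, p, k))
    varexp_rot = np.empty((m, k))
    unrotated_topk = np.empty(m)
    unrotated_total = np.empty(m)
    for i in range(m):
        lam, V = np.linalg.eigh(corr[i])
        lam, V = lam[::-1], V[:, ::-1]
        unrotated_total[i] = float(np.sum(lam)) / p
        unrotated_topk[i] = float(np.sum(lam[:k])) / p
        L = V[:, :k] * np.sqrt(np.clip(lam[:k], 0, None))
        Lr, _, _ = varimax(L, kaiser=kaiser, max_iter=200)
        rotated[i] = Lr
        varexp_rot[i] = np.sum(Lr**2, axis=0) / p

    aligned, source = align_draws(rotated, reference)
    varexp_aligned = np.take_along_axis(varexp_rot, source, axis=1)

    med = np.median(aligned, axis=0)
    lo50, hi50 = np.quantile(aligned, [0.25, 0.75], axis=0)
    lo95, hi95 = np.quantile(aligned, [0.025, 0.975], axis=0)
    alpha = 1.0 - config.ci_level
    ve_med = np.median(varexp_aligned, axis=0)
    ve_lo, ve_hi = np.quantile(varexp_aligned, [alpha / 2, 1 - alpha / 2], axis=0)

    ve_chain = varexp_aligned.reshape(cov_draws.n_chains, cov_draws.n_kept, k)
    rhat = gelman_rubin(DrawMatrix(ve_chain, tuple(f"varexp[{j+1}]" for j in range(k))))

    scores = Z @ med @ np.linalg.inv(med.T @ med)
    return BPCAResult(
        trait_names=std.trait_names,
        k=k,
        loadings_median=med,
        loadings_ci50_low=lo50,
        loadings_ci50_high=hi50,
        loadings_ci95_low=lo95,
        loadings_ci95_high=hi95,
        varexp_median=ve_med,
        varexp_ci_low=ve_lo,
        varexp_ci_high=ve_hi,
        scores=scores,
        reference=reference,
        n_draws=m,
        n_populations=n,
        rhat_varexp=rhat,
        varexp_draws_total=np.sum(varexp_aligned, axis=1),
        unrotated_topk_total=unrotated_topk,
        unrotated_total=unrotated_total,
    )
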