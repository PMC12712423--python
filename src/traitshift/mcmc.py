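"""Conjugate Gibbs samplers and convergence diagnostics shared by all models.

The inference protocol mirrors the field-standard setup for this kind of
analysis: three Markov chains of 4000 iterations each, the first 1000
discarded as burn-in, vague priors throughout — Normal(0, 100^2) on location
parameters and regression coefficients, Uniform(0, 100) on residual SDs
(with a conjugate InvGamma(0.001, 0.001) alternative), and
Inverse-Wishart(I, d+1) on covariance matrices.  Convergence is monitored
with the classic Gelman-Rubin potential scale reduction factor at the
conventional 1.1 threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import invgamma, invwishart

RHAT_THRESHOLD = 1.1


@dataclass
class MCMCConfig:
    """Sampler settings; defaults follow the three-chain, 4000-iteration protocol."""

    n_chains: int = 3
    n_iterations: int = 4000
    n_burnin: int = 1000
    seed: int = 0
    prior_coef_sd: float = 100.0
    prior_sigma_upper: float = 100.0
    prior_wishart_df_offset: int = 1
    ci_level: float = 0.95
    sigma_prior: str = "uniform"  # "uniform" on sigma, or "invgamma" on sigma^2
    interval: str = "equal_tailed"  # or "hpd"

    def validate(self) -> None:
        if self.n_chains < 1 or self.n_iterations < 1 or self.n_burnin < 0:
            raise ValueError("chain counts and iteration counts must be positive")
        if self.n_burnin >= self.n_iterations:
            raise ValueError(
                f"n_burnin ({self.n_burnin}) must be < n_iterations ({self.n_iterations})"
            )
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.prior_coef_sd <= 0 or self.prior_sigma_upper <= 0:
            raise ValueError("prior scales must be positive")
        if self.sigma_prior not in ("uniform", "invgamma"):
            raise ValueError("sigma_prior must be 'uniform' or 'invgamma'")
        if self.interval not in ("equal_tailed", "hpd"):
            raise ValueError("interval must be 'equal_tailed' or 'hpd'")

    @property
    def n_kept(self) -> int:
        return self.n_iterations - self.n_burnin

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=int(seed))


@dataclass
class DrawMatrix:
    """Posterior draws with chain structure: (chains, kept iterations, parameters)."""

    draws: np.ndarray
    parameter_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, parameters)")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("parameter_names length must match draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """Pooled draws, chains stacked in order: (chains*iterations, parameters)."""
        c, t, p = self.draws.shape
        return self.draws.reshape(c * t, p)

    def parameter(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.parameter_names.index(name)]

    def subset(self, names: Sequence[str]) -> "DrawMatrix":
        idx = [self.parameter_names.index(n) for n in names]
        return DrawMatrix(self.draws[:, :, idx].copy(), tuple(names))

    def to_tsv(self, path: str | Path) -> None:
        c, t, p = self.draws.shape
        chain = np.repeat(np.arange(1, c + 1), t * p)
        iteration = np.tile(np.repeat(np.arange(1, t + 1), p), c)
        param = np.tile(np.array(self.parameter_names, dtype=object), c * t)
        pd.DataFrame(
            {"chain": chain, "iteration": iteration, "parameter": param,
             "value": self.draws.ravel()}
        ).to_csv(Path(path), sep="\t", index=False)


@dataclass
class PosteriorSummary:
    """Parameter summary: central tendency, CI, R-hat, significance flag."""

    name: str
    mean: float
    median: float
    ci_low: float
    ci_high: float
    rhat: float
    n_draws: int
    significant: bool

    def as_dict(self) -> dict[str, object]:
        return {
            "parameter": self.name,
            "mean": self.mean,
            "median": self.median,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "rhat": self.rhat,
            "n_draws": self.n_draws,
            "significant": self.significant,
        }


def _chain_rngs(seed: int, n_chains: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(int(seed)).spawn(n_chains)]


def _draw_sigma2(rng: np.random.Generator, n_eff: float, ss: float, config: MCMCConfig) -> float:
    """One draw of the residual variance given the current sum of squares.

    Uniform(0, upper) prior on sigma gives sigma^2 | . ~ InvGamma((n-1)/2, SS/2)
    truncated at upper^2 (sampled by rejection; the truncation essentially
    never binds for vague settings, with an inverse-CDF fallback).  The
    conjugate alternative is InvGamma(0.001 + n/2, 0.001 + SS/2).
    """
    ss = max(ss, 1e-300)
    if config.sigma_prior == "invgamma":
        shape = 0.001 + n_eff / 2.0
        scale = 0.001 + ss / 2.0
        return scale / rng.gamma(shape)
    shape = (n_eff - 1.0) / 2.0
    scale = ss / 2.0
    upper2 = config.prior_sigma_upper**2
    for _ in range(100):
        v = scale / rng.gamma(shape)
        if v <= upper2:
            return v
    u = rng.uniform(0.0, invgamma.cdf(upper2, shape, scale=scale))
    return float(invgamma.ppf(max(u, 1e-300), shape, scale=scale))


def sample_normal_mean(y: np.ndarray, config: MCMCConfig) -> DrawMatrix:
    """Gibbs sampler for the mean/SD of a normal sample: parameters (mu, sigma).

    Chains are initialized overdispersed around the closed-form estimate.  The
    chain is run on sign-canonicalized data (s*y with s = sign of the sample
    sum) and location draws are mapped back by s, which makes the sampler
    exactly equivariant under negation of the data; this is valid because the
    location prior is symmetric about zero.
    """
    config.validate()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y) == 0 and n < 3:
        raise ValueError("constant y with n < 3: sigma is unidentifiable")
    s = 1.0 if y.sum() >= 0 else -1.0
    ys = s * y
    ybar = ys.mean()
    ssy = float(((ys - ybar) ** 2).sum())
    sd0 = math.sqrt(ssy / (n - 1)) if ssy > 0 else 1e-6
    se = sd0 / math.sqrt(n)
    tau0 = 1.0 / config.prior_coef_sd**2

    C, kept = config.n_chains, config.n_kept
    out = np.empty((C, kept, 2))
    for c, rng in enumerate(_chain_rngs(config.seed, C)):
        mu = ybar + (c - (C - 1) / 2.0) * 2.0 * se
        sigma2 = sd0**2
        for t in range(config.n_iterations):
            ss = ssy + n * (ybar - mu) ** 2
            sigma2 = _draw_sigma2(rng, n, ss, config)
            prec = n / sigma2 + tau0
            m = (n * ybar / sigma2) / prec
            mu = m + math.sqrt(1.0 / prec) * rng.standard_normal()
            if t >= config.n_burnin:
                out[c, t - config.n_burnin, 0] = s * mu
                out[c, t - config.n_burnin, 1] = math.sqrt(sigma2)
    return DrawMatrix(out, ("mu", "sigma"))


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[j] for j in range(X.shape[1]) if diag[j] <= tol]


def sample_linear_model(
    X: np.ndarray,
    y: np.ndarray,
    config: MCMCConfig,
    coef_names: Sequence[str] | None = None,
) -> DrawMatrix:
    """Gibbs sampler for a normal linear model: coefficients + residual sigma.

    Coefficient prior Normal(0, prior_coef_sd^2 I).  Same sign
    canonicalization as :func:`sample_normal_mean` (run on s*y, coefficients
    mapped back by s), so negating the response negates every coefficient
    draw exactly.
    """
    config.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError("X and y have incompatible shapes")
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    if coef_names is None:
        coef_names = tuple(f"b{j}" for j in range(p))
    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_columns(X, list(coef_names))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    s = 1.0 if y.sum() >= 0 else -1.0
    ys = s * y
    XtX = X.T @ X
    Xty = X.T @ ys
    yty = float(ys @ ys)
    beta_hat, *_ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ beta_hat
    dof = max(n - p, 1)
    sigma2_hat = max(float(resid @ resid) / dof, 1e-12)
    XtX_inv = np.linalg.inv(XtX)
    se_hat = np.sqrt(sigma2_hat * np.diag(XtX_inv))
    tau0 = 1.0 / config.prior_coef_sd**2
    eye = np.eye(p)

    C, kept = config.n_chains, config.n_kept
    out = np.empty((C, kept, p + 1))
    for c, rng in enumerate(_chain_rngs(config.seed, C)):
        offset = (c - (C - 1) / 2.0) * 2.0
        beta = beta_hat + offset * se_hat
        sigma2 = sigma2_hat
        for t in range(config.n_iterations):
            ss = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
            sigma2 = _draw_sigma2(rng, n, max(ss, 0.0), config)
            A = XtX / sigma2 + tau0 * eye
            L = np.linalg.cholesky(A)
            m = np.linalg.solve(A, Xty / sigma2)
            z = rng.standard_normal(p)
            beta = m + np.linalg.solve(L.T, z)
            if t >= config.n_burnin:
                out[c, t - config.n_burnin, :p] = s * beta
                out[c, t - config.n_burnin, p] = math.sqrt(sigma2)
    return DrawMatrix(out, tuple(coef_names) + ("sigma",))


def mvnormal_param_names(d: int, labels: Sequence[str] | None = None) -> tuple[str, ...]:
    if labels is None:
        labels = [str(i) for i in range(d)]
    names = [f"mu[{labels[i]}]" for i in range(d)]
    names += [f"Sigma[{labels[i]},{labels[j]}]" for i in range(d) for j in range(i, d)]
    return tuple(names)


def sample_mvnormal_cov(
    Y: np.ndarray, config: MCMCConfig, labels: Sequence[str] | None = None
) -> DrawMatrix:
    """Gibbs sampler for a multivariate-normal mean and covariance matrix.

    Flat prior on the mean vector; Inverse-Wishart(Psi0 = I, nu0 = d + offset)
    on the covariance.  Alternates mu | Sigma ~ Normal(ybar, Sigma/n) and
    Sigma | mu ~ InvWishart(Psi0 + S_mu, nu0 + n).  Every draw of Sigma is
    symmetric positive definite by construction.  Parameters are the mean
    entries followed by the upper triangle of Sigma.
    """
    config.validate()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D array")
    n, d = Y.shape
    if d < 2:
        raise ValueError("need at least 2 variables")
    if n <= d:
        raise ValueError(f"need n > d (got n={n}, d={d})")
    if np.isnan(Y).any():
        raise ValueError("Y must have no missing cells")

    ybar = Y.mean(axis=0)
    S_bar = (Y - ybar).T @ (Y - ybar)
    S_hat = S_bar / (n - 1)
    psi0 = np.eye(d)
    nu0 = d + config.prior_wishart_df_offset
    iu = np.triu_indices(d)
    names = mvnormal_param_names(d, labels)

    C, kept = config.n_chains, config.n_kept
    out = np.empty((C, kept, d + iu[0].size))
    for c, rng in enumerate(_chain_rngs(config.seed, C)):
        # overdispersed start: scale the sample covariance up/down per chain
        sigma = S_hat * math.exp(0.6 * (c - (C - 1) / 2.0))
        for t in range(config.n_iterations):
            L = np.linalg.cholesky(sigma / n)
            mu = ybar + L @ rng.standard_normal(d)
            dev = ybar - mu
            S_mu = S_bar + n * np.outer(dev, dev)
            sigma = invwishart.rvs(df=nu0 + n, scale=psi0 + S_mu, random_state=rng)
            if t >= config.n_burnin:
                out[c, t - config.n_burnin, :d] = mu
                out[c, t - config.n_burnin, d:] = sigma[iu]
    return DrawMatrix(out, names)


def cov_draws_as_matrices(draws: DrawMatrix, d: int) -> np.ndarray:
    """Rebuild (n_draws, d, d) symmetric covariance matrices from a DrawMatrix."""
    flat = draws.flat()[:, d:]
    iu = np.triu_indices(d)
    out = np.zeros((flat.shape[0], d, d))
    out[:, iu[0], iu[1]] = flat
    out = out + np.transpose(out, (0, 2, 1))
    out[:, np.arange(d), np.arange(d)] /= 2.0
    return out


def gelman_rubin(draws: DrawMatrix) -> np.ndarray:
    """Classic potential-scale-reduction factor, one value per parameter.

    R-hat = sqrt((n-1)/n + B/(n W)) with B the between-chain and W the
    within-chain variance.  A parameter with zero within-chain variance is
    reported as +inf.
    """
    x = draws.draws
    c, t, p = x.shape
    if c < 2:
        raise ValueError("need at least 2 chains")
    if t < 2:
        raise ValueError("need at least 2 kept iterations")
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = t * chain_means.var(axis=0, ddof=1)
    out = np.empty(p)
    for j in range(p):
        if W[j] == 0:
            out[j] = math.inf if B[j] > 0 else 1.0
        else:
            out[j] = math.sqrt((t - 1) / t + B[j] / (t * W[j]))
    return out


def _hpd_interval(x: np.ndarray, level: float) -> tuple[float, float]:
    x = np.sort(x)
    m = max(int(math.ceil(level * x.size)), 2)
    widths = x[m - 1 :] - x[: x.size - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize(
    draws: DrawMatrix, ci_level: float = 0.95, interval: str = "equal_tailed"
) -> list[PosteriorSummary]:
    """Summarize each parameter: mean, median, CI, R-hat, significance.

    The CI is the equal-tailed posterior interval at ``ci_level`` (HPD
    optionally); an effect is flagged significant when its CI excludes zero.
    """
    if not np.isfinite(draws.draws).all():
        raise ValueError("draws must be finite")
    flat = draws.flat()
    rhats = gelman_rubin(draws) if draws.n_chains >= 2 and draws.n_kept >= 2 else np.full(
        flat.shape[1], np.nan
    )
    alpha = 1.0 - ci_level
    out = []
    for j, name in enumerate(draws.parameter_names):
        col = flat[:, j]
        if interval == "hpd":
            lo, hi = _hpd_interval(col, ci_level)
        else:
            lo, hi = np.quantile(col, [alpha / 2.0, 1.0 - alpha / 2.0])
        out.append(
            PosteriorSummary(
                name=name,
                mean=float(col.mean()),
                median=float(np.median(col)),
                ci_low=float(lo),
                ci_high=float(hi),
                rhat=float(rhats[j]),
                n_draws=col.size,
                significant=bool(lo > 0 or hi < 0),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[PosteriorSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
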