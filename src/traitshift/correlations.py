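"""Posterior trait-pair correlations per stage and stage regression contrasts.

Each trait pair within a stage is modeled as draws from a bivariate normal
distribution; the correlation coefficient is derived from each posterior
draw of the covariance matrix.  Where a pair's correlation is similar
between stages, simple linear regressions are fitted per stage and the
posterior distributions of intercepts and slopes are contrasted by pairing
the independent per-stage draws in iteration order (any fixed pairing of
independent draws is a draw from the difference distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import (
    DrawMatrix,
    MCMCConfig,
    PosteriorSummary,
    cov_draws_as_matrices,
    sample_linear_model,
    sample_mvnormal_cov,
    summarize,
)

logger = logging.getLogger(__name__)

#: trait pairs examined by the default pipeline (dependent-variable choice is
#: made per pair from the overall shift magnitudes)
CANONICAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("DA_pit", "d_h"),
    ("DA_pit", "VD"),
    ("VD", "d_h"),
    ("LDMC", "SLA"),
)

#: stage correlations are deemed "similar" (triggering the regression
#: comparison) when |rho_adult - rho_seedling| is at most this value
SIMILARITY_THRESHOLD = 0.2


@dataclass
class CorrelationResult:
    """Posterior correlation between two traits within one stage."""

    trait_x: str
    trait_y: str
    stage: str
    rho: PosteriorSummary
    n: int

    def as_dict(self) -> dict[str, object]:
        d = self.rho.as_dict()
        d.update(trait_x=self.trait_x, trait_y=self.trait_y, stage=self.stage, n=self.n)
        return d


def _complete_pairs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def fit_correlation(
    x: np.ndarray,
    y: np.ndarray,
    config: MCMCConfig,
    trait_x: str = "x",
    trait_y: str = "y",
    stage: str = "",
) -> CorrelationResult:
    """Posterior of the correlation between two standardized trait vectors.

    The two variables are ordered by trait name internally before sampling,
    which makes the result exactly symmetric in its arguments (the
    correlation itself is symmetric; the covariance sampler's Cholesky
    factorization is not permutation-equivariant).
    """
    x, y = _complete_pairs(x, y)
    if x.size < 4:
        raise ValueError(f"need >= 4 complete pairs, got {x.size}")
    if trait_y < trait_x:
        x, y = y, x  # canonical order; rho is symmetric
    Y = np.column_stack([x, y])
    draws = sample_mvnormal_cov(Y, config)
    sigmas = cov_draws_as_matrices(draws, 2)
    rho = sigmas[:, 0, 1] / np.sqrt(sigmas[:, 0, 0] * sigmas[:, 1, 1])
    rho_chain = rho.reshape(draws.n_chains, draws.n_kept, 1)
    summ = summarize(DrawMatrix(rho_chain, ("rho",)), config.ci_level, config.interval)[0]
    return CorrelationResult(trait_x=trait_x, trait_y=trait_y, stage=stage, rho=summ, n=x.size)


def choose_dependent_variable(
    pair: tuple[str, str], shift_results: dict[str, "object"]
) -> str:
    """Dependent variable = the trait with the larger absolute overall shift.

    Ties break lexicographically (logged).  ``shift_results`` maps trait name
    to a fitted overall :class:`~traitshift.shifts.ShiftModelResult`.
    """
    a, b = pair
    for t in pair:
        if t not in shift_results or getattr(shift_results[t], "overall", None) is None:
            raise ValueError(f"missing overall shift fit for trait {t}")
    mag_a = abs(shift_results[a].overall.mean)
    mag_b = abs(shift_results[b].overall.mean)
    if mag_a == mag_b:
        winner = min(a, b)
        logger.info(
            "equal shift magnitudes for %s and %s; dependent variable chosen lexicographically: %s",
            a, b, winner,
        )
        return winner
    return a if mag_a > mag_b else b


@dataclass
class StageRegressionContrast:
    """Per-stage simple-regression posteriors and their stage differences."""

    dependent: str
    independent: str
    intercept_seedling: PosteriorSummary
    slope_seedling: PosteriorSummary
    intercept_adult: PosteriorSummary
    slope_adult: PosteriorSummary
    intercept_diff: PosteriorSummary  # seedling - adult
    slope_diff: PosteriorSummary  # seedling - adult
    n_seedling: int
    n_adult: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in (
            self.intercept_seedling,
            self.slope_seedling,
            self.intercept_adult,
            self.slope_adult,
            self.intercept_diff,
            self.slope_diff,
        ):
            rows.append(
                dict(dependent=self.dependent, independent=self.independent, **s.as_dict())
            )
        return pd.DataFrame(rows)


def _simple_regression(
    x: np.ndarray, y: np.ndarray, config: MCMCConfig, tag: str
) -> DrawMatrix:
    X = np.column_stack([np.ones_like(x), x])
    return sample_linear_model(
        X, y, config, coef_names=(f"alpha_{tag}", f"beta_{tag}")
    )


def compare_stage_regressions(
    seedling_xy: tuple[np.ndarray, np.ndarray],
    adult_xy: tuple[np.ndarray, np.ndarray],
    config: MCMCConfig,
    dependent: str = "y",
    independent: str = "x",
) -> StageRegressionContrast:
    """Fit y ~ x independently per stage and contrast intercepts and slopes.

    Both stages must use the same (pooled) standardization so intercept
    differences are meaningful.  Difference draws are the elementwise
    differences of the two independent fits, matched by draw index; the two
    fits must therefore use identical chain/iteration settings.
    """
    xs, ys = _complete_pairs(*seedling_xy)
    xa, ya = _complete_pairs(*adult_xy)
    if xs.size < 4 or xa.size < 4:
        raise ValueError("each stage needs >= 4 complete pairs")
    draws_s = _simple_regression(xs, ys, config.with_seed(config.seed * 2 + 1), "seedling")
    draws_a = _simple_regression(xa, ya, config.with_seed(config.seed * 2 + 2), "adult")
    if draws_s.draws.shape[:2] != draws_a.draws.shape[:2]:
        raise ValueError("stage fits have mismatched draw counts; configs must match")

    summ_s = {s.name: s for s in summarize(draws_s, config.ci_level, config.interval)}
    summ_a = {s.name: s for s in summarize(draws_a, config.ci_level, config.interval)}

    diff = np.stack(
        [
            draws_s.parameter("alpha_seedling") - draws_a.parameter("alpha_adult"),
            draws_s.parameter("beta_seedling") - draws_a.parameter("beta_adult"),
        ],
        axis=-1,
    )
    diff_summ = summarize(
        DrawMatrix(diff, ("alpha_seedling-alpha_adult", "beta_seedling-beta_adult")),
        config.ci_level,
        config.interval,
    )
    return StageRegressionContrast(
        dependent=dependent,
        independent=independent,
        intercept_seedling=summ_s["alpha_seedling"],
        slope_seedling=summ_s["beta_seedling"],
        intercept_adult=summ_a["alpha_adult"],
        slope_adult=summ_a["beta_adult"],
        intercept_diff=diff_summ[0],
        slope_diff=diff_summ[1],
        n_seedling=xs.size,
        n_adult=xa.size,
    )


def correlations_similar(
    rho_seedling: CorrelationResult,
    rho_adult: CorrelationResult,
    threshold: float = SIMILARITY_THRESHOLD,
) -> bool:
    """Numeric trigger for the stage regression comparison."""
    return abs(rho_adult.rho.mean - rho_seedling.rho.mean) <= threshold
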