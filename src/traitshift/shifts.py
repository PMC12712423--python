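"""Ontogenetic trait-shift models: overall, per-site, and site + covariates.

Three nested models are fitted per trait to the paired adult-minus-seedling
standardized differences Delta_i ~ Normal(mu_i, sigma^2):

* overall: mu_i = mu (a single mean shift);
* site:    mu_i = alpha_k for the site k of population i (cell-means coding,
  no global intercept, so site intercepts and their pairwise contrasts are
  direct);
* full:    mu_i = alpha_k + beta1 * deciduous_i + beta2 * liana_i, with the
  evergreen free-standing class absorbed into the site intercepts.

A shared residual sigma is used within each model by default; the site model
can optionally fit an independent sigma per site.  Pairwise site contrasts
are summarized from the posterior
draws of alpha_j - alpha_k, and a compact letter display is built so that
two sites share a letter iff their shift difference is not significant.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ShiftDataset
from .mcmc import (
    DrawMatrix,
    MCMCConfig,
    PosteriorSummary,
    sample_linear_model,
    sample_normal_mean,
    summarize,
)

logger = logging.getLogger(__name__)

MODEL_VARIANTS = ("overall", "site", "site+phenology+growthform")


@dataclass
class ShiftModelResult:
    """Fitted shift model for one trait."""

    trait: str
    variant: str
    n_populations: int
    draws: DrawMatrix
    overall: PosteriorSummary | None = None
    alpha: dict[int, PosteriorSummary] = field(default_factory=dict)
    beta_deciduous: PosteriorSummary | None = None
    beta_liana: PosteriorSummary | None = None
    pairwise: dict[tuple[int, int], PosteriorSummary] = field(default_factory=dict)
    letters: dict[int, str] = field(default_factory=dict)
    dropped_terms: list[str] = field(default_factory=list)

    def summaries(self) -> list[PosteriorSummary]:
        out = []
        if self.overall is not None:
            out.append(self.overall)
        out.extend(self.alpha.values())
        if self.beta_deciduous is not None:
            out.append(self.beta_deciduous)
        if self.beta_liana is not None:
            out.append(self.beta_liana)
        out.extend(self.pairwise.values())
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(trait=self.trait, model=self.variant, n=self.n_populations, **s.as_dict())
            for s in self.summaries()
        ]
        return pd.DataFrame(rows)


def fit_overall_shift(data: ShiftDataset, config: MCMCConfig) -> ShiftModelResult:
    """Posterior for the single mean shift of one trait."""
    if data.n < 3:
        raise ValueError(f"need >= 3 paired populations, got {data.n}")
    draws = sample_normal_mean(data.delta, config)
    named = DrawMatrix(draws.draws, ("shift", "sigma"))
    summ = {s.name: s for s in summarize(named, config.ci_level, config.interval)}
    return ShiftModelResult(
        trait=data.trait,
        variant="overall",
        n_populations=data.n,
        draws=named,
        overall=summ["shift"],
    )


def _site_design(data: ShiftDataset) -> tuple[np.ndarray, list[int]]:
    sites = sorted(set(int(s) for s in data.site))
    X = np.column_stack([(data.site == s).astype(float) for s in sites])
    return X, sites


def _warn_small_sites(data: ShiftDataset, sites: Sequence[int]) -> None:
    for s in sites:
        count = int((data.site == s).sum())
        if count < 2:
            msg = f"site {s} has a single population for trait {data.trait}; retained (sigma is pooled)"
            warnings.warn(msg)
            logger.warning(msg)


def _finish_site_model(
    data: ShiftDataset,
    variant: str,
    draws: DrawMatrix,
    sites: Sequence[int],
    config: MCMCConfig,
    dropped: list[str],
) -> ShiftModelResult:
    summ = {s.name: s for s in summarize(draws, config.ci_level, config.interval)}
    alpha = {s: summ[f"alpha[{s}]"] for s in sites}
    pairwise = pairwise_site_contrasts(draws, config)
    sig = {pair: s.significant for pair, s in pairwise.items()}
    letters = significance_letters(list(sites), sig)
    return ShiftModelResult(
        trait=data.trait,
        variant=variant,
        n_populations=data.n,
        draws=draws,
        alpha=alpha,
        beta_deciduous=summ.get("beta_deciduous"),
        beta_liana=summ.get("beta_liana"),
        pairwise=pairwise,
        letters=letters,
        dropped_terms=dropped,
    )


def fit_site_shift(
    data: ShiftDataset, config: MCMCConfig, per_site_sigma: bool = False
) -> ShiftModelResult:
    """Per-site mean shifts (cell-means coding); sites absent from the data
    are simply absent from the result, not reported as zero.

    With ``per_site_sigma`` each site gets its own normal-mean fit (its own
    residual sigma); contrasts pair the independent per-site draws by index.
    """
    X, sites = _site_design(data)
    _warn_small_sites(data, sites)
    names = [f"alpha[{s}]" for s in sites]
    if per_site_sigma:
        blocks, block_names = [], []
        for i, s in enumerate(sites):
            sub = data.delta[data.site == s]
            if sub.size < 2:
                raise ValueError(f"per-site sigma needs >= 2 populations in site {s}")
            d = sample_normal_mean(sub, config.with_seed(config.seed * 1000 + i))
            blocks.append(d.draws)
            block_names += [f"alpha[{s}]", f"sigma[{s}]"]
        draws = DrawMatrix(np.concatenate(blocks, axis=2), tuple(block_names))
    else:
        draws = sample_linear_model(X, data.delta, config, coef_names=names)
    return _finish_site_model(data, "site", draws, sites, config, [])


def fit_full_shift(data: ShiftDataset, config: MCMCConfig) -> ShiftModelResult:
    """Site intercepts plus phenology and growth-form effects.

    An indicator column that is constant in the data (e.g. no lianas among
    the paired populations) makes that coefficient unidentifiable; it is
    dropped with a logged warning rather than erroring, so the same model
    runs across per-trait subsets.
    """
    X, sites = _site_design(data)
    _warn_small_sites(data, sites)
    names = [f"alpha[{s}]" for s in sites]
    dropped: list[str] = []
    for col, name in ((data.deciduous, "beta_deciduous"), (data.liana, "beta_liana")):
        if np.ptp(col) == 0:
            dropped.append(name)
            msg = f"indicator {name} is constant for trait {data.trait}; coefficient dropped"
            warnings.warn(msg)
            logger.warning(msg)
        else:
            X = np.column_stack([X, col.astype(float)])
            names.append(name)
    draws = sample_linear_model(X, data.delta, config, coef_names=names)
    return _finish_site_model(
        data, "site+phenology+growthform", draws, sites, config, dropped
    )


def pairwise_site_contrasts(
    draws: DrawMatrix, config: MCMCConfig | None = None
) -> dict[tuple[int, int], PosteriorSummary]:
    """Posterior summaries of alpha_j - alpha_k for every pair of site intercepts."""
    site_params = [n for n in draws.parameter_names if n.startswith("alpha[")]
    if len(site_params) < 2:
        return {}
    ci = config.ci_level if config is not None else 0.95
    interval = config.interval if config is not None else "equal_tailed"
    sites = [int(n[len("alpha["):-1]) for n in site_params]
    out: dict[tuple[int, int], PosteriorSummary] = {}
    diffs, names, pairs = [], [], []
    for (j, nj), (k, nk) in itertools.combinations(zip(sites, site_params), 2):
        diffs.append(draws.parameter(nj) - draws.parameter(nk))
        names.append(f"alpha[{j}]-alpha[{k}]")
        pairs.append((j, k))
    diff_draws = DrawMatrix(np.stack(diffs, axis=-1), tuple(names))
    for pair, summ in zip(pairs, summarize(diff_draws, ci, interval)):
        out[pair] = summ
    return out


def _maximal_cliques(nodes: Sequence[int], adjacent: set[frozenset[int]]) -> list[tuple[int, ...]]:
    """Maximal cliques of the 'not significantly different' graph, by brute
    force over subsets (the site scale makes this exact and cheap)."""
    nodes = list(nodes)
    cliques = []
    for r in range(len(nodes), 0, -1):
        for subset in itertools.combinations(nodes, r):
            if all(frozenset(p) in adjacent for p in itertools.combinations(subset, 2)):
                if not any(set(subset) <= set(c) for c in cliques):
                    cliques.append(subset)
    return cliques


def significance_letters(
    sites: Sequence[int], significant: Mapping[tuple[int, int], bool]
) -> dict[int, str]:
    """Compact letter display: two sites share a letter iff not significantly
    different.  Letters are assigned to maximal cliques of the
    not-significantly-different graph, ordered by their lowest-numbered site.
    """
    sites = sorted(int(s) for s in sites)
    sig = {frozenset(k): bool(v) for k, v in significant.items()}
    for pair in itertools.combinations(sites, 2):
        if frozenset(pair) not in sig:
            raise ValueError(f"missing significance entry for site pair {pair}")
    adjacent = {
        frozenset(p) for p in itertools.combinations(sites, 2) if not sig[frozenset(p)]
    }
    cliques = _maximal_cliques(sites, adjacent)
    cliques.sort(key=lambda c: (min(c), c))
    letters: dict[int, list[str]] = {s: [] for s in sites}
    for i, clique in enumerate(cliques):
        label = chr(ord("a") + i)
        for s in clique:
            letters[s].append(label)
    return {s: "".join(sorted(v)) for s, v in letters.items()}


def fit_all_variants(
    data: ShiftDataset, config: MCMCConfig
) -> dict[str, ShiftModelResult]:
    """Fit the three nested models on one trait's shift data."""
    return {
        "overall": fit_overall_shift(data, config),
        "site": fit_site_shift(data, config),
        "site+phenology+growthform": fit_full_shift(data, config),
    }
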