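"""Shift models: recovery, nesting, contrasts, compact letter display."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitshift import (
    DrawMatrix,
    fit_full_shift,
    fit_overall_shift,
    fit_site_shift,
    pairwise_site_contrasts,
    significance_letters,
)
from traitshift.data import ShiftDataset
from traitshift.shifts import fit_all_variants


def make_shift_data(
    delta, site=None, deciduous=None, liana=None, trait="SLA"
) -> ShiftDataset:
    delta = np.asarray(delta, dtype=float)
    n = delta.size
    site = np.asarray(site if site is not None else np.ones(n), dtype=int)
    return ShiftDataset(
        trait=trait,
        population_index=[(f"sp{i}", int(site[i])) for i in range(n)],
        delta=delta,
        site=site,
        deciduous=np.asarray(deciduous if deciduous is not None else np.zeros(n), dtype=int),
        liana=np.asarray(liana if liana is not None else np.zeros(n), dtype=int),
    )


class TestOverallShift:
    def test_recovers_true_shift(self, fast_mcmc):
        rng = np.random.default_rng(21)
        data = make_shift_data(rng.normal(1.0, 0.5, 40))
        res = fit_overall_shift(data, fast_mcmc)
        assert res.overall.ci_low <= 1.0 <= res.overall.ci_high
        assert res.n_populations == 40

    def test_requires_three_pairs(self, fast_mcmc):
        with pytest.raises(ValueError, match=">= 3"):
            fit_overall_shift(make_shift_data([0.1, 0.2]), fast_mcmc)

    def test_negating_deltas_negates_location_summaries_exactly(self, fast_mcmc):
        rng = np.random.default_rng(22)
        delta = rng.normal(0.5, 0.4, 30)
        site = rng.integers(1, 5, 30)
        dec = rng.integers(0, 2, 30)
        li = rng.integers(0, 2, 30)
        for fit in (fit_overall_shift, fit_site_shift, fit_full_shift):
            r1 = fit(make_shift_data(delta, site, dec, li), fast_mcmc)
            r2 = fit(make_shift_data(-delta, site, dec, li), fast_mcmc)
            for s1, s2 in zip(r1.summaries(), r2.summaries()):
                assert s2.mean == -s1.mean
                assert s2.median == -s1.median
                # CI bounds: draws negate exactly; quantile interpolation
                # arithmetic is only sign-symmetric to rounding
                assert abs(s2.ci_low - (-s1.ci_high)) < 1e-12
                assert abs(s2.ci_high - (-s1.ci_low)) < 1e-12


class TestSiteShift:
    def test_recovers_per_site_intercepts(self, fast_mcmc):
        rng = np.random.default_rng(23)
        alpha = {1: -1.0, 2: -0.5, 3: 0.5, 4: 1.0}
        site = np.repeat([1, 2, 3, 4], 15)
        delta = np.array([alpha[s] for s in site]) + rng.normal(0, 0.3, site.size)
        res = fit_site_shift(make_shift_data(delta, site), fast_mcmc)
        for s, true in alpha.items():
            assert res.alpha[s].ci_low <= true <= res.alpha[s].ci_high

    def test_single_site_nests_overall_model(self, fast_mcmc):
        rng = np.random.default_rng(24)
        delta = rng.normal(0.8, 0.5, 25)
        res_site = fit_site_shift(make_shift_data(delta, np.ones(25)), fast_mcmc)
        res_overall = fit_overall_shift(make_shift_data(delta), fast_mcmc)
        mc_se = 3 * 0.5 / np.sqrt(25)
        assert abs(res_site.alpha[1].mean - res_overall.overall.mean) < mc_se
        assert list(res_site.alpha) == [1]  # absent sites are absent, not zero

    def test_site_relabeling_permutes_summaries(self, fast_mcmc):
        rng = np.random.default_rng(25)
        site = np.repeat([1, 2], 20)
        delta = np.where(site == 1, -0.5, 0.7) + rng.normal(0, 0.2, 40)
        res = fit_site_shift(make_shift_data(delta, site), fast_mcmc)
        relabeled = np.where(site == 1, 2, 1)
        res2 = fit_site_shift(make_shift_data(delta, relabeled), fast_mcmc)
        assert abs(res.alpha[1].mean - res2.alpha[2].mean) < 0.05
        assert abs(res.alpha[2].mean - res2.alpha[1].mean) < 0.05

    def test_singleton_site_warns_but_is_retained(self, fast_mcmc):
        site = np.array([1] * 10 + [2])
        delta = np.concatenate([np.random.default_rng(26).normal(0, 0.3, 10), [0.5]])
        with pytest.warns(UserWarning, match="single population"):
            res = fit_site_shift(make_shift_data(delta, site), fast_mcmc)
        assert 2 in res.alpha

    def test_per_site_sigma_option(self, fast_mcmc):
        rng = np.random.default_rng(27)
        site = np.repeat([1, 2], 25)
        delta = np.where(site == 1, 0.0, 1.0) + rng.normal(0, 0.3, 50)
        res = fit_site_shift(make_shift_data(delta, site), fast_mcmc, per_site_sigma=True)
        assert res.alpha[1].ci_low <= 0.0 <= res.alpha[1].ci_high
        assert res.alpha[2].ci_low <= 1.0 <= res.alpha[2].ci_high


class TestFullShift:
    def test_recovers_covariate_effects(self, fast_mcmc):
        rng = np.random.default_rng(28)
        n = 120
        site = rng.integers(1, 5, n)
        dec = rng.integers(0, 2, n)
        li = rng.integers(0, 2, n)
        delta = 0.3 - 0.7 * dec + 0.6 * li + rng.normal(0, 0.4, n)
        res = fit_full_shift(make_shift_data(delta, site, dec, li), fast_mcmc)
        assert res.beta_deciduous.ci_low <= -0.7 <= res.beta_deciduous.ci_high
        assert res.beta_liana.ci_low <= 0.6 <= res.beta_liana.ci_high

    def test_constant_indicator_dropped_and_nests_site_model(self, fast_mcmc):
        rng = np.random.default_rng(29)
        site = np.repeat([1, 2, 3, 4], 10)
        delta = rng.normal(0.2, 0.4, 40)
        data = make_shift_data(delta, site)  # all evergreen free-standing
        with pytest.warns(UserWarning, match="constant"):
            res_full = fit_full_shift(data, fast_mcmc)
        assert res_full.dropped_terms == ["beta_deciduous", "beta_liana"]
        assert res_full.beta_deciduous is None
        res_site = fit_site_shift(data, fast_mcmc)
        for s in (1, 2, 3, 4):
            assert abs(res_full.alpha[s].mean - res_site.alpha[s].mean) < 3 * 0.4 / np.sqrt(10)


class TestPairwiseContrasts:
    def _alpha_draws(self, a1, a2, a3=None, a4=None):
        cols = [c for c in (a1, a2, a3, a4) if c is not None]
        arr = np.stack([np.asarray(c, dtype=float) for c in cols], axis=-1)
        arr = arr.reshape(2, -1, len(cols))
        names = tuple(f"alpha[{i+1}]" for i in range(len(cols)))
        return DrawMatrix(arr, names)

    def test_identical_draws_give_zero_nonsignificant_difference(self):
        base = np.random.default_rng(30).normal(0, 1, 100)
        d = self._alpha_draws(base, base)
        summ = pairwise_site_contrasts(d)[(1, 2)]
        assert summ.mean == 0.0 and not summ.significant

    def test_constant_offset_is_exact(self):
        base = np.random.default_rng(31).normal(0, 1, 100)
        summ = pairwise_site_contrasts(self._alpha_draws(base + 2.0, base))[(1, 2)]
        assert abs(summ.mean - 2.0) < 1e-12

    def test_constructed_pattern_yields_expected_significant_pairs(self):
        rng = np.random.default_rng(32)
        a = [rng.normal(m, 0.01, 200) for m in (0.0, 0.0, 1.0, 1.0)]
        pairwise = pairwise_site_contrasts(self._alpha_draws(*a))
        sig = {pair: s.significant for pair, s in pairwise.items()}
        assert sig == {
            (1, 2): False, (1, 3): True, (1, 4): True,
            (2, 3): True, (2, 4): True, (3, 4): False,
        }


class TestSignificanceLetters:
    def test_no_significant_pairs_single_letter(self):
        sig = {p: False for p in itertools.combinations((1, 2, 3, 4), 2)}
        assert significance_letters([1, 2, 3, 4], sig) == {1: "a", 2: "a", 3: "a", 4: "a"}

    def test_all_significant_distinct_letters(self):
        sig = {p: True for p in itertools.combinations((1, 2, 3, 4), 2)}
        letters = significance_letters([1, 2, 3, 4], sig)
        assert letters == {1: "a", 2: "b", 3: "c", 4: "d"}

    def test_single_significant_pair_cover(self):
        sig = {p: p == (1, 4) for p in itertools.combinations((1, 2, 3, 4), 2)}
        letters = significance_letters([1, 2, 3, 4], sig)
        assert set(letters[1]) & set(letters[4]) == set()
        for p in itertools.combinations((1, 2, 3, 4), 2):
            if p != (1, 4):
                assert set(letters[p[0]]) & set(letters[p[1]])

    @settings(max_examples=64, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=63))
    def test_share_letter_iff_not_significant_for_all_patterns(self, pattern):
        pairs = list(itertools.combinations((1, 2, 3, 4), 2))
        sig = {p: bool(pattern >> i & 1) for i, p in enumerate(pairs)}
        letters = significance_letters([1, 2, 3, 4], sig)
        for p in pairs:
            share = bool(set(letters[p[0]]) & set(letters[p[1]]))
            assert share == (not sig[p])


class TestNesting:
    def test_all_variants_agree_when_covariates_constant(self, fast_mcmc):
        rng = np.random.default_rng(33)
        delta = rng.normal(0.6, 0.5, 30)
        data = make_shift_data(delta, np.ones(30))
        with pytest.warns(UserWarning, match="constant"):
            results = fit_all_variants(data, fast_mcmc)
        means = [
            results["overall"].overall.mean,
            results["site"].alpha[1].mean,
            results["site+phenology+growthform"].alpha[1].mean,
        ]
        mc_se = 3 * 0.5 / np.sqrt(30)
        assert max(means) - min(means) < mc_se
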