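"""Benchmark-concentration modeling: trend filter, fits, filters, pathways."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from toxconcord import bmc
from toxconcord.errors import InvalidInputError

CONC = np.array([0.0, 0.1, 1.0, 10.0, 100.0])


def _dose_data(mu_fn, n_rep=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.repeat(CONC, n_rep)
    y = mu_fn(x) + noise * rng.standard_normal(len(x))
    return x, y


class TestWilliamsFilter:
    def _expr(self, rows, n_rep=3):
        x = np.repeat(CONC, n_rep)
        expr = pd.DataFrame(rows, columns=[f"s{i}" for i in range(len(x))])
        conc = pd.Series(x, index=expr.columns)
        return expr, conc

    def test_monotone_signal_retained(self):
        rng = np.random.default_rng(0)
        x = np.repeat(CONC, 3)
        hits = 0
        for seed in range(20):
            y = np.log1p(x) * 2 + 0.1 * rng.standard_normal(len(x))
            expr, conc = self._expr([y])
            kept, p = bmc.williams_trend_filter(expr, conc, n_perm=500, seed=seed)
            hits += len(kept)
        assert hits >= 19  # >=95% of seeded runs

    def test_decreasing_signal_also_retained(self):
        x = np.repeat(CONC, 3)
        rng = np.random.default_rng(1)
        y = -np.log1p(x) + 0.05 * rng.standard_normal(len(x))
        expr, conc = self._expr([y])
        kept, _p = bmc.williams_trend_filter(expr, conc, n_perm=500, seed=2)
        assert len(kept) == 1

    def test_flat_zero_noise_gene_p_one(self):
        expr, conc = self._expr([np.full(15, 7.0)])
        kept, p = bmc.williams_trend_filter(expr, conc, n_perm=200, seed=0)
        assert kept == []
        assert p.iloc[0] == 1.0

    def test_requires_enough_groups_and_replicates(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], columns=list("abcd"))
        conc = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        with pytest.raises(InvalidInputError):
            bmc.williams_trend_filter(expr, conc)  # 1 replicate per group
        conc2 = pd.Series([0.0, 0.0, 1.0, 1.0], index=list("abcd"))
        with pytest.raises(InvalidInputError):
            bmc.williams_trend_filter(expr, conc2)  # too few groups


class TestModelFits:
    def test_linear_closed_form_bmc(self):
        """Noiseless y = 2 + x with BMR sigma fixed at 0.5 -> BMC = 0.5."""
        x, y = _dose_data(lambda x: 2.0 + x)
        fits = bmc.fit_models(y, x, gene="g", sd=0.5, models=("linear",),
                              compute_ci=False)
        assert fits[0].converged
        assert fits[0].bmc == pytest.approx(0.5, abs=1e-6)

    def test_linear_bmc_scale_equivariant(self):
        x, y = _dose_data(lambda x: 2.0 + x)
        base = bmc.fit_models(y, x, sd=0.5, models=("linear",), compute_ci=False)[0]
        for c in (3.0, 0.25):
            scaled = bmc.fit_models(y, x * c, sd=0.5, models=("linear",),
                                    compute_ci=False)[0]
            assert scaled.bmc == pytest.approx(c * base.bmc, rel=1e-6)

    def test_zero_slope_no_finite_bmc(self):
        x, y = _dose_data(lambda x: np.full_like(x, 5.0))
        fits = bmc.fit_models(y, x, sd=0.5, models=("linear",), compute_ci=False)
        assert not math.isfinite(fits[0].bmc)
        winners = bmc.filter_bmc(fits, x)
        assert winners[0].filter_status in ("above_range", "poor_fit")

    def test_hill_recovery_within_one_percent(self):
        """Noiseless hill data: hill wins and BMC matches analytic inversion."""
        a, b, g, k = 1.0, 6.0, 2.0, 5.0
        x, y = _dose_data(lambda x: a + b * x**g / (k**g + x**g))
        sd = 0.25
        fits = bmc.fit_models(y, x, sd=sd, compute_ci=False)
        winner = [f for f in fits if f.winning][0]
        assert winner.model == "hill"
        delta = sd  # bmr = 1 * sd
        bmc_true = k * (delta / (b - delta)) ** (1.0 / g)
        assert winner.bmc == pytest.approx(bmc_true, rel=0.01)

    def test_profile_bounds_bracket_estimate(self):
        x, y = _dose_data(lambda x: 2.0 + 0.05 * x, noise=0.3, seed=4)
        fits = bmc.fit_models(y, x, models=("linear",))
        ft = fits[0]
        if math.isfinite(ft.bmc):
            assert ft.bmcl <= ft.bmc <= ft.bmcu

    def test_noise_widens_profile_interval_on_average(self):
        widths = {}
        for noise in (0.1, 0.8):
            ws = []
            for seed in range(5):
                x, y = _dose_data(lambda x: 2.0 + 0.05 * x, noise=noise, seed=seed)
                ft = bmc.fit_models(y, x, models=("linear",))[0]
                if math.isfinite(ft.bmc) and math.isfinite(ft.bmcu):
                    ws.append(np.log(ft.bmcu) - np.log(max(ft.bmcl, 1e-12)))
            widths[noise] = np.mean(ws) if ws else np.inf
        assert widths[0.8] >= widths[0.1]


class TestBmcFilters:
    def _fit(self, bmc_val, bmcl=None, bmcu=None, fit_p=0.5):
        ft = bmc.BmcFit(gene="g", model="linear", converged=True, winning=True)
        ft.bmc, ft.fit_p = bmc_val, fit_p
        ft.bmcl = bmcl if bmcl is not None else bmc_val / 2
        ft.bmcu = bmcu if bmcu is not None else bmc_val * 2
        return ft

    def test_below_range_rule(self):
        # lowest concentration 0.1: BMC < 0.01 is >10-fold below
        ft = self._fit(0.005)
        assert bmc.filter_bmc([ft], CONC)[0].filter_status == "below_range"

    def test_above_range_rule(self):
        ft = self._fit(600.0)
        assert bmc.filter_bmc([ft], np.array([0.0, 5, 50, 500]))[0].filter_status == "above_range"

    @pytest.mark.parametrize(
        "bmcl,bmcu,status",
        [
            (0.04, 2.0, "wide_ci"),  # bmc/bmcl = 25 > 20
            (0.5, 25.0, "wide_ci"),  # bmcu/bmc = 25 > 20
            (0.06, 2.5, "wide_ci"),  # bmcu/bmcl ~ 42 > 40
            (0.5, 2.0, "pass"),
        ],
    )
    def test_wide_ci_ratio_rules(self, bmcl, bmcu, status):
        ft = self._fit(1.0, bmcl=bmcl, bmcu=bmcu)
        assert bmc.filter_bmc([ft], CONC)[0].filter_status == status

    def test_poor_fit_rule_takes_precedence(self):
        ft = self._fit(0.005, fit_p=0.05)
        assert bmc.filter_bmc([ft], CONC)[0].filter_status == "poor_fit"

    def test_fit_p_at_threshold_retained(self):
        ft = self._fit(1.0, fit_p=0.1)  # 'winning model fit p >= .1' retained
        assert bmc.filter_bmc([ft], CONC)[0].filter_status == "pass"


def _passing(gene, bmc_val):
    ft = bmc.BmcFit(gene=gene, model="linear", converged=True, winning=True)
    ft.bmc, ft.filter_status = bmc_val, "pass"
    return ft


class TestPathwayClassification:
    def test_median_bmc_over_passing_genes(self):
        universe = [f"G{i}" for i in range(20)]
        fits = [_passing("G0", 1.0), _passing("G1", 2.0), _passing("G2", 9.0)]
        sets = {"S": ["G0", "G1", "G2"]}
        out = bmc.pathway_classification(fits, sets, universe)
        assert len(out) == 1
        assert out["median_bmc"].iloc[0] == pytest.approx(2.0)
        assert out["n_genes_passing"].iloc[0] == 3

    def test_two_tailed_fisher_matches_enumeration_small_universe(self):
        """Brute-force oracle: two-tailed Fisher p = sum of hypergeometric
        outcomes no more probable than the observed table, for N <= 12."""
        from scipy.stats import fisher_exact

        for N in range(2, 13):
            for m in range(1, N + 1):
                for npass in range(N + 1):
                    for k in range(max(0, m + npass - N), min(m, npass) + 1):
                        table = [[k, npass - k], [m - k, N - m - npass + k]]
                        _o, p = fisher_exact(table, alternative="two-sided")
                        probs = hypergeom.pmf(
                            np.arange(max(0, m + npass - N), min(m, npass) + 1),
                            N, m, npass,
                        )
                        p_obs = hypergeom.pmf(k, N, m, npass)
                        expected = probs[probs <= p_obs * (1 + 1e-9)].sum()
                        assert p == pytest.approx(expected, rel=1e-7, abs=1e-12)

    def test_empty_passing_list_empty_output(self):
        out = bmc.pathway_classification([], {"S": ["G0"]}, ["G0", "G1"])
        assert out.empty

    def test_set_without_passing_genes_omitted(self):
        universe = [f"G{i}" for i in range(10)]
        fits = [_passing("G0", 1.0)]
        sets = {"HIT": ["G0"], "MISS": ["G5", "G6"]}
        out = bmc.pathway_classification(fits, sets, universe, p_max=1.1)
        assert out["set_name"].tolist() == ["HIT"]

    def test_accumulation_table_sorted_with_rank(self):
        df = pd.DataFrame(
            dict(set_name=["a", "b", "c"], n_genes_passing=[1, 2, 3],
                 fisher_two_tail_p=[0.01] * 3, median_bmc=[5.0, 1.0, 3.0])
        )
        out = bmc.accumulation_table(df)
        assert out["median_bmc"].tolist() == [1.0, 3.0, 5.0]
        assert out["cumulative_rank"].tolist() == [1, 2, 3]
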