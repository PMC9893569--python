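import numpy as np
import pandas as pd
import pytest
from scipy import stats

from healthineq.concentration import erreygers_index
from healthineq.decomposition import (
    CovariateDesign,
    DecompositionTable,
    contribution_shares,
    decompose,
    fit_probit,
    generalized_concentration,
    partial_effects,
)
from healthineq.exceptions import SeparationError
from healthineq.ranking import fractional_rank
from healthineq.synthetic import (
    CovariateSpec,
    GeneratorConfig,
    OutcomeSpec,
    RegionSpec,
    generate,
)

ONE_REGION = (RegionSpec("A", 1.0, np.log(1000.0)),)


def design_of(matrix, names, kinds=None, roles=None):
    return CovariateDesign(
        matrix=np.asarray(matrix, float),
        names=list(names),
        roles=roles or {n: "enabling" for n in names},
        kinds=dict(kinds or {}),
    )


class TestProbitFit:
    def test_intercept_only_mle_is_probit_inverse_of_the_mean(self, rng):
        n = 1000
        y = np.zeros(n)
        y[:700] = 1.0
        design = design_of(np.empty((n, 0)), [])
        fit = fit_probit(y, design, np.ones(n))
        assert fit.coefficients["intercept"] == pytest.approx(
            stats.norm.ppf(0.7), abs=1e-6
        )
        np.testing.assert_allclose(fit.fitted_probabilities, 0.7, atol=1e-6)

    def test_recovers_known_latent_coefficients(self):
        cfg = GeneratorConfig(
            n_persons=50_000, seed=17, regions=ONE_REGION,
            covariates=(
                CovariateSpec("ins", "enabling", "binary",
                              rank_slope=2.0, rank_intercept=-1.5),
            ),
            outcomes=(OutcomeSpec("u", model="probit", intercept=-0.4,
                                  coefficients={"ins": 0.8}),),
        )
        data, truth = generate(cfg)
        df = data.table
        design = CovariateDesign.from_frame(df, ["ins"], {"ins": "enabling"})
        fit = fit_probit(df["u"].to_numpy(), design, df["weight"].to_numpy())
        # within a few standard errors of the generating coefficients
        import statsmodels.api as sm
        se = 1.0 / np.sqrt(len(df))  # conservative scale; check via wide band
        assert fit.coefficients["ins"] == pytest.approx(0.8, abs=0.05)
        assert fit.coefficients["intercept"] == pytest.approx(-0.4, abs=0.05)

    def test_null_covariate_coefficient_is_small(self, rng):
        n = 20_000
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.4).astype(float)
        design = design_of(x[:, None], ["noise"])
        fit = fit_probit(y, design, np.ones(n))
        assert abs(fit.coefficients["noise"]) < 0.05

    def test_perfect_separation_names_the_covariate(self):
        y = np.array([0, 0, 0, 1, 1, 1.0] * 10)
        x = y.copy()
        design = design_of(x[:, None], ["sep"])
        with pytest.raises(SeparationError, match="sep"):
            fit_probit(y, design, np.ones(y.shape[0]))

    def test_collinear_design_rejected(self, rng):
        n = 50
        x = rng.random(n)
        design = design_of(np.column_stack([x, 2 * x]), ["a", "b"],
                           kinds={"a": "continuous", "b": "continuous"})
        y = (rng.random(n) < 0.5).astype(float)
        with pytest.raises(ValueError, match="rank"):
            fit_probit(y, design, np.ones(n))

    def test_constant_column_rejected_at_design_time(self):
        with pytest.raises(ValueError, match="constant"):
            design_of(np.ones((10, 1)), ["c"])


class TestPartialEffects:
    def test_zero_coefficient_covariate_has_zero_effect(self, rng):
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        design = design_of(x[:, None], ["x"])
        fit = fit_probit(y, design, np.ones(n))
        fit.coefficients["x"] = 0.0  # force the null effect
        pe = partial_effects(fit)
        np.testing.assert_array_equal(pe.per_observation["x"], np.zeros(n))
        assert pe.effects["x"] == 0.0

    def test_continuous_effect_matches_hand_computed_density_formula(self):
        # single continuous covariate z with coefficient b, zero intercept:
        # average effect = mean of b * phi(b * z)
        z = np.array([-1.0, -0.3, 0.1, 0.8, 1.7])
        b = 0.6
        design = design_of(z[:, None], ["z"], kinds={"z": "continuous"})
        # build the fit object directly so b is exact
        from healthineq.decomposition import ProbitFit
        fit = ProbitFit(
            coefficients=pd.Series({"intercept": 0.0, "z": b}),
            converged=True,
            log_likelihood=0.0,
            fitted_probabilities=stats.norm.cdf(b * z),
            design=design,
            weights=np.ones(5),
        )
        pe = partial_effects(fit)
        expected = np.mean(b * stats.norm.pdf(b * z))
        assert pe.effects["z"] == pytest.approx(expected, abs=1e-12)

    def test_binary_subgroup_average_differs_from_overall_when_heterogeneous(self):
        # 6 rows: z shifts the latent index so the discrete effect of x varies
        from healthineq.decomposition import ProbitFit
        x = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        z = np.array([-2.0, 0.0, 2.0, -1.0, 1.0, 0.5])
        design = design_of(
            np.column_stack([x, z]), ["x", "z"],
            kinds={"x": "binary", "z": "continuous"},
        )
        coef = pd.Series({"intercept": 0.2, "x": 0.9, "z": 1.1})
        eta = design.full_matrix() @ coef.to_numpy()
        fit = ProbitFit(coef, True, 0.0, stats.norm.cdf(eta), design, np.ones(6))
        pe = partial_effects(fit)
        # hand-computed oracle for the discrete change
        delta = stats.norm.cdf(eta + 0.9 * (1 - x)) - stats.norm.cdf(eta - 0.9 * x)
        assert pe.effects["x"] == pytest.approx(delta[x == 1].mean(), abs=1e-12)
        assert pe.overall_effects["x"] == pytest.approx(delta.mean(), abs=1e-12)
        assert pe.effects["x"] != pytest.approx(pe.overall_effects["x"], abs=1e-6)
        assert pe.averaging_rule["x"] == "subgroup_mean"


class TestGeneralizedConcentration:
    def test_constant_covariate_gives_zero(self):
        rk = fractional_rank(np.arange(4.0), np.ones(4))
        assert generalized_concentration(np.full(4, 7.0), rk, np.ones(4)) == pytest.approx(0.0, abs=1e-15)

    def test_rank_itself_gives_one_sixth(self):
        n = 10_000
        rk = fractional_rank(np.arange(float(n)), np.ones(n))
        gc = generalized_concentration(rk.ranks, rk, np.ones(n))
        assert gc == pytest.approx(1 / 6, abs=1e-3)

    def test_richest_half_indicator_gives_quarter(self):
        rk = fractional_rank(np.arange(4.0), np.ones(4))
        gc = generalized_concentration(np.array([0, 0, 1, 1.0]), rk, np.ones(4))
        assert gc == pytest.approx(0.25, abs=1e-12)


class TestDecompose:
    def _random_case(self, rng, n=400, k=3):
        income = rng.uniform(0, 100, n)
        w = rng.uniform(0.5, 2.0, n)
        X = np.column_stack(
            [rng.integers(0, 2, n).astype(float) for _ in range(k - 1)]
            + [rng.normal(size=n)]
        )
        names = [f"b{i}" for i in range(k - 1)] + ["z"]
        rk = fractional_rank(income, w)
        eta = -0.3 + X @ rng.uniform(-0.8, 0.8, k) + 0.8 * rk.ranks
        h = (rng.random(n) < stats.norm.cdf(eta)).astype(float)
        design = design_of(X, names)
        return h, design, rk, w

    def test_intercept_only_design_puts_everything_in_the_residual(self, rng):
        n = 200
        income = rng.uniform(0, 100, n)
        w = np.ones(n)
        rk = fractional_rank(income, w)
        h = (rng.random(n) < 0.3 + 0.5 * rk.ranks).astype(float)
        design = design_of(np.empty((n, 0)), [])
        table = decompose(h, design, rk, w)
        assert len(table.table) == 0
        e = erreygers_index(h, rk, w).value
        assert table.residual_contribution == pytest.approx(e, abs=1e-12)

    def test_additivity_holds_exactly_on_random_designs(self, rng):
        for _ in range(10):
            h, design, rk, w = self._random_case(rng)
            if h.mean() in (0.0, 1.0):
                continue
            table = decompose(h, design, rk, w)
            total = table.table["contribution"].sum() + table.residual_contribution
            assert abs(total - table.total_index) < 1e-10
            # closure residual agrees with the directly computed 4*GC(e)
            assert table.residual_contribution == pytest.approx(
                table.residual_gc_diagnostic, abs=1e-8
            )

    def test_rank_independent_covariate_contributes_exactly_zero(self):
        # x symmetric around the median income: cov(x, R) = 0 exactly
        income = np.arange(4.0)
        w = np.ones(4)
        rk = fractional_rank(income, w)
        x = np.array([1.0, 0.0, 0.0, 1.0])
        h = np.array([0.0, 1.0, 0.0, 1.0])
        design = design_of(x[:, None], ["sym"])
        table = decompose(h, design, rk, w)
        assert generalized_concentration(x, rk, w) == pytest.approx(0.0, abs=1e-15)
        assert table.table.loc["sym", "contribution"] == pytest.approx(0.0, abs=1e-15)

    def test_linear_approximation_reproduces_the_explained_sum(self, rng):
        # decomposing the linearised fitted outcome yields the identical
        # explained contributions with zero residual
        h, design, rk, w = self._random_case(rng, n=600)
        table = decompose(h, design, rk, w)
        beta = table.table["beta_m"].to_numpy()
        lin = design.matrix @ beta
        wn = w / w.sum()
        lin = lin - np.sum(wn * lin) + np.sum(wn * h)  # match the mean
        e_lin = 8.0 * np.sum(wn * (lin - np.sum(wn * lin)) * (rk.ranks - 0.5))
        assert e_lin == pytest.approx(table.table["contribution"].sum(), abs=1e-10)

    def test_single_pro_rich_driver_dominates(self):
        cfg = GeneratorConfig(
            n_persons=30_000, seed=23, regions=ONE_REGION,
            covariates=(
                CovariateSpec("insurance", "enabling", "binary",
                              rank_slope=3.0, rank_intercept=-1.5),
                CovariateSpec("noise_bin", "predisposing", "binary",
                              rank_intercept=0.0),
            ),
            outcomes=(OutcomeSpec("u", model="probit", intercept=-0.8,
                                  coefficients={"insurance": 1.2}),),
        )
        data, _ = generate(cfg)
        df = data.table
        design = CovariateDesign.from_frame(
            df, ["insurance", "noise_bin"],
            {"insurance": "enabling", "noise_bin": "predisposing"},
        )
        rk = fractional_rank(df["income_pc"].to_numpy(), df["weight"].to_numpy())
        table = decompose(df["u"].to_numpy(), design, rk, df["weight"].to_numpy())
        shares = contribution_shares(table)["share"]
        assert shares["insurance"] > 0.5
        assert shares["insurance"] > abs(shares["noise_bin"])

    def test_share_suppression_guards_near_zero_index(self, rng):
        n = 2000
        income = rng.uniform(0, 100, n)
        w = np.ones(n)
        rk = fractional_rank(income, w)
        h = (rng.random(n) < 0.5).astype(float)  # no income gradient
        x = rng.integers(0, 2, n).astype(float)
        table = decompose(h, design_of(x[:, None], ["x"]), rk, w, share_floor=0.05)
        assert table.shares_suppressed
        assert np.isnan(table.table["share"]).all()
        with pytest.raises(ValueError, match="suppressed"):
            contribution_shares(table)


class TestContributionShares:
    def _table(self):
        frame = pd.DataFrame(
            {
                "role": ["enabling", "need"],
                "beta_m": [0.1, -0.05],
                "averaging_rule": ["subgroup_mean", "subgroup_mean"],
                "gc": [0.2, 0.1],
                "contribution": [0.08, -0.02],
                "share": [0.8, -0.2],
            },
            index=pd.Index(["A", "B"], name="covariate"),
        )
        sub = frame.groupby("role")["contribution"].sum().to_frame()
        sub["share"] = sub["contribution"] / 0.10
        return DecompositionTable(
            table=frame,
            residual_contribution=0.04,
            residual_gc_diagnostic=0.04,
            total_index=0.10,
            role_subtotals=sub,
        )

    def test_share_arithmetic_sums_to_one(self):
        shares = contribution_shares(self._table())
        assert shares.loc["A", "share"] == pytest.approx(0.8)
        assert shares.loc["B", "share"] == pytest.approx(-0.2)
        assert shares.loc["residual", "share"] == pytest.approx(0.4)
        assert shares["share"].sum() == pytest.approx(1.0)

    def test_role_grouping_aggregates_contributions(self):
        shares = contribution_shares(self._table(), grouping="role")
        assert shares.loc["enabling", "contribution"] == pytest.approx(0.08)
        assert shares.loc["need", "contribution"] == pytest.approx(-0.02)
        assert shares.loc["residual", "share"] == pytest.approx(0.4)

    def test_single_covariate_explaining_everything(self):
        frame = pd.DataFrame(
            {
                "role": ["enabling"], "beta_m": [0.2],
                "averaging_rule": ["subgroup_mean"],
                "gc": [0.125], "contribution": [0.1], "share": [1.0],
            },
            index=pd.Index(["only"], name="covariate"),
        )
        table = DecompositionTable(
            table=frame, residual_contribution=0.0, residual_gc_diagnostic=0.0,
            total_index=0.1, role_subtotals=frame.groupby("role")[["contribution"]].sum(),
        )
        shares = contribution_shares(table)
        assert shares.loc["only", "share"] == pytest.approx(1.0)
        assert shares.loc["residual", "share"] == pytest.approx(0.0)
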