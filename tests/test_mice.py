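"""PMM imputation and the chained-equations engine."""

import numpy as np
import pytest

from crimpsim import AMPUTABLE_NAMES, BINARY_NAMES, mice, pmm_impute_variable
from crimpsim.mice import bayes_linear_draw


class TestPmm:
    def test_nearest_donor_identity_with_k1(self):
        # with one donor and a missing row whose predicted mean equals an
        # observed row's exactly, the imputation is that donor's value
        z = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 2.0])
        y = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, np.nan])
        out = pmm_impute_variable(y, z[:, None], donors=1,
                                  rng=np.random.default_rng(0))
        assert out[-1] == 4.0  # the z = 2 donor
        assert np.array_equal(out[:-1], y[:-1])

    def test_no_missing_returns_unchanged(self):
        y = np.arange(5.0)
        out = pmm_impute_variable(y, np.ones((5, 1)), rng=np.random.default_rng(1))
        assert np.array_equal(out, y)

    def test_binary_target_stays_binary(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(300)
        y = (z + rng.standard_normal(300) > 0).astype(float)
        y[rng.choice(300, 80, replace=False)] = np.nan
        out = pmm_impute_variable(y, z[:, None], rng=rng)
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_imputations_stay_in_observed_range(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(500)
        y = 2 * z + rng.standard_normal(500)
        miss = rng.choice(500, 200, replace=False)
        y_obs_min, y_obs_max = np.delete(y, miss).min(), np.delete(y, miss).max()
        y[miss] = np.nan
        out = pmm_impute_variable(y, z[:, None], rng=rng)
        assert out.min() >= y_obs_min and out.max() <= y_obs_max

    def test_too_few_observed_rows_fails(self):
        y = np.array([1.0, 2.0, np.nan, np.nan, np.nan])
        Z = np.random.default_rng(4).standard_normal((5, 3))
        with pytest.raises(ValueError, match="too few"):
            pmm_impute_variable(y, Z, rng=np.random.default_rng(5))

    def test_aliased_predictors_are_dropped(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(100)
        Z = np.column_stack([z, 2 * z])  # exactly collinear
        y = z + 0.1 * rng.standard_normal(100)
        y[:20] = np.nan
        out = pmm_impute_variable(y, Z, rng=rng)
        assert not np.isnan(out).any()


class TestBayesLinearDraw:
    def test_draws_vary_but_center_on_ols(self):
        rng = np.random.default_rng(7)
        Z = np.column_stack([np.ones(2000), rng.standard_normal(2000)])
        y = Z @ np.array([1.0, 2.0]) + rng.standard_normal(2000)
        draws = []
        for s in range(30):
            beta_hat, beta_draw, sigma, _ = bayes_linear_draw(
                Z, y, np.random.default_rng(s))
            draws.append(beta_draw)
        draws = np.array(draws)
        assert np.abs(draws.mean(axis=0) - beta_hat).max() < 0.05
        assert draws.std(axis=0).min() > 0  # proper (posterior) variation


class TestMiceEngine:
    def test_no_missing_gives_identical_copies(self, sample_amputed):
        _, full = sample_amputed
        stack = mice(full, m=3, cycles=2, seed=11)
        for d in stack.datasets:
            assert d.equals(full)

    def test_observed_cells_preserved_and_complete(self, sample_amputed):
        amp, _ = sample_amputed
        stack = mice(amp, strategy="all_causes", m=3, cycles=3, seed=12)
        obs_mask = ~amp[AMPUTABLE_NAMES].isna()
        for d in stack.datasets:
            assert not d.isna().any().any()
            for col in AMPUTABLE_NAMES:
                same = d.loc[obs_mask[col], col] == amp.loc[obs_mask[col], col]
                assert same.all(), col
            for col in BINARY_NAMES:
                assert set(np.unique(d[col])) <= {0.0, 1.0}, col

    def test_reproducible_given_seed(self, sample_amputed):
        amp, _ = sample_amputed
        a = mice(amp, m=2, cycles=2, seed=13)
        b = mice(amp, m=2, cycles=2, seed=13)
        for da, db in zip(a.datasets, b.datasets):
            assert da.equals(db)

    def test_between_imputation_variation_exists(self, sample_amputed):
        amp, _ = sample_amputed
        stack = mice(amp, m=3, cycles=3, seed=14)
        miss = amp["cholesterol"].isna()
        imputed = np.array([d.loc[miss, "cholesterol"].to_numpy()
                            for d in stack.datasets])
        # proper imputation: chains must not coincide
        assert np.var(imputed, axis=0).sum() > 0

    def test_mi_beats_complete_case_on_outcome_dependent_mar(self):
        """Simulation oracle: linear model y = x + z + noise with x MAR
        given (z, y).  Complete-case regression is then biased while PMM
        imputation using (z, y) as predictors recovers the coefficient."""
        from crimpsim.pooling import pool_rubin

        rng = np.random.default_rng(15)
        n, reps, m = 2000, 60, 5
        cc_err, mi_err = [], []
        for _ in range(reps):
            z = rng.standard_normal(n)
            x = 0.5 * z + rng.standard_normal(n)
            y = x + z + rng.standard_normal(n)
            p_mis = 1 / (1 + np.exp(-(y + z)))          # MAR via observed y, z
            miss = rng.uniform(size=n) < np.clip(p_mis, 0, 0.9)
            xm = np.where(miss, np.nan, x)
            obs = ~miss
            # complete-case slope of y ~ x + z
            A = np.column_stack([np.ones(obs.sum()), xm[obs], z[obs]])
            cc = np.linalg.lstsq(A, y[obs], rcond=None)[0][1]
            cc_err.append(cc - 1.0)
            est, var = [], []
            for _ in range(m):
                xi = pmm_impute_variable(xm, np.column_stack([z, y]), rng=rng)
                Ai = np.column_stack([np.ones(n), xi, z])
                coef, res, *_ = np.linalg.lstsq(Ai, y, rcond=None)
                resid = y - Ai @ coef
                s2 = resid @ resid / (n - 3)
                covb = s2 * np.linalg.inv(Ai.T @ Ai)
                est.append(coef[1])
                var.append(covb[1, 1])
            mi_err.append(pool_rubin(est, var, n - 3).qbar - 1.0)
        assert abs(np.mean(mi_err)) < abs(np.mean(cc_err))
        assert abs(np.mean(cc_err)) > 0.05  # the design really biases CC
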