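"""Substantive-model-compatible FCS engine."""

import numpy as np
import pytest
from scipy import stats

from crimpsim import (
    AMPUTABLE_NAMES,
    BINARY_NAMES,
    CoefficientSet,
    ScenarioConfig,
    ampute,
    build_superpopulation,
    cause_specific_likelihood,
    smcfcs,
)
from crimpsim.smcfcs import SubstantiveModelState


def _state(betas, baselines=None):
    if baselines is None:
        t = np.array([1.0, 2.0])
        baselines = tuple((t, np.array([0.2, 0.5])) for _ in range(3))
    return SubstantiveModelState(betas=np.asarray(betas, dtype=float),
                                 baselines=baselines)


class TestLikelihoodFactor:
    def test_null_coefficients_make_weight_independent_of_x(self):
        state = _state(np.zeros((3, 10)))
        t = 1.5
        w1 = cause_specific_likelihood(np.zeros(10), t, 0, state)
        w2 = cause_specific_likelihood(np.full(10, 3.0), t, 0, state)
        assert w1 == pytest.approx(w2)
        # exp(-sum_k H0_k(t)) with H0_k(1.5) = 0.2 each
        assert w1 == pytest.approx(np.exp(-0.6))

    def test_zero_exposure_gives_unit_weight(self):
        state = _state(np.zeros((3, 10)))
        assert cause_specific_likelihood(np.ones(10), 0.5, 0, state) \
            == pytest.approx(1.0)  # before any baseline jump

    def test_hand_coded_formula_on_one_row(self):
        rng = np.random.default_rng(0)
        betas = rng.normal(0, 0.2, size=(3, 10))
        state = _state(betas)
        x = rng.standard_normal(10)
        t, event = 1.7, 1
        lp = betas @ x
        expected = np.exp(lp[0]) * np.exp(-(0.2 * np.exp(lp)).sum())
        got = cause_specific_likelihood(x, t, event, state)
        assert got == pytest.approx(expected, rel=1e-12)
        # doubling the cause-1 hazard factor doubles the event term and
        # shrinks the survival term
        x2 = x.copy()
        state2 = _state(betas)
        lp2 = lp.copy()
        lp2[0] += np.log(2)
        expected2 = np.exp(lp2[0]) * np.exp(-(0.2 * np.exp(lp2)).sum())
        assert expected2 / expected < 2.0
        assert expected2 / expected > 2.0 * np.exp(-0.2 * np.exp(lp2[0]))

    def test_negative_baseline_rejected(self):
        t = np.array([1.0, 2.0])
        bad = ((t, np.array([0.3, 0.1])),) * 3   # decreasing H0
        with pytest.raises(ValueError, match="nondecreasing"):
            _state(np.zeros((3, 10)), bad)


@pytest.fixture(scope="module")
def small_amputed(cov_model, pattern_library):
    cfg = ScenarioConfig(n_super=5000, p_missing=0.4, seed=31)
    from crimpsim import default_coefficient_set

    data, _ = build_superpopulation(cfg, cov_model, default_coefficient_set())
    return data, ampute(data, lib=pattern_library, p_missing=0.4, seed=32)


class TestSmcfcsEngine:
    def test_no_missing_gives_identical_copies(self, small_amputed):
        complete, _ = small_amputed
        sub = complete.head(800)
        stack = smcfcs(sub, m=2, cycles=2, seed=33)
        for d in stack.datasets:
            assert d.equals(sub)

    def test_observed_cells_preserved_binary_in_01(self, small_amputed):
        _, amputed = small_amputed
        sub = amputed.head(1000).reset_index(drop=True)
        stack = smcfcs(sub, m=2, cycles=3, seed=34)
        obs_mask = ~sub[AMPUTABLE_NAMES].isna()
        for d in stack.datasets:
            assert not d.isna().any().any()
            for col in AMPUTABLE_NAMES:
                same = d.loc[obs_mask[col], col] == sub.loc[obs_mask[col], col]
                assert same.all(), col
            for col in BINARY_NAMES:
                assert set(np.unique(d[col])) <= {0.0, 1.0}

    def test_reproducible_given_seed(self, small_amputed):
        _, amputed = small_amputed
        sub = amputed.head(600).reset_index(drop=True)
        a = smcfcs(sub, m=2, cycles=2, seed=35)
        b = smcfcs(sub, m=2, cycles=2, seed=35)
        for da, db in zip(a.datasets, b.datasets):
            assert da.equals(db)

    def test_null_substantive_model_matches_covariate_model(
            self, cov_model, pattern_library):
        """With all generating coefficients zero the outcome carries no
        information about the covariates, so SMCFCS imputations of a
        continuous variable must be distributionally indistinguishable
        from draws of the plain covariate model (two-sample KS)."""
        from crimpsim.mice import bayes_linear_draw
        from crimpsim.population import COVARIATE_NAMES

        zeros = CoefficientSet(beta_cvd=np.zeros(10),
                               beta_cancer=np.zeros(10),
                               beta_other=np.zeros(10))
        cfg = ScenarioConfig(n_super=5000, p_missing=0.4, seed=36)
        data, _ = build_superpopulation(cfg, cov_model, zeros, fit_truth=False)
        amputed = ampute(data, lib=pattern_library, p_missing=0.4, seed=37)
        stack = smcfcs(amputed, m=1, cycles=5, seed=38)
        miss = amputed["cholesterol"].isna()
        imputed = stack.datasets[0].loc[miss, "cholesterol"].to_numpy()

        # covariate-model-only imputation: Bayesian linear draw off the
        # true covariates, predictive noise added
        rng = np.random.default_rng(39)
        others = [c for c in COVARIATE_NAMES if c != "cholesterol"]
        Z = np.column_stack([np.ones(len(data)), data[others].to_numpy()])
        y = data["cholesterol"].to_numpy()
        _, gamma, sigma, keep = bayes_linear_draw(Z[~miss.to_numpy()],
                                                  y[~miss.to_numpy()], rng)
        ref = Z[miss.to_numpy()][:, keep] @ gamma \
            + sigma * rng.standard_normal(int(miss.sum()))
        ks = stats.ks_2samp(imputed, ref)
        assert ks.pvalue > 0.01
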