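"""Replicate orchestration, metrics and the factorial grid."""

import numpy as np
import pandas as pd
import pytest

from crimpsim import COVARIATE_NAMES, ScenarioConfig
from crimpsim.evaluation import (
    METHODS,
    compute_metrics,
    run_replicate,
    scenario_grid,
)
from crimpsim.outcomes import TrueValues


class TestRunReplicate:
    def test_bit_identical_under_same_seed(self, small_world, small_scenario):
        superpop, amputed, _ = small_world
        a = run_replicate(superpop, amputed, small_scenario, 777,
                          methods=("complete_case", "no_missing"))
        b = run_replicate(superpop, amputed, small_scenario, 777,
                          methods=("complete_case", "no_missing"))
        pd.testing.assert_frame_equal(a, b)

    def test_all_methods_report_all_coefficients(self, small_world,
                                                 small_scenario):
        superpop, amputed, _ = small_world
        tab = run_replicate(superpop, amputed, small_scenario, 778)
        assert set(tab["method"]) == set(METHODS)
        counts = tab.groupby("method").size()
        assert (counts == 30).all()  # 3 causes x 10 covariates

    def test_no_duplicate_sample_indices(self, small_world, small_scenario):
        # sampling without replacement: identical seeds, disjoint methods
        # agree on the no-missing arm regardless of method list
        superpop, amputed, _ = small_world
        a = run_replicate(superpop, amputed, small_scenario, 779,
                          methods=("no_missing",))
        b = run_replicate(superpop, amputed, small_scenario, 779,
                          methods=("complete_case", "no_missing"))
        pd.testing.assert_frame_equal(
            a, b[b.method == "no_missing"].reset_index(drop=True))

    def test_degenerate_zero_missingness_collapses_methods(self, small_world,
                                                           small_scenario):
        """With p_missing = 0 every arm coincides with the no-missing fit
        (imputation stacks are M identical copies)."""
        superpop, _, _ = small_world
        tab = run_replicate(superpop, superpop, small_scenario, 780,
                            methods=("mice_all", "smcfcs", "complete_case",
                                     "no_missing"))
        ref = tab[tab.method == "no_missing"].set_index(["cause", "variable"])
        for method in ("mice_all", "smcfcs", "complete_case"):
            got = tab[tab.method == method].set_index(["cause", "variable"])
            assert np.allclose(got["qbar"], ref.loc[got.index, "qbar"])


class TestComputeMetrics:
    @staticmethod
    def _truth(value=1.0):
        v = np.full(10, value)
        return TrueValues(beta_true_cvd=v, beta_true_cancer=v, beta_true_other=v)

    def _results(self, qbar, lo, hi, reps=4):
        rows = []
        for rep in range(reps):
            rows.append({"method": "m", "cause": 1, "variable": "age",
                         "qbar": qbar, "se": 0.1, "df": 100,
                         "ci_low": lo, "ci_high": hi, "rep": rep})
        return pd.DataFrame(rows)

    def test_unbiased_fully_covered_case(self):
        tab = compute_metrics(self._results(1.0, 0.5, 1.5), self._truth())
        row = tab.iloc[0]
        assert row["relative_bias"] == pytest.approx(0.0)
        assert row["coverage"] == 100.0
        assert row["n_reps_used"] == 4

    def test_ten_percent_relative_bias(self):
        tab = compute_metrics(self._results(1.1, 1.05, 1.15), self._truth())
        row = tab.iloc[0]
        assert row["relative_bias"] == pytest.approx(10.0)
        assert row["coverage"] == 0.0  # CIs exclude the true value 1.0

    def test_zero_truth_leaves_relative_bias_undefined(self):
        tab = compute_metrics(self._results(0.05, -0.1, 0.2),
                              self._truth(0.0))
        row = tab.iloc[0]
        assert np.isnan(row["relative_bias"])
        assert row["abs_bias"] == pytest.approx(0.05)

    def test_coverage_significance_band_for_1000_reps(self):
        # the normal-theory band around 95% at 1000 replicates
        half = 1.96 * np.sqrt(0.95 * 0.05 / 1000) * 100
        assert 95 - half == pytest.approx(93.65, abs=0.005)
        assert 95 + half == pytest.approx(96.35, abs=0.005)


class TestGrid:
    def test_full_factorial_enumeration(self):
        cells = scenario_grid(ScenarioConfig(seed=5))
        assert len(cells) == 30
        rates = {(c.lambda_cvd, c.lambda_cancer, c.lambda_other) for c in cells}
        assert (1.0, 1.0 / 3.0, 1.0 / 3.0) in rates
        assert (1.0, 3.0, 3.0) in rates
        assert len(rates) == 5
        ps = sorted({c.p_missing for c in cells})
        assert ps == [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        # deterministic, order-stable, distinct seeds
        again = scenario_grid(ScenarioConfig(seed=5))
        assert [c.seed for c in cells] == [c.seed for c in again]
        assert len({c.seed for c in cells}) == 30


def test_cli_simulate_ampute_roundtrip(tmp_path):
    from click.testing import CliRunner

    from crimpsim.cli import main

    runner = CliRunner()
    sim = tmp_path / "pop.csv"
    res = runner.invoke(main, ["simulate", "--n", "3000", "--seed", "9",
                               "--out", str(sim)])
    assert res.exit_code == 0, res.output
    df = pd.read_csv(sim)
    assert list(df.columns) == COVARIATE_NAMES + ["time", "event"]
    amp = tmp_path / "amp.csv"
    res = runner.invoke(main, ["ampute", "--data", str(sim),
                               "--p-missing", "0.3", "--seed", "9",
                               "--out", str(amp)])
    assert res.exit_code == 0, res.output
    out = pd.read_csv(amp)
    frac = out[COVARIATE_NAMES].isna().any(axis=1).mean()
    assert abs(frac - 0.3) < 0.02
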