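"""Activity and poising tests against brute-force statistical oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bh_oracle, fisher_greater_oracle, poisson_sf_oracle
from pol2poise.poising import (
    CLASSES,
    IgGBackground,
    bh_adjust,
    call_poising,
    classify,
    expected_igg_counts,
    fisher_poised_test,
    fisher_poised_test_batch,
    igg_background,
    poisson_activity_test,
)


def _background(prom_density, body_density=1.0, lib=10**7):
    return IgGBackground(prom_density, body_density, lib)


class TestPoissonActivity:
    def test_zero_observed_is_one(self):
        bg = _background(prom_density=5.0 / (0.6 * 10))  # lambda = 5 at lib 1e7
        assert poisson_activity_test(0, bg, 600, 10**7) == 1.0

    @pytest.mark.parametrize("observed,lam", [(20, 5.0), (5, 5.0), (1, 0.5), (150, 100.0)])
    def test_matches_pmf_summation_oracle(self, observed, lam):
        # build a background whose promoter expectation equals lam
        bg = _background(lam / (0.6 * 10))
        p = poisson_activity_test(observed, bg, 600, 10**7)
        assert p == pytest.approx(poisson_sf_oracle(observed, lam), rel=1e-12)

    def test_known_values(self):
        bg = _background(5.0 / (0.6 * 10))
        assert poisson_activity_test(5, bg, 600, 10**7) == pytest.approx(0.5595, abs=2e-4)
        assert poisson_activity_test(20, bg, 600, 10**7) == pytest.approx(3.5e-7, rel=0.05)

    def test_zero_rate_edge(self):
        bg = _background(0.0)
        assert poisson_activity_test(0, bg, 600, 10**7) == 1.0
        assert poisson_activity_test(3, bg, 600, 10**7) == 0.0

    def test_lambda_scales_with_polii_depth(self):
        # doubling the Pol II library doubles the null expectation, so the
        # same observed count becomes less surprising
        bg = _background(2.0)
        p_shallow = poisson_activity_test(30, bg, 600, 10**7)
        p_deep = poisson_activity_test(30, bg, 600, 2 * 10**7)
        assert p_deep > p_shallow

    def test_negative_observed_rejected(self):
        with pytest.raises(ValueError):
            poisson_activity_test(-1, _background(1.0), 600, 10**7)


class TestBH:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_single_and_capped(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_step_up_oracle(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_oracle(pvals))

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj = bh_adjust(pvals)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        assert [adj[i] for i in perm] == pytest.approx(list(adj_perm))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFisher:
    def test_extreme_table(self):
        # [[5,0],[0,5]]: only one arrangement at least this extreme
        assert fisher_poised_test(5, 0, 0, 5) == pytest.approx(1 / 252, rel=1e-9)

    def test_null_consistent_table(self):
        p = fisher_poised_test(10, 10, 10, 10)
        assert p == pytest.approx(fisher_greater_oracle(10, 10, 10, 10), rel=1e-9)
        assert p >= 0.5

    def test_zero_row_returns_one(self):
        assert fisher_poised_test(0, 0, 3, 4) == 1.0
        assert fisher_poised_test(3, 4, 0, 0) == 1.0
        assert fisher_poised_test(0, 3, 0, 4) == 1.0

    @given(
        st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_poised_test(a, b, c, d) == pytest.approx(
            fisher_greater_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )

    def test_batch_agrees_with_scalar(self, rng):
        tables = rng.integers(0, 40, size=(200, 4))
        batch = fisher_poised_test_batch(*tables.T)
        for row, p in zip(tables, batch):
            assert p == pytest.approx(fisher_poised_test(*row), rel=1e-12)


class TestBackgroundAndClassify:
    def test_background_is_mean_density(self):
        counts = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "igg_prom": [6, 18],  # RPKM 1.0 and 3.0 at len 600, lib 1e7
                "igg_body": [0, 0],
                "igg_library": [10**7, 10**7],
                "prom_len": [600, 600],
                "body_len": [4000, 4000],
            }
        )
        bg = igg_background(counts)
        assert bg.mean_prom_density == pytest.approx(2.0)
        assert bg.mean_body_density == 0.0

    def test_background_empty_rejected(self):
        with pytest.raises(ValueError):
            igg_background(pd.DataFrame(columns=["igg_library"]))

    def test_expected_counts_floor(self):
        bg = IgGBackground(0.001, 0.0, 10**6)
        prom, body = expected_igg_counts(bg, 600, 4000)
        assert prom == 1  # rounds to 0 but density positive -> floored
        assert body == 0  # zero density stays zero

    def test_classify_thresholds(self, config):
        assert classify(0.5, 1e-9, config) == "I"  # inactive regardless of poising p
        assert classify(0.001, 1e-6, config) == "P"
        assert classify(0.001, 0.5, config) == "NP"
        assert classify(0.01, 1e-6, config) == "I"  # boundary: adj >= alpha is inactive


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(7)
    n = 300
    klass = np.array(["I"] * 100 + ["NP"] * 100 + ["P"] * 100)
    prom_mult = np.select([klass == "NP", klass == "P"], [10, 20], default=1)
    body_mult = np.select([klass == "NP", klass == "P"], [10, 2], default=1)
    lam_prom, lam_body = 12.0, 60.0
    counts = pd.DataFrame(
        {
            "gene_id": [f"g{i:03d}" for i in range(n)],
            "polii_prom": rng.poisson(lam_prom * prom_mult),
            "polii_body": rng.poisson(lam_body * body_mult),
            "igg_prom": rng.poisson(lam_prom, n),
            "igg_body": rng.poisson(lam_body, n),
            "polii_library": 2 * 10**6,
            "igg_library": 2 * 10**6,
            "prom_len": 600,
            "body_len": 3000,
        }
    )
    return counts, klass


class TestCallPoising:

    def test_partition_and_recovery(self, cohort, config):
        counts, klass = cohort
        calls = call_poising(counts, config)
        assert sorted(calls["klass"].unique()) == sorted(set(klass))
        assert len(calls) == len(counts)
        assert set(calls["klass"]).issubset(set(CLASSES))
        assert (calls["klass"].to_numpy() == klass).mean() >= 0.95

    def test_adjusted_at_least_raw(self, cohort, config):
        counts, _ = cohort
        calls = call_poising(counts, config)
        assert (calls["p_active_adj"] >= calls["p_active_raw"] - 1e-15).all()
        tested = calls["p_poised_raw"].notna()
        assert (
            calls.loc[tested, "p_poised_adj"] >= calls.loc[tested, "p_poised_raw"] - 1e-15
        ).all()

    def test_poised_family_restricted_to_polii_positive(self, cohort, config):
        counts, _ = cohort
        calls = call_poising(counts, config)
        inactive = calls["klass"] == "I"
        assert calls.loc[inactive, "p_poised_raw"].isna().all()
        assert calls.loc[~inactive, "p_poised_raw"].notna().all()

    def test_per_gene_igg_mode_runs(self, cohort, config):
        counts, klass = cohort
        calls = call_poising(counts, config, igg_mode="per_gene")
        assert (calls["klass"].to_numpy() == klass).mean() >= 0.9


def test_null_calibration_small(config):
    """Class-I genes drawn at the IgG rate are rarely called Pol II+."""
    rng = np.random.default_rng(21)
    n = 2000
    lam = 12.0
    counts = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "polii_prom": rng.poisson(lam, n),
            "polii_body": rng.poisson(60.0, n),
            "igg_prom": rng.poisson(lam, n),
            "igg_body": rng.poisson(60.0, n),
            "polii_library": 2 * 10**6,
            "igg_library": 2 * 10**6,
            "prom_len": 600,
            "body_len": 3000,
        }
    )
    calls = call_poising(counts, config)
    fpr = (calls["klass"] != "I").mean()
    mc_se = np.sqrt(config.active_alpha * (1 - config.active_alpha) / n)
    assert fpr <= config.active_alpha + 3 * mc_se
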