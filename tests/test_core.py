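"""The enrichment z-test: statistics, nulls, BH adjustment, calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slea import (
    EnrichmentConfig,
    ExpressionMatrix,
    GeneModuleSet,
    SleaError,
    analytic_null_mean,
    bh_adjust,
    classify_calls,
    enrich_sample_module,
    module_statistic,
    normalize_rows,
    permutation_null,
    run_slea,
)


def enumerated_null(values, m, statistic):
    """Exact null over all C(N, m) subsets — the brute-force oracle."""
    finite = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    agg = np.mean if statistic == "mean" else np.median
    stats = [agg(np.asarray(c)) for c in itertools.combinations(finite, m)]
    return float(np.mean(stats)), float(np.std(stats))


class TestModuleStatistic:
    def test_median_of_selected(self):
        assert module_statistic([1.0, 3.0, 5.0], [0, 2], "median") == 3.0

    def test_mean_of_full_set(self):
        assert module_statistic([1.0, 3.0, 5.0], [0, 1, 2], "mean") == 3.0

    def test_no_finite_values_signals_nan(self):
        assert math.isnan(module_statistic([1.0, np.nan, 5.0], [1], "median"))

    def test_even_length_median_averages_central_pair(self):
        assert module_statistic([1.0, 2.0, 10.0, 20.0], [0, 1, 2, 3], "median") == 6.0


class TestAnalyticNull:
    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("n,m", [(5, 2), (8, 3), (12, 4), (6, 6)])
    def test_exact_agreement_with_enumeration(self, seed, n, m):
        values = np.random.default_rng(seed).normal(size=n)
        mu, sd = analytic_null_mean(values, m)
        mu_e, sd_e = enumerated_null(values, m, "mean")
        assert mu == pytest.approx(mu_e, abs=1e-12)
        assert sd == pytest.approx(sd_e, abs=1e-12)

    def test_hand_example(self):
        mu, sd = analytic_null_mean([1, 2, 3, 4, 5], 2)
        assert mu == pytest.approx(3.0)
        assert sd == pytest.approx(0.8660254, abs=1e-6)

    def test_full_set_has_zero_sd(self):
        assert analytic_null_mean([1, 2, 3, 4, 5], 5)[1] == 0.0

    def test_constant_values_have_zero_sd(self):
        assert analytic_null_mean([2.0, 2.0, 2.0], 2)[1] == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(SleaError):
            analytic_null_mean([1.0], 1)


class TestPermutationNull:
    def test_matches_enumeration_within_monte_carlo_tolerance(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=10)
        for statistic, m in [("mean", 3), ("median", 4), ("mean", 2)]:
            mu_e, sd_e = enumerated_null(values, m, statistic)
            mu_p, sd_p = permutation_null(
                values, m, statistic, 10_000, np.random.default_rng(1)
            )
            assert mu_p == pytest.approx(mu_e, abs=4 * sd_e / math.sqrt(10_000) + 1e-12)
            assert sd_p == pytest.approx(sd_e, rel=0.1)

    def test_matches_closed_form_for_mean(self):
        values = np.random.default_rng(3).normal(size=200)
        mu_a, sd_a = analytic_null_mean(values, 30)
        mu_p, sd_p = permutation_null(values, 30, "mean", 10_000, np.random.default_rng(2))
        assert mu_p == pytest.approx(mu_a, abs=4 * sd_a / math.sqrt(10_000))
        assert sd_p == pytest.approx(sd_a, rel=0.05)

    def test_full_size_and_constant_samples_are_degenerate(self):
        rng = np.random.default_rng(0)
        assert permutation_null([1, 2, 3, 4, 5], 5, "mean", 100, rng)[1] == 0.0
        assert permutation_null([3.0] * 8, 3, "median", 100, rng)[1] == 0.0

    def test_module_larger_than_sample_rejected(self):
        with pytest.raises(SleaError, match="exceeds"):
            permutation_null([1.0, 2.0, np.nan], 3, "mean", 100, np.random.default_rng(0))

    def test_deterministic_given_seed(self):
        values = np.random.default_rng(5).normal(size=50)
        a = permutation_null(values, 10, "median", 500, np.random.default_rng(9))
        b = permutation_null(values, 10, "median", 500, np.random.default_rng(9))
        assert a == b


class TestEnrichSampleModule:
    CFG = EnrichmentConfig(statistic="mean", n_permutations=10_000, min_module_size=2, seed=0)

    def test_hand_example_against_analytic_oracle(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        z, p, n_mapped = enrich_sample_module(
            values, [3, 4], self.CFG, rng=np.random.default_rng(4)
        )
        # oracle: (4.5 - 3) / 0.8660 from the exhaustive enumeration
        assert n_mapped == 2
        assert z == pytest.approx(1.732, abs=0.1)
        assert 0 < p < 1

    def test_observed_equal_to_null_mean_gives_zero(self):
        # module {1, 5} has mean 3, exactly the null mean for m = 2
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        null = analytic_null_mean(values, 2)
        z, p, _ = enrich_sample_module(values, [0, 4], self.CFG, null=null)
        assert z == 0.0 and p == 1.0

    def test_degenerate_null_convention(self):
        z, p, n = enrich_sample_module(
            [2.0] * 10, list(range(3)), self.CFG, rng=np.random.default_rng(0)
        )
        assert (z, p) == (0.0, 1.0)
        assert n == 3

    def test_too_few_mapped_genes_not_testable(self):
        cfg = EnrichmentConfig(min_module_size=10)
        z, p, n = enrich_sample_module(
            [1.0, 2.0, np.nan, 4.0], [0, 1, 2], cfg, rng=np.random.default_rng(0)
        )
        assert n == 2
        assert math.isnan(z) and math.isnan(p)

    @pytest.mark.parametrize("statistic", ["mean", "median"])
    def test_location_scale_invariance(self, statistic):
        """z is unchanged when a sample's values become a*x + b (a > 0)."""
        rng = np.random.default_rng(11)
        values = rng.normal(size=80)
        idx = list(range(0, 20))
        cfg = EnrichmentConfig(statistic=statistic, n_permutations=1_000, seed=0)
        z1, _, _ = enrich_sample_module(values, idx, cfg, rng=np.random.default_rng(42))
        z2, _, _ = enrich_sample_module(
            2.5 * values + 7.0, idx, cfg, rng=np.random.default_rng(42)
        )
        assert z2 == pytest.approx(z1, rel=1e-9, abs=1e-9)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1], [np.nan]])
    def test_domain_violations_rejected(self, bad):
        with pytest.raises(SleaError):
            bh_adjust(bad)

    @given(
        p=st.lists(
            st.floats(min_value=1e-10, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_adjusted_dominates_raw_and_is_permutation_equivariant(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), adj[perm], atol=1e-15)


@pytest.fixture(scope="module")
def structured_run():
    """Small normalized cohort with one active module plus a decoy."""
    rng = np.random.default_rng(21)
    n_genes, n_samples = 300, 40
    values = rng.normal(size=(n_genes, n_samples))
    activity = rng.normal(0, 2.0, size=n_samples)
    values[:30] += activity  # module genes = G0000..G0029
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{j:02d}" for j in range(n_samples)]
    matrix = normalize_rows(
        ExpressionMatrix(data=pd.DataFrame(values, index=genes, columns=samples))
    )
    modules = GeneModuleSet(
        modules={
            "active": frozenset(genes[:30]),
            "decoy": frozenset(genes[100:130]),
            "unmapped": frozenset({"X1", "X2", "X3"}),
        }
    )
    config = EnrichmentConfig(n_permutations=1_000, min_module_size=10, seed=17)
    return matrix, modules, config, run_slea(matrix, modules, config), activity


class TestRunSlea:
    def test_requires_normalized_matrix(self, tiny_matrix, tiny_modules):
        with pytest.raises(SleaError, match="normalized"):
            run_slea(tiny_matrix, tiny_modules, EnrichmentConfig())

    def test_unmapped_module_not_testable_everywhere(self, structured_run):
        _, _, _, result, _ = structured_run
        calls = result.calls_for("unmapped")
        assert (calls == "not-testable").all()

    def test_no_testable_module_is_an_error(self, structured_run):
        matrix, _, config, _, _ = structured_run
        only_unmapped = GeneModuleSet(modules={"unmapped": frozenset({"X1", "X2"})})
        with pytest.raises(SleaError, match="mapped sizes"):
            run_slea(matrix, only_unmapped, config)

    def test_top_value_module_gives_maximal_positive_z(self, structured_run):
        """A module holding a sample's largest values has that sample's z
        positive and maximal across the cohort."""
        matrix, _, config, _, _ = structured_run
        col = matrix.values[:, 0]
        top = np.argsort(col)[-15:]
        genes = [matrix.gene_ids[i] for i in top]
        mods = GeneModuleSet(modules={"top_of_s0": frozenset(genes)})
        res = run_slea(matrix, mods, config)
        z = res.z_matrix().loc["top_of_s0"]
        assert z["S00"] > 0
        assert z.idxmax() == "S00"

    def test_z_tracks_true_activity(self, structured_run):
        _, _, _, result, activity = structured_run
        z = result.z_matrix().loc["active"].to_numpy()
        assert np.corrcoef(z, activity)[0, 1] > 0.9

    def test_bh_is_within_sample(self, structured_run):
        _, _, _, result, _ = structured_run
        for _, grp in result.table.groupby("sample_id"):
            testable = grp.dropna(subset=["p"])
            np.testing.assert_allclose(
                testable["p_adj"].to_numpy(),
                bh_adjust(testable["p"].to_numpy()),
                atol=1e-12,
            )

    def test_bit_identical_under_same_config(self, structured_run):
        matrix, modules, config, result, _ = structured_run
        again = run_slea(matrix, modules, config)
        pd.testing.assert_frame_equal(result.table, again.table)

    def test_result_round_trips_through_tsv(self, structured_run, tmp_path):
        _, _, _, result, _ = structured_run
        result.to_tsv(tmp_path / "r.tsv")
        back = type(result).read_table(tmp_path / "r.tsv")
        np.testing.assert_allclose(back["z"].to_numpy(), result.table["z"].to_numpy())
        assert (back["call"] == result.table["call"]).all()


class TestClassifyCalls:
    @pytest.mark.parametrize(
        "z, p_adj, expected",
        [
            (2.5, 0.01, "positive-enriched"),
            (-4.0, 1e-6, "non-enriched"),  # the rule is one-directional
            (3.0, 0.2, "non-enriched"),
            (math.nan, math.nan, "not-testable"),
        ],
    )
    def test_call_rule(self, z, p_adj, expected, structured_run):
        _, _, config, result, _ = structured_run
        table = result.table.iloc[:1].copy()
        table.loc[:, ["z", "p_adj"]] = [[z, p_adj]]
        table.loc[:, "p"] = p_adj
        patched = type(result)(
            table=table,
            config=config,
            sample_ids=result.sample_ids,
            module_names=result.module_names,
        )
        assert classify_calls(patched, 0.05).table["call"].iloc[0] == expected
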