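import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm import (
    TestResult,
    chi_square_test,
    generate,
    module_contingency,
    one_way_anova,
    study_config,
    partition_targets,
    pearson_correlation,
    two_sample_t,
    validation_battery,
)
from netpharm.centrality import centrality_table
from netpharm.network import build_bipartite, integrate_master, project_targets
from netpharm.partition import ContingencyTable


def table(observed):
    return ContingencyTable(observed=np.asarray(observed, dtype=int))


class TestChiSquare:
    def test_study_contingency(self):
        res = chi_square_test(table([[14, 0], [38, 12], [114, 50]]))
        assert res.statistic == pytest.approx(6.386, abs=5e-4)
        assert res.df == (2.0,)
        assert res.p_value == pytest.approx(0.041, abs=5e-4)
        aux = res.auxiliaries
        assert aux["min_expected"] == pytest.approx(3.8, abs=0.05)
        assert aux["n_cells_expected_lt_5"] == 1
        assert aux["pct_cells_expected_lt_5"] == pytest.approx(100 / 6, abs=0.05)

    def test_homogeneous_table(self):
        res = chi_square_test(table([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # all expected counts 15; four cells of (±5)²/15
        res = chi_square_test(table([[20, 10], [10, 20]]))
        assert res.statistic == pytest.approx(20 / 3, rel=1e-12)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="zero row or column"):
            chi_square_test(table([[0, 0], [10, 20]]))

    @settings(derandomize=True, max_examples=50)
    @given(
        obs=st.lists(
            st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=4),
            min_size=2, max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_expected_counts_conserve_grand_total(self, obs):
        res = chi_square_test(table(obs))
        assert res.auxiliaries["expected"].sum() == pytest.approx(np.sum(obs))
        assert 0.0 <= res.p_value <= 1.0
        assert res.statistic >= 0.0

    def test_row_permutation_invariance(self):
        a = chi_square_test(table([[14, 0], [38, 12], [114, 50]]))
        b = chi_square_test(table([[114, 50], [14, 0], [38, 12]]))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = two_sample_t(a, b, variant="pooled")
        sp2 = (
            ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        ) / (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == (6.0,)

    def test_antisymmetry(self):
        a, b = [1.0, 4.0, 2.0], [3.0, 5.0, 8.0, 2.0]
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_degenerate_constant_groups(self):
        same = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert same.statistic == 0.0 and same.p_value == 1.0
        diff = two_sample_t([2.0, 2.0], [3.0, 3.0])
        assert diff.error is not None

    def test_welch_variant(self):
        res = two_sample_t([1, 2, 3], [10, 20, 30, 40], variant="welch")
        assert res.ok
        assert res.df[0] != 5.0  # Satterthwaite df, not pooled


class TestAnova:
    def test_equal_groups_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_pooled_t_squared(self):
        a, b = [1.0, 3.0, 5.0, 2.0], [4.0, 6.0, 8.0]
        f = one_way_anova([a, b])
        t = two_sample_t(a, b, variant="pooled")
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_three_groups_hand_ss_decomposition(self):
        groups = [np.array([1.0, 2.0]), np.array([4.0, 6.0]), np.array([3.0])]
        res = one_way_anova(groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ss_between / 2) / (ss_within / 2)
        assert res.statistic == pytest.approx(f_hand, rel=1e-12)
        assert res.df == (2.0, 2.0)

    def test_degenerate(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert res.error is not None
        res2 = one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        assert res2.statistic == 0.0 and res2.p_value == 1.0


class TestPearson:
    def test_exact_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, x).statistic == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = pearson_correlation(x, y)
        r_hand = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert res.statistic == pytest.approx(r_hand, rel=1e-12)
        assert res.df == (8.0,)

    def test_nan_pairs_dropped_listwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 4.1, 5.3]
        res = pearson_correlation(x, y)
        assert res.auxiliaries["n"] == 4

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def battery():
    datasets = generate(study_config(seed=3))
    universes = tuple(d.target_universe for d in datasets)
    part = partition_targets(*universes)
    tps = [project_targets(build_bipartite(d)) for d in datasets]
    master = integrate_master(*tps, universes)
    cent = centrality_table(master.formula_graph())
    return validation_battery(part, cent), part


class TestValidationBattery:
    def test_contains_ten_results(self, battery):
        report, _ = battery
        assert len(report) == 10
        assert all(isinstance(r, TestResult) for r in report.values())

    def test_chi_square_slot_reproduces_study_statistic(self, battery):
        report, _ = battery
        chi = report["chi_square_modules"]
        assert chi.statistic == pytest.approx(6.386, abs=5e-4)
        assert chi.p_value == pytest.approx(0.041, abs=5e-4)

    def test_vertex_order_invariance(self, battery):
        report, part = battery
        datasets = generate(study_config(seed=3))
        universes = tuple(d.target_universe for d in datasets)
        tps = [project_targets(build_bipartite(d)) for d in datasets]
        master = integrate_master(*tps, universes)
        cent = centrality_table(master.formula_graph())
        shuffled = cent.sample(frac=1.0, random_state=1)
        report2 = validation_battery(part, shuffled)
        for key, res in report.items():
            if res.ok:
                assert report2[key].statistic == pytest.approx(
                    res.statistic, rel=1e-9
                ), key
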