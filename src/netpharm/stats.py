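"""Statistical validation battery for the target network.

Four families of tests check that the network's module structure and
centralities are not random: a Pearson chi-squared test on the
module-by-drug-target contingency table, two-sample t-tests of each
centrality split by the drug-target dummy, one-way ANOVAs of each
centrality across the formula modules, and Pearson correlations among the
three centralities. Conventions: no continuity correction on the
chi-squared statistic; pooled-variance Student t by default (Welch behind a
flag); asymptotic p-values throughout; undefined closeness values dropped
listwise per test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .centrality import centrality_table  # noqa: F401  (re-export convenience)
from .partition import ContingencyTable, ModulePartition, module_contingency

logger = logging.getLogger(__name__)

CENTRALITY_COLUMNS = ("degree", "betweenness", "closeness")


@dataclass
class TestResult:
    """One test's outcome: statistic, degrees of freedom, p-value, auxiliaries."""

    __test__ = False  # not a pytest collectible despite the name

    name: str
    statistic: float | None = None
    df: tuple[float, ...] = ()
    p_value: float | None = None
    auxiliaries: dict = field(default_factory=dict)
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def chi_square_test(tab: ContingencyTable) -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction.

    Auxiliaries: the expected-count table, minimum expected count, and the
    count/percentage of cells with expected count below 5.
    """
    observed = np.asarray(tab.observed, dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (observed < 0).any():
        raise ValueError("negative observed count")
    if observed.sum() <= 0:
        raise ValueError("empty contingency table")
    if (observed.sum(axis=1) == 0).any() or (observed.sum(axis=0) == 0).any():
        raise ValueError("zero row or column total: expected counts undefined")
    stat, p, dof, expected = sps.chi2_contingency(observed, correction=False)
    n_low = int((expected < 5).sum())
    return TestResult(
        name="chi_square",
        statistic=float(stat),
        df=(float(dof),),
        p_value=float(p),
        auxiliaries={
            "expected": expected,
            "min_expected": float(expected.min()),
            "n_cells_expected_lt_5": n_low,
            "pct_cells_expected_lt_5": 100.0 * n_low / expected.size,
        },
    )


def two_sample_t(group_a, group_b, variant: str = "pooled") -> TestResult:
    """Independent two-sample t-test (pooled Student by default, or Welch)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    aux = {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
           "n_a": len(a), "n_b": len(b), "variant": variant}
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if math.isclose(a.mean(), b.mean()):
            df = float(len(a) + len(b) - 2)
            return TestResult("t_test", 0.0, (df,), 1.0, aux)
        return TestResult("t_test", auxiliaries=aux,
                          error="degenerate: zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(
        name="t_test",
        statistic=float(res.statistic),
        df=(float(res.df),),
        p_value=float(res.pvalue),
        auxiliaries=aux,
    )


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA; df = (k-1, N-k)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 1 for g in arrays):
        raise ValueError("need >= 2 non-empty groups")
    n_total = sum(len(g) for g in arrays)
    if n_total - len(arrays) < 1 or not any(len(g) >= 2 for g in arrays):
        raise ValueError("need at least one group with >= 2 values")
    aux = {"group_means": [float(g.mean()) for g in arrays],
           "group_sizes": [len(g) for g in arrays]}
    within_var = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    means = np.array([g.mean() for g in arrays])
    if within_var == 0:
        if np.allclose(means, means[0]):
            df = (float(len(arrays) - 1), float(n_total - len(arrays)))
            return TestResult("anova", 0.0, df, 1.0, aux)
        return TestResult("anova", auxiliaries=aux,
                          error="degenerate: zero within-group variance, unequal means")
    f, p = sps.f_oneway(*arrays)
    return TestResult(
        name="anova",
        statistic=float(f),
        df=(float(len(arrays) - 1), float(n_total - len(arrays))),
        p_value=float(p),
        auxiliaries=aux,
    )


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with a two-sided t-based p on n - 2 degrees of freedom.

    Pairs where either value is NaN (e.g. undefined closeness) are dropped
    listwise before computing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        name="pearson",
        statistic=float(r),
        df=(float(len(x) - 2),),
        p_value=float(p),
        auxiliaries={"n": len(x)},
    )


FORMULA_MODULES = (
    "common_nodrug", "common_drug",
    "xzd_only_nodrug", "xzd_only_drug",
    "gxbd_only_nodrug", "gxbd_only_drug",
)


def validation_battery(
    partition: ModulePartition,
    centralities,
    t_variant: str = "pooled",
) -> dict[str, TestResult]:
    """Run the full battery and assemble one structured report.

    ``centralities`` is the per-vertex indicator table over the formula
    targets of ``partition``. The report holds 1 chi-squared + 3 t-tests
    (each centrality vs the drug-target dummy) + 3 ANOVAs (each centrality
    across the formula modules present) + 3 Pearson correlations = 10
    results; sub-test failures are recorded per test and do not stop the
    battery.
    """
    report: dict[str, TestResult] = {}

    def run(key, fn, *args, **kwargs):
        try:
            res = fn(*args, **kwargs)
        except (ValueError, ZeroDivisionError) as exc:
            res = TestResult(name=key, error=str(exc))
        res.name = key
        report[key] = res

    run("chi_square_modules", chi_square_test, module_contingency(partition))

    symbols = [s for s in centralities.index if s in partition.assignment]
    dummy = np.array([partition.is_drug_target(s) for s in symbols])
    modules = np.array([partition.assignment[s] for s in symbols])

    for col in CENTRALITY_COLUMNS:
        vals = centralities.loc[symbols, col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        run(
            f"t_{col}_by_drug_target",
            two_sample_t,
            vals[ok & ~dummy],
            vals[ok & dummy],
            variant=t_variant,
        )
    for col in CENTRALITY_COLUMNS:
        vals = centralities.loc[symbols, col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        groups = []
        for label in FORMULA_MODULES:
            g = vals[ok & (modules == label)]
            if len(g):
                groups.append(g)
            elif (modules == label).any():
                logger.info("module %s has no finite %s values; skipped", label, col)
            else:
                logger.info("module %s empty; skipped in ANOVA", label)
        run(f"anova_{col}_by_module", one_way_anova, groups)

    pairs = (("degree", "closeness"), ("degree", "betweenness"),
             ("closeness", "betweenness"))
    for a, b in pairs:
        run(
            f"pearson_{a}_{b}",
            pearson_correlation,
            centralities.loc[symbols, a].to_numpy(dtype=float),
            centralities.loc[symbols, b].to_numpy(dtype=float),
        )
    return report
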