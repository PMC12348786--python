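import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canopycc import anova_table, linear_r2, tukey_hsd


def normal_equations_fit(x, y):
    """Independent least-squares oracle via the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return beta[1], beta[0], 1.0 - ss_res / ss_tot


def balanced_table(rng, n_rep=3, treatment_shift=0.0):
    rows = []
    for sp in ("a", "b", "c"):
        for se in ("early", "middle", "late"):
            for tr in ("full", "drought"):
                for rep in range(1, n_rep + 1):
                    mu = 0.4 + (treatment_shift if tr == "drought" else 0.0)
                    rows.append(
                        dict(species=sp, season=se, treatment=tr, replicate=rep,
                             value=mu + rng.normal(0, 0.05))
                    )
    return pd.DataFrame(rows)


def test_perfect_linear_fit():
    x = np.arange(5.0)
    res = linear_r2(x, 2.0 * x)
    assert res.r2 == pytest.approx(1.0, abs=1e-12)
    assert res.slope == pytest.approx(2.0, abs=1e-12)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)


def test_linear_r2_matches_normal_equations_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = linear_r2(x, y)
        slope, intercept, r2 = normal_equations_fit(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)


def test_linear_r2_near_zero_under_independence():
    rng = np.random.default_rng(11)
    res = linear_r2(rng.normal(size=2000), rng.normal(size=2000))
    assert res.r2 < 0.01


def test_linear_r2_degenerate_inputs():
    with pytest.raises(ValueError, match="constant"):
        linear_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="constant"):
        linear_r2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(ValueError):
        linear_r2([1.0, 2.0], [1.0, 2.0])


def test_anova_degenerate_data_raises():
    table = balanced_table(np.random.default_rng(0))
    table["value"] = 0.4
    with pytest.raises(ValueError, match="degenerate"):
        anova_table(table, factors=("species", "season", "treatment"))


def test_anova_unbalanced_raises():
    table = balanced_table(np.random.default_rng(0)).iloc[:-1]
    with pytest.raises(ValueError, match="unbalanced"):
        anova_table(table, factors=("species", "season", "treatment"))


def test_single_factor_f_equals_squared_t():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
    table = pd.DataFrame(
        {"treatment": ["a"] * 12 + ["b"] * 12, "value": np.concatenate([a, b])}
    )
    res = anova_table(table, factors=("treatment",), block=None)
    t, p = stats.ttest_ind(a, b)
    assert res.frame.loc["treatment", "F"] == pytest.approx(t**2, rel=1e-10)
    assert res.frame.loc["treatment", "p"] == pytest.approx(p, rel=1e-10)


def test_partial_eta2_definition():
    rng = np.random.default_rng(4)
    table = balanced_table(rng, treatment_shift=0.08)
    res = anova_table(table, factors=("species", "season", "treatment"), block=None)
    row = res.frame.loc["treatment"]
    ss_effect = row["MS"] * row["df"]
    ss_error = res.error_ms * res.error_df
    assert row["partial_eta2"] == pytest.approx(ss_effect / (ss_effect + ss_error), rel=1e-9)
    assert 0.0 <= row["partial_eta2"] <= 1.0


def test_anova_invariant_to_row_order_and_relabeling():
    rng = np.random.default_rng(6)
    table = balanced_table(rng, treatment_shift=0.05)
    base = anova_table(table, factors=("species", "season", "treatment"))
    shuffled = table.sample(frac=1.0, random_state=1)
    relabeled = shuffled.assign(species=shuffled["species"].map({"a": "z1", "b": "z2", "c": "z3"}))
    again = anova_table(relabeled, factors=("species", "season", "treatment"))
    pd.testing.assert_frame_equal(base.frame, again.frame, check_exact=False, rtol=1e-10)


def test_anova_matches_statsmodels_two_way_f():
    """Independent check of the F statistics against a direct OLS decomposition."""
    rng = np.random.default_rng(8)
    table = balanced_table(rng, treatment_shift=0.06)
    res = anova_table(table, factors=("season", "treatment"), block=None)
    # brute-force sums of squares for a balanced additive two-way layout
    y = table["value"].to_numpy()
    grand = y.mean()
    ss = {}
    for f in ("season", "treatment"):
        means = table.groupby(f)["value"].mean()
        counts = table.groupby(f)["value"].size()
        ss[f] = float((counts * (means - grand) ** 2).sum())
    fitted = (
        table.groupby("season")["value"].transform("mean")
        + table.groupby("treatment")["value"].transform("mean")
        - grand
    )
    ss_err = float(((y - fitted) ** 2).sum())
    df_err = len(y) - 1 - (3 - 1) - (2 - 1)
    for f, df in (("season", 2), ("treatment", 1)):
        expected_f = (ss[f] / df) / (ss_err / df_err)
        assert res.frame.loc[f, "F"] == pytest.approx(expected_f, rel=1e-9)


def test_tukey_identical_groups():
    comps = tukey_hsd({"a": [1.0, 1.1, 0.9], "b": [1.0, 1.1, 0.9]})
    assert comps[0].mean_diff == pytest.approx(0.0)
    assert comps[0].p_adjusted == pytest.approx(1.0)


def test_tukey_two_groups_equals_t_test():
    rng = np.random.default_rng(9)
    a, b = rng.normal(0, 1, 10), rng.normal(0.7, 1, 10)
    comp = tukey_hsd({"a": a, "b": b})[0]
    _, p = stats.ttest_ind(a, b)
    assert comp.p_adjusted == pytest.approx(p, abs=1e-8)


def test_tukey_matches_scipy_three_groups():
    rng = np.random.default_rng(10)
    groups = {k: rng.normal(mu, 1, 8) for k, mu in (("a", 0.0), ("b", 0.5), ("c", 2.0))}
    ours = {frozenset((c.level_a, c.level_b)): c.p_adjusted for c in tukey_hsd(groups)}
    ref = stats.tukey_hsd(*groups.values())
    names = list(groups)
    for i in range(3):
        for j in range(i + 1, 3):
            assert ours[frozenset((names[i], names[j]))] == pytest.approx(
                ref.pvalue[i, j], abs=1e-8
            )
    # the far-separated pair has the smallest adjusted p
    assert min(ours, key=ours.get) == frozenset(("a", "c"))


def test_tukey_zero_variance_raises():
    with pytest.raises(ValueError, match="degenerate|zero"):
        tukey_hsd({"a": [1.0, 1.0], "b": [1.0, 1.0]})
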