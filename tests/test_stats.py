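"""Inference machinery: residualization, permutation t, FDR, demographics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from connstats import (
    adjust_covariates,
    chi_square_2x2,
    compare_groups,
    fdr_bh,
    mann_whitney,
    pearson_correlation,
    permutation_ttest,
    two_sample_t,
)
from connstats.stats import _pooled_t


# ---------- covariate residualization ----------

def test_residuals_orthogonal_to_covariates_and_zero_sum(rng):
    n = 60
    age = rng.uniform(18, 60, n)
    gender = rng.integers(0, 2, n).astype(float)
    y = rng.normal(size=n) + 0.1 * age - 0.5 * gender
    r = adjust_covariates(y, age, gender)
    assert abs(r.sum()) < 1e-8
    assert abs(r @ age) < 1e-6
    assert abs(r @ gender) < 1e-8


def test_metric_exactly_linear_in_age_residualizes_to_zero(rng):
    age = rng.uniform(18, 60, 20)
    gender = rng.integers(0, 2, 20).astype(float)
    r = adjust_covariates(2 * age, age, gender)
    assert np.allclose(r, 0, atol=1e-10)


def test_orthogonal_metric_residuals_are_centered_values(rng):
    # covariates constant -> dropped; residual = mean-centered metric
    y = rng.normal(size=10)
    r = adjust_covariates(y, np.full(10, 30.0), np.zeros(10))
    assert np.allclose(r, y - y.mean(), atol=1e-10)


# ---------- permutation t ----------

def exhaustive_permutation_p(values, n1):
    """Enumerate all group-1 index sets and count |t*| >= |t_obs|."""
    n = len(values)
    idx = np.arange(n)
    t_obs = _pooled_t(values[:n1], values[n1:])
    count = total = 0
    for combo in itertools.combinations(idx, n1):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        t = _pooled_t(values[mask], values[~mask])
        total += 1
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    return t_obs, count / total


def test_sampled_permutation_p_matches_exhaustive_enumeration(rng):
    values = rng.normal(size=7)
    groups = np.array(["A"] * 4 + ["B"] * 3)
    t_obs, p_exact = exhaustive_permutation_p(values, 4)
    t_hat, p_hat = permutation_ttest(values, groups, n_perm=5000, seed=1)
    assert t_hat == pytest.approx(t_obs, abs=1e-12)
    assert p_hat == pytest.approx(p_exact, abs=0.05)


def test_extreme_separation_gives_tiny_p(rng):
    x = rng.normal(0, 1, 20)
    y = rng.normal(10, 1, 20)
    groups = np.array(["A"] * 20 + ["B"] * 20)
    _, p = permutation_ttest(np.concatenate([x, y]), groups, n_perm=10_000, seed=2)
    assert p <= 0.001


def test_permutation_p_invariant_to_affine_transform(rng):
    values = rng.normal(size=24)
    groups = np.array(["A"] * 12 + ["B"] * 12)
    _, p1 = permutation_ttest(values, groups, n_perm=2000, seed=5)
    _, p2 = permutation_ttest(7.5 * values - 3.0, groups, n_perm=2000, seed=5)
    assert p1 == p2


def test_identical_groups_give_t_zero(rng):
    half = rng.normal(size=10)
    values = np.concatenate([half, half])
    groups = np.array(["A"] * 10 + ["B"] * 10)
    t, _ = permutation_ttest(values, groups, n_perm=100, seed=0)
    assert t == pytest.approx(0.0, abs=1e-12)


def test_degenerate_zero_variance_errors():
    values = np.ones(8)
    groups = np.array(["A"] * 4 + ["B"] * 4)
    with pytest.raises(ValueError, match="variance"):
        permutation_ttest(values, groups, n_perm=10, seed=0)


# ---------- FDR ----------

def test_bh_hand_example():
    assert np.allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_edge_cases():
    assert fdr_bh([0.2]) == pytest.approx([0.2])
    assert np.allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)


def test_bh_reordering_permutes_output_identically(rng):
    p = rng.uniform(size=15)
    perm = rng.permutation(15)
    assert np.allclose(fdr_bh(p)[perm], fdr_bh(p[perm]))


def test_bh_adjusted_never_below_raw(rng):
    p = rng.uniform(size=30)
    q = fdr_bh(p)
    assert np.all(q >= p - 1e-15) and np.all(q <= 1)


# ---------- chi-square ----------

def test_chi_square_printed_gender_table():
    table = [[29, 52], [14, 34]]
    assert chi_square_2x2(table) == pytest.approx(0.597, abs=5e-4)
    assert chi_square_2x2(table, yates=True) == pytest.approx(0.336, abs=5e-4)


def test_chi_square_matches_scipy():
    table = [[29, 52], [14, 34]]
    chi_plain = sps.chi2_contingency(np.array(table), correction=False)[0]
    chi_yates = sps.chi2_contingency(np.array(table), correction=True)[0]
    assert chi_square_2x2(table) == pytest.approx(chi_plain, abs=1e-12)
    assert chi_square_2x2(table, yates=True) == pytest.approx(chi_yates, abs=1e-12)


def test_chi_square_homogeneous_table_is_zero():
    assert chi_square_2x2([[10, 10], [10, 10]]) == 0.0


def test_chi_square_invariances_and_errors():
    t = np.array([[7, 3], [2, 9]])
    assert chi_square_2x2(t) == pytest.approx(chi_square_2x2(t.T))
    assert chi_square_2x2(t) == pytest.approx(chi_square_2x2(t[::-1]))
    with pytest.raises(ValueError, match="margin"):
        chi_square_2x2([[0, 0], [3, 4]])


# ---------- t / Mann-Whitney / Pearson ----------

def test_two_sample_t_matches_scipy_formula(rng):
    x, y = rng.normal(size=12), rng.normal(1, 2, size=9)
    assert two_sample_t(x, y) == pytest.approx(
        sps.ttest_ind(x, y, equal_var=True).statistic, abs=1e-12
    )
    assert two_sample_t(x, y, pooled=False) == pytest.approx(
        sps.ttest_ind(x, y, equal_var=False).statistic, abs=1e-12
    )
    assert two_sample_t(x, x) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        two_sample_t([0.0, 0.0], [1.0, 1.0])


def mann_whitney_brute_force_u(x, y):
    wins = sum(xi > yi for xi in x for yi in y)
    ties = sum(xi == yi for xi in x for yi in y)
    return wins + 0.5 * ties


def test_mann_whitney_u_matches_pairwise_enumeration(rng):
    for _ in range(10):
        x = rng.integers(0, 8, size=9).astype(float)  # integer values force ties
        y = rng.integers(0, 8, size=7).astype(float)
        U, z = mann_whitney(x, y)
        assert U == pytest.approx(mann_whitney_brute_force_u(x, y))
        assert np.isfinite(z)


def test_mann_whitney_complete_separation_and_tie_degenerate():
    U, _ = mann_whitney([1.0, 2.0], [5.0, 6.0])
    assert U == 0.0
    U, z = mann_whitney([3.0, 3.0], [3.0, 3.0])
    assert np.isnan(z)


def test_pearson_correlation_exact_lines_and_formula(rng):
    x = rng.normal(size=20)
    assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)
    y = rng.normal(size=20)
    r, p = pearson_correlation(x, y)
    r_manual = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
    assert r == pytest.approx(r_manual, abs=1e-12)
    with pytest.raises(ValueError):
        pearson_correlation(x, np.zeros(20))


# ---------- family-level comparison ----------

def _toy_table(rng, n1=15, n2=12, shift=0.0):
    n = n1 + n2
    return pd.DataFrame(
        {
            "group": ["PD"] * n1 + ["HC"] * n2,
            "age": rng.uniform(18, 60, n),
            "gender_code": rng.integers(0, 2, n),
            "m1": np.concatenate([rng.normal(shift, 1, n1), rng.normal(0, 1, n2)]),
            "m2": rng.normal(size=n),
        }
    )


def test_compare_groups_reports_raw_scale_summaries_and_fdr(rng):
    tbl = _toy_table(rng, shift=3.0)
    res = compare_groups(tbl, ["m1", "m2"], n_perm=2000, seed=7)
    r1 = next(r for r in res if r.metric_name == "m1")
    assert r1.mean_pd == pytest.approx(tbl.loc[tbl.group == "PD", "m1"].mean())
    assert r1.sd_hc == pytest.approx(tbl.loc[tbl.group == "HC", "m1"].std(ddof=1))
    assert r1.observed_t > 0  # PD - HC sign convention
    for r in res:
        assert r.p_fdr >= r.p_perm
        assert 0 < r.p_perm <= 1


def test_compare_groups_identical_groups_t_zero(rng):
    n = 10
    half = rng.normal(size=n)
    tbl = pd.DataFrame(
        {
            "group": ["PD"] * n + ["HC"] * n,
            "age": np.tile(rng.uniform(18, 60, n), 2),
            "gender_code": np.tile(rng.integers(0, 2, n), 2),
            "m": np.concatenate([half, half]),
        }
    )
    res = compare_groups(tbl, ["m"], n_perm=200, seed=1)
    assert res[0].observed_t == pytest.approx(0.0, abs=1e-10)


def test_compare_groups_seed_reproducible(rng):
    tbl = _toy_table(rng)
    a = compare_groups(tbl, ["m1", "m2"], n_perm=500, seed=42)
    b = compare_groups(tbl, ["m1", "m2"], n_perm=500, seed=42)
    assert [(r.observed_t, r.p_perm, r.p_fdr) for r in a] == [
        (r.observed_t, r.p_perm, r.p_fdr) for r in b
    ]
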