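"""Statistical layer against independent oracles (closed forms, scipy, SVD)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from morpholink.association import (
    anova_tukey,
    assemble_report,
    benjamini_hochberg,
    pairwise_linear,
    pca,
    pearson,
    pls2,
    spearman,
    standardize,
    tukey_fwer_simulation,
)
from morpholink.synthetic import CohortSpec, default_cohort_spec, generate_cohort


# --- pairwise linear fits ---------------------------------------------------

def test_exact_linear_relation():
    x = np.arange(6.0)
    fit = pairwise_linear(x, 2 * x + 1)
    assert fit["slope"] == pytest.approx(2.0)
    assert fit["intercept"] == pytest.approx(1.0)
    assert fit["r_squared"] == pytest.approx(1.0)
    assert fit["p_linear"] == 0.0


def test_constant_y_gives_zero_r2_and_constant_x_flagged():
    x = np.arange(5.0)
    assert pairwise_linear(x, np.ones(5))["r_squared"] == 0.0
    fit = pairwise_linear(np.ones(5), x)
    assert fit["degenerate"] and math.isnan(fit["r_squared"])


def test_five_point_fit_matches_normal_equations_oracle():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 6])
    fit = pairwise_linear(x, y)
    # independent oracle: solve the normal equations and F-test directly
    X = np.column_stack([np.ones(5), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    f_stat = (ss_tot - ss_res) / (ss_res / 3)
    p = stats.f.sf(f_stat, 1, 3)
    assert fit["slope"] == pytest.approx(beta[1], abs=1e-10)
    assert fit["intercept"] == pytest.approx(beta[0], abs=1e-10)
    assert fit["r_squared"] == pytest.approx(r2, abs=1e-10)
    assert fit["p_linear"] == pytest.approx(p, abs=1e-10)


def test_r_squared_equals_pearson_squared(rng):
    x = rng.normal(size=30)
    y = 0.5 * x + rng.normal(size=30)
    assert pairwise_linear(x, y)["r_squared"] == pytest.approx(pearson(x, y) ** 2, abs=1e-10)


# --- rank correlations ------------------------------------------------------

def test_spearman_monotone_nonlinear():
    x = np.arange(1.0, 11.0)
    rho, _ = spearman(x, x**3)
    assert rho == pytest.approx(1.0)
    assert pearson(x, x**3) < 1.0
    rho_neg, _ = spearman(x, -x)
    assert rho_neg == pytest.approx(-1.0)
    assert pearson(x, -x) == pytest.approx(-1.0)


def test_spearman_ties_match_rank_then_pearson_oracle():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([1.0, 1.0, 2.0])
    rho, _ = spearman(x, y)
    oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
    assert rho == oracle


def test_spearman_exact_permutation_p_matches_enumeration():
    x = np.array([1.0, 2, 3, 4, 5, 6])
    y = np.array([2.0, 1, 4, 3, 6, 5])
    rho, p = spearman(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = sum(
        abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
        for perm in itertools.permutations(ry)
    )
    assert p == pytest.approx(hits / math.factorial(6), abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_spearman_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    rho, _ = spearman(x, y)
    rho_t, _ = spearman(np.exp(x), y**3)
    assert rho_t == pytest.approx(rho, abs=1e-12)


def test_constant_input_flagged():
    assert math.isnan(pearson(np.ones(5), np.arange(5.0)))
    rho, p = spearman(np.ones(5), np.arange(5.0))
    assert math.isnan(rho) and math.isnan(p)


# --- ANOVA + Tukey ----------------------------------------------------------

def test_identical_groups_no_significance():
    g = np.arange(10.0)
    res = anova_tukey({"a": g, "b": g.copy()})
    assert res.significant_pairs() == set()
    assert all(v == "" for v in res.letters.values())


def test_extreme_separation_is_significant(rng):
    res = anova_tukey(
        {"lo": rng.normal(0, 0.01, 10), "hi": rng.normal(10, 0.01, 10)}
    )
    assert res.significant_pairs() == {("hi", "lo")}
    assert res.letters["lo"] == "b" and res.letters["hi"] == "a"


def test_tukey_p_matches_studentized_range_oracle(rng):
    """Adjusted p agrees with scipy's independent Tukey HSD implementation
    (its own studentized-range integration) to 1e-6."""
    groups = {
        "a": rng.normal(0.0, 1.0, 12),
        "b": rng.normal(0.6, 1.0, 15),
        "c": rng.normal(-0.4, 1.0, 9),
    }
    res = anova_tukey(groups)
    oracle = stats.tukey_hsd(*groups.values())
    pairs = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
    for _, row in res.comparisons.iterrows():
        i, j = pairs[(row["group_1"], row["group_2"])]
        assert row["p_adj"] == pytest.approx(oracle.pvalue[i, j], abs=1e-6)


def test_small_group_excluded_with_warning(rng):
    with pytest.warns(UserWarning, match="excluded"):
        res = anova_tukey({"a": rng.normal(size=5), "b": rng.normal(size=6), "tiny": [1.0]})
    assert res.excluded == ["tiny"]
    assert set(res.letters) == {"a", "b"}


def test_letters_symmetric_six_groups(rng):
    groups = {g: rng.normal(loc, 0.5, 12) for g, loc in zip("abcdef", [0, 0.1, 3, 3.1, 6, 6.1])}
    res = anova_tukey(groups)
    for _, row in res.comparisons.iterrows():
        g1, g2 = row["group_1"], row["group_2"]
        in_1 = res.group_letters[g2] in res.letters[g1]
        in_2 = res.group_letters[g1] in res.letters[g2]
        assert in_1 == in_2 == (row["p_adj"] < 0.05)


def test_tukey_familywise_error_calibrated():
    fwer = tukey_fwer_simulation(n_groups=6, n_per_group=20, n_sims=2000, seed=77)
    assert fwer == pytest.approx(0.05, abs=0.015)


# --- PCA --------------------------------------------------------------------

def test_pca_perfectly_correlated_columns(rng):
    x = rng.normal(size=20)
    X = pd.DataFrame({"a": x, "b": 2 * x + 1})
    res = pca(X)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_loadings_orthonormal_and_ratios_sum_to_one(rng):
    X = pd.DataFrame(rng.normal(size=(15, 6)))
    res = pca(X)
    L = res.loadings.to_numpy()
    assert np.abs(L.T @ L - np.eye(L.shape[1])).max() < 1e-8
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)


def test_pca_matches_svd_oracle(rng):
    X = pd.DataFrame(rng.normal(size=(12, 5)))
    res = pca(X, standardize_cols=True)
    Z = standardize(X).to_numpy()
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    for k in range(res.loadings.shape[1]):
        v = Vt[k]
        l = res.loadings.iloc[:, k].to_numpy()
        assert min(np.abs(l - v).max(), np.abs(l + v).max()) < 1e-8
        t = res.scores.iloc[:, k].to_numpy()
        s = U[:, k] * S[k]
        assert min(np.abs(t - s).max(), np.abs(t + s).max()) < 1e-8


def test_pca_constant_column_error(rng):
    X = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
    with pytest.raises(ValueError, match="constant"):
        pca(X, standardize_cols=True)


# --- PLS2 -------------------------------------------------------------------

@pytest.fixture()
def xy(rng):
    X = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
    Y = pd.DataFrame(
        rng.normal(size=(10, 2)) + X[["a", "b"]].to_numpy() * 0.8, columns=["u", "v"]
    )
    return X, Y


def test_pls_univariate_y_weight_closed_form(rng):
    X = pd.DataFrame(rng.normal(size=(12, 4)))
    y = pd.DataFrame({"y": X.iloc[:, 0] * 0.5 + rng.normal(size=12)})
    model = pls2(X, y, n_components=1)
    Z = standardize(X).to_numpy()
    yz = standardize(y).to_numpy().ravel()
    w_oracle = Z.T @ yz
    w_oracle /= np.linalg.norm(w_oracle)
    w = model.x_weights.iloc[:, 0].to_numpy()
    assert min(np.abs(w - w_oracle).max(), np.abs(w + w_oracle).max()) < 1e-8


def test_pls_first_weight_is_dominant_singular_vector(xy):
    X, Y = xy
    model = pls2(X, Y, n_components=2)
    U, _, _ = np.linalg.svd(standardize(X).to_numpy().T @ standardize(Y).to_numpy())
    w1 = model.x_weights.iloc[:, 0].to_numpy()
    assert min(np.abs(w1 - U[:, 0]).max(), np.abs(w1 + U[:, 0]).max()) < 1e-8


def test_pls_scores_orthogonal_and_full_deflation(xy):
    X, Y = xy
    model = pls2(X, Y, n_components=3)
    T = model.x_scores.to_numpy()
    gram = T.T @ T
    assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-8
    full = pls2(X, Y, n_components=5)  # k = rank(X)
    assert full.x_residual_norm < 1e-8


def test_pls_agrees_with_sklearn_cross_check(xy):
    X, Y = xy
    model = pls2(X, Y, n_components=2)
    from sklearn.cross_decomposition import PLSRegression

    sk = PLSRegression(n_components=2, scale=True, tol=1e-10).fit(X, Y)
    for k in range(2):
        a = model.x_weights.iloc[:, k].to_numpy()
        b = sk.x_weights_[:, k]
        # agreement is limited by sklearn's own inner-loop stopping rule
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-4


def test_pls_validation(xy):
    X, Y = xy
    with pytest.raises(ValueError):
        pls2(X, Y, n_components=20)
    with pytest.raises(ValueError):
        pls2(X, Y.reset_index(drop=True).set_index(pd.Index(range(1, 11))), n_components=1)


# --- report assembly --------------------------------------------------------

def test_report_grid_shape_and_planted_signs():
    spec = default_cohort_spec(n_lines=30, noise_sd=0.0, seed=9)
    features, outcomes = generate_cohort(spec)
    report = assemble_report(features, outcomes, n_components=2)
    assert len(report.cells) == features.shape[1] * outcomes.shape[1]
    # noiseless planting: every spearman is exactly +/-1 with the planted sign
    rho = report.spearman_rho
    assert np.allclose(np.abs(rho.to_numpy()), 1.0)
    signs = spec.planted_signs.loc[rho.index, rho.columns]
    assert np.array_equal(np.sign(rho.to_numpy()), signs.to_numpy())


def test_report_small_grid_count(rng):
    features = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("fgh"))
    outcomes = pd.DataFrame(rng.normal(size=(8, 2)), columns=list("uv"))
    report = assemble_report(features, outcomes, n_components=2)
    assert report.grid.shape[0] == 6
    assert report.r_squared.shape == (3, 2)


def test_report_misaligned_rows_error(rng):
    features = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
    outcomes = pd.DataFrame(rng.normal(size=(6, 2)), index=list("abcdeX"))
    with pytest.raises(ValueError, match="row index"):
        assemble_report(features, outcomes)


def test_benjamini_hochberg_adjustment():
    p = np.array([0.01, 0.04, 0.03, 0.005])
    adj = benjamini_hochberg(p)
    # oracle: statsmodels' implementation
    from statsmodels.stats.multitest import multipletests

    _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(adj, adj_sm)
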