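"""Association layer: which in vitro metric tracks in vivo outcome?

With a handful of cell lines as the statistical unit (per-line means of
each assay), the analysis is deliberately simple and exhaustive: for every
feature x outcome pair an ordinary least-squares fit (slope, R², F-test p),
Pearson's r and Spearman's rho (average ranks, exact permutation null for
n <= 8); one-way ANOVA with Tukey's HSD and compact letter annotations for
per-cell group comparisons; PCA for unsupervised structure; and a
two-block partial least squares (PLS2, NIPALS algorithm) whose X-scores
and loadings display how cell lines and variables co-project on the
covariance-maximizing components.

Columns are z-scored (n-1 sd) before PCA/PLS because the features mix
units (µm², µm/min, unit-free ratios).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# simple pairwise statistics

@dataclass
class AssociationCell:
    """All pairwise statistics for one feature x outcome pair."""

    feature: str
    outcome: str
    slope: float
    intercept: float
    r_squared: float
    p_linear: float  # F-test (1, n-2) of the OLS fit
    pearson_r: float
    spearman_rho: float
    spearman_p: float
    n: int
    degenerate: bool = False  # constant x: fit/correlations undefined


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """z-score each column with the n-1 sd convention."""
    sd = df.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"cannot standardize constant column(s): {bad}")
    return (df - df.mean()) / sd


def pairwise_linear(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """OLS fit of y on x: slope, intercept, R², F-test p with (1, n-2) df.

    Constant x makes the fit undefined (NaNs, ``degenerate=True``);
    constant y gives a flat fit with R² = 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need >= 3 paired observations")
    out = {"n": n, "degenerate": False}
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        return {**out, "slope": np.nan, "intercept": np.nan, "r_squared": np.nan,
                "p_linear": np.nan, "degenerate": True}
    syy = ((y - y.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    if syy == 0:
        return {**out, "slope": 0.0, "intercept": y.mean(), "r_squared": 0.0, "p_linear": 1.0}
    r2 = sxy**2 / (sxx * syy)
    if r2 >= 1.0:
        p = 0.0
    else:
        f_stat = r2 / (1.0 - r2) * (n - 2)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return {**out, "slope": slope, "intercept": intercept, "r_squared": float(r2), "p_linear": p}


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient; NaN for a constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 pairs")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


#: sample size at or below which the Spearman null is enumerated exactly
SPEARMAN_EXACT_N = 8


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman's rho with average ranks, and its two-sided p-value.

    rho is Pearson's r on average-ranked data.  The p-value enumerates all
    n! rank permutations for n <= 8 and uses the usual t-approximation
    with n-2 df for larger samples.  Constant input gives (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need >= 3 pairs")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_N:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
        observed = abs(rho)
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs((rxc * ryc[list(perm)]).sum() / denom)
            hits += r >= observed - 1e-12
            total += 1
        return rho, hits / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD with compact letter annotations

@dataclass
class TukeyResult:
    """One-way ANOVA with all-pairs Tukey-Kramer comparisons.

    ``letters`` maps each group to the letters of the *other* groups it
    differs from at the chosen alpha (the annotation convention used on
    multi-line bar charts: group a's bar annotated "bc" differs from the
    groups labelled b and c).
    """

    anova_f: float
    anova_p: float
    comparisons: pd.DataFrame  # group_1, group_2, mean_diff, q, p_adj
    letters: dict[str, str]
    group_letters: dict[str, str]
    alpha: float
    excluded: list[str] = field(default_factory=list)

    def significant_pairs(self) -> set[tuple[str, str]]:
        sig = self.comparisons[self.comparisons["p_adj"] < self.alpha]
        return {tuple(sorted(p)) for p in zip(sig["group_1"], sig["group_2"])}


def _tukey_q_stats(
    means: np.ndarray, ns: np.ndarray, mse: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Studentized-range statistics for all group pairs (Tukey-Kramer)."""
    k = means.size
    ii, jj = np.triu_indices(k, 1)
    se = np.sqrt(mse / 2.0 * (1.0 / ns[ii] + 1.0 / ns[jj]))
    q = np.abs(means[ii] - means[jj]) / se
    return ii, jj, q


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA plus Tukey's HSD over all group pairs.

    Adjusted p-values come from the studentized range distribution with
    the Tukey-Kramer unequal-n standard error.  Groups with fewer than 2
    observations are excluded with a warning.
    """
    kept: dict[str, np.ndarray] = {}
    excluded = []
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            warnings.warn(f"group {name!r} has < 2 observations; excluded", stacklevel=2)
            excluded.append(name)
        else:
            kept[name] = values
    if len(kept) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    names = list(kept)
    arrays = [kept[g] for g in names]
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    n_total = int(ns.sum())
    k = len(names)
    df_within = n_total - k
    sse = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    mse = sse / df_within
    f_stat, anova_p = stats.f_oneway(*arrays)
    if mse == 0:
        # all-identical groups: no variability, nothing can differ
        ii, jj = np.triu_indices(k, 1)
        q = np.where(means[ii] == means[jj], 0.0, np.inf)
        p_adj = np.where(np.isinf(q), 0.0, 1.0)
        anova_p = 1.0 if np.allclose(means, means[0]) else 0.0
    else:
        ii, jj, q = _tukey_q_stats(means, ns, mse)
        p_adj = stats.studentized_range.sf(q, k, df_within)
    comparisons = pd.DataFrame(
        {
            "group_1": [names[i] for i in ii],
            "group_2": [names[j] for j in jj],
            "mean_diff": means[ii] - means[jj],
            "q": q,
            "p_adj": np.clip(p_adj, 0.0, 1.0),
        }
    )
    group_letters = {g: chr(ord("a") + i) for i, g in enumerate(names)}
    letters = {g: "" for g in names}
    for _, row in comparisons.iterrows():
        if row["p_adj"] < alpha:
            letters[row["group_1"]] += group_letters[row["group_2"]]
            letters[row["group_2"]] += group_letters[row["group_1"]]
    letters = {g: "".join(sorted(v)) for g, v in letters.items()}
    return TukeyResult(
        anova_f=float(f_stat),
        anova_p=float(anova_p),
        comparisons=comparisons,
        letters=letters,
        group_letters=group_letters,
        alpha=alpha,
        excluded=excluded,
    )


def tukey_fwer_simulation(
    n_groups: int = 6,
    n_per_group: int = 20,
    n_sims: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Familywise error rate of Tukey's HSD under a global null.

    Simulates ``n_sims`` balanced one-way layouts of pure N(0, 1) noise and
    reports the fraction in which any pair is declared significant.  Under
    correct calibration this should sit at ``alpha``.  Uses the same
    studentized-range statistic as :func:`anova_tukey`, compared against a
    single critical quantile so thousands of simulations stay cheap.
    """
    rng = np.random.default_rng(seed)
    df_within = n_groups * (n_per_group - 1)
    q_crit = stats.studentized_range.ppf(1.0 - alpha, n_groups, df_within)
    data = rng.normal(size=(n_sims, n_groups, n_per_group))
    means = data.mean(axis=2)
    sse = ((data - means[..., None]) ** 2).sum(axis=(1, 2))
    mse = sse / df_within
    ns = np.full(n_groups, n_per_group)
    rejections = 0
    for s in range(n_sims):
        _, _, q = _tukey_q_stats(means[s], ns, mse[s])
        rejections += bool((q > q_crit).any())
    return rejections / n_sims


# ---------------------------------------------------------------------------
# PCA and PLS2

@dataclass
class PCAResult:
    scores: pd.DataFrame  # lines x components
    loadings: pd.DataFrame  # variables x components, orthonormal columns
    explained_variance_ratio: np.ndarray


def pca(X: pd.DataFrame, standardize_cols: bool = True, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of a feature matrix.

    Columns are z-scored by default (mixed units).  Explained-variance
    fractions are taken over all components, so they sum to 1.
    """
    from sklearn.decomposition import PCA as _PCA

    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    Z = standardize(X) if standardize_cols else X - X.mean()
    k_full = min(Z.shape)
    model = _PCA(n_components=k_full).fit(Z.to_numpy())
    k = k_full if n_components is None else min(n_components, k_full)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = model.transform(Z.to_numpy())[:, :k]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_[:k].T, index=X.columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_[:k],
    )


@dataclass
class PLSModel:
    """Two-block PLS (NIPALS) decomposition.

    x_scores (T) have mutually orthogonal columns; x_weights (W) are unit
    vectors; the first weight is proportional to the dominant left
    singular vector of X'Y, the covariance-maximizing direction.
    """

    x_scores: pd.DataFrame  # T, lines x k
    x_loadings: pd.DataFrame  # P, X-variables x k
    y_loadings: pd.DataFrame  # Q, Y-variables x k
    x_weights: pd.DataFrame  # W, X-variables x k
    n_components: int
    x_mean: pd.Series
    x_sd: pd.Series
    y_mean: pd.Series
    y_sd: pd.Series
    x_residual_norm: float


def pls2(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_components: int = 2,
    standardize_cols: bool = True,
    max_iter: int = 1000,
    tol: float = 1e-26,
) -> PLSModel:
    """Two-block partial least squares via NIPALS with X-deflation.

    Per component: iterate w = X'u/||X'u||, t = Xw, q = Y't/t't, u = Yq/q'q
    to convergence, then deflate X by t p' (p = X't/t't) and Y by t q'.
    Both blocks are z-scored by default.

    Raises RuntimeError with diagnostics if the inner iteration fails to
    converge within ``max_iter``.
    """
    if X.shape[0] < 3:
        raise ValueError("need >= 3 rows")
    if not X.index.equals(Y.index):
        raise ValueError("X and Y must share an identical row index")
    k_max = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= k_max):
        raise ValueError(f"n_components must lie in [1, {k_max}]")
    x_mean, y_mean = X.mean(), Y.mean()
    if standardize_cols:
        x_sd, y_sd = X.std(ddof=1), Y.std(ddof=1)
        if (x_sd == 0).any() or (y_sd == 0).any():
            raise ValueError("constant column: cannot standardize")
    else:
        x_sd = pd.Series(1.0, index=X.columns)
        y_sd = pd.Series(1.0, index=Y.columns)
    Xc = ((X - x_mean) / x_sd).to_numpy()
    Yc = ((Y - y_mean) / y_sd).to_numpy()
    T, P, Q, W = [], [], [], []
    for comp in range(n_components):
        u = Yc[:, [np.argmax(Yc.var(axis=0))]]
        t_old = None
        for it in range(max_iter):
            w = Xc.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w < 1e-300:
                raise RuntimeError(f"component {comp + 1}: X block exhausted (zero weight vector)")
            w /= norm_w
            t = Xc @ w
            q = Yc.T @ t / (t.T @ t)
            u = Yc @ q / (q.T @ q)
            if t_old is not None and float(np.sum((t - t_old) ** 2)) < tol * float(np.sum(t**2)):
                break
            t_old = t
        else:
            raise RuntimeError(
                f"NIPALS failed to converge for component {comp + 1} after {max_iter} "
                f"iterations (last score change {float(np.sum((t - t_old) ** 2)):.3e})"
            )
        p = Xc.T @ t / (t.T @ t)
        Xc = Xc - t @ p.T
        Yc = Yc - t @ q.T
        T.append(t)
        P.append(p)
        Q.append(q)
        W.append(w)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PLSModel(
        x_scores=pd.DataFrame(np.hstack(T), index=X.index, columns=comp_names),
        x_loadings=pd.DataFrame(np.hstack(P), index=X.columns, columns=comp_names),
        y_loadings=pd.DataFrame(np.hstack(Q), index=Y.columns, columns=comp_names),
        x_weights=pd.DataFrame(np.hstack(W), index=X.columns, columns=comp_names),
        n_components=n_components,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        x_residual_norm=float(np.linalg.norm(Xc)),
    )


# ---------------------------------------------------------------------------
# full report

@dataclass
class AssociationReport:
    """Feature x outcome association grids plus PCA/PLS tables."""

    cells: list[AssociationCell]
    grid: pd.DataFrame  # long form, one row per feature x outcome
    r_squared: pd.DataFrame  # features x outcomes
    spearman_rho: pd.DataFrame
    pca: PCAResult
    pls: PLSModel

    def rank_by_abs_spearman(self, outcome: str) -> pd.Series:
        """Features sorted by |rho| against one outcome, descending."""
        sub = self.grid[self.grid["outcome"] == outcome].set_index("feature")
        return sub["spearman_rho"].abs().sort_values(ascending=False)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up), preserving input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def assemble_report(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    n_components: int = 2,
    standardize_cols: bool = True,
    bh_correct: bool = False,
) -> AssociationReport:
    """Every feature x outcome AssociationCell, plus PCA and PLS2 tables.

    ``features`` and ``outcomes`` must share an identical row index (cell
    lines).  P-values are reported raw per cell by default; set
    ``bh_correct`` to add Benjamini-Hochberg adjusted columns.
    """
    if not features.index.equals(outcomes.index):
        raise ValueError("feature and outcome matrices must share an identical row index")
    cells = []
    for f in features.columns:
        for o in outcomes.columns:
            x = features[f].to_numpy()
            y = outcomes[o].to_numpy()
            fit = pairwise_linear(x, y)
            rho, rho_p = spearman(x, y) if not fit["degenerate"] else (np.nan, np.nan)
            cells.append(
                AssociationCell(
                    feature=f,
                    outcome=o,
                    slope=fit["slope"],
                    intercept=fit["intercept"],
                    r_squared=fit["r_squared"],
                    p_linear=fit["p_linear"],
                    pearson_r=pearson(x, y),
                    spearman_rho=rho,
                    spearman_p=rho_p,
                    n=fit["n"],
                    degenerate=fit["degenerate"],
                )
            )
    grid = pd.DataFrame([vars(c) for c in cells])
    if bh_correct:
        grid["p_linear_bh"] = benjamini_hochberg(grid["p_linear"].to_numpy())
        grid["spearman_p_bh"] = benjamini_hochberg(grid["spearman_p"].to_numpy())
    pca_res = pca(features, standardize_cols=standardize_cols)
    pls_res = pls2(features, outcomes, n_components=n_components, standardize_cols=standardize_cols)
    return AssociationReport(
        cells=cells,
        grid=grid,
        r_squared=grid.pivot(index="feature", columns="outcome", values="r_squared"),
        spearman_rho=grid.pivot(index="feature", columns="outcome", values="spearman_rho"),
        pca=pca_res,
        pls=pls_res,
    )
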