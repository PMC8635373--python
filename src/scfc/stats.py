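"""Inferential layer: ANCOVA, post-hoc contrasts, edgewise tests,
behavior correlations, and the two-independent-correlations test.

The group test is a partial F test of the diagnostic-group factor in a
linear model with age and a 0/1 sex indicator as covariates:

    F = ((SSE_reduced - SSE_full) / (k - 1)) / (SSE_full / (n - p_full))

Edgewise contrasts run a Welch two-sample t per connection with
Benjamini-Hochberg FDR over the tested edge set.  The comparison of two
correlations from independent groups uses the Fisher r-to-z statistic

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from scfc.graph import bh_reject
from scfc.matrices import ConnectivityMatrix

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p: float
    group_means: dict[str, float] = field(default_factory=dict)
    group_sems: dict[str, float] = field(default_factory=dict)
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class CorrDiffResult:
    """Fisher r-to-z comparison of two independent correlations."""

    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float


def _encode_sex(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "OUS":
        return np.array([1.0 if str(s).lower().startswith("m") else 0.0 for s in arr])
    return arr.astype(float)


def _sse(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def _group_summary(y, group):
    means, sems = {}, {}
    for g in pd.unique(np.asarray(group)):
        vals = y[np.asarray(group) == g]
        means[g] = float(vals.mean())
        sems[g] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    return means, sems


def ancova_group_test(y, group, age, sex) -> StatResult:
    """Partial F test for the group factor, adjusting for age and sex.

    Full model: intercept + group dummies + age + sex; reduced model drops
    the group dummies.  Reports raw per-group means and SEMs.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    age = np.asarray(age, dtype=float)
    sex01 = _encode_sex(sex)
    n = len(y)
    levels = list(pd.unique(group))
    if len(levels) < 2:
        raise ValueError("ANCOVA needs >= 2 groups")
    counts = [(group == g).sum() for g in levels]
    if min(counts) < 2:
        raise ValueError("each group needs >= 2 subjects")
    dummies = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    ones = np.ones((n, 1))
    x_full = np.hstack([ones, dummies, age[:, None], sex01[:, None]])
    x_red = np.hstack([ones, age[:, None], sex01[:, None]])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("singular ANCOVA design")
    sse_f, sse_r = _sse(x_full, y), _sse(x_red, y)
    df_num = len(levels) - 1
    df_den = n - x_full.shape[1]
    if sse_f <= 0:
        f_stat = 0.0 if sse_r - sse_f <= 1e-30 else np.inf
    else:
        f_stat = ((sse_r - sse_f) / df_num) / (sse_f / df_den)
    f_stat = max(f_stat, 0.0)
    p = float(sps.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0
    means, sems = _group_summary(y, group)
    return StatResult(
        test="ancova_group",
        statistic=float(f_stat),
        df=(df_num, df_den),
        p=p,
        group_means=means,
        group_sems=sems,
    )


def _covariate_adjusted(y, covs) -> np.ndarray:
    """Residuals of y on [1, covariates], plus the grand mean."""
    n = len(y)
    x = np.hstack([np.ones((n, 1)), covs])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta + y.mean()


def pairwise_posthoc(
    y, group, covariates: np.ndarray | None = None, method: str = "tukey"
) -> list[StatResult]:
    """All pairwise group comparisons.

    ``tukey``: Tukey-Kramer on covariate-adjusted residuals (the Table-style
    adjusted p-values).  ``welch_t``: unadjusted Welch two-sample t (the
    figure-style contrasts).  ``bonferroni``: Welch p times the number of
    pairs, capped at 1.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = list(pd.unique(group))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    if method not in ("tukey", "welch_t", "bonferroni"):
        raise ValueError(f"unknown post-hoc method {method!r}")
    pairs = list(itertools.combinations(levels, 2))
    out: list[StatResult] = []
    if method == "tukey":
        y_adj = (
            _covariate_adjusted(y, np.asarray(covariates, dtype=float))
            if covariates is not None and np.size(covariates)
            else y
        )
        tk = pairwise_tukeyhsd(y_adj, group)
        for (g1, g2), p_adj, stat in zip(
            itertools.combinations(tk.groupsunique, 2), tk.pvalues, tk.meandiffs
        ):
            means, sems = _group_summary(
                y[np.isin(group, [g1, g2])], group[np.isin(group, [g1, g2])]
            )
            out.append(
                StatResult(
                    test="tukey",
                    statistic=float(stat),
                    df=(float(len(y) - len(levels)),),
                    p=float(p_adj),
                    group_means=means,
                    group_sems=sems,
                    adjusted_p=float(p_adj),
                    extra={"pair": (g1, g2)},
                )
            )
        return out
    for g1, g2 in pairs:
        a, b = y[group == g1], y[group == g2]
        t_res = sps.ttest_ind(a, b, equal_var=False)
        p = float(t_res.pvalue)
        p_adj = min(1.0, p * len(pairs)) if method == "bonferroni" else None
        means, sems = _group_summary(
            y[np.isin(group, [g1, g2])], group[np.isin(group, [g1, g2])]
        )
        out.append(
            StatResult(
                test=method,
                statistic=float(t_res.statistic),
                df=(float(t_res.df),),
                p=p,
                group_means=means,
                group_sems=sems,
                adjusted_p=p_adj,
                extra={"pair": (g1, g2)},
            )
        )
    return out


def edgewise_group_contrast(
    matrices_a: list[ConnectivityMatrix],
    matrices_b: list[ConnectivityMatrix],
    edge_transform: str = "fc_z",
    q: float = 0.05,
) -> dict:
    """Welch t per upper-triangle edge with BH FDR over the edge set.

    ``edge_transform``: ``log1p_sc`` applies log(1 + x) (fiber counts);
    ``fc_z`` uses values as-is (already Fisher-z).  Edges with zero variance
    in both groups are excluded from testing and reported.

    Returns a dict with the signed ``t`` map, the boolean significance
    ``mask`` (both N x N symmetric), per-edge ``p`` values, the excluded-edge
    count, and a tidy ``edges`` DataFrame.
    """
    if edge_transform not in ("log1p_sc", "fc_z"):
        raise ValueError(f"unknown edge transform {edge_transform!r}")
    if len(matrices_a) < 2 or len(matrices_b) < 2:
        raise ValueError("need >= 2 subjects per group")
    labels = matrices_a[0].node_labels
    n = len(labels)
    iu = np.triu_indices(n, k=1)

    def stack(mats):
        arr = np.stack([m.values[iu] for m in mats])
        return np.log1p(arr) if edge_transform == "log1p_sc" else arr

    a, b = stack(matrices_a), stack(matrices_b)
    var_a, var_b = a.var(axis=0), b.var(axis=0)
    testable = (var_a > 0) | (var_b > 0)
    n_excluded = int((~testable).sum())
    if n_excluded:
        logger.info("edgewise contrast: %d zero-variance edges excluded", n_excluded)
    t_vals = np.full(len(iu[0]), np.nan)
    p_vals = np.full(len(iu[0]), np.nan)
    if testable.any():
        res = sps.ttest_ind(a[:, testable], b[:, testable], axis=0, equal_var=False)
        t_vals[testable] = res.statistic
        p_vals[testable] = res.pvalue
    sig = np.zeros(len(iu[0]), dtype=bool)
    sig[testable] = bh_reject(p_vals[testable], q)

    t_map = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    t_map[iu] = np.where(np.isnan(t_vals), 0.0, t_vals)
    t_map += t_map.T
    mask[iu] = sig
    mask |= mask.T
    edges = pd.DataFrame(
        {
            "node_i": [labels[i] for i in iu[0]],
            "node_j": [labels[j] for j in iu[1]],
            "t": t_vals,
            "p": p_vals,
            "q_flag": sig,
        }
    )
    return {
        "t_map": t_map,
        "mask": mask,
        "p": p_vals,
        "n_excluded": n_excluded,
        "edges": edges,
    }


def pearson_corr_test(x, y) -> StatResult:
    """Pearson correlation with the exact two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return StatResult(
        test="pearson",
        statistic=float(res.statistic),
        df=(float(len(x) - 2),),
        p=float(res.pvalue),
    )


def independent_corr_diff_test(r1: float, n1: int, r2: float, n2: int) -> CorrDiffResult:
    """Fisher r-to-z test for a difference between independent correlations."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise ValueError(f"n must exceed 3, got {n}")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return CorrDiffResult(r1=r1, n1=n1, r2=r2, n2=n2, z=float(z), p=p)


def behavior_coupling_analysis(
    coupling: pd.Series,
    manifest: pd.DataFrame,
    scores: tuple[str, ...] = ("swan_hyper", "swan_inatt"),
    estimator: str = "pearson",
) -> dict[str, pd.DataFrame]:
    """Per-group coupling-behavior correlations plus between-group tests.

    Parameters
    ----------
    coupling
        Per-subject coupling values (e.g. the DMN row of the feature table),
        indexed by subject id.
    manifest
        Subject table with ``group`` and the score columns, indexed by id.
    estimator
        ``pearson`` (default) or ``spearman``.

    Returns ``{"correlations": ..., "differences": ...}``.  Subjects with a
    missing score are excluded per score and counted; a group with fewer
    than 4 usable subjects is reported as not estimable.
    """
    if estimator not in ("pearson", "spearman"):
        raise ValueError(f"unknown estimator {estimator!r}")
    groups = list(pd.unique(manifest["group"]))
    corr_rows, diff_rows = [], []
    per_score_group: dict[tuple[str, str], tuple[float, int]] = {}
    for score in scores:
        for g in groups:
            ids = manifest.index[manifest["group"] == g]
            sub = pd.DataFrame(
                {"c": coupling.reindex(ids), "s": manifest.loc[ids, score]}
            ).dropna()
            n_used, n_missing = len(sub), len(ids) - len(sub)
            row = {
                "score": score,
                "group": g,
                "n": n_used,
                "n_missing": n_missing,
                "r": np.nan,
                "p": np.nan,
                "estimable": False,
            }
            if n_used >= 4 and sub["c"].nunique() > 1 and sub["s"].nunique() > 1:
                if estimator == "pearson":
                    res = sps.pearsonr(sub["c"], sub["s"])
                else:
                    res = sps.spearmanr(sub["c"], sub["s"])
                row.update(r=float(res.statistic), p=float(res.pvalue), estimable=True)
                per_score_group[(score, g)] = (float(res.statistic), n_used)
            corr_rows.append(row)
        for g1, g2 in itertools.combinations(groups, 2):
            k1, k2 = (score, g1), (score, g2)
            row = {"score": score, "group_1": g1, "group_2": g2,
                   "z": np.nan, "p": np.nan, "estimable": False}
            if k1 in per_score_group and k2 in per_score_group:
                (r1, m1), (r2, m2) = per_score_group[k1], per_score_group[k2]
                if abs(r1) < 1 and abs(r2) < 1:
                    res = independent_corr_diff_test(r1, m1, r2, m2)
                    row.update(z=res.z, p=res.p, estimable=True)
            diff_rows.append(row)
    return {
        "correlations": pd.DataFrame(corr_rows),
        "differences": pd.DataFrame(diff_rows),
    }
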