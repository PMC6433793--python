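"""Covariate-adjusted nonparametric group comparison and clinical
correlation of network-metric AUCs.

The comparison follows the standard permutation recipe: residualize the
per-subject AUCs on nuisance covariates by ordinary least squares, take
the difference of group means as the statistic, build the null by
relabeling subjects without replacement, and correct families of tests
with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationResult",
    "residualize",
    "permutation_test",
    "permutation_test_many",
    "fdr_bh",
    "partial_correlation",
    "demographics_compare",
    "compare_groups",
    "correlate_clinical",
]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one permutation test (one metric, optionally one node)."""

    metric_name: str
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    node: int | None = None
    p_fdr: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")
        if self.p_fdr is not None and self.p_fdr < self.p_value - 1e-12:
            raise ValueError("p_fdr cannot be smaller than p_value")


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Covariate matrix with an intercept column prepended."""
    ones = np.ones((n, 1))
    if covariates is None or (
        hasattr(covariates, "size") and np.asarray(covariates).size == 0
    ):
        return ones
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError(f"covariates have {cov.shape[0]} rows for {n} samples")
    return np.hstack([ones, cov])


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``values`` on covariates (intercept included).

    ``values`` may be a vector or an (n x m) matrix of many outcomes
    sharing one design.  Collinear designs fall back to the
    pseudo-inverse with a warning.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    x = _design(covariates, n)
    if x.shape[1] >= n:
        raise ValueError("need more samples than covariates")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn(
            "collinear covariates; using pseudo-inverse", stacklevel=2
        )
    beta = np.linalg.pinv(x) @ values
    return values - x @ beta


def _group_mask(groups: Sequence) -> np.ndarray:
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {list(levels)}")
    # "patient"-like level first if present, else first-seen level
    first = "patient" if "patient" in levels else levels[0]
    return groups == first


def permutation_test(
    values: np.ndarray,
    groups: Sequence,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
    metric_name: str = "metric",
) -> PermutationResult:
    """Two-tailed permutation test of a group difference in means.

    The statistic is mean(group A) - mean(group B); permutations shuffle
    labels preserving group sizes.  With ``exhaustive=True`` every
    distinct assignment is enumerated and the p-value is the exact
    fraction (the identity assignment counts itself); otherwise Monte
    Carlo sampling with the add-one correction is used:
    ``p = (#{|null| >= |obs|} + 1) / (n_perm + 1)``.
    """
    values = np.asarray(values, dtype=float)
    mask = _group_mask(groups)
    n_a, n_b = int(mask.sum()), int((~mask).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need at least 2 subjects")
    if not exhaustive and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low", stacklevel=2)
    observed = float(values[mask].mean() - values[~mask].mean())

    n = len(values)
    if exhaustive:
        total = 0
        count = 0
        nulls = []
        tol = 1e-12 * max(1.0, abs(observed))
        for combo in combinations(range(n), n_a):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            diff = values[sel].mean() - values[~sel].mean()
            nulls.append(diff)
            total += 1
            if abs(diff) >= abs(observed) - tol:
                count += 1
        p = count / total
        null_diffs = np.array(nulls)
    else:
        rng = np.random.default_rng(seed)
        null_diffs = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            sel = np.zeros(n, dtype=bool)
            sel[perm[:n_a]] = True
            null_diffs[i] = values[sel].mean() - values[~sel].mean()
        tol = 1e-12 * max(1.0, abs(observed))
        count = int((np.abs(null_diffs) >= abs(observed) - tol).sum())
        p = (count + 1) / (n_perm + 1)
    return PermutationResult(
        metric_name=metric_name,
        observed_diff=observed,
        null_diffs=null_diffs,
        p_value=float(p),
    )


def permutation_test_many(
    values: np.ndarray,
    groups: Sequence,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized permutation tests for many outcomes sharing one design.

    ``values`` is (n_subjects x m); the same label permutations are used
    for every column.  Returns (observed_diffs, p_values), each length m.
    """
    values = np.asarray(values, dtype=float)
    mask = _group_mask(groups)
    n, m = values.shape
    n_a = int(mask.sum())
    observed = values[mask].mean(axis=0) - values[~mask].mean(axis=0)
    rng = np.random.default_rng(seed)
    counts = np.zeros(m)
    tol = 1e-12 * np.maximum(1.0, np.abs(observed))
    # chunked to bound memory at ~ chunk * n floats
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        order = rng.random((b, n)).argsort(axis=1)
        sel = order < n_a  # b x n boolean group-A masks
        sum_a = sel @ values
        mean_a = sum_a / n_a
        mean_b = (values.sum(axis=0) - sum_a) / (n - n_a)
        diffs = mean_a - mean_b
        counts += (np.abs(diffs) >= (np.abs(observed) - tol)).sum(axis=0)
        done += b
    p = (counts + 1) / (n_perm + 1)
    return observed, p


def fdr_bh(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (adjusted p-values, rejection mask).  Adjusted p for the
    k-th smallest p is ``min_{j >= k} m * p_(j) / j`` capped at 1; the
    mask rejects every test with adjusted p <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted, adjusted <= q


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of ``x`` and ``y`` given covariates.

    Correlates the two OLS residual vectors; the p-value comes from the
    t distribution with ``n - K - 2`` degrees of freedom (K covariates).
    With no covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    k = 0
    if covariates is not None and np.asarray(covariates).size > 0:
        cov = np.asarray(covariates, dtype=float)
        k = 1 if cov.ndim == 1 else cov.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > K + 3 samples (n={n}, K={k})")
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    sx, sy = rx.std(), ry.std()
    if sx <= 1e-10 * max(x.std(), 1e-300) or sy <= 1e-10 * max(y.std(), 1e-300):
        raise ValueError("zero-variance residual; correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def demographics_compare(
    cohort: pd.DataFrame,
    group_col: str = "group",
    categorical: Sequence[str] = ("sex",),
    exclude: Sequence[str] = ("subject_id", "coupling_jitter"),
) -> pd.DataFrame:
    """Per-variable between-group tests for the cohort table.

    Categorical variables get the exact (Fisher) two-sided test on the
    2x2 table; continuous variables get the two-sample pooled-variance
    t-test.  Returns one row per variable with the group summaries,
    the statistic and the p-value.
    """
    groups = cohort[group_col]
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("cohort must contain exactly 2 groups")
    if "patient" in levels:  # stable, reader-friendly ordering
        levels = ["patient"] + [lv for lv in levels if lv != "patient"]
    a = cohort[groups == levels[0]]
    b = cohort[groups == levels[1]]

    rows = []
    for col in cohort.columns:
        if col == group_col or col in exclude:
            continue
        if col in categorical:
            table = np.array(
                [
                    [(a[col] == 1).sum(), (a[col] != 1).sum()],
                    [(b[col] == 1).sum(), (b[col] != 1).sum()],
                ]
            )
            stat, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append(
                {
                    "variable": col,
                    "test": "fisher_exact",
                    f"{levels[0]}_summary": f"{table[0, 0]}/{table[0, 1]}",
                    f"{levels[1]}_summary": f"{table[1, 0]}/{table[1, 1]}",
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
        else:
            va, vb = a[col].to_numpy(float), b[col].to_numpy(float)
            if np.ptp(va) == 0 and np.ptp(vb) == 0 and va.mean() == vb.mean():
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_ind(va, vb, equal_var=True)
            rows.append(
                {
                    "variable": col,
                    "test": "t_test",
                    f"{levels[0]}_summary": f"{va.mean():.2f} ({va.std(ddof=1):.2f})",
                    f"{levels[1]}_summary": f"{vb.mean():.2f} ({vb.std(ddof=1):.2f})",
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    auc_table: pd.DataFrame,
    cohort: pd.DataFrame,
    covariate_cols: Sequence[str] = ("age", "sex"),
    n_perm: int = 10_000,
    seed: int = 0,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Permutation group comparison of every AUC record, FDR per family.

    ``auc_table`` is long-format with columns (subject_id, metric, node,
    auc); node is empty/NaN for global metrics.  Residualization on the
    covariates happens before permutation.  FDR families are one per
    metric name: the global metrics together, and each nodal metric
    across its nodes.
    """
    merged = auc_table.merge(
        cohort[["subject_id", "group", *covariate_cols]], on="subject_id"
    )
    results = []
    for metric, sub in merged.groupby("metric", sort=False):
        wide = sub.pivot_table(
            index="subject_id", columns="node", values="auc", dropna=False
        )
        meta = sub.drop_duplicates("subject_id").set_index("subject_id")
        meta = meta.loc[wide.index]
        cov = meta[list(covariate_cols)].to_numpy(float) if covariate_cols else None
        resid = residualize(wide.to_numpy(float), cov)
        obs, p = permutation_test_many(
            resid, meta["group"].to_numpy(), n_perm=n_perm, seed=seed
        )
        p_adj, reject = fdr_bh(p, fdr_q)
        for j, node in enumerate(wide.columns):
            results.append(
                {
                    "metric": metric,
                    "node": node,
                    "observed_diff": obs[j],
                    "p_value": p[j],
                    "p_fdr": p_adj[j],
                    "significant": bool(reject[j]),
                }
            )
    return pd.DataFrame(results)


def correlate_clinical(
    auc_table: pd.DataFrame,
    cohort: pd.DataFrame,
    clinical_vars: Sequence[str],
    covariate_cols: Sequence[str] = ("age", "sex"),
    group: str | None = "patient",
    metrics: Sequence[str] | None = None,
    nodes: Sequence | None = None,
) -> pd.DataFrame:
    """Partial correlations between AUC metrics and clinical variables.

    By default runs within the patient group with age and sex as
    covariates, for every (metric, node, clinical variable) triple;
    restrict with ``metrics`` / ``nodes`` for targeted follow-up.
    """
    cohort_sel = cohort if group is None else cohort[cohort["group"] == group]
    merged = auc_table.merge(cohort_sel, on="subject_id")
    if metrics is not None:
        merged = merged[merged["metric"].isin(metrics)]
    if nodes is not None:
        merged = merged[merged["node"].isin(nodes)]
    rows = []
    for (metric, node), sub in merged.groupby(["metric", "node"], sort=False, dropna=False):
        cov = sub[list(covariate_cols)].to_numpy(float) if covariate_cols else None
        for var in clinical_vars:
            r, p = partial_correlation(
                sub["auc"].to_numpy(float), sub[var].to_numpy(float), cov
            )
            rows.append(
                {
                    "metric": metric,
                    "node": node,
                    "clinical_var": var,
                    "r": r,
                    "p_value": p,
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)
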