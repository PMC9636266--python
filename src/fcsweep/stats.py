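"""Statistical layer: regressions, cross-threshold correlations, permutation
tests, and connectivity-distribution descriptives.

* metric-vs-threshold OLS (how much of a graph measure's variance the
  threshold level explains),
* Spearman correlation of subject metric vectors between every pair of
  threshold levels (stability of the subject ordering across thresholds),
* two-sample permutation t-test (Welch statistic, Monte-Carlo label
  permutations with exact enumeration when feasible) with pooled-SD
  Cohen's d,
* per-threshold group-effect profiles flagging contiguous significant
  intervals and effect-sign reversals,
* OMST-vs-matched-threshold comparison tables,
* median / mean / MAD / SD descriptives of a subject's edge-weight
  distribution.

Significance is two-sided alpha = 0.05 throughout; no multiple-testing
correction is applied by default (an FDR switch is available), which is a
documented limitation of the per-threshold profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .spectral import ConnectivityMatrix

__all__ = [
    "RegressionFit",
    "ComparisonResult",
    "DescriptivesRow",
    "connectivity_descriptives",
    "fit_density_regression",
    "cross_threshold_correlations",
    "permutation_ttest",
    "group_effect_profile",
    "significant_intervals",
    "compare_omst_vs_matched",
]

#: above this many distinct group-label splits, fall back to Monte-Carlo
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass
class DescriptivesRow:
    subject: str
    measure: str
    median: float
    mean: float
    mad: float  # median absolute deviation (raw, unscaled)
    sd: float  # sample SD (ddof=1)


def connectivity_descriptives(m: ConnectivityMatrix) -> DescriptivesRow:
    """Four descriptives of the upper-triangle weight distribution."""
    w = m.upper_values()
    if w.size == 0:
        raise ValueError("matrix has no off-diagonal weights")
    med = float(np.median(w))
    return DescriptivesRow(
        subject=m.subject_id,
        measure=m.measure,
        median=med,
        mean=float(np.mean(w)),
        mad=float(np.median(np.abs(w - med))),
        sd=float(np.std(w, ddof=1)) if w.size > 1 else 0.0,
    )


@dataclass
class RegressionFit:
    intercept: float
    slope: float
    adj_r_squared: float
    p_intercept: float
    p_slope: float
    n: int
    x: str
    metric: str


def fit_density_regression(
    records: pd.DataFrame,
    metric: str,
    x: str = "q",
    measure: str | None = None,
) -> RegressionFit:
    """OLS of a graph metric on the threshold level, pooled over subjects.

    ``x`` selects the regressor: the quantile level ``"q"`` (the paper-style
    "density value", i.e. the knob actually swept) or the realized edge
    ``"density"``; slope signs flip between the two since density falls as q
    rises.  Rows with missing metric values are dropped.
    """
    df = records
    if measure is not None:
        df = df[df["measure"] == measure]
    df = df[[x, metric]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(df[x].to_numpy()) == 0:
        raise ValueError(f"regressor {x!r} has zero variance")
    X = sm.add_constant(df[x].to_numpy())
    fit = sm.OLS(df[metric].to_numpy(), X).fit()
    return RegressionFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        adj_r_squared=float(fit.rsquared_adj),
        p_intercept=float(fit.pvalues[0]),
        p_slope=float(fit.pvalues[1]),
        n=int(fit.nobs),
        x=x,
        metric=metric,
    )


def cross_threshold_correlations(
    records: pd.DataFrame,
    metric: str,
    measure: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-wise Spearman rho between metric vectors at every q pair.

    Returns (rho, p) DataFrames indexed by q.  A threshold level whose
    metric vector is constant across subjects has no rank ordering; its
    correlations are recorded as missing.
    """
    df = records
    if measure is not None:
        df = df[df["measure"] == measure]
    wide = df.pivot_table(index="subject", columns="q", values=metric)
    if wide.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    qs = wide.columns.to_numpy()
    data = wide.to_numpy()
    import warnings as _warnings

    with _warnings.catch_warnings():
        # constant columns are expected; they are reported as missing below
        _warnings.simplefilter("ignore", scipy.stats.ConstantInputWarning)
        rho, p = scipy.stats.spearmanr(data, nan_policy="omit")
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    const = np.nanstd(data, axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    p[const, :] = np.nan
    p[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    return (
        pd.DataFrame(rho, index=qs, columns=qs),
        pd.DataFrame(p, index=qs, columns=qs),
    )


@dataclass
class ComparisonResult:
    t_stat: float
    p_value: float
    cohens_d: float
    n_permutations: int
    seed: int | None
    exact: bool = False


def _welch_t(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    var_a = np.maximum(sumsq_a / n_a - mean_a**2, 0.0) * n_a / (n_a - 1)
    var_b = np.maximum(sumsq_b / n_b - mean_b**2, 0.0) * n_b / (n_b - 1)
    denom = np.sqrt(var_a / n_a + var_b / n_b)
    num = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0),
                     np.where(num == 0, 0.0, np.sign(num) * np.inf))
    return t


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference."""
    n_a, n_b = len(a), len(b)
    s2 = ((n_a - 1) * np.var(a, ddof=1) + (n_b - 1) * np.var(b, ddof=1)) / (
        n_a + n_b - 2
    )
    diff = float(np.mean(a) - np.mean(b))
    if s2 == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return diff / float(np.sqrt(s2))


def permutation_ttest(
    a,
    b,
    n_permutations: int = 10_000,
    seed: int | None = None,
    force_monte_carlo: bool = False,
) -> ComparisonResult:
    """Two-sample permutation test on the Welch t statistic.

    The p-value is the fraction of group-label permutations whose |t| meets
    or exceeds the observed |t|.  All C(n_a + n_b, n_a) splits are enumerated
    exactly when there are at most 20,000 of them (unless
    ``force_monte_carlo``); otherwise ``n_permutations`` Monte-Carlo
    permutations are drawn and the observed labelling is counted among them.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    n = n_a + n_b
    d = cohens_d(a, b)
    t_obs = float(
        _welch_t(a.sum(), (a**2).sum(), n_a, b.sum(), (b**2).sum(), n_b)
    )
    if np.var(pooled) == 0:
        return ComparisonResult(0.0, 1.0, 0.0, 0, seed, exact=True)

    n_splits = comb(n, n_a)
    exact = n_splits <= EXACT_ENUMERATION_LIMIT and not force_monte_carlo
    if exact:
        membership = np.zeros((n_splits, n), dtype=float)
        for r, idx in enumerate(combinations(range(n), n_a)):
            membership[r, list(idx)] = 1.0
        n_used = n_splits
    else:
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_permutations, n)), axis=1)
        membership = np.zeros((n_permutations, n), dtype=float)
        np.put_along_axis(membership, order[:, :n_a], 1.0, axis=1)
        n_used = n_permutations

    sum_a = membership @ pooled
    sumsq_a = membership @ pooled**2
    sum_all = pooled.sum()
    sumsq_all = (pooled**2).sum()
    t_perm = _welch_t(sum_a, sumsq_a, n_a, sum_all - sum_a, sumsq_all - sumsq_a, n_b)
    tol = 1e-12 * max(1.0, abs(t_obs))
    hits = int(np.sum(np.abs(t_perm) >= abs(t_obs) - tol))
    if exact:
        p = hits / n_splits
    else:
        p = (hits + 1) / (n_used + 1)
    return ComparisonResult(
        t_stat=t_obs,
        p_value=float(min(p, 1.0)),
        cohens_d=d,
        n_permutations=n_used,
        seed=seed,
        exact=exact,
    )


def group_effect_profile(
    records: pd.DataFrame,
    metric: str,
    measure: str | None = None,
    group_col: str = "group",
    n_permutations: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Permutation test and Cohen's d at every threshold level.

    Returns one row per q with t, p, d, and a ``significant`` flag at the
    given alpha (Benjamini-Hochberg adjusted when ``fdr``).  Threshold levels
    where either group is missing or degenerate are skipped with a warning
    column rather than aborting.  Interval structure (contiguous significant
    runs, d sign changes) is read off with :func:`significant_intervals`.
    """
    df = records
    if measure is not None:
        df = df[df["measure"] == measure]
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    ga, gb = groups
    rows = []
    for k, (q, sub) in enumerate(df.groupby("q")):
        a = sub.loc[sub[group_col] == ga, metric].to_numpy(dtype=float)
        b = sub.loc[sub[group_col] == gb, metric].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            continue
        res = permutation_ttest(
            a, b, n_permutations=n_permutations,
            seed=None if seed is None else (seed + k) % (2**31),
        )
        rows.append(
            {"q": q, "t_stat": res.t_stat, "p_value": res.p_value,
             "cohens_d": res.cohens_d, "n_a": len(a), "n_b": len(b)}
        )
    out = pd.DataFrame(rows).sort_values("q").reset_index(drop=True)
    if out.empty:
        raise ValueError("no threshold level had both groups present")
    if fdr:
        out["significant"] = multipletests(out["p_value"], alpha=alpha,
                                           method="fdr_bh")[0]
    else:
        out["significant"] = out["p_value"] < alpha
    out["d_sign"] = np.sign(out["cohens_d"])
    return out


def significant_intervals(profile: pd.DataFrame) -> list[dict]:
    """Contiguous runs of significant thresholds, with their d sign.

    A run whose Cohen's d changes sign is split, so two intervals with
    opposite signs (the direction-reversal phenomenon) show up as two
    entries.
    """
    runs: list[dict] = []
    current: dict | None = None
    for _, row in profile.iterrows():
        if row["significant"] and (
            current is None or row["d_sign"] == current["d_sign"]
        ):
            if current is None:
                current = {"q_start": row["q"], "q_end": row["q"],
                           "n_levels": 1, "d_sign": row["d_sign"]}
            else:
                current["q_end"] = row["q"]
                current["n_levels"] += 1
        else:
            if current is not None:
                runs.append(current)
                current = None
            if row["significant"]:
                current = {"q_start": row["q"], "q_end": row["q"],
                           "n_levels": 1, "d_sign": row["d_sign"]}
    if current is not None:
        runs.append(current)
    return runs


def compare_omst_vs_matched(
    omst_metrics: pd.DataFrame,
    matched_metrics: pd.DataFrame,
    metrics: tuple[str, ...] = ("cpl", "clustering", "participation", "swi"),
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per (measure, metric) comparison of OMST vs matched-density networks.

    Both frames need columns subject, measure, and the metric columns; the
    subject sets must match exactly per measure.  One row per
    measure x metric with the permutation t, p, and Cohen's d.
    """
    rows = []
    for k, measure in enumerate(sorted(omst_metrics["measure"].unique())):
        o = omst_metrics[omst_metrics["measure"] == measure].set_index("subject")
        t = matched_metrics[matched_metrics["measure"] == measure].set_index("subject")
        missing = sorted(set(o.index) ^ set(t.index))
        if missing:
            raise ValueError(f"unmatched subjects for {measure}: {missing}")
        t = t.loc[o.index]
        for j, metric in enumerate(metrics):
            ok = np.isfinite(o[metric].to_numpy(dtype=float)) & np.isfinite(
                t[metric].to_numpy(dtype=float)
            )
            a = o.loc[ok, metric].to_numpy()
            b = t.loc[ok, metric].to_numpy()
            if len(a) < 2:
                rows.append({"measure": measure, "metric": metric,
                             "t-stat": np.nan, "p-value": np.nan,
                             "Cohen's d": np.nan})
                continue
            res = permutation_ttest(
                a, b, n_permutations=n_permutations,
                seed=None if seed is None else (seed + 97 * k + j) % (2**31),
            )
            rows.append(
                {"measure": measure, "metric": metric, "t-stat": res.t_stat,
                 "p-value": res.p_value, "Cohen's d": res.cohens_d}
            )
    return pd.DataFrame(rows)
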