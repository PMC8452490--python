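"""Cohort-level statistics on MEA parameter tables.

A parameter table has one row per well, 17 activity/connectivity parameter
columns plus metadata columns (line_id, div, mea_batch, astro_batch, ...).
This module provides:

- per-parameter coefficient of variation within lines (parameter stability);
- PCA on Z-scored parameters (phenotype embedding);
- batch variance decomposition via separate one-way linear models per factor,
  with a "combined" share computed on stacked Z-scored parameter values;
- group comparisons: Kruskal-Wallis with Dunn's post hoc correction or
  one-way ANOVA with Tukey (multi-group), Mann-Whitney U with Bonferroni
  (two-group), gated on a Kolmogorov-Smirnov normality test;
- per-bin burst-shape comparisons with Holm-Sidak correction;
- power planning: wells per group for a target power, and post hoc power,
  both via the noncentral-t two-sample approximation.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

from .errors import AnalysisError, ParameterError

logger = logging.getLogger(__name__)

#: the 17 per-well parameters, in canonical order
PARAMETERS: tuple[str, ...] = (
    "MFR", "PRS", "BR", "BD", "BSR", "IBI",
    "NBR", "NBD", "NIBI", "CV_NIBI", "RT", "DT",
    "C_0", "C_peak", "link_weight", "n_connections", "shape_peak_rate",
)

CV_STABILITY_CUTOFF = 50.0  # percent; parameters above are flagged unstable


def _param_columns(table: pd.DataFrame, params=None) -> list[str]:
    if params is None:
        params = [p for p in PARAMETERS if p in table.columns]
    missing = [p for p in params if p not in table.columns]
    if missing:
        raise KeyError(f"parameter columns missing from table: {missing}")
    return list(params)


# ---------------------------------------------------------------------------
# Parameter stability (coefficient of variation)
# ---------------------------------------------------------------------------

def parameter_cv(
    table: pd.DataFrame,
    group_by: str = "line_id",
    params=None,
    cutoff: float = CV_STABILITY_CUTOFF,
) -> pd.DataFrame:
    """Within-group CV% per parameter, summarized across groups.

    CV% = 100 * sample SD / mean within each group (line); returns per
    parameter the mean and SD of CV% across groups and a stability flag
    (mean CV% above ``cutoff`` marks the parameter as variable).
    """
    cols = _param_columns(table, params)
    rows = []
    for p in cols:
        cvs = []
        for _, grp in table.groupby(group_by):
            v = grp[p].dropna().to_numpy(dtype=float)
            if v.size >= 2 and np.mean(v) != 0:
                cvs.append(100.0 * np.std(v, ddof=1) / abs(np.mean(v)))
        rows.append({
            "parameter": p,
            "mean_cv_pct": float(np.mean(cvs)) if cvs else float("nan"),
            "sd_cv_pct": float(np.std(cvs, ddof=1)) if len(cvs) >= 2 else float("nan"),
            "n_groups": len(cvs),
            "stable": bool(cvs and np.mean(cvs) <= cutoff),
        })
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------

def pca_embed(table: pd.DataFrame, params=None, n_components: int | None = None) -> dict:
    """PCA on column-wise Z-scored parameters.

    Returns scores (wells x PCs), loadings (parameters x PCs) and
    variance_explained (percent, summing to 100 over all components).  Sign
    convention: each component's largest-magnitude loading is positive.
    """
    cols = _param_columns(table, params)
    X = table[cols].to_numpy(dtype=float)
    keep = ~np.any(np.isnan(X), axis=1)
    if keep.sum() < 2 or len(cols) < 2:
        raise AnalysisError("PCA needs >= 2 complete wells and >= 2 parameters")
    X = X[keep]
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()
    for k in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return {
        "scores": pd.DataFrame(
            scores, index=table.index[keep],
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        "loadings": pd.DataFrame(
            loadings, index=cols,
            columns=[f"PC{i + 1}" for i in range(loadings.shape[1])],
        ),
        "variance_explained": 100.0 * pca.explained_variance_ratio_,
        "mean": mu, "sd": sd,
    }


# ---------------------------------------------------------------------------
# Batch variance decomposition
# ---------------------------------------------------------------------------

def _one_way_r2(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """R^2 (SS_between / SS_total) and p-value of a one-way linear model."""
    ok = ~np.isnan(y)
    y, groups = y[ok], groups[ok]
    levels = pd.unique(groups)
    if y.size < 2 or len(levels) < 2:
        return 0.0, float("nan")
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0:
        return 0.0, float("nan")
    ss_between = float(sum(
        (y[groups == g]).size * (y[groups == g].mean() - grand) ** 2 for g in levels
    ))
    samples = [y[groups == g] for g in levels]
    try:
        _, p = stats.f_oneway(*samples)
    except Exception:  # degenerate groups (e.g. constant within)
        p = float("nan")
    return ss_between / ss_total, float(p)


def variance_explained_by_batch(
    table: pd.DataFrame, factor: str, params=None
) -> dict:
    """Share of parameter variance explained by one batch factor.

    Per parameter: one-way linear model with the factor as categorical
    predictor, R^2 = SS_between / SS_total, with Benjamini-Hochberg adjusted
    p-values across parameters.  The combined percentage fits the same
    one-way model to all parameters' Z-scored values stacked into a single
    response.
    """
    if factor not in table.columns:
        raise KeyError(f"factor column {factor!r} missing")
    cols = _param_columns(table, params)
    groups = table[factor].astype(str).to_numpy()
    if len(pd.unique(groups)) < 2:
        warnings.warn(f"factor {factor!r} has a single level: R^2 is 0 by design",
                      stacklevel=2)
    rows = []
    stacked_y, stacked_g = [], []
    for p in cols:
        y = table[p].to_numpy(dtype=float)
        r2, pval = _one_way_r2(y, groups)
        rows.append({"parameter": p, "r2": r2, "p": pval})
        ok = ~np.isnan(y)
        if ok.sum() >= 2 and np.std(y[ok]) > 0:
            z = (y[ok] - y[ok].mean()) / y[ok].std(ddof=0)
            stacked_y.append(z)
            stacked_g.append(groups[ok])
    per_param = pd.DataFrame(rows).set_index("parameter")
    raw_p = per_param["p"].to_numpy()
    adj = np.full_like(raw_p, np.nan)
    ok = ~np.isnan(raw_p)
    if ok.any():
        adj[ok] = multipletests(raw_p[ok], method="fdr_bh")[1]
    per_param["p_adj"] = adj
    per_param["significant"] = per_param["p_adj"] < 0.05
    if stacked_y:
        combined_r2, _ = _one_way_r2(np.concatenate(stacked_y), np.concatenate(stacked_g))
    else:
        combined_r2 = 0.0
    return {"per_parameter": per_param, "combined_pct": 100.0 * combined_r2}


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _dunn_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal-Wallis.

    Z statistics on mean ranks with tie correction; pairwise p-values are
    Bonferroni-adjusted over the pairs (the usual "Dunn's correction").
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes, offset = {}, {}, 0
    for g in names:
        n = samples[g].size
        mean_ranks[g] = ranks[offset:offset + n].mean()
        sizes[g] = n
        offset += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"comparison": f"{a}|{b}", "statistic": z, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.minimum(df["p"] * len(df), 1.0)
    return df


def _normality_ok(samples: list[np.ndarray], alpha: float = 0.05) -> bool:
    """Kolmogorov-Smirnov normality gate on each group's standardized values."""
    for s in samples:
        if s.size < 3:
            return False
        sd = s.std(ddof=1)
        if sd == 0:
            return False
        if stats.kstest((s - s.mean()) / sd, "norm").pvalue < alpha:
            return False
    return True


def group_compare(
    table: pd.DataFrame,
    grouping: str,
    params=None,
    design: str = "auto",
    correction: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter group comparison with the matching multiplicity correction.

    - two groups: Mann-Whitney U, Bonferroni-adjusted across parameters;
    - more groups: one-way ANOVA + Tukey if every group passes a KS normality
      gate, otherwise Kruskal-Wallis + Dunn.  ``design`` forces
      ``two_group``/``multi_group``; ``correction`` overrides the post hoc
      family ("tukey" or "dunn").

    Returns a tidy frame: parameter, comparison (omnibus or pair), test,
    statistic, p, p_adj, significant.
    """
    if grouping not in table.columns:
        raise KeyError(f"grouping column {grouping!r} missing")
    cols = _param_columns(table, params)
    names = sorted(table[grouping].dropna().astype(str).unique())
    if len(names) < 2:
        raise AnalysisError("group_compare needs >= 2 groups")
    if design == "auto":
        design = "two_group" if len(names) == 2 else "multi_group"
    rows = []
    for p in cols:
        samples = {
            g: table.loc[table[grouping].astype(str) == g, p].dropna().to_numpy(dtype=float)
            for g in names
        }
        values = list(samples.values())
        if any(v.size < 2 for v in values):
            rows.append({"parameter": p, "comparison": "omnibus", "test": "skipped",
                         "statistic": float("nan"), "p": float("nan")})
            continue
        if design == "two_group":
            u, pv = stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
            rows.append({"parameter": p, "comparison": f"{names[0]}|{names[1]}",
                         "test": "mann-whitney", "statistic": float(u), "p": float(pv)})
        else:
            use_anova = (correction == "tukey") if correction else _normality_ok(values)
            if use_anova:
                f, pv = stats.f_oneway(*values)
                rows.append({"parameter": p, "comparison": "omnibus",
                             "test": "anova", "statistic": float(f), "p": float(pv)})
                res = stats.tukey_hsd(*values)
                for i, j in itertools.combinations(range(len(names)), 2):
                    rows.append({
                        "parameter": p, "comparison": f"{names[i]}|{names[j]}",
                        "test": "tukey", "statistic": float(res.statistic[i, j]),
                        "p": float(res.pvalue[i, j]), "p_adj": float(res.pvalue[i, j]),
                    })
            else:
                h, pv = stats.kruskal(*values)
                rows.append({"parameter": p, "comparison": "omnibus",
                             "test": "kruskal-wallis", "statistic": float(h), "p": float(pv)})
                dunn = _dunn_posthoc(samples)
                for _, r in dunn.iterrows():
                    rows.append({"parameter": p, "comparison": r["comparison"],
                                 "test": "dunn", "statistic": float(r["statistic"]),
                                 "p": float(r["p"]), "p_adj": float(r["p_adj"])})
    out = pd.DataFrame(rows)
    if design == "two_group":
        # Bonferroni family = the parameters compared
        m = out["p"].notna().sum()
        out["p_adj"] = np.minimum(out["p"] * m, 1.0)
    else:
        omnibus = out["comparison"] == "omnibus"
        out.loc[omnibus, "p_adj"] = out.loc[omnibus, "p"]
    out["significant"] = out["p_adj"] < alpha
    return out


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value for a family of m tests."""
    return min(1.0, p * m)


# ---------------------------------------------------------------------------
# Burst-shape bin tests
# ---------------------------------------------------------------------------

def burst_shape_compare(
    shapes_a: np.ndarray,
    shapes_b: np.ndarray,
    bin_width: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin two-sample t tests on aligned shape profiles, Holm-Sidak family.

    ``shapes_a``/``shapes_b`` are (wells x bins) arrays on identical bin grids.
    """
    A = np.atleast_2d(np.asarray(shapes_a, dtype=float))
    B = np.atleast_2d(np.asarray(shapes_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ParameterError(
            f"shape bin grids differ: {A.shape[1]} vs {B.shape[1]} bins"
        )
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise AnalysisError("burst_shape_compare needs >= 2 wells per group")
    t, p = stats.ttest_ind(A, B, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    bw = bin_width or 1.0
    return pd.DataFrame({
        "bin_t": (np.arange(A.shape[1]) + 0.5) * bw,
        "mean_a": A.mean(axis=0), "mean_b": B.mean(axis=0),
        "statistic": t, "p": p, "p_adj": p_adj, "significant": reject,
    })


# ---------------------------------------------------------------------------
# Power planning
# ---------------------------------------------------------------------------

def wells_required(
    effect: float, alpha: float = 0.05, power: float = 0.8, max_n: int = 10_000
) -> int:
    """Smallest per-group n for a two-sample t test at the target power."""
    if effect == 0:
        raise ParameterError("effect size must be nonzero")
    solver = TTestIndPower()
    d = abs(effect)
    for n in range(2, max_n + 1):
        if solver.power(effect_size=d, nobs1=n, alpha=alpha) >= power:
            return n
    raise AnalysisError(f"no n <= {max_n} reaches power {power}")


def post_hoc_power(
    table: pd.DataFrame, grouping: str, parameter: str, alpha: float = 0.05
) -> float:
    """Observed power of a two-group comparison on one parameter.

    Uses the pooled-SD Cohen's d of the observed groups in the two-sample
    noncentral-t approximation (also where the comparison itself was
    rank-based, the standard asymptotic-relative-efficiency shortcut).
    """
    groups = [g.dropna().to_numpy(dtype=float)
              for _, g in table.groupby(grouping)[parameter]]
    if len(groups) != 2:
        raise AnalysisError("post_hoc_power is defined for exactly 2 groups")
    a, b = groups
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise AnalysisError("each group needs >= 2 wells")
    sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    d = abs(a.mean() - b.mean()) / sp if sp > 0 else 0.0
    return float(TTestIndPower().power(effect_size=d, nobs1=n1,
                                       ratio=n2 / n1, alpha=alpha))


__all__ = [
    "PARAMETERS", "CV_STABILITY_CUTOFF",
    "parameter_cv", "pca_embed", "variance_explained_by_batch",
    "group_compare", "bonferroni_adjust", "burst_shape_compare",
    "wells_required", "post_hoc_power",
]
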