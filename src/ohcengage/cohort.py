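"""Cohort-level comparisons across engagement clusters.

Collapsing rules for the health-care-utilization questionnaire, the
standard between/within-group tests used to compare clusters (paired t,
chi-square, Kruskal-Wallis), an exact power calculation for the paired
design, and table builders mirroring the study-report layout.

All tests are two-sided at alpha = .05 and no multiple-testing adjustment
is applied — the tables report each comparison as-is, so readers should
treat borderline p-values accordingly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import pam as pam_mod
from .eq5d import DIMENSIONS, utility
from .synthetic import VISIT_CATEGORIES, VISIT_SERVICES

__all__ = [
    "UtilizationRecord",
    "collapse_visit_categories",
    "binarize_any_visit",
    "categorize_hospital_days",
    "paired_t",
    "power_paired_t",
    "chi_square_table",
    "kruskal_wallis",
    "build_tables",
]

COLLAPSED_CATEGORIES = ("never", "1-3", "4+")
HOSPITAL_BINS = ("none", "1-5", "6-10", ">10")


class DataError(ValueError):
    pass


@dataclasses.dataclass
class UtilizationRecord:
    """Visit-frequency categories plus hospital days at one time point."""

    gp: str
    nurse: str
    outpatient: str
    ae: str
    hospital_days: int

    def validate(self) -> None:
        for svc in VISIT_SERVICES:
            v = getattr(self, svc)
            if v not in VISIT_CATEGORIES and v not in COLLAPSED_CATEGORIES:
                raise DataError(f"{svc}: unknown category {v!r}")
        if self.hospital_days < 0:
            raise DataError(f"hospital_days must be >= 0, got {self.hospital_days}")


def collapse_visit_categories(rec: UtilizationRecord) -> UtilizationRecord:
    """Merge the two highest visit categories: {never, 1-3, 4-6, >6} -> {never, 1-3, 4+}.

    The 4-6 and >6 groups are combined because of small cell counts.
    """
    rec.validate()

    def _collapse(v: str) -> str:
        return "4+" if v in ("4-6", ">6", "4+") else v

    return dataclasses.replace(
        rec,
        gp=_collapse(rec.gp),
        nurse=_collapse(rec.nurse),
        outpatient=_collapse(rec.outpatient),
        ae=_collapse(rec.ae),
    )


def binarize_any_visit(rec: UtilizationRecord) -> dict:
    """Any-visit flags per service: true iff the category is not 'never'.

    Hospitalization: true iff at least one inpatient day.
    """
    rec.validate()
    out = {svc: getattr(rec, svc) != "never" for svc in VISIT_SERVICES}
    out["hospital"] = rec.hospital_days >= 1
    return out


def categorize_hospital_days(days: int) -> str:
    """Bin inpatient days into none / 1-5 / 6-10 / >10."""
    days = int(days)
    if days < 0:
        raise DataError(f"hospital days must be >= 0, got {days}")
    if days == 0:
        return "none"
    if days <= 5:
        return "1-5"
    if days <= 10:
        return "6-10"
    return ">10"


# ---------------------------------------------------------------------------
# tests and power
# ---------------------------------------------------------------------------


def paired_t(before, after) -> dict:
    """Two-sided paired t test with the 95% CI of the mean difference.

    Differences are after - before.  With zero variance of the differences
    the degenerate case is reported explicitly: p = 1 when the mean
    difference is 0 (zero statistic convention), p = 0 otherwise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must be paired, equal-length vectors")
    n = len(before)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    diff = after - before
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return {
            "n": n,
            "mean_diff": mean,
            "sd_diff": 0.0,
            "t": 0.0 if mean == 0 else np.inf,
            "p_value": 1.0 if mean == 0 else 0.0,
            "ci95": (mean, mean),
            "degenerate": True,
        }
    res = stats.ttest_rel(after, before)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return {
        "n": n,
        "mean_diff": mean,
        "sd_diff": sd,
        "t": float(res.statistic),
        "p_value": float(res.pvalue),
        "ci95": (mean - half, mean + half),
        "degenerate": False,
    }


def power_paired_t(n: int, delta: float, sd_diff: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided paired t test.

    P(|T| > t_crit) for T noncentral-t with df = n-1 and noncentrality
    sqrt(n) * delta / sd_diff.  Monotone increasing in n and delta,
    decreasing in sd_diff; at delta = 0 it returns the test size alpha.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    df = n - 1
    nc = np.sqrt(n) * delta / sd_diff
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    # wrong-direction rejection probability; underflows to NaN deep in the
    # tail, where it is numerically zero
    wrong_tail = float(stats.nct.cdf(-t_crit, df, nc))
    if not np.isfinite(wrong_tail):
        wrong_tail = 0.0
    return float(stats.nct.sf(t_crit, df, nc)) + wrong_tail


def chi_square_table(table) -> dict:
    """Pearson chi-square on a clusters x categories count table.

    No continuity correction.  Flags the result when any expected count is
    below 5; raises on a zero row or column margin.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0):
        raise ValueError(f"zero row margin at row {int(np.argmin(rows > 0))}")
    if np.any(cols == 0):
        raise ValueError(f"zero column margin at column {int(np.argmin(cols > 0))}")
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    return {
        "statistic": float(stat),
        "df": int(df),
        "p_value": float(p),
        "expected": expected,
        "low_expected_warning": bool((expected < 5).any()),
    }


def kruskal_wallis(*groups) -> dict:
    """Kruskal-Wallis H across two or more groups, with tie correction.

    When every value is identical across all groups, H = 0 and p = 1 by
    convention (scipy raises on zero variance).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return {"statistic": 0.0, "p_value": 1.0}
    stat, p = stats.kruskal(*arrays)
    return {"statistic": float(stat), "p_value": float(p)}


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def _pct(count: int, denom: int) -> float:
    return round(100.0 * count / denom, 1) if denom else np.nan


def build_tables(surveys: pd.DataFrame, assignments: pd.DataFrame, X=None) -> dict:
    """Report tables comparing engagement clusters.

    ``surveys`` is the wide survey frame, ``assignments`` maps user_id to
    cluster, and ``X`` (optional) is the engaged-day flag matrix in
    assignment row order.  Returns a dict of DataFrames:

    - ``clusters``: per-cluster n, percent and active-day summaries;
    - ``pam_levels``: activation-level distributions at both time points,
      per cluster (ceiling scores excluded pairwise);
    - ``utilization``: any-visit counts and percentages per service, time
      point and cluster, with a chi-square comparison across clusters;
    - ``eq5d``: mean utility (toy value set unless scored upstream) per
      cluster and time point.

    Percentages use per-cell non-missing denominators.
    """
    merged = surveys.merge(assignments[["user_id", "cluster"]], on="user_id")
    clusters = sorted(merged["cluster"].unique())

    # cluster sizes and active days
    rows = []
    for k in clusters:
        sub = merged[merged["cluster"] == k]
        row = {"cluster": k, "n": len(sub), "percent": _pct(len(sub), len(merged))}
        rows.append(row)
    cluster_df = pd.DataFrame(rows)
    if X is not None:
        X = np.asarray(X).astype(bool)
        days = X.sum(axis=1)
        order = assignments.reset_index(drop=True)
        cluster_df["active_days_mean"] = [
            round(float(days[order["cluster"] == k].mean()), 1) for k in clusters
        ]
        cluster_df["active_days_sd"] = [
            round(float(days[order["cluster"] == k].std(ddof=1)), 1)
            if (order["cluster"] == k).sum() > 1
            else 0.0
            for k in clusters
        ]

    # activation levels by cluster and time point
    pam_rows = []
    pam_cols_b = [f"pam{i}_b" for i in range(1, 14)]
    pam_cols_f = [f"pam{i}_f" for i in range(1, 14)]
    scored = {}
    for _, r in merged.iterrows():
        try:
            sb = pam_mod.score(r[pam_cols_b])
            sf = pam_mod.score(r[pam_cols_f])
        except pam_mod.ScoringError:
            continue
        if sb.excluded_ceiling or sf.excluded_ceiling:
            continue
        scored[r["user_id"]] = (sb, sf, r["cluster"])
    for tp, idx in (("baseline", 0), ("follow-up", 1)):
        for lvl in (1, 2, 3, 4):
            row = {"time_point": tp, "level": lvl}
            for k in clusters:
                vals = [s for s in scored.values() if s[2] == k]
                cnt = sum(1 for s in vals if s[idx].level == lvl)
                row[f"cluster_{k}_n"] = cnt
                row[f"cluster_{k}_pct"] = _pct(cnt, len(vals))
            pam_rows.append(row)
    pam_df = pd.DataFrame(pam_rows)

    # any-visit utilization with chi-square across clusters
    util_rows = []
    for svc in VISIT_SERVICES + ("hospital",):
        for tp, suffix in (("baseline", "b"), ("follow-up", "f")):
            col = f"hospital_days_{suffix}" if svc == "hospital" else f"{svc}_{suffix}"
            if col not in merged.columns:
                continue
            row = {"service": svc, "time_point": tp}
            counts = []
            for k in clusters:
                sub = merged.loc[merged["cluster"] == k, col].dropna()
                if svc == "hospital":
                    any_v = (sub.astype(int) >= 1).sum()
                else:
                    any_v = (sub != "never").sum()
                row[f"cluster_{k}_n"] = int(any_v)
                row[f"cluster_{k}_pct"] = _pct(int(any_v), len(sub))
                counts.append([int(any_v), int(len(sub) - any_v)])
            total_any = sum(c[0] for c in counts)
            total_n = sum(c[0] + c[1] for c in counts)
            row["total_n"] = total_any
            row["total_pct"] = _pct(total_any, total_n)
            try:
                row["chi2_p"] = round(chi_square_table(np.array(counts))["p_value"], 4)
            except ValueError:
                row["chi2_p"] = np.nan
            util_rows.append(row)
    util_df = pd.DataFrame(util_rows)

    # mean health-status utility per cluster/time point (toy value set)
    from .eq5d import toy_value_set

    vs = toy_value_set()
    eq_rows = []
    for tp, suffix in (("baseline", "b"), ("follow-up", "f")):
        cols = [f"eq_{d}_{suffix}" for d in DIMENSIONS]
        if not set(cols).issubset(merged.columns):
            continue
        row = {"time_point": tp}
        for k in clusters:
            sub = merged.loc[merged["cluster"] == k, cols].dropna()
            if len(sub):
                u = [utility(r, vs) for r in sub.itertuples(index=False)]
                row[f"cluster_{k}_mean"] = round(float(np.mean(u)), 2)
            else:
                row[f"cluster_{k}_mean"] = np.nan
        eq_rows.append(row)
    eq_df = pd.DataFrame(eq_rows)

    return {
        "clusters": cluster_df,
        "pam_levels": pam_df,
        "utilization": util_df,
        "eq5d": eq_df,
    }
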