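"""Scoring of the 13-item Patient Activation Measure (PAM).

Each of the 13 statements is answered on a 4-point agreement scale
(strongly disagree = 1 ... strongly agree = 4).  The raw sum (13..52) is
converted to a 0-100 scaled score and categorized into four activation
levels.  The instrument owner's raw-to-scaled conversion table is licensed
and not distributed; the default here is the linear map anchored at 0 and
100, and any proprietary table can be supplied as a two-column CSV.

Scaled scores of exactly 100 are treated as implausible ceiling responses
and excluded from paired change analyses.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PamScore",
    "ScoringError",
    "score",
    "level_from_scaled",
    "load_conversion_table",
    "exclude_ceiling",
    "change_stats",
    "meaningful_change",
]

N_ITEMS = 13
RAW_MIN, RAW_MAX = 13, 52

#: Activation level upper bounds on the one-decimal scaled score.
#: level 1: <= 47.0, level 2: 47.1-55.1, level 3: 55.2-72.4, level 4: >= 72.5
_LEVEL_UPPER = (47.0, 55.1, 72.4, 100.0)


class ScoringError(ValueError):
    """Raised for unscorable responses (missing or out-of-range items)."""


@dataclasses.dataclass
class PamScore:
    raw: int
    scaled: float
    level: int
    excluded_ceiling: bool


def _default_scaled(raw: int) -> float:
    return round((raw - RAW_MIN) / (RAW_MAX - RAW_MIN) * 100.0, 1)


def level_from_scaled(scaled: float) -> int:
    """Activation level (1..4) of a scaled score, after one-decimal rounding."""
    s = round(float(scaled), 1)
    if not 0.0 <= s <= 100.0:
        raise ScoringError(f"scaled score {s} outside 0..100")
    for lvl, upper in enumerate(_LEVEL_UPPER, start=1):
        if s <= upper:
            return lvl
    return 4


def score(items: Sequence, conversion: dict | None = None) -> PamScore:
    """Score one 13-item response.

    ``conversion`` optionally maps each raw score 13..52 to a scaled value;
    without it the linear map (raw-13)/39*100 is used, rounded to one
    decimal.  Missing items (None/NaN) raise; the caller decides exclusion.
    """
    items = list(items)
    if len(items) != N_ITEMS:
        raise ScoringError(f"expected {N_ITEMS} items, got {len(items)}")
    vals = []
    for i, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ScoringError(f"item {i} is missing")
        v = int(v)
        if not 1 <= v <= 4:
            raise ScoringError(f"item {i} value {v} outside 1..4")
        vals.append(v)
    raw = int(sum(vals))
    if conversion is not None:
        scaled = round(float(conversion[raw]), 1)
    else:
        scaled = _default_scaled(raw)
    return PamScore(
        raw=raw,
        scaled=scaled,
        level=level_from_scaled(scaled),
        excluded_ceiling=scaled == 100.0,
    )


def load_conversion_table(path) -> dict:
    """Read a raw->scaled conversion CSV (columns: raw, scaled).

    Validates full coverage of raw scores 13..52 and monotonicity of the
    scaled values.
    """
    df = pd.read_csv(path)
    if not {"raw", "scaled"}.issubset(df.columns):
        raise ScoringError("conversion table needs columns 'raw' and 'scaled'")
    table = dict(zip(df["raw"].astype(int), df["scaled"].astype(float)))
    missing = [r for r in range(RAW_MIN, RAW_MAX + 1) if r not in table]
    if missing:
        raise ScoringError(f"conversion table missing raw scores {missing}")
    vals = [table[r] for r in range(RAW_MIN, RAW_MAX + 1)]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ScoringError("conversion table must be monotone in raw score")
    return table


def exclude_ceiling(pairs: Sequence[tuple]) -> tuple[list, int]:
    """Drop pairs with a scaled score of exactly 100 at either time point.

    A perfect score is treated as implausible.  Returns the retained pairs
    (unaltered) and the number removed.
    """
    retained = [
        (b, f) for b, f in pairs if b.scaled != 100.0 and f.scaled != 100.0
    ]
    return retained, len(pairs) - len(retained)


def change_stats(pairs: Sequence[tuple], stratify_levels: bool = True) -> dict:
    """Paired baseline-to-follow-up change summary on ceiling-excluded pairs.

    Returns mean change, SD of change, paired-t statistic/p-value and 95%
    CI; when ``stratify_levels`` is set, the same summary for the baseline
    activation strata {level 1, 2} and {level 3, 4}.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for change statistics")
    base = np.array([b.scaled for b, _ in pairs])
    fup = np.array([f.scaled for _, f in pairs])
    out = _paired_summary(base, fup)
    if stratify_levels:
        lev = np.array([b.level for b, _ in pairs])
        for name, mask in (("levels_12", lev <= 2), ("levels_34", lev >= 3)):
            out[name] = (
                _paired_summary(base[mask], fup[mask]) if mask.sum() >= 2 else None
            )
    return out


def _paired_summary(base, fup) -> dict:
    diff = fup - base
    n = len(diff)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        t_stat, p = 0.0 if mean == 0 else np.inf, 1.0 if mean == 0 else 0.0
        ci = (mean, mean)
    else:
        res = stats.ttest_rel(fup, base)
        t_stat, p = float(res.statistic), float(res.pvalue)
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    return {
        "n": n,
        "mean_change": mean,
        "sd_change": sd,
        "t": t_stat,
        "p_value": p,
        "ci95": ci,
    }


def meaningful_change(
    pairs: Sequence[tuple],
    threshold: float = 5.0,
    *,
    strict: bool = False,
    clusters: Sequence | None = None,
) -> dict:
    """Proportions with a clinically meaningful activation change.

    A change of ``threshold`` points or more counts as an increase
    (``strict=True`` switches to strictly-greater-than semantics);
    symmetrically for decreases.  Percentages are one-decimal values
    computed from integer counts; with ``clusters`` the same breakdown is
    returned per cluster.
    """
    diff = np.array([f.scaled - b.scaled for b, f in pairs])

    def _summ(d):
        n = len(d)
        inc = int((d > threshold).sum()) if strict else int((d >= threshold).sum())
        dec = int((d < -threshold).sum()) if strict else int((d <= -threshold).sum())
        return {
            "n": n,
            "n_increase": inc,
            "n_decrease": dec,
            "pct_increase": round(100.0 * inc / n, 1) if n else np.nan,
            "pct_decrease": round(100.0 * dec / n, 1) if n else np.nan,
        }

    out = _summ(diff)
    if clusters is not None:
        clusters = np.asarray(clusters)
        out["by_cluster"] = {
            int(k): _summ(diff[clusters == k]) for k in np.unique(clusters)
        }
    return out
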