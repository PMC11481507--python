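"""Differential CAZyme-family selection across bacterial phyla.

The chain mirrors the standard nonparametric workflow for overdispersed
count data: Tukey-fence outlier removal within (family, phylum) cells,
Levene (median-centered) and Shapiro-Wilk assumption checks, Kruskal-Wallis
across phyla per family, post-hoc pairwise Mann-Whitney U tests, and
Bonferroni correction across the families tested.  The final selection
intersects the Bonferroni-significant families (adjusted p below alpha,
default 1e-4) with the rule table's lignocellulolytic categories
(cellulase, hemicellulase, ligninase), excluding GT and PL class tokens and
CE4, and attaches the CBM families linked to selected families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .records import parse_family_token
from .rules import (
    ActivityRuleTable,
    FunctionalCall,
    FunctionalCategory,
    LIGNOCELLULOLYTIC_CATEGORIES,
    categorize_activities,
)

logger = logging.getLogger(__name__)


@dataclass
class AssumptionReport:
    family: str
    levene_p: Optional[float]
    shapiro_p: Optional[float]
    assumptions_met: bool


@dataclass
class SelectionResult:
    family: str
    kw_H: float
    df: int
    p_raw: float
    p_adjusted: float
    significant: bool
    category: Optional[FunctionalCategory] = None


def remove_outliers(values: Sequence[float], k: float = 1.5) -> np.ndarray:
    """Drop values outside the Tukey fences [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation; an all-equal or empty vector is
    returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return x
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return x[(x >= lo) & (x <= hi)]


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank tie correction) and chi-square p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValidationError("empty group")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def check_assumptions(
    matrix: pd.DataFrame,
    groups: Sequence,
    alpha: float = 0.05,
    outlier_k: Optional[float] = 1.5,
) -> list[AssumptionReport]:
    """Levene (Brown-Forsythe) and Shapiro-Wilk per family.

    assumptions_met requires both p-values above *alpha* — i.e. no evidence
    against homoscedasticity or normality.  Constant cells make Shapiro
    inapplicable (reported as None, assumptions not met).
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    if min((groups == g).sum() for g in labels) < 3:
        raise ValidationError("each group needs at least 3 members")
    reports = []
    for family in matrix.columns:
        col = matrix[family].to_numpy(dtype=float)
        samples = []
        for g in labels:
            cell = col[groups == g]
            if outlier_k is not None:
                cell = remove_outliers(cell, outlier_k)
            if len(cell) >= 3:
                samples.append(cell)
        if len(samples) < 2:
            reports.append(AssumptionReport(family, None, None, False))
            continue
        levene_p: Optional[float]
        shapiro_p: Optional[float]
        try:
            _, levene_p = stats.levene(*samples, center="median")
            levene_p = float(levene_p)
        except Exception:
            levene_p = None
        pooled_residuals = np.concatenate([s - np.median(s) for s in samples])
        if np.ptp(pooled_residuals) == 0 or len(pooled_residuals) < 3:
            shapiro_p = None
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    _, shapiro_p = stats.shapiro(pooled_residuals)
                    shapiro_p = float(shapiro_p)
                except Exception:
                    shapiro_p = None
        met = (
            levene_p is not None
            and shapiro_p is not None
            and levene_p > alpha
            and shapiro_p > alpha
        )
        reports.append(AssumptionReport(family, levene_p, shapiro_p, met))
    return reports


def posthoc_pairwise(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U p-values between all group pairs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa, xb = values[groups == a], values[groups == b]
            if len(xa) == 0 or len(xb) == 0:
                logger.warning("post-hoc pair (%s, %s) skipped: empty group", a, b)
                continue
            if np.ptp(np.concatenate([xa, xb])) == 0:
                p = 1.0
            else:
                _, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            out.loc[a, b] = out.loc[b, a] = float(p)
    np.fill_diagonal(out.values, 1.0)
    return out


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """p * m capped at 1 (m = number of tests)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(p * len(p), 1.0)


def run_family_selection(
    matrix: pd.DataFrame,
    groups: Sequence,
    rules: Optional[ActivityRuleTable] = None,
    alpha: float = 1e-4,
    outlier_k: Optional[float] = 1.5,
) -> list[SelectionResult]:
    """Kruskal-Wallis per family with Bonferroni correction across families.

    Outliers are removed within each (family, phylum) cell before testing.
    Families whose post-removal values are constant get H = 0, p = 1.
    """
    groups = np.asarray(groups)
    if len(groups) != len(matrix):
        raise ValidationError("group labels must align with matrix rows")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    results = []
    for family in matrix.columns:
        col = matrix[family].to_numpy(dtype=float)
        vals, labs = [], []
        for g in labels:
            cell = col[groups == g]
            if outlier_k is not None:
                cell = remove_outliers(cell, outlier_k)
            vals.append(cell)
            labs.append(np.repeat(g, len(cell)))
        values = np.concatenate(vals)
        glab = np.concatenate(labs)
        present = pd.unique(glab)
        if len(present) < 2 or np.ptp(values) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = kruskal_wallis(values, glab)
        results.append(
            SelectionResult(
                family=family,
                kw_H=h,
                df=len(present) - 1 if len(present) >= 2 else 0,
                p_raw=p,
                p_adjusted=1.0,
                significant=False,
            )
        )
    adjusted = bonferroni([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
        r.significant = bool(p_adj < alpha)
        if rules is not None:
            r.category = family_category(r.family, rules)
    return results


def family_category(family: str, rules: ActivityRuleTable) -> FunctionalCategory:
    """Category a family maps to under the rule table (family-level key)."""
    rule = rules.lookup(family, None)
    if rule is None:
        return FunctionalCategory.OTHER
    return categorize_activities(rule.activities, rule.substrates, family, rule.category)


def select_lignocellulolytic(
    results: Sequence[SelectionResult],
    rules: ActivityRuleTable,
    calls: Optional[Sequence[FunctionalCall]] = None,
    alpha: float = 1e-4,
) -> dict:
    """Intersect significant families with the lignocellulolytic rule set.

    Keeps families with adjusted p < alpha whose rule category is cellulase,
    hemicellulase or ligninase; GT/PL class tokens and CE4 are excluded.
    CBM families are attached via gene-level linkage when *calls* is given.
    """
    selected: dict[str, FunctionalCategory] = {}
    for r in results:
        if not (r.p_adjusted < alpha):
            continue
        cls, family, _ = parse_family_token(r.family)
        if cls in ("GT", "PL", "CBM"):
            continue
        if family == "CE4":
            continue
        category = r.category if r.category is not None else family_category(family, rules)
        if category in LIGNOCELLULOLYTIC_CATEGORIES:
            selected[family] = category
    linked_cbms: set[str] = set()
    if calls is not None:
        for call in calls:
            if call.family in selected:
                linked_cbms.update(call.linked_cbms)
    if not selected:
        logger.warning("no significant lignocellulolytic families at alpha=%g", alpha)
    return {
        "families": {f: c.value for f, c in sorted(selected.items())},
        "linked_cbms": sorted(linked_cbms),
        "n_selected": len(selected),
        "n_cbms": len(linked_cbms),
        "alpha": alpha,
    }


def selection_to_frame(results: Sequence[SelectionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "kw_H": r.kw_H,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "category": r.category.value if r.category is not None else "",
            }
            for r in results
        ]
    )
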