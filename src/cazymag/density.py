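"""Gene densities, genes-per-genome summaries and host-group comparisons.

Gene density (GD) normalizes the number of genes a MAG carries in a
functional category by its total number of predicted genes, expressed as a
percentage — a coding-capacity measure that is robust to genome completeness
differences.  GPG (genes per genome) is the mean gene count of a feature
across the MAGs of a lineage.

Host-group comparisons (lower vs higher termites) use the two-sample
Wilcoxon rank-sum (Mann-Whitney) test with midranks, normal approximation
with continuity correction, and report the effect size r = |Z| / sqrt(n)
(the ``wilcox_effsize`` convention).  GD-abundance relationships use
Spearman rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .records import RANKS, MagRecord


@dataclass
class DensityRecord:
    mag_id: str
    feature: str
    gene_count: int
    gd_percent: float


@dataclass
class LineageSummary:
    lineage: str
    rank: str
    feature: str
    n_mags: int
    total_genes: int
    gpg: float
    gd_values: np.ndarray


@dataclass
class ComparisonResult:
    """Rank-sum comparison: U statistic, Z, p, effect size r = |Z|/sqrt(n)."""

    statistic: float
    z: float
    p_value: float
    effect_size_r: float
    group_sizes: tuple[int, int]


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def gene_density(gene_count: int, n_predicted_genes: int) -> float:
    """GD in percent: 100 * gene_count / n_predicted_genes."""
    if n_predicted_genes <= 0:
        raise ValidationError("n_predicted_genes must be positive")
    if gene_count < 0 or gene_count > n_predicted_genes:
        raise ValidationError(
            f"gene_count {gene_count} outside [0, {n_predicted_genes}]"
        )
    return 100.0 * gene_count / n_predicted_genes


def density_table(matrix: pd.DataFrame, mags: Sequence[MagRecord]) -> pd.DataFrame:
    """Long-format DensityRecord table for every (MAG, feature) cell."""
    sizes = {m.mag_id: m.n_predicted_genes for m in mags}
    missing = set(matrix.index) - set(sizes)
    if missing:
        raise ValidationError(f"count matrix rows without MAG metadata: {sorted(missing)[:5]}")
    rows = []
    for mag_id, row in matrix.iterrows():
        n_genes = sizes[mag_id]
        for feature, count in row.items():
            rows.append(
                {
                    "mag_id": mag_id,
                    "feature": feature,
                    "gene_count": int(count),
                    "gd_percent": gene_density(int(count), n_genes),
                }
            )
    return pd.DataFrame(rows)


def lineage_summaries(
    matrix: pd.DataFrame,
    mags: Sequence[MagRecord],
    rank: str = "phylum",
) -> list[LineageSummary]:
    """Per-(lineage, feature) totals, GPG and GD vectors.

    GPG divides the lineage's column sum by the number of retained MAGs in
    the lineage (MAGs without the feature included in the denominator).
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown taxonomic rank {rank!r}")
    by_id = {m.mag_id: m for m in mags}
    labels = {}
    for mag_id in matrix.index:
        if mag_id not in by_id:
            raise ValidationError(f"count matrix row {mag_id!r} has no MAG metadata")
        labels[mag_id] = by_id[mag_id].rank(rank)
    if all(v == "" for v in labels.values()):
        raise ValidationError(f"all MAGs have an empty {rank} label")
    summaries = []
    gd = matrix.div(
        pd.Series({m.mag_id: m.n_predicted_genes for m in mags}), axis=0
    ) * 100.0
    lineage_series = pd.Series(labels)
    for lineage, sub in matrix.groupby(lineage_series):
        if lineage == "":
            continue
        n_mags = len(sub)
        for feature in matrix.columns:
            total = int(sub[feature].sum())
            summaries.append(
                LineageSummary(
                    lineage=lineage,
                    rank=rank,
                    feature=feature,
                    n_mags=n_mags,
                    total_genes=total,
                    gpg=total / n_mags,
                    gd_values=gd.loc[sub.index, feature].to_numpy(),
                )
            )
    return summaries


def summaries_to_frame(summaries: Sequence[LineageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lineage": s.lineage,
                "rank": s.rank,
                "feature": s.feature,
                "n_mags": s.n_mags,
                "total_genes": s.total_genes,
                "gpg": s.gpg,
                "mean_gd_percent": float(np.mean(s.gd_values)) if s.n_mags else float("nan"),
            }
            for s in summaries
        ]
    )


def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (for x) and tie-corrected Z with continuity correction."""
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u1, 0.0
    diff = u1 - mu
    # continuity correction toward the mean
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - cc) / math.sqrt(sigma2)
    return u1, z


def compare_host_groups(
    gd_a: Sequence[float],
    gd_b: Sequence[float],
    paired: bool = False,
) -> ComparisonResult:
    """Compare GD between two host groups (e.g. LT vs HT MAG sets).

    Default is the unpaired two-sample rank-sum test; *paired* switches to
    the signed-rank test for genuinely paired designs.  Effect size is
    r = |Z| / sqrt(n_total).
    """
    x = np.asarray(gd_a, dtype=float)
    y = np.asarray(gd_b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    if paired:
        if len(x) != len(y):
            raise ValidationError("paired comparison requires equal-length vectors")
        res = stats.wilcoxon(x, y, correction=True, method="approx")
        n = len(x)
        z = float(getattr(res, "zstatistic", stats.norm.isf(res.pvalue / 2)))
        return ComparisonResult(
            statistic=float(res.statistic),
            z=z,
            p_value=float(res.pvalue),
            effect_size_r=min(abs(z) / math.sqrt(n), 1.0),
            group_sizes=(len(x), len(y)),
        )
    u1, z = _rank_sum_z(x, y)
    p = 2 * stats.norm.sf(abs(z))
    n = len(x) + len(y)
    return ComparisonResult(
        statistic=float(u1),
        z=float(z),
        p_value=float(min(p, 1.0)),
        effect_size_r=min(abs(z) / math.sqrt(n), 1.0),
        group_sizes=(len(x), len(y)),
    )


def correlate_gd_abundance(
    gd: Sequence[float], relative_abundance: Sequence[float]
) -> CorrelationResult:
    """Spearman rank correlation (midranks; two-sided p via t approximation)."""
    x = np.asarray(gd, dtype=float)
    y = np.asarray(relative_abundance, dtype=float)
    if len(x) != len(y):
        raise ValidationError("vectors must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(x))
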