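"""Synthetic MAG communities with planted, fully known structure.

The generator emulates the statistical shape of a termite-gut MAG survey so
that every pipeline stage can be verified against ground truth:

* per-MAG gene totals are lognormal (draft genomes of a few thousand genes);
* per-family CAZyme gene counts are negative-binomial (real per-MAG counts
  are overdispersed across lineages), with phylum-specific mean shifts for
  designated differential families;
* domain hits pass or fail the HMM validation thresholds in controlled
  proportions; secretion flags are Bernoulli per family with two correlated
  predictor flags;
* a configurable fraction of MAGs is planted to fail the completeness /
  contamination filter, and designated rare phyla are planted below the
  5-MAG cutoff;
* a lower/higher-termite gene-density shift is planted with a target
  rank-sum effect size r (converted to a count-scale mean shift through the
  normal-approximation relation r = sqrt(12 q (1-q)) * (AUC - 1/2) and
  AUC = Phi(delta / (sigma sqrt(2))));
* MAG relative abundances are coupled to gene density through a Gaussian
  copula in designated phyla, so the target Spearman rho is planted
  independently of the marginals.

All randomness flows from one master seed through named substreams, so each
table is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .records import MagRecord
from .rules import ActivityRule, ActivityRuleTable, FunctionalCategory

_CATEGORY_ACTIVITIES = {
    FunctionalCategory.CELLULASE: ("endo-β-1,4-glucanase",),
    FunctionalCategory.HEMICELLULASE: ("xylanase", "β-xylosidase"),
    FunctionalCategory.LIGNINASE: ("laccase", "peroxidase"),
    FunctionalCategory.PECTINASE: ("pectate lyase",),
    FunctionalCategory.CHITINASE: ("chitinase",),
    FunctionalCategory.OTHER: ("α-amylase",),
}

_CATEGORY_SUBSTRATES = {
    FunctionalCategory.CELLULASE: ("cellulose",),
    FunctionalCategory.HEMICELLULASE: ("xylan",),
    FunctionalCategory.LIGNINASE: ("lignin",),
    FunctionalCategory.PECTINASE: ("pectin",),
    FunctionalCategory.CHITINASE: ("chitin",),
    FunctionalCategory.OTHER: ("starch",),
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic community."""

    seed: int
    n_phyla: int = 5
    mags_per_phylum: int = 60
    family_pool_size: int = 200
    n_differential: int = 20
    fold_change: float = 4.0
    baseline_mean: float = 2.0
    baseline_mean_sigma: float = 0.4  # lognormal spread of per-family means
    nb_dispersion: float = 5.0  # NB size parameter (larger = less dispersed)
    genes_per_mag_mean: float = 2000.0
    genes_per_mag_sigma: float = 0.2  # lognormal sigma of gene totals
    secretion_prob: float = 0.6
    predictor_agreement: float = 0.8  # P(phobius copies signalp)
    invalid_hit_fraction: float = 0.1  # extra genes whose hits fail validation
    cbm_prob: float = 0.15  # P(categorized gene carries a linked CBM)
    orphan_cbm_per_mag: float = 0.5  # Poisson mean of CBM-only genes per MAG
    qc_fail_fraction: float = 0.1
    rare_phylum_sizes: tuple[int, ...] = (2, 3)
    lt_fraction: float = 0.5
    host_effect_r: float = 0.0  # target rank-sum effect size on cellulase GD
    gd_abundance_rho: float = 0.0  # target Spearman rho in designated phyla
    correlated_phyla: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1 < self.gd_abundance_rho < 1:
            raise ConfigurationError("gd_abundance_rho must lie in (-1, 1)")
        if self.fold_change <= 0:
            raise ConfigurationError("fold_change must be positive")
        for p in (self.secretion_prob, self.qc_fail_fraction, self.lt_fraction,
                  self.cbm_prob, self.invalid_hit_fraction, self.predictor_agreement):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted structure, re-derivable by direct counting of the tables."""

    differential_families: dict[str, str]  # family -> elevated phylum
    category_of_family: dict[str, str]
    mag_category_counts: dict[str, dict[str, int]]  # validated genes
    mag_secreted_category_counts: dict[str, dict[str, int]]
    qc_fail_mags: list[str]
    rare_phyla: list[str]
    host_effect_r: float
    gd_abundance_rho: float
    correlated_phyla: list[str]
    n_mags: int
    n_genes_valid: int


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    """Named substream off the master seed."""
    digest = hashlib.sha256(f"{config.seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def _family_pool(config: SyntheticConfig) -> list[tuple[str, FunctionalCategory]]:
    """Family tokens with planted categories.

    Roughly 15% cellulase, 15% hemicellulase, 6% ligninase, 5% pectinase,
    5% chitinase, remainder other; GH3 and CE4 always present (excluded by
    the engine).
    """
    rng = _rng(config, "families")
    n = config.family_pool_size
    pool: list[tuple[str, FunctionalCategory]] = [
        ("GH3", FunctionalCategory.EXCLUDED),
        ("CE4", FunctionalCategory.EXCLUDED),
    ]
    fractions = [
        (FunctionalCategory.CELLULASE, 0.15),
        (FunctionalCategory.HEMICELLULASE, 0.15),
        (FunctionalCategory.LIGNINASE, 0.06),
        (FunctionalCategory.PECTINASE, 0.05),
        (FunctionalCategory.CHITINASE, 0.05),
    ]
    counters = {"GH": 4, "CE": 5, "AA": 1, "PL": 1, "GT": 1}

    def next_token(cls: str) -> str:
        token = f"{cls}{counters[cls]}"
        counters[cls] += 1
        return token

    remaining = n - len(pool)
    for category, frac in fractions:
        k = round(n * frac)
        for _ in range(min(k, remaining)):
            cls = {"cellulase": "GH", "hemicellulase": "GH", "ligninase": "AA",
                   "pectinase": "PL", "chitinase": "GH"}[category.value]
            pool.append((next_token(cls), category))
            remaining -= 1
    for _ in range(remaining):
        cls = rng.choice(["GH", "CE", "GT"], p=[0.6, 0.2, 0.2])
        pool.append((next_token(str(cls)), FunctionalCategory.OTHER))
    return pool[:n]


def build_rule_table(config: SyntheticConfig) -> ActivityRuleTable:
    rules = []
    for family, category in _family_pool(config):
        rules.append(
            ActivityRule(
                key=family,
                activities=frozenset(_CATEGORY_ACTIVITIES.get(category, ())),
                substrates=frozenset(_CATEGORY_SUBSTRATES.get(category, ())),
                category=category,
            )
        )
    return ActivityRuleTable(rules)


def _host_latent_shift(config: SyntheticConfig) -> float:
    """Latent-normal shift delta planting the target rank-sum effect size.

    For the Mann-Whitney normal approximation, r = sqrt(12 q (1-q)) *
    (AUC - 1/2) with q the LT fraction; two unit-variance normals separated
    by delta have AUC = Phi(delta / sqrt(2)).  Cellulase totals are then
    drawn as a monotone (quantile) transform of the latent variable, so the
    planted AUC carries over to gene density exactly up to count ties.
    """
    r = config.host_effect_r
    if r == 0:
        return 0.0
    q = config.lt_fraction
    auc = 0.5 + r / np.sqrt(12 * q * (1 - q))
    if not 0 < auc < 1:
        raise ConfigurationError(f"host_effect_r={r} infeasible at lt_fraction={q}")
    return float(np.sqrt(2) * stats.norm.ppf(auc))


@dataclass
class _Planted:
    """Internal: everything up to the count matrix, before gene emission."""

    roster: list[tuple[str, str]]
    families: list[str]
    category: dict[str, FunctionalCategory]
    counts: np.ndarray
    elevated: dict[str, str]
    host_group: np.ndarray
    genes_total: np.ndarray
    abundance: np.ndarray
    completeness: np.ndarray
    contamination: np.ndarray
    fail_idx: set[int]
    rare: list[str]
    rules: ActivityRuleTable


def _plant(config: SyntheticConfig) -> _Planted:
    pool = _family_pool(config)
    rules = build_rule_table(config)
    families = [f for f, _ in pool]
    category = {f: c for f, c in pool}

    rng_means = _rng(config, "means")
    base_mean = {
        f: (config.baseline_mean if c is not FunctionalCategory.OTHER
            else float(config.baseline_mean * rng_means.lognormal(0, config.baseline_mean_sigma)))
        for f, c in pool
    }

    # planted differential lignocellulolytic families, one elevated phylum each
    rng_diff = _rng(config, "differential")
    phyla = [f"Phylum{chr(65 + i)}" for i in range(config.n_phyla)]
    ligno = [f for f, c in pool if c in (FunctionalCategory.CELLULASE,
                                         FunctionalCategory.HEMICELLULASE,
                                         FunctionalCategory.LIGNINASE)]
    n_diff = min(config.n_differential, len(ligno))
    diff_families = sorted(str(f) for f in rng_diff.choice(ligno, size=n_diff, replace=False))
    elevated = {f: phyla[int(rng_diff.integers(len(phyla)))] for f in diff_families}

    # MAG roster: phyla + planted rare phyla
    rng_mags = _rng(config, "mags")
    roster: list[tuple[str, str]] = []  # (mag_id, phylum)
    for p in phyla:
        for k in range(config.mags_per_phylum):
            roster.append((f"{p}_MAG{k:04d}", p))
    rare = []
    for i, size in enumerate(config.rare_phylum_sizes):
        p = f"RarePhylum{chr(65 + i)}"
        rare.append(p)
        for k in range(size):
            roster.append((f"{p}_MAG{k:04d}", p))
    n_mags = len(roster)

    # quality fields: a planted fraction of non-rare MAGs fails the QC filter
    n_fail = int(round(config.qc_fail_fraction * config.n_phyla * config.mags_per_phylum))
    fail_idx = set(
        rng_mags.choice(config.n_phyla * config.mags_per_phylum, size=n_fail, replace=False).tolist()
    )
    completeness = rng_mags.uniform(60, 100, size=n_mags)
    contamination = rng_mags.uniform(0, 8, size=n_mags)
    for i in sorted(fail_idx):
        if rng_mags.random() < 0.5:
            completeness[i] = rng_mags.uniform(10, 49.9)
        else:
            contamination[i] = rng_mags.uniform(10.0, 30)

    genes_total = np.maximum(
        rng_mags.lognormal(np.log(config.genes_per_mag_mean), config.genes_per_mag_sigma, n_mags),
        500,
    ).astype(int)
    host_group = np.where(rng_mags.random(n_mags) < config.lt_fraction, "LT", "HT")

    # per-(MAG, family) valid gene counts
    rng_counts = _rng(config, "counts")
    theta = config.nb_dispersion
    counts = np.zeros((n_mags, len(families)), dtype=int)
    cellulase_cols = [j for j, f in enumerate(families)
                      if category[f] is FunctionalCategory.CELLULASE]
    host_delta = _host_latent_shift(config)
    mu_matrix = np.empty((n_mags, len(families)))
    for j, f in enumerate(families):
        mu = np.full(n_mags, base_mean[f])
        if f in elevated:
            mu[[p == elevated[f] for _, p in roster]] *= config.fold_change
        mu_matrix[:, j] = mu
        if host_delta != 0 and j in cellulase_cols:
            continue  # drawn jointly below
        p_nb = theta / (theta + mu)
        counts[:, j] = rng_counts.negative_binomial(theta, p_nb)
    if host_delta != 0:
        # latent z (shifted for HT) -> NB quantile of the cellulase total,
        # scaled by each MAG's gene total so GD stays monotone in z; the
        # total is split across cellulase families multinomially
        cell_mean = float(mu_matrix[:, cellulase_cols].mean(axis=0).sum())
        cell_var = float(
            (mu_matrix[:, cellulase_cols].mean(axis=0)
             + mu_matrix[:, cellulase_cols].mean(axis=0) ** 2 / theta).sum()
        )
        theta_tot = cell_mean**2 / (cell_var - cell_mean)
        z = rng_counts.standard_normal(n_mags) + host_delta * (host_group == "HT")
        u = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
        base_total = stats.nbinom.ppf(u, theta_tot, theta_tot / (theta_tot + cell_mean))
        totals = np.round(base_total * genes_total / config.genes_per_mag_mean).astype(int)
        for i in range(n_mags):
            w = mu_matrix[i, cellulase_cols]
            counts[i, cellulase_cols] = rng_counts.multinomial(totals[i], w / w.sum())

    # relative abundance: Gaussian copula against cellulase GD in designated phyla
    rng_ab = _rng(config, "abundance")
    abundance = rng_ab.lognormal(np.log(0.3), 1.0, n_mags)
    corr_phyla = set(config.correlated_phyla)
    if config.gd_abundance_rho != 0 and corr_phyla:
        gd_cell = counts[:, cellulase_cols].sum(axis=1) / genes_total
        rho_pearson = 2 * np.sin(np.pi * config.gd_abundance_rho / 6)
        for p in corr_phyla:
            idx = np.array([i for i, (_, ph) in enumerate(roster) if ph == p])
            if len(idx) < 3:
                continue
            u = (stats.rankdata(gd_cell[idx]) - 0.5) / len(idx)
            z_gd = stats.norm.ppf(u)
            eps = rng_ab.standard_normal(len(idx))
            z_ab = rho_pearson * z_gd + np.sqrt(1 - rho_pearson**2) * eps
            abundance[idx] = np.exp(np.log(0.3) + 1.0 * z_ab)
    abundance = np.minimum(abundance, 100.0)

    return _Planted(
        roster=roster,
        families=families,
        category=category,
        counts=counts,
        elevated=elevated,
        host_group=host_group,
        genes_total=genes_total,
        abundance=abundance,
        completeness=completeness,
        contamination=contamination,
        fail_idx=fail_idx,
        rare=rare,
        rules=rules,
    )


def _mag_records(config: SyntheticConfig, planted: _Planted) -> tuple[list[MagRecord], list[str]]:
    rng = _rng(config, "mag-extras")
    hosts = ["Nasutitermes sp.", "Reticulitermes sp.", "Macrotermes sp."]
    mags: list[MagRecord] = []
    qc_fail_ids: list[str] = []
    for i, (mag_id, phylum) in enumerate(planted.roster):
        if i in planted.fail_idx:
            qc_fail_ids.append(mag_id)
        mags.append(
            MagRecord(
                mag_id=mag_id,
                taxonomy=f"d__Bacteria;p__{phylum};c__;o__;f__F_{phylum};g__;s__",
                completeness=round(float(planted.completeness[i]), 2),
                contamination=round(float(planted.contamination[i]), 2),
                n_predicted_genes=int(planted.genes_total[i]),
                coding_density=round(float(rng.uniform(85, 95)), 2),
                host_species=hosts[i % len(hosts)],
                host_group=str(planted.host_group[i]),
                host_family_or_subfamily="Termitidae" if planted.host_group[i] == "HT" else "Rhinotermitidae",
                diet="wood",
                gut_compartment="P3",
                relative_abundance=round(float(planted.abundance[i]), 4),
            )
        )
    return mags, qc_fail_ids


def generate_count_matrix(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Count-matrix shortcut (no gene-level tables).

    Returns (MAG x family count matrix, per-MAG metadata frame with
    phylum / host_group / n_predicted_genes / relative_abundance columns,
    planted-truth dict).  Counts use the same substreams as
    :func:`generate_community`, so the planted structure is identical;
    intended for statistical recovery experiments.
    """
    planted = _plant(config)
    mag_ids = [m for m, _ in planted.roster]
    matrix = pd.DataFrame(planted.counts, index=pd.Index(mag_ids, name="mag_id"),
                          columns=planted.families)
    meta = pd.DataFrame(
        {
            "phylum": [p for _, p in planted.roster],
            "host_group": planted.host_group,
            "n_predicted_genes": planted.genes_total,
            "relative_abundance": planted.abundance,
        },
        index=matrix.index,
    )
    truth = {
        "differential_families": dict(planted.elevated),
        "category_of_family": {f: c.value for f, c in planted.category.items()},
        "rare_phyla": planted.rare,
        "host_effect_r": config.host_effect_r,
        "gd_abundance_rho": config.gd_abundance_rho,
        "correlated_phyla": list(config.correlated_phyla),
        "cellulase_families": [f for f, c in planted.category.items()
                               if c is FunctionalCategory.CELLULASE],
    }
    return matrix, meta, truth


def generate_community(
    config: SyntheticConfig,
) -> tuple[list[MagRecord], pd.DataFrame, pd.DataFrame, pd.DataFrame, ActivityRuleTable, SyntheticTruth]:
    """Generate one community.

    Returns (MAG records, dbCAN-overview frame, SignalP frame, Phobius
    frame, rule table, truth).  The overview/signal frames use exactly the
    TSV dialect :mod:`cazymag.ingest` consumes.
    """
    planted = _plant(config)
    roster = planted.roster
    families = planted.families
    category = planted.category
    counts = planted.counts
    rules = planted.rules
    mags, qc_fail_ids = _mag_records(config, planted)

    # emit gene-level tables
    rng_genes = _rng(config, "genes")
    cbm_pool = ["CBM4", "CBM6", "CBM9", "CBM22", "CBM35", "CBM62"]
    overview_rows: list[dict] = []
    signalp_rows: list[dict] = []
    phobius_rows: list[dict] = []
    mag_cat_counts: dict[str, dict[str, int]] = {}
    mag_sec_counts: dict[str, dict[str, int]] = {}
    n_valid_genes = 0

    def hit_row(gene_id, mag_id, length, family, start, end, valid, substrates=""):
        if valid:
            ev = 10.0 ** rng_genes.uniform(-50, -16)
            score = rng_genes.uniform(105, 600)
            cov = rng_genes.uniform(0.4, 1.0)
        else:
            which = rng_genes.integers(3)
            ev = 10.0 ** rng_genes.uniform(-14, -5) if which == 0 else 10.0 ** rng_genes.uniform(-50, -16)
            score = rng_genes.uniform(10, 95) if which == 1 else rng_genes.uniform(105, 600)
            cov = rng_genes.uniform(0.05, 0.3) if which == 2 else rng_genes.uniform(0.4, 1.0)
        return {
            "gene_id": gene_id, "mag_id": mag_id, "length_aa": length,
            "family": family, "start_aa": start, "end_aa": end,
            "evalue": f"{ev:.3e}", "score": round(float(score), 1),
            "coverage": round(float(cov), 3), "substrates": substrates,
            "diamond_identity": round(float(rng_genes.uniform(55, 99)), 1),
            "diamond_evalue": f"{10.0 ** rng_genes.uniform(-60, -20):.3e}",
        }

    for i, (mag_id, phylum) in enumerate(roster):
        cat_counts: dict[str, int] = {}
        sec_counts: dict[str, int] = {}
        gene_no = 0
        for j, f in enumerate(families):
            cat = category[f]
            for _ in range(int(counts[i, j])):
                gene_no += 1
                gene_id = f"{mag_id}_g{gene_no:05d}"
                length = int(rng_genes.integers(250, 900))
                end = int(rng_genes.integers(length // 2, length))
                substrates = ";".join(_CATEGORY_SUBSTRATES.get(cat, ()))
                overview_rows.append(hit_row(gene_id, mag_id, length, f, 1, end, True, substrates))
                if rng_genes.random() < config.cbm_prob and cat not in (
                    FunctionalCategory.OTHER, FunctionalCategory.EXCLUDED
                ):
                    cbm = cbm_pool[int(rng_genes.integers(len(cbm_pool)))]
                    overview_rows.append(hit_row(gene_id, mag_id, length, cbm, 1, end, True))
                signalp = rng_genes.random() < config.secretion_prob
                phobius = signalp if rng_genes.random() < config.predictor_agreement \
                    else rng_genes.random() < config.secretion_prob
                if signalp:
                    signalp_rows.append({"gene_id": gene_id, "prediction": "SP"})
                if phobius:
                    phobius_rows.append({"gene_id": gene_id, "prediction": "SIGNAL"})
                n_valid_genes += 1
                if cat not in (FunctionalCategory.OTHER, FunctionalCategory.EXCLUDED):
                    cat_counts[cat.value] = cat_counts.get(cat.value, 0) + 1
                    if signalp or phobius:
                        sec_counts[cat.value] = sec_counts.get(cat.value, 0) + 1
        # genes whose hits fail validation (must vanish downstream)
        n_invalid = rng_genes.poisson(config.invalid_hit_fraction * max(1, gene_no))
        for _ in range(n_invalid):
            gene_no += 1
            gene_id = f"{mag_id}_g{gene_no:05d}"
            length = int(rng_genes.integers(250, 900))
            f = families[int(rng_genes.integers(len(families)))]
            overview_rows.append(
                hit_row(gene_id, mag_id, length, f, 1, int(rng_genes.integers(125, length)), False)
            )
        # CBM-only genes (dropped by linkage)
        for _ in range(rng_genes.poisson(config.orphan_cbm_per_mag)):
            gene_no += 1
            gene_id = f"{mag_id}_g{gene_no:05d}"
            length = int(rng_genes.integers(250, 900))
            cbm = cbm_pool[int(rng_genes.integers(len(cbm_pool)))]
            overview_rows.append(
                hit_row(gene_id, mag_id, length, cbm, 1, int(rng_genes.integers(125, length)), True)
            )
        mag_cat_counts[mag_id] = cat_counts
        mag_sec_counts[mag_id] = sec_counts

    truth = SyntheticTruth(
        differential_families=dict(planted.elevated),
        category_of_family={f: c.value for f, c in category.items()},
        mag_category_counts=mag_cat_counts,
        mag_secreted_category_counts=mag_sec_counts,
        qc_fail_mags=sorted(qc_fail_ids),
        rare_phyla=planted.rare,
        host_effect_r=config.host_effect_r,
        gd_abundance_rho=config.gd_abundance_rho,
        correlated_phyla=sorted(config.correlated_phyla),
        n_mags=len(roster),
        n_genes_valid=n_valid_genes,
    )
    overview = pd.DataFrame(overview_rows)
    signalp_df = pd.DataFrame(signalp_rows, columns=["gene_id", "prediction"])
    phobius_df = pd.DataFrame(phobius_rows, columns=["gene_id", "prediction"])
    return mags, overview, signalp_df, phobius_df, rules, truth


def simulate_tree(
    n_tips: int,
    seed: int,
    planted_clade_size: int = 0,
    balanced: bool = False,
    labels: Optional[Sequence[str]] = None,
) -> tuple[str, list[str]]:
    """Random (or balanced) bifurcating Newick tree with an optional planted
    clade returned as a list of tip labels."""
    if n_tips < 4:
        raise ConfigurationError("need at least 4 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i:03d}" for i in range(n_tips)]
    else:
        labels = list(labels)
        if len(labels) != n_tips:
            raise ConfigurationError("labels length must equal n_tips")

    def build(lab: list[str]) -> str:
        if len(lab) == 1:
            return lab[0]
        if balanced:
            k = len(lab) // 2
        else:
            k = int(rng.integers(1, len(lab)))
        return f"({build(lab[:k])},{build(lab[k:])})"

    clade: list[str] = []
    if planted_clade_size:
        if planted_clade_size > n_tips - 2:
            raise ConfigurationError("planted clade too large")
        clade = labels[:planted_clade_size]
        rest = labels[planted_clade_size:]
        newick = f"({build(clade)},{build(rest)});"
    else:
        newick = build(labels) + ";"
    return newick, clade


def clade_trait(
    tips: Sequence[str],
    clade: Sequence[str],
    shift: float,
    seed: int,
    sigma: float = 1.0,
) -> np.ndarray:
    """Gaussian trait elevated by *shift* on the planted clade."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, sigma, len(tips))
    members = set(clade)
    return x + shift * np.array([t in members for t in tips], dtype=float)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(config: SyntheticConfig, directory) -> dict:
    """Generate a community and write every table the pipeline consumes.

    Emits mag_metadata.tsv, overview.tsv, signalp.tsv, phobius.tsv,
    rules.tsv, tree.nwk, truth.json, config.json and a manifest with sha256
    checksums of every file.
    """
    from .ingest import write_mag_metadata

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mags, overview, signalp_df, phobius_df, rules, truth = generate_community(config)
    write_mag_metadata(mags, directory / "mag_metadata.tsv")
    overview.to_csv(directory / "overview.tsv", sep="\t", index=False)
    signalp_df.to_csv(directory / "signalp.tsv", sep="\t", index=False)
    phobius_df.to_csv(directory / "phobius.tsv", sep="\t", index=False)
    rules.to_tsv(directory / "rules.tsv")
    # tree over a subset of QC-passing MAG ids so traits join by tip label
    passing = [m.mag_id for m in mags
               if m.completeness >= 50 and m.contamination < 10][:64]
    n_tips = max(len(passing), 4)
    newick, clade = simulate_tree(
        n_tips, seed=config.seed, planted_clade_size=max(4, n_tips // 8),
        labels=passing if len(passing) >= 4 else None,
    )
    (directory / "tree.nwk").write_text(newick + "\n")
    (directory / "truth.json").write_text(
        json.dumps({**dataclasses.asdict(truth), "planted_clade": clade}, indent=1)
    )
    (directory / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=1))
    files = [
        "mag_metadata.tsv", "overview.tsv", "signalp.tsv", "phobius.tsv",
        "rules.tsv", "tree.nwk", "truth.json", "config.json",
    ]
    manifest = {
        "seed": config.seed,
        "files": {f: _sha256(directory / f) for f in files},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def verify_bundle(directory) -> bool:
    """Re-hash a bundle against its manifest (tamper detection)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return all(_sha256(directory / f) == h for f, h in manifest["files"].items())


# --- study-structure replay -------------------------------------------------

#: phylum tallies with the structure of a large termite-gut MAG survey:
#: 22 phyla / 2223 MAGs, of which 7 phyla hold fewer than 5 MAGs (19 MAGs),
#: leaving 2204 MAGs in 15 phyla after the rare-phylum filter.
STUDY_PHYLUM_TALLIES = {
    "Bacillota": 509,
    "Bacteroidota": 450,
    "Spirochaetota": 300,
    "Pseudomonadota": 200,
    "Actinomycetota": 150,
    "Desulfobacterota": 120,
    "Fibrobacterota": 100,
    "Verrucomicrobiota": 90,
    "Elusimicrobiota": 80,
    "Planctomycetota": 70,
    "Synergistota": 50,
    "Patescibacteria": 40,
    "Acidobacteriota": 25,
    "Thermoplasmatota": 15,
    "Campylobacterota": 5,
    "Chlamydiota": 1,
    "Cyanobacteriota": 2,
    "Myxococcota": 2,
    "Cloacimonadota": 3,
    "Chloroflexota": 3,
    "Fusobacteriota": 4,
    "Deferribacteria": 4,
}


def generate_study_scale_metadata(seed: int = 0) -> list[MagRecord]:
    """Metadata-only MAG roster mirroring the survey's phylum-tally shape
    (synthetic reconstruction; per-phylum proportions are illustrative, the
    totals and the rare-phylum structure are the replay target)."""
    rng = np.random.default_rng(seed)
    mags = []
    for phylum, n in STUDY_PHYLUM_TALLIES.items():
        for k in range(n):
            mags.append(
                MagRecord(
                    mag_id=f"{phylum}_M{k:04d}",
                    taxonomy=f"d__Bacteria;p__{phylum};c__;o__;f__;g__;s__",
                    completeness=round(float(rng.uniform(50, 100)), 2),
                    contamination=round(float(rng.uniform(0, 9.99)), 2),
                    n_predicted_genes=int(rng.integers(1200, 4500)),
                    coding_density=round(float(rng.uniform(85, 95)), 2),
                    host_group="HT" if rng.random() < 0.5 else "LT",
                    relative_abundance=round(float(rng.uniform(0.004, 19.8)), 4),
                )
            )
    return mags
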