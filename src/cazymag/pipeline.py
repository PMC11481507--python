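"""End-to-end pipeline orchestration with a config file and a run manifest.

Stages: ingest -> validate/classify -> count matrices -> family selection ->
densities / host-group comparisons -> ordination statistics -> phylogenetic
signal (when a tree is supplied) -> report.  Every threshold defaults to
the survey convention (completeness 50 / contamination 10 / rare-phylum 5;
HMM e-value 1e-15, score 100, coverage 0.35; selection alpha 1e-4); the
manifest snapshots the config, per-stage output checksums and warnings so a
rerun with identical inputs is bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .density import compare_host_groups, correlate_gd_abundance, density_table, lineage_summaries, summaries_to_frame
from .errors import StageError
from .ingest import (
    filter_genome_quality,
    filter_rare_phyla,
    parse_gene_annotations,
    parse_mag_metadata,
    phylum_tallies,
    qc_report,
    write_mag_metadata,
)
from .ordination import anosim, bray_curtis, embed_umap, pca, permanova, sqrt_wisconsin
from .phylo import abouheif_proximity, abouheif_test, lipa_moran, read_newick
from .rules import ActivityRuleTable, build_count_matrix, calls_to_frame, classify_collection
from .selection import run_family_selection, select_lignocellulolytic, selection_to_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mag_metadata: str
    overview: str
    rules: str
    signalp: Optional[str] = None
    phobius: Optional[str] = None
    tree: Optional[str] = None
    output_dir: str = "cazymag_out"
    min_completeness: float = 50.0
    max_contamination: float = 10.0
    min_mags_per_phylum: int = 5
    skip_quality_filter: bool = False
    evalue_max: float = 1e-15
    score_min: float = 100.0
    coverage_min: float = 0.35
    secretion_mode: str = "union"
    secreted_only: bool = True
    alpha: float = 1e-4
    outlier_k: float = 1.5
    n_permutations: int = 1000
    seed: int = 0
    run_umap: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to the output dir)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
        "warnings": [],
    }

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest["stages"].append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})
        return result

    # --- ingest + QC
    def _ingest():
        mags = parse_mag_metadata(config.mag_metadata)
        tallies_in = phylum_tallies(mags)
        after_q = mags if config.skip_quality_filter else filter_genome_quality(
            mags, config.min_completeness, config.max_contamination
        )
        retained = filter_rare_phyla(after_q, config.min_mags_per_phylum)
        report = qc_report(len(mags), len(after_q), len(retained), tallies_in, phylum_tallies(retained))
        (out / "qc_report.json").write_text(json.dumps(report, indent=1))
        write_mag_metadata(retained, out / "mags_retained.tsv")
        return retained

    mags = stage("ingest_qc", _ingest)

    # --- classify
    def _classify():
        genes = parse_gene_annotations(config.overview, config.signalp, config.phobius, mags=None)
        genes = [g for g in genes if g.mag_id in {m.mag_id for m in mags}]
        rules = ActivityRuleTable.from_tsv(config.rules)
        calls = classify_collection(genes, rules, secretion_mode=config.secretion_mode)
        calls_to_frame(calls).to_csv(out / "functional_calls.tsv", sep="\t", index=False)
        return rules, calls

    rules, calls = stage("classify", _classify)

    # --- count matrices
    def _counts():
        fam = build_count_matrix(calls, mags, level="family", secreted_only=config.secreted_only)
        cat = build_count_matrix(calls, mags, level="category", secreted_only=False)
        fam.to_csv(out / "counts_family.tsv", sep="\t")
        cat.to_csv(out / "counts_category.tsv", sep="\t")
        return fam, cat

    fam_matrix, cat_matrix = stage("count_matrices", _counts)
    phyla = np.array([m.phylum for m in mags])

    # --- family selection
    def _select():
        results = run_family_selection(
            fam_matrix, phyla, rules=rules, alpha=config.alpha, outlier_k=config.outlier_k
        )
        selection_to_frame(results).to_csv(out / "family_selection.tsv", sep="\t", index=False)
        selected = select_lignocellulolytic(results, rules, calls=calls, alpha=config.alpha)
        (out / "selected_families.json").write_text(json.dumps(selected, indent=1))
        return results, selected

    sel_results, selected = stage("family_selection", _select)

    # --- densities + host-group comparisons + GD-abundance correlations
    def _density():
        dens = density_table(cat_matrix, mags)
        dens.to_csv(out / "gene_density.tsv", sep="\t", index=False)
        summaries_to_frame(lineage_summaries(fam_matrix, mags, rank="phylum")).to_csv(
            out / "lineage_summary_family.tsv", sep="\t", index=False
        )
        host = {m.mag_id: m.host_group for m in mags}
        ra = {m.mag_id: m.relative_abundance for m in mags}
        stats_out: dict = {"host_group": {}, "gd_abundance": {}}
        for category in [c for c in cat_matrix.columns]:
            sub = dens[dens.feature == category].set_index("mag_id")["gd_percent"]
            lt = sub[[host[m] == "LT" for m in sub.index]]
            ht = sub[[host[m] == "HT" for m in sub.index]]
            if len(lt) >= 3 and len(ht) >= 3:
                cmp = compare_host_groups(lt.to_numpy(), ht.to_numpy())
                stats_out["host_group"][category] = {
                    "p_value": cmp.p_value,
                    "effect_size_r": cmp.effect_size_r,
                    "group_sizes": cmp.group_sizes,
                }
            ra_vec = np.array([ra[m] for m in sub.index])
            if len(sub) >= 3 and np.ptp(sub.to_numpy()) > 0 and np.ptp(ra_vec) > 0:
                corr = correlate_gd_abundance(sub.to_numpy(), ra_vec)
                stats_out["gd_abundance"][category] = {"rho": corr.rho, "p_value": corr.p_value, "n": corr.n}
        (out / "density_stats.json").write_text(json.dumps(stats_out, indent=1))
        return stats_out

    density_stats = stage("density_stats", _density)

    # --- ordination
    def _ordinate():
        transformed = sqrt_wisconsin(fam_matrix)
        dist = bray_curtis(transformed)
        dist.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
        res = {
            "anosim_phylum": dataclasses.asdict(
                anosim(dist, phyla, n_permutations=config.n_permutations, seed=config.seed)
            ),
            "permanova_phylum": dataclasses.asdict(
                permanova(dist, phyla, n_permutations=config.n_permutations, seed=config.seed)
            ),
        }
        host_labels = np.array([m.host_family_or_subfamily for m in mags])
        if len(set(host_labels)) >= 2 and min(np.unique(host_labels, return_counts=True)[1]) >= 2:
            res["anosim_host"] = dataclasses.asdict(
                anosim(dist, host_labels, n_permutations=config.n_permutations, seed=config.seed)
            )
        p = pca(transformed, k=min(5, len(mags) - 1, transformed.shape[1]))
        res["pca_variance_explained"] = [float(v) for v in p.variance_explained]
        if config.run_umap:
            coords = embed_umap(transformed, seed=config.seed)
            if coords is not None:
                coords.to_csv(out / "umap.tsv", sep="\t")
                res["umap"] = {"n_neighbors": 15, "n_epochs": 500, "seed": config.seed}
            else:
                manifest["warnings"].append("umap backend missing; embedding skipped")
        (out / "ordination.json").write_text(json.dumps(res, indent=1))
        return res

    ordination = stage("ordination", _ordinate)

    # --- phylogenetic signal (optional)
    signal = None
    if config.tree:
        def _signal():
            tree = read_newick(config.tree)
            W = abouheif_proximity(tree)
            tips = set(W.tips)
            dens = density_table(cat_matrix, mags).set_index(["mag_id", "feature"])["gd_percent"]
            results = {}
            for category in cat_matrix.columns:
                trait = []
                for t in W.tips:
                    trait.append(float(dens.get((t, category), np.nan)) if t in tips else np.nan)
                trait = np.array(trait)
                if np.isnan(trait).any() or np.ptp(trait[~np.isnan(trait)]) == 0:
                    continue
                i_stat, p = abouheif_test(
                    trait, tree, n_permutations=config.n_permutations, seed=config.seed, W=W
                )
                lipa = lipa_moran(trait, W, n_permutations=config.n_permutations, seed=config.seed)
                results[category] = {
                    "abouheif_I": i_stat,
                    "abouheif_p": p,
                    "n_significant_tips": len(lipa.significant_tips),
                }
            (out / "phylo_signal.json").write_text(json.dumps(results, indent=1))
            return results

        signal = stage("phylo_signal", _signal)
    else:
        manifest["warnings"].append("no tree supplied; phylo-signal stage skipped")

    # --- report
    def _report():
        report = {
            "n_mags_retained": len(mags),
            "n_phyla": len(set(phyla)),
            "n_families_tested": int(fam_matrix.shape[1]),
            "n_significant_families": int(sum(r.significant for r in sel_results)),
            "selection": selected,
            "ordination": {
                k: v for k, v in ordination.items() if k.startswith(("anosim", "permanova"))
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        return report

    stage("report", _report)

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
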