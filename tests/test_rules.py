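"""Threshold validation and the lignocellulolytic classification engine."""

import itertools

import pytest

from cazymag.errors import ConfigurationError, ValidationError
from cazymag.records import DomainHit, GeneAnnotation, MagRecord
from cazymag.rules import (
    ActivityRule,
    ActivityRuleTable,
    CELLULOLYTIC_ACTIVITIES,
    CHITINOLYTIC_ACTIVITIES,
    FunctionalCategory,
    HEMICELLULOLYTIC_ACTIVITIES,
    LIGNINOLYTIC_ACTIVITIES,
    PECTINOLYTIC_ACTIVITIES,
    build_count_matrix,
    categorize_activities,
    classify_gene,
    confirm_homology,
    is_secreted,
    link_cbms,
    validate_domain_hit,
)


def _hit(family, evalue=1e-30, score=250.0, coverage=0.8, end=200):
    return DomainHit(
        gene_id="g", family_token=family, start_aa=1, end_aa=end,
        evalue=evalue, score=score, hmm_coverage=coverage,
    )


def _gene(families, gene_id="g1", mag_id="m1", signalp=False, phobius=False,
          substrates=()):
    return GeneAnnotation(
        gene_id=gene_id, mag_id=mag_id, length_aa=400,
        domain_hits=[_hit(f) for f in families],
        signalp_flag=signalp, phobius_flag=phobius,
        substrates=list(substrates),
    )


def _table(rows):
    return ActivityRuleTable(
        ActivityRule(key=k, activities=frozenset(a), substrates=frozenset(s),
                     category=FunctionalCategory(c))
        for k, a, s, c in rows
    )


class TestValidateDomainHit:
    @pytest.mark.parametrize(
        "evalue,score,coverage,valid",
        [
            (1e-16, 101, 0.36, True),
            (1e-15, 200, 0.9, False),  # e-value threshold is strict
            (1e-20, 100, 0.9, False),  # score threshold is strict
            (1e-20, 200, 0.35, False),  # coverage threshold is strict
        ],
    )
    def test_thresholds_strict(self, evalue, score, coverage, valid):
        assert validate_domain_hit(_hit("GH5", evalue, score, coverage)) is valid


class TestConfirmHomology:
    @pytest.mark.parametrize(
        "identity,evalue,ok",
        [(60, 1e-20, True), (50, 1e-20, False), (60, 1e-15, False)],
    )
    def test_thresholds_strict(self, identity, evalue, ok):
        assert confirm_homology(identity, evalue) is ok


class TestIsSecreted:
    def test_modes(self):
        g = _gene(["GH5"], signalp=True, phobius=False)
        assert is_secreted(g, "union") is True
        assert is_secreted(g, "intersection") is False
        assert is_secreted(g, "signalp_only") is True
        assert is_secreted(_gene(["GH5"]), "union") is False

    def test_unknown_mode(self):
        with pytest.raises(ConfigurationError):
            is_secreted(_gene(["GH5"]), "majority")


RULES = _table([
    ("GH9", ["endo-β-1,4-glucanase"], ["cellulose"], "cellulase"),
    ("GH5", ["endo-β-1,4-glucanase"], ["cellulose"], "cellulase"),
    ("GH5_4", ["endo-β-1,4-glucanase", "xyloglucanase"], ["xyloglucan"], "hemicellulase"),
    ("AA3", ["aryl alcohol oxidase"], ["lignin"], "ligninase"),
    ("PL1", ["pectate lyase"], ["pectin"], "pectinase"),
    ("GH18", ["chitinase"], ["chitin"], "chitinase"),
    ("GH3", ["β-glucosidase"], ["cellobiose"], "excluded"),
    ("CE4", ["chitin deacetylase"], ["chitin"], "excluded"),
    ("GT2", [], ["glycan"], "other"),
])


class TestClassifyGene:
    def test_pure_cellulase(self):
        calls = classify_gene(_gene(["GH9"]), RULES)
        assert [c.category for c in calls] == [FunctionalCategory.CELLULASE]

    def test_hemicellulase_precedence_with_subfamily_override(self):
        """Mixed endoglucanase + xyloglucanase activity goes hemicellulase,
        via the GH5_4 subfamily rule overriding the GH5 family rule."""
        gene = GeneAnnotation(
            gene_id="g", mag_id="m", length_aa=400,
            domain_hits=[_hit("GH5_4")],
        )
        calls = classify_gene(gene, RULES)
        assert len(calls) == 1
        assert calls[0].category is FunctionalCategory.HEMICELLULASE
        assert calls[0].subfamily == "GH5_4"

    def test_ligninase(self):
        calls = classify_gene(_gene(["AA3"]), RULES)
        assert calls[0].category is FunctionalCategory.LIGNINASE

    def test_gh3_always_excluded(self):
        calls = classify_gene(_gene(["GH3"]), RULES)
        assert calls[0].category is FunctionalCategory.EXCLUDED

    def test_ce4_excluded_without_acetylxylan_substrate(self):
        assert classify_gene(_gene(["CE4"]), RULES)[0].category is FunctionalCategory.EXCLUDED
        with_substrate = _gene(["CE4"], substrates=["acetylxylan"])
        # with acetylxylan among predicted substrates CE4 escapes the exclusion
        assert classify_gene(with_substrate, RULES)[0].category is not FunctionalCategory.EXCLUDED

    def test_unknown_family_is_other_not_crash(self):
        calls = classify_gene(_gene(["GH999"]), RULES)
        assert calls[0].category is FunctionalCategory.OTHER

    def test_invalid_hits_ignored(self):
        gene = GeneAnnotation(
            gene_id="g", mag_id="m", length_aa=400,
            domain_hits=[_hit("GH9", evalue=1e-5)],
        )
        assert classify_gene(gene, RULES) == []

    def test_one_call_per_family_and_mutual_exclusion(self):
        gene = _gene(["GH9", "GH9", "GH18"])
        calls = classify_gene(gene, RULES)
        assert sorted((c.family, c.category.value) for c in calls) == [
            ("GH18", "chitinase"), ("GH9", "cellulase"),
        ]


class TestRuleEngineTruthTable:
    """classify output must equal an exhaustive truth-table evaluation of the
    precedence rules over ~100 (family, activity-set) combinations."""

    ATOMS = [
        ("endo-β-1,4-glucanase", "cell"),
        ("cellobiohydrolase", "cell"),
        ("xylanase", "hemi"),
        ("xyloglucanase", "hemi"),
        ("laccase", "lign"),
        ("pectate lyase", "pect"),
        ("chitinase", "chit"),
    ]

    @staticmethod
    def oracle(family, activities, substrates):
        """Independent truth-table evaluation of the precedence order."""
        if family == "GH3":
            return FunctionalCategory.EXCLUDED
        if family == "CE4" and "acetylxylan" not in substrates:
            return FunctionalCategory.EXCLUDED
        if any(a in HEMICELLULOLYTIC_ACTIVITIES for a in activities):
            return FunctionalCategory.HEMICELLULASE
        if activities and all(a in CELLULOLYTIC_ACTIVITIES for a in activities):
            return FunctionalCategory.CELLULASE
        if any(a in LIGNINOLYTIC_ACTIVITIES for a in activities):
            return FunctionalCategory.LIGNINASE
        if any(a in PECTINOLYTIC_ACTIVITIES for a in activities):
            return FunctionalCategory.PECTINASE
        if any(a in CHITINOLYTIC_ACTIVITIES for a in activities):
            return FunctionalCategory.CHITINASE
        return FunctionalCategory.OTHER

    def test_equivalence_over_all_combinations(self):
        families = ["GH5", "GH3", "CE4"]
        n_checked = 0
        for family in families:
            for r in range(len(self.ATOMS) + 1):
                for combo in itertools.combinations([a for a, _ in self.ATOMS], r):
                    if r > 2:
                        continue
                    activities = frozenset(combo)
                    got = categorize_activities(activities, frozenset(), family, None)
                    assert got is self.oracle(family, activities, frozenset()), (
                        family, combo,
                    )
                    n_checked += 1
        assert n_checked >= 80  # truth table actually exercised


def _mag(mag_id):
    return MagRecord(
        mag_id=mag_id, taxonomy="d__Bacteria;p__X;c__;o__;f__;g__;s__",
        completeness=90, contamination=1, n_predicted_genes=2000, coding_density=90,
    )


class TestLinkCbms:
    def test_cbm_attached_to_categorized_call(self):
        gene = _gene(["GH5", "CBM6"])
        calls = link_cbms(gene, classify_gene(gene, RULES))
        assert calls[0].linked_cbms == ["CBM6"]

    def test_orphan_cbm_dropped(self):
        gene = _gene(["CBM4"])
        calls = link_cbms(gene, classify_gene(gene, RULES))
        assert calls == []

    def test_cbm_on_excluded_gene_dropped(self):
        gene = _gene(["GH3", "CBM6"])
        calls = link_cbms(gene, classify_gene(gene, RULES))
        assert len(calls) == 1
        assert calls[0].category is FunctionalCategory.EXCLUDED
        assert calls[0].linked_cbms == []


class TestCountMatrix:
    def test_within_gene_family_dedup(self):
        gene = _gene(["GH9", "GH9"])
        calls = classify_gene(gene, RULES)
        m = build_count_matrix(calls, [_mag("m1")], level="family")
        assert m.loc["m1", "GH9"] == 1

    def test_all_zero_row_present(self):
        gene = _gene(["GH9"], mag_id="m1")
        calls = classify_gene(gene, RULES)
        m = build_count_matrix(calls, [_mag("m1"), _mag("m2")], level="family")
        assert m.loc["m2"].sum() == 0

    def test_secreted_only_filter(self):
        g1 = _gene(["GH9"], gene_id="g1", signalp=True)
        g2 = _gene(["GH9"], gene_id="g2")
        calls = classify_gene(g1, RULES) + classify_gene(g2, RULES)
        m = build_count_matrix(calls, [_mag("m1")], level="family", secreted_only=True)
        assert m.loc["m1", "GH9"] == 1

    def test_category_level_excludes_other_and_excluded(self):
        calls = []
        for i, fam in enumerate(["GH9", "GH3", "GT2"]):
            calls.extend(classify_gene(_gene([fam], gene_id=f"g{i}"), RULES))
        m = build_count_matrix(calls, [_mag("m1")], level="category")
        assert list(m.columns) == ["cellulase"]

    def test_order_invariance(self):
        genes = [_gene(["GH9"], gene_id=f"g{i}") for i in range(5)]
        calls = [c for g in genes for c in classify_gene(g, RULES)]
        m1 = build_count_matrix(calls, [_mag("m1")], level="family")
        m2 = build_count_matrix(calls[::-1], [_mag("m1")], level="family")
        assert m1.equals(m2)

    def test_unknown_level_rejected(self):
        with pytest.raises(ConfigurationError):
            build_count_matrix([], [_mag("m1")], level="clan")

    def test_no_cbm_columns_without_linkage(self):
        gene = _gene(["GH5", "CBM6"])
        calls = link_cbms(gene, classify_gene(gene, RULES))
        m = build_count_matrix(calls, [_mag("m1")], level="family")
        assert "CBM6" not in m.columns
        m2 = build_count_matrix(calls, [_mag("m1")], level="family", include_linked_cbms=True)
        assert m2.loc["m1", "CBM6"] == 1
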