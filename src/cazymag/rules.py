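"""Threshold validation of CAZyme calls and the lignocellulolytic rule engine.

Domain calls are accepted only when they pass the dbCAN-style HMM thresholds
(e-value < 1e-15, score > 100, coverage > 0.35, all strict) and can optionally
be confirmed by a DIAMOND best hit (e-value < 1e-15, identity > 50%).

Classification maps each categorized domain family on a gene to one
functional category — cellulase, hemicellulase, ligninase, pectinase or
chitinase — using an activity-rule table ((sub)family -> activity terms ->
category).  Precedence:

1. a subfamily rule overrides its family rule (GH5_4 beats GH5);
2. families flagged EXCLUDED are excluded outright (GH3, whose broad
   β-glucosidase specificity precludes (hemi)cellulase assignment; CE4
   unless its predicted substrates include acetylxylan);
3. any hemicellulolytic activity wins even when endo-β-1,4-glucanase
   activity co-occurs;
4. otherwise, only classically cellulolytic activities -> cellulase;
5. peroxidase / aryl-alcohol-oxidase / laccase activities -> ligninase;
6. pectate lyase / pectin methylesterase / pectin acetylesterase -> pectinase;
7. chitinase / chitin deacetylase / acetylglucosaminosidase -> chitinase;
8. anything else -> other.

Carbohydrate-binding modules (CBMs) are never categorized on their own:
they are attached to a categorized catalytic call on the same gene, and CBMs
on genes without a categorized GH/AA domain are dropped from all counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError
from .records import DomainHit, GeneAnnotation, MagRecord, parse_family_token

PathLike = Union[str, Path]


class FunctionalCategory(str, Enum):
    CELLULASE = "cellulase"
    HEMICELLULASE = "hemicellulase"
    LIGNINASE = "ligninase"
    PECTINASE = "pectinase"
    CHITINASE = "chitinase"
    EXCLUDED = "excluded"
    OTHER = "other"


#: activity-term vocabulary driving precedence rules 3-7
HEMICELLULOLYTIC_ACTIVITIES = {
    "xylanase",
    "endo-β-1,4-xylanase",
    "β-xylosidase",
    "xyloglucanase",
    "arabinofuranosidase",
    "α-arabinofuranosidase",
    "α-arabinosidase",
    "arabinosidase",
    "endo-mannanase",
    "β-mannosidase",
    "mannanase",
    "β-galactosidase",
    "acetylxylan esterase",
}

CELLULOLYTIC_ACTIVITIES = {
    "endo-β-1,4-glucanase",
    "exo-β-1,4-glucanase",
    "cellobiohydrolase",
    "cellodextrin phosphorylase",
    "cellobiose phosphorylase",
    "lytic polysaccharide monooxygenase",
    "endo-β-1,3-glucanase",
    "lichenase",
    "laminarinase",
}

LIGNINOLYTIC_ACTIVITIES = {
    "laccase",
    "peroxidase",
    "lignin peroxidase",
    "manganese peroxidase",
    "aryl alcohol oxidase",
}

PECTINOLYTIC_ACTIVITIES = {
    "pectate lyase",
    "pectin lyase",
    "pectin methylesterase",
    "pectin acetylesterase",
}

CHITINOLYTIC_ACTIVITIES = {
    "chitinase",
    "chitin deacetylase",
    "acetylglucosaminosidase",
}

SECRETION_MODES = ("union", "intersection", "signalp_only")
COUNT_LEVELS = ("family", "subfamily", "category")

LIGNOCELLULOLYTIC_CATEGORIES = frozenset(
    {
        FunctionalCategory.CELLULASE,
        FunctionalCategory.HEMICELLULASE,
        FunctionalCategory.LIGNINASE,
    }
)


@dataclass(frozen=True)
class ActivityRule:
    """(Sub)family -> activities/substrates -> functional category."""

    key: str
    activities: frozenset[str]
    substrates: frozenset[str]
    category: FunctionalCategory


class ActivityRuleTable:
    """Rule table keyed by family or subfamily token; subfamily keys override
    family keys at lookup time."""

    def __init__(self, rules: Iterable[ActivityRule]):
        self.rules: dict[str, ActivityRule] = {}
        for rule in rules:
            if rule.key in self.rules:
                raise ValidationError(f"duplicate rule key {rule.key!r}")
            parse_family_token(rule.key)  # grammar check
            self.rules[rule.key] = rule

    def __len__(self) -> int:
        return len(self.rules)

    def __contains__(self, key: str) -> bool:
        return key in self.rules

    def lookup(self, family: str, subfamily: Optional[str] = None) -> Optional[ActivityRule]:
        """Most specific applicable rule, or None."""
        if subfamily is not None and subfamily in self.rules:
            return self.rules[subfamily]
        return self.rules.get(family)

    @classmethod
    def from_tsv(cls, path: PathLike) -> "ActivityRuleTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
        for col in ("key", "activities", "substrates", "category"):
            if col not in df.columns:
                raise FormatError(f"rule table {path} is missing required column '{col}'")
        rules = []
        for row in df.itertuples(index=False):
            try:
                category = FunctionalCategory(row.category.strip().lower())
            except ValueError:
                raise FormatError(f"unknown category {row.category!r} for key {row.key!r}") from None
            rules.append(
                ActivityRule(
                    key=row.key.strip(),
                    activities=frozenset(s.strip() for s in row.activities.split(";") if s.strip()),
                    substrates=frozenset(s.strip() for s in row.substrates.split(";") if s.strip()),
                    category=category,
                )
            )
        return cls(rules)

    def to_tsv(self, path: PathLike) -> None:
        pd.DataFrame(
            [
                {
                    "key": r.key,
                    "activities": ";".join(sorted(r.activities)),
                    "substrates": ";".join(sorted(r.substrates)),
                    "category": r.category.value,
                }
                for r in self.rules.values()
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class FunctionalCall:
    """One categorized (gene, family) assignment."""

    gene_id: str
    mag_id: str
    family: str
    subfamily: Optional[str]
    category: FunctionalCategory
    secreted: bool
    linked_cbms: list[str] = field(default_factory=list)


def validate_domain_hit(
    hit: DomainHit,
    evalue_max: float = 1e-15,
    score_min: float = 100.0,
    coverage_min: float = 0.35,
) -> bool:
    """True iff the HMM hit passes all three thresholds (each strict)."""
    if not 0 <= hit.hmm_coverage <= 1:
        raise ValidationError(f"coverage {hit.hmm_coverage} outside [0, 1]")
    return (
        hit.evalue < evalue_max
        and hit.score > score_min
        and hit.hmm_coverage > coverage_min
    )


def confirm_homology(
    identity: float,
    evalue: float,
    id_min: float = 50.0,
    evalue_max: float = 1e-15,
) -> bool:
    """True iff the DIAMOND best hit confirms the call (both thresholds strict)."""
    return evalue < evalue_max and identity > id_min


def is_secreted(gene: GeneAnnotation, mode: str = "union") -> bool:
    """Combine the two signal-peptide predictor flags."""
    if mode == "union":
        return gene.signalp_flag or gene.phobius_flag
    if mode == "intersection":
        return gene.signalp_flag and gene.phobius_flag
    if mode == "signalp_only":
        return gene.signalp_flag
    raise ConfigurationError(f"unknown secretion mode {mode!r}; expected one of {SECRETION_MODES}")


def categorize_activities(
    activities: frozenset[str] | set[str],
    substrates: frozenset[str] | set[str],
    family: str,
    table_category: Optional[FunctionalCategory] = None,
) -> FunctionalCategory:
    """Apply the activity-precedence rules to one (family, activity-set) pair.

    Exclusions dominate; then hemicellulase > cellulase > ligninase >
    pectinase > chitinase; a rule-table category is the fallback when no
    activity term matches; otherwise OTHER.
    """
    if family == "GH3":
        return FunctionalCategory.EXCLUDED
    if family == "CE4":
        # acetylxylan esterase activity (a hemicellulose-debranching function)
        # is the only thing that rescues CE4 from the blanket exclusion
        if "acetylxylan" in {s.lower() for s in substrates}:
            return FunctionalCategory.HEMICELLULASE
        return FunctionalCategory.EXCLUDED
    if table_category is FunctionalCategory.EXCLUDED:
        return FunctionalCategory.EXCLUDED
    if activities & HEMICELLULOLYTIC_ACTIVITIES:
        return FunctionalCategory.HEMICELLULASE
    if activities and activities <= CELLULOLYTIC_ACTIVITIES:
        return FunctionalCategory.CELLULASE
    if activities & LIGNINOLYTIC_ACTIVITIES:
        return FunctionalCategory.LIGNINASE
    if activities & PECTINOLYTIC_ACTIVITIES:
        return FunctionalCategory.PECTINASE
    if activities & CHITINOLYTIC_ACTIVITIES:
        return FunctionalCategory.CHITINASE
    if table_category is not None:
        return table_category
    return FunctionalCategory.OTHER


def classify_gene(
    gene: GeneAnnotation,
    rules: ActivityRuleTable,
    secretion_mode: str = "union",
    validated_only: bool = True,
) -> list[FunctionalCall]:
    """Assign one functional call per distinct categorized domain family on
    the gene.  CBM and GT domains never generate calls of their own (CBMs
    are handled by :func:`link_cbms`; glycosyltransferases are not part of
    the lignocellulolytic categorization and fall to OTHER via the table).
    """
    secreted = is_secreted(gene, secretion_mode)
    calls: dict[tuple[str, Optional[str]], FunctionalCall] = {}
    for hit in gene.domain_hits:
        if validated_only and not validate_domain_hit(hit):
            continue
        if hit.cazy_class == "CBM":
            continue
        rule = rules.lookup(hit.family, hit.subfamily)
        if rule is None:
            activities: frozenset[str] = frozenset()
            substrates = frozenset(gene.substrates)
            table_category = None
        else:
            activities = rule.activities
            substrates = rule.substrates | frozenset(gene.substrates)
            table_category = rule.category
        category = categorize_activities(activities, substrates, hit.family, table_category)
        key = (hit.family, hit.subfamily if rule is not None and rule.key == hit.subfamily else None)
        if key not in calls:
            calls[(hit.family, key[1])] = FunctionalCall(
                gene_id=gene.gene_id,
                mag_id=gene.mag_id,
                family=hit.family,
                subfamily=key[1],
                category=category,
                secreted=secreted,
            )
    return list(calls.values())


def link_cbms(
    gene: GeneAnnotation,
    calls: Sequence[FunctionalCall],
    validated_only: bool = True,
) -> list[FunctionalCall]:
    """Attach the gene's CBM domains to its categorized catalytic calls.

    CBMs on genes whose calls are all EXCLUDED/OTHER are dropped (they are
    not connected to a categorized enzyme and vanish from downstream counts).
    """
    cbms = sorted(
        {
            hit.family
            for hit in gene.domain_hits
            if hit.cazy_class == "CBM" and (not validated_only or validate_domain_hit(hit))
        }
    )
    if not cbms:
        return list(calls)
    out = []
    for call in calls:
        if call.category in LIGNOCELLULOLYTIC_CATEGORIES or call.category in (
            FunctionalCategory.PECTINASE,
            FunctionalCategory.CHITINASE,
        ):
            call.linked_cbms = list(cbms)
        out.append(call)
    return out


def classify_collection(
    genes: Iterable[GeneAnnotation],
    rules: ActivityRuleTable,
    secretion_mode: str = "union",
) -> list[FunctionalCall]:
    """Classify every gene and run CBM linkage; order-independent output."""
    all_calls: list[FunctionalCall] = []
    for gene in genes:
        calls = classify_gene(gene, rules, secretion_mode=secretion_mode)
        all_calls.extend(link_cbms(gene, calls))
    return all_calls


def build_count_matrix(
    calls: Sequence[FunctionalCall],
    mags: Sequence[MagRecord],
    level: str = "family",
    secreted_only: bool = False,
    include_linked_cbms: bool = False,
) -> pd.DataFrame:
    """MAG x feature integer count matrix.

    Every retained MAG appears as a row (all-zero rows included).  A gene
    contributes at most 1 to any single cell; at category level it
    contributes once per distinct category.  With *include_linked_cbms*
    (family/subfamily level only) linked CBM families gain their own
    columns, counting genes that carry them attached to a categorized call.
    """
    if level not in COUNT_LEVELS:
        raise ConfigurationError(f"unknown level {level!r}; expected one of {COUNT_LEVELS}")
    mag_ids = [m.mag_id for m in mags]
    known = set(mag_ids)
    cells: set[tuple[str, str, str]] = set()  # (mag, feature, gene) dedup
    for call in calls:
        if call.mag_id not in known:
            raise ValidationError(f"call for gene {call.gene_id} references unknown MAG {call.mag_id!r}")
        if secreted_only and not call.secreted:
            continue
        if call.category in (FunctionalCategory.EXCLUDED,):
            continue
        if level == "family":
            feature = call.family
        elif level == "subfamily":
            feature = call.subfamily or call.family
        else:
            if call.category is FunctionalCategory.OTHER:
                continue
            feature = call.category.value
        cells.add((call.mag_id, feature, call.gene_id))
        if include_linked_cbms and level != "category":
            for cbm in call.linked_cbms:
                cells.add((call.mag_id, cbm, call.gene_id))
    if cells:
        df = pd.DataFrame(list(cells), columns=["mag_id", "feature", "gene_id"])
        counts = df.groupby(["mag_id", "feature"]).size().unstack(fill_value=0)
    else:
        counts = pd.DataFrame(index=pd.Index([], name="mag_id"))
    counts = counts.reindex(index=mag_ids, fill_value=0).fillna(0).astype(int)
    counts.index.name = "mag_id"
    counts = counts[sorted(counts.columns)]
    return counts


def calls_to_frame(calls: Sequence[FunctionalCall]) -> pd.DataFrame:
    """Long-format table of functional calls (for TSV export)."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "mag_id": c.mag_id,
                "family": c.family,
                "subfamily": c.subfamily or "",
                "category": c.category.value,
                "secreted": c.secreted,
                "linked_cbms": ";".join(c.linked_cbms),
            }
            for c in calls
        ]
    )
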