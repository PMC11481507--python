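"""Core domain records: genomes (MAGs), CAZyme domain hits and gene annotations.

A MAG (metagenome-assembled genome) is a draft genome binned from a
metagenomic assembly; each carries a GTDB-style 7-rank taxonomy string,
CheckM-style quality estimates, host metadata (termite species, lower/higher
termite group, diet, gut compartment) and the fraction of metagenome reads
recruited to it.  Genes carry validated CAZyme domain calls (dbCAN-overview
style), an optional DIAMOND best-hit confirmation and two signal-peptide
predictor flags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import FormatError, ValidationError

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

#: CAZy class grammar: GH/GT/PL/CE/AA/CBM followed by a family number,
#: optionally a _subfamily number (e.g. GH5, GH5_4, CBM6, AA3_2).
FAMILY_TOKEN_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)(?:_(\d+))?$")

HOST_GROUPS = ("LT", "HT")


def split_taxonomy(taxonomy: str) -> dict[str, str]:
    """Split a GTDB taxonomy string into its 7 rank slots.

    ``"d__Bacteria;p__Spirochaetota;c__;o__;f__;g__;s__"`` yields
    ``{"domain": "Bacteria", "phylum": "Spirochaetota", "class": "", ...}``.
    Lower ranks may be empty; exactly 7 slots are required.
    """
    parts = [p.strip() for p in taxonomy.split(";")]
    if len(parts) != 7:
        raise ValidationError(
            f"taxonomy must have exactly 7 rank slots, got {len(parts)}: {taxonomy!r}"
        )
    out: dict[str, str] = {}
    for rank, prefix, part in zip(RANKS, RANK_PREFIXES, parts):
        if not part.startswith(prefix):
            raise ValidationError(
                f"taxonomy slot for {rank} must start with {prefix!r}: {part!r}"
            )
        out[rank] = part[len(prefix):]
    return out


def join_taxonomy(ranks: dict[str, str]) -> str:
    return ";".join(f"{p}{ranks.get(r, '')}" for r, p in zip(RANKS, RANK_PREFIXES))


def parse_family_token(token: str) -> tuple[str, str, Optional[str]]:
    """Validate a CAZyme family token and return (class, family, subfamily).

    ``"GH5_4"`` -> ``("GH", "GH5", "GH5_4")``; ``"CBM6"`` -> ``("CBM", "CBM6", None)``.
    """
    m = FAMILY_TOKEN_RE.match(token)
    if m is None:
        raise FormatError(f"invalid CAZyme family token: {token!r}")
    cls, fam_num, sub_num = m.groups()
    family = f"{cls}{fam_num}"
    subfamily = f"{family}_{sub_num}" if sub_num is not None else None
    return cls, family, subfamily


@dataclass
class MagRecord:
    """One genome with taxonomy, quality, host metadata and abundance."""

    mag_id: str
    taxonomy: str
    completeness: float
    contamination: float
    n_predicted_genes: int
    coding_density: float
    host_species: str = ""
    host_group: str = "LT"
    host_family_or_subfamily: str = ""
    diet: str = ""
    gut_compartment: str = ""
    relative_abundance: float = 0.0
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValidationError(
                f"{self.mag_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0:
            raise ValidationError(
                f"{self.mag_id}: contamination {self.contamination} negative"
            )
        if self.n_predicted_genes < 0:
            raise ValidationError(f"{self.mag_id}: negative predicted-gene count")
        if not 0 <= self.relative_abundance <= 100:
            raise ValidationError(
                f"{self.mag_id}: relative abundance {self.relative_abundance} outside [0, 100]"
            )
        if self.host_group not in HOST_GROUPS:
            raise ValidationError(
                f"{self.mag_id}: host_group must be one of {HOST_GROUPS}, got {self.host_group!r}"
            )
        self.ranks = split_taxonomy(self.taxonomy)

    @property
    def phylum(self) -> str:
        return self.ranks["phylum"]

    def rank(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown taxonomic rank {rank!r}")
        return self.ranks[rank]


@dataclass
class DomainHit:
    """One HMM/DIAMOND domain call on a predicted protein."""

    gene_id: str
    family_token: str
    start_aa: int
    end_aa: int
    evalue: float
    score: float
    hmm_coverage: float
    source: str = "hmm"

    def __post_init__(self) -> None:
        self.cazy_class, self.family, self.subfamily = parse_family_token(self.family_token)
        if self.start_aa > self.end_aa:
            raise ValidationError(
                f"{self.gene_id}/{self.family_token}: start_aa > end_aa"
            )
        if self.evalue < 0:
            raise ValidationError(f"{self.gene_id}: negative e-value")
        if not 0 <= self.hmm_coverage <= 1:
            raise ValidationError(
                f"{self.gene_id}/{self.family_token}: coverage {self.hmm_coverage} outside [0, 1]"
            )
        if self.source not in ("hmm", "dbcan_sub", "diamond"):
            raise ValidationError(f"unknown hit source {self.source!r}")


@dataclass
class GeneAnnotation:
    """One predicted gene with its CAZyme domain hits and secretion flags."""

    gene_id: str
    mag_id: str
    length_aa: int
    domain_hits: list[DomainHit] = field(default_factory=list)
    diamond_identity: Optional[float] = None
    diamond_evalue: Optional[float] = None
    signalp_flag: bool = False
    phobius_flag: bool = False
    substrates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValidationError(f"{self.gene_id}: non-positive protein length")
        for hit in self.domain_hits:
            if hit.end_aa > self.length_aa:
                raise ValidationError(
                    f"{self.gene_id}: domain {hit.family_token} end {hit.end_aa} "
                    f"beyond protein length {self.length_aa}"
                )
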