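"""Input parsing, genome-quality filtering and rare-lineage removal.

All tables are UTF-8, tab-delimited, one header row; lines starting with
``#`` are comments.  Taxonomy strings and trees are consumed pre-computed
(GTDB-Tk / IQ-TREE outputs are upstream of this package); quality estimates
are CheckM-style completeness/contamination percentages.

The two filters mirror the genome-retention policy of genome-centric
termite-gut surveys: keep MAGs that are at least 50% complete and less than
10% contaminated, then drop every phylum represented by fewer than 5 MAGs.
Both boundaries follow that wording exactly: completeness is inclusive,
contamination and the phylum count are strict.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import FormatError, ValidationError
from .records import DomainHit, GeneAnnotation, MagRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MAG_REQUIRED_COLUMNS = (
    "mag_id",
    "taxonomy",
    "completeness",
    "contamination",
    "n_predicted_genes",
    "coding_density",
    "host_species",
    "host_group",
    "host_family_or_subfamily",
    "diet",
    "gut_compartment",
    "relative_abundance",
)

OVERVIEW_REQUIRED_COLUMNS = (
    "gene_id",
    "mag_id",
    "length_aa",
    "family",
    "start_aa",
    "end_aa",
    "evalue",
    "score",
    "coverage",
    "substrates",
    "diamond_identity",
    "diamond_evalue",
)

#: values accepted as a positive signal-peptide prediction
_TRUTHY = {"sp", "sp(sec/spi)", "y", "yes", "true", "1", "signal", "signal_peptide"}


def _read_tsv(path: PathLike, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{what} table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} table {path} is missing required column '{col}'")
    return df


def _to_float(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(
            f"row {row}: cannot parse {column} value {value!r} as a number"
        ) from None


def _to_int(value: str, column: str, row: int) -> int:
    try:
        return int(float(value))
    except ValueError:
        raise ValidationError(
            f"row {row}: cannot parse {column} value {value!r} as an integer"
        ) from None


def parse_mag_metadata(path: PathLike) -> list[MagRecord]:
    """Parse a MAG metadata table into :class:`MagRecord` objects.

    Row order is preserved; columns beyond the required set are kept as
    opaque per-record metadata in ``record.extra``.
    """
    df = _read_tsv(path, MAG_REQUIRED_COLUMNS, "MAG metadata")
    extra_cols = [c for c in df.columns if c not in MAG_REQUIRED_COLUMNS]
    records: list[MagRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = row._asdict()
        mag_id = row["mag_id"]
        if mag_id in seen:
            raise ValidationError(f"row {i}: duplicate mag_id {mag_id!r}")
        seen.add(mag_id)
        records.append(
            MagRecord(
                mag_id=mag_id,
                taxonomy=row["taxonomy"],
                completeness=_to_float(row["completeness"], "completeness", i),
                contamination=_to_float(row["contamination"], "contamination", i),
                n_predicted_genes=_to_int(row["n_predicted_genes"], "n_predicted_genes", i),
                coding_density=_to_float(row["coding_density"], "coding_density", i),
                host_species=row["host_species"],
                host_group=row["host_group"],
                host_family_or_subfamily=row["host_family_or_subfamily"],
                diet=row["diet"],
                gut_compartment=row["gut_compartment"],
                relative_abundance=_to_float(row["relative_abundance"], "relative_abundance", i),
                extra={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_mag_metadata(mags: Iterable[MagRecord], path: PathLike) -> None:
    """Write MAG records back to the tab-delimited dialect (round-trip safe)."""
    rows = []
    for m in mags:
        row = {c: getattr(m, c) for c in MAG_REQUIRED_COLUMNS}
        row.update(m.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_genome_quality(
    mags: Sequence[MagRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> list[MagRecord]:
    """Keep MAGs with completeness >= *min_completeness* and contamination
    strictly below *max_contamination*.
    """
    if not mags:
        logger.warning("filter_genome_quality called on an empty collection")
        return []
    retained = [
        m
        for m in mags
        if m.completeness >= min_completeness and m.contamination < max_contamination
    ]
    logger.info(
        "genome-quality filter: %d retained, %d discarded",
        len(retained),
        len(mags) - len(retained),
    )
    return retained


def phylum_tallies(mags: Iterable[MagRecord]) -> Counter:
    """Number of MAGs per phylum."""
    return Counter(m.phylum for m in mags)


def filter_rare_phyla(
    mags: Sequence[MagRecord], min_mags_per_phylum: int = 5
) -> list[MagRecord]:
    """Drop every MAG whose phylum has fewer than *min_mags_per_phylum*
    members in the input (strict: a phylum with exactly the minimum is kept).
    """
    tallies = phylum_tallies(mags)
    for m in mags:
        if not m.phylum:
            raise ValidationError(f"{m.mag_id}: empty phylum slot")
    retained = [m for m in mags if tallies[m.phylum] >= min_mags_per_phylum]
    removed = {p: n for p, n in tallies.items() if n < min_mags_per_phylum}
    logger.info(
        "rare-phylum filter: %d retained; removed %d phyla (%s)",
        len(retained),
        len(removed),
        ", ".join(f"{p}:{n}" for p, n in sorted(removed.items())) or "none",
    )
    return retained


def _read_signal_table(path: Optional[PathLike], what: str) -> set[str]:
    """Gene ids flagged positive by one signal-peptide predictor."""
    if path is None:
        return set()
    df = _read_tsv(path, ("gene_id", "prediction"), what)
    return {
        row.gene_id
        for row in df.itertuples(index=False)
        if str(row.prediction).strip().lower() in _TRUTHY
    }


def parse_gene_annotations(
    overview_path: PathLike,
    signalp_path: Optional[PathLike] = None,
    phobius_path: Optional[PathLike] = None,
    mags: Optional[Sequence[MagRecord]] = None,
) -> list[GeneAnnotation]:
    """Parse a dbCAN-overview-style domain table plus signal-peptide tables.

    One row of the overview table is one domain hit; rows are grouped by
    ``gene_id`` into :class:`GeneAnnotation` objects.  Genes absent from a
    signal-peptide table get that predictor's flag ``False``.  When *mags*
    is given, every ``mag_id`` must resolve to a known MAG.
    """
    df = _read_tsv(overview_path, OVERVIEW_REQUIRED_COLUMNS, "dbCAN overview")
    signalp_pos = _read_signal_table(signalp_path, "SignalP")
    phobius_pos = _read_signal_table(phobius_path, "Phobius")
    known_mags = {m.mag_id for m in mags} if mags is not None else None

    genes: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        gene_id = row["gene_id"]
        hit = DomainHit(
            gene_id=gene_id,
            family_token=row["family"],
            start_aa=_to_int(row["start_aa"], "start_aa", i),
            end_aa=_to_int(row["end_aa"], "end_aa", i),
            evalue=_to_float(row["evalue"], "evalue", i),
            score=_to_float(row["score"], "score", i),
            hmm_coverage=_to_float(row["coverage"], "coverage", i),
        )
        entry = genes.setdefault(
            gene_id,
            {
                "mag_id": row["mag_id"],
                "length_aa": _to_int(row["length_aa"], "length_aa", i),
                "hits": [],
                "substrates": [],
                "diamond_identity": None,
                "diamond_evalue": None,
            },
        )
        if known_mags is not None and entry["mag_id"] not in known_mags:
            raise ValidationError(
                f"row {i}: gene {gene_id} references unknown MAG {entry['mag_id']!r}"
            )
        entry["hits"].append(hit)
        for s in str(row["substrates"]).split(";"):
            s = s.strip()
            if s and s not in entry["substrates"]:
                entry["substrates"].append(s)
        if row["diamond_identity"] not in ("", "-", "NA"):
            entry["diamond_identity"] = _to_float(row["diamond_identity"], "diamond_identity", i)
        if row["diamond_evalue"] not in ("", "-", "NA"):
            entry["diamond_evalue"] = _to_float(row["diamond_evalue"], "diamond_evalue", i)

    annotations = [
        GeneAnnotation(
            gene_id=gene_id,
            mag_id=entry["mag_id"],
            length_aa=entry["length_aa"],
            domain_hits=entry["hits"],
            diamond_identity=entry["diamond_identity"],
            diamond_evalue=entry["diamond_evalue"],
            signalp_flag=gene_id in signalp_pos,
            phobius_flag=gene_id in phobius_pos,
            substrates=entry["substrates"],
        )
        for gene_id, entry in genes.items()
    ]
    return annotations


def qc_report(
    n_input: int,
    n_after_quality: int,
    n_after_rare: int,
    tallies_in: Counter,
    tallies_out: Counter,
) -> dict:
    """JSON-serializable QC summary (counts in/out per filter)."""
    return {
        "n_input": n_input,
        "n_after_quality_filter": n_after_quality,
        "n_discarded_quality": n_input - n_after_quality,
        "n_after_rare_phylum_filter": n_after_rare,
        "n_discarded_rare_phylum": n_after_quality - n_after_rare,
        "phylum_tallies_before": dict(sorted(tallies_in.items())),
        "phylum_tallies_after": dict(sorted(tallies_out.items())),
    }
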