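"""FASTA and taxonomy-table parsing, and grouping of segments into viruses.

FASTA reading is backed by Bio.SeqIO with additional validation so malformed
input fails with a useful message (line number for text before the first
header, accession for an empty sequence).  The taxonomy table is a TSV with
one row per accession carrying ICTV ranks, host category, completeness and an
optional segment label.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .records import HOST_CATEGORIES, SequenceRecord, TaxonomyAnnotation, VirusAssembly

__all__ = [
    "FastaParseError",
    "TaxonomyTableError",
    "read_fasta",
    "write_fasta",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "assemble_viruses",
]

logger = logging.getLogger(__name__)

TAXONOMY_COLUMNS = (
    "accession",
    "species",
    "genus",
    "family",
    "order",
    "phylum",
    "kingdom",
    "realm",
    "host_category",
    "genome_composition",
    "is_complete",
    "segment_label",
)

_MANDATORY_COLUMNS = ("accession", "species", "genus", "host_category", "is_complete")


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input."""


class TaxonomyTableError(ValueError):
    """Raised for an invalid taxonomy TSV (missing columns, duplicates)."""


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) FASTA file into SequenceRecords.

    The accession is the first whitespace-delimited token of each header.
    Residues are upper-cased and U is normalized to T.

    Raises
    ------
    FastaParseError
        If sequence text precedes the first ``>`` header (reported with its
        line number) or a header has no sequence (reported by accession).
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
            break
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: empty sequence under accession {rec.id!r}")
        records.append(
            SequenceRecord(
                accession=rec.id,
                description=rec.description,
                residues=str(rec.seq),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as normalized FASTA (upper-case, U already folded to T)."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.description if rec.description else rec.accession
            if not header.startswith(rec.accession):
                header = f"{rec.accession} {header}"
            handle.write(f">{header}\n")
            for i in range(0, rec.length, width):
                handle.write(rec.residues[i : i + width] + "\n")


def read_taxonomy_table(path: str | Path) -> list[TaxonomyAnnotation]:
    """Read the taxonomy TSV into annotations.

    Host strings outside the closed vocabulary are mapped to ``unknown`` with
    a logged warning; missing optional ranks are stored as empty strings.

    Raises
    ------
    TaxonomyTableError
        On a missing mandatory column or duplicate accessions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise TaxonomyTableError(f"{path}: missing mandatory column {col!r}")
    dupes = df["accession"][df["accession"].duplicated()].unique().tolist()
    if dupes:
        raise TaxonomyTableError(f"{path}: duplicate accessions: {dupes}")

    annotations: list[TaxonomyAnnotation] = []
    for row in df.to_dict("records"):
        host = row.get("host_category", "").strip()
        if host not in HOST_CATEGORIES:
            logger.warning(
                "accession %s: host %r not in vocabulary, mapped to 'unknown'",
                row["accession"],
                host,
            )
            host = "unknown"
        annotations.append(
            TaxonomyAnnotation(
                accession=row["accession"],
                species=row["species"],
                genus=row.get("genus", ""),
                family=row.get("family", ""),
                order=row.get("order", ""),
                phylum=row.get("phylum", ""),
                kingdom=row.get("kingdom", ""),
                realm=row.get("realm", ""),
                host_category=host,
                genome_composition=row.get("genome_composition", ""),
                is_complete=_parse_bool(row.get("is_complete", "true")),
                segment_label=row.get("segment_label", ""),
            )
        )
    return annotations


def write_taxonomy_table(annotations: Iterable[TaxonomyAnnotation], path: str | Path) -> None:
    """Write annotations back out as a validated TSV (provenance echo)."""
    rows = []
    for ann in annotations:
        row = {col: getattr(ann, col) for col in TAXONOMY_COLUMNS}
        row["is_complete"] = "true" if ann.is_complete else "false"
        rows.append(row)
    pd.DataFrame(rows, columns=list(TAXONOMY_COLUMNS)).to_csv(path, sep="\t", index=False)


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in {"true", "t", "1", "yes", "y"}:
        return True
    if v in {"false", "f", "0", "no", "n"}:
        return False
    raise TaxonomyTableError(f"unparseable is_complete value {value!r}")


def assemble_viruses(
    records: Sequence[SequenceRecord],
    annotations: Sequence[TaxonomyAnnotation],
) -> list[VirusAssembly]:
    """Group per-segment records into one assembly per virus species.

    Segments of one species are ordered lexicographically by
    ``(segment_label, accession)``.  Records whose accession is absent from
    the annotations are excluded with a logged count.  Assemblies are
    returned sorted by species name so output order is independent of the
    input record order.

    Raises
    ------
    ValueError
        If segments of one species carry conflicting genus values.
    """
    by_accession = {ann.accession: ann for ann in annotations}
    grouped: dict[str, list[tuple[TaxonomyAnnotation, SequenceRecord]]] = defaultdict(list)
    n_excluded = 0
    for rec in records:
        ann = by_accession.get(rec.accession)
        if ann is None:
            n_excluded += 1
            logger.warning("record %s has no annotation; excluded", rec.accession)
            continue
        grouped[ann.species].append((ann, rec))
    if n_excluded:
        logger.warning("%d record(s) lacked annotations and were excluded", n_excluded)

    assemblies: list[VirusAssembly] = []
    for species in sorted(grouped):
        pairs = grouped[species]
        genera = {ann.genus for ann, _ in pairs}
        if len(genera) > 1:
            raise ValueError(
                f"species {species!r}: segments carry conflicting genus values {sorted(genera)}"
            )
        pairs.sort(key=lambda p: (p[0].segment_label, p[0].accession))
        assemblies.append(
            VirusAssembly(
                species=species,
                taxonomy=pairs[0][0],
                segments=tuple(rec for _, rec in pairs),
            )
        )
    return assemblies
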