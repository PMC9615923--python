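"""Core domain types: sequence records, taxonomy annotations, and per-virus assemblies.

A deposited viral genome may arrive as a single nucleotide sequence or as
several segments, each its own FASTA record.  :class:`SequenceRecord` holds one
deposit, :class:`TaxonomyAnnotation` carries its ICTV ranks and host category,
and :class:`VirusAssembly` groups all segments of one species so that
genome-scale quantities (total length, pooled GC, pooled ORFs) are well
defined for segmented and non-segmented viruses alike.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "HOST_CATEGORIES",
    "GENOME_COMPOSITIONS",
    "SequenceRecord",
    "TaxonomyAnnotation",
    "VirusAssembly",
]

#: Closed host vocabulary, in display order (fungi .. vertebrates, then unknown).
HOST_CATEGORIES = (
    "fungi",
    "plants",
    "plants+invertebrates",
    "invertebrates",
    "invertebrates+vertebrates",
    "vertebrates",
    "unknown",
)

#: Baltimore-style genome composition labels commonly seen for RNA viruses.
GENOME_COMPOSITIONS = ("+ssRNA", "-ssRNA", "dsRNA", "ssRNA-RT")

# IUPAC nucleotide one-letter codes (U accepted on input, normalized to T).
_IUPAC_NT = set("ACGTUNRYSWKMBDHV")
_VALID_RE = re.compile(r"^[ACGTUNRYSWKMBDHV]+$")


@dataclass(frozen=True)
class SequenceRecord:
    """One deposited nucleotide sequence (a genome or a single segment).

    Residues are stored upper-case with U normalized to T, so one k-mer
    alphabet serves RNA and DNA deposits.
    """

    accession: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for accession {self.accession!r}")
        normalized = self.residues.upper().replace("U", "T")
        if not _VALID_RE.match(normalized):
            bad = sorted(set(normalized) - _IUPAC_NT)
            raise ValueError(
                f"accession {self.accession!r}: non-IUPAC nucleotide codes {bad}"
            )
        object.__setattr__(self, "residues", normalized)

    @property
    def length(self) -> int:
        """Sequence length in nucleotides."""
        return len(self.residues)


@dataclass(frozen=True)
class TaxonomyAnnotation:
    """ICTV ranks, host category and completeness for one accession."""

    accession: str
    species: str
    genus: str = ""
    family: str = ""
    order: str = ""
    phylum: str = ""
    kingdom: str = ""
    realm: str = ""
    host_category: str = "unknown"
    genome_composition: str = ""
    is_complete: bool = True
    segment_label: str = ""

    def __post_init__(self) -> None:
        if self.host_category not in HOST_CATEGORIES:
            raise ValueError(
                f"host_category {self.host_category!r} not in closed vocabulary "
                f"{HOST_CATEGORIES}; map unknown hosts to 'unknown' before "
                "constructing the annotation"
            )


@dataclass(frozen=True)
class VirusAssembly:
    """All segments of one virus species, with genome-scale totals.

    ``total_length`` is the "multiple-segments" quantity: the summed length of
    all segments.  For non-segmented viruses it equals the single record's
    length.
    """

    species: str
    taxonomy: TaxonomyAnnotation
    segments: tuple[SequenceRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"assembly for {self.species!r} has no segments")

    @property
    def segment_count(self) -> int:
        return len(self.segments)

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def is_segmented(self) -> bool:
        return self.segment_count > 1
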