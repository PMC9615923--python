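"""Genome length and GC content per record and per virus.

GC content is the fraction of residues that are G or C.  By default the
denominator is the full residue count, so ambiguity codes and N dilute GC —
matching how sequence-statistics tools report GC on deposited genomes.  An
``acgt_only`` flag restricts the denominator to unambiguous A/C/G/T calls.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .records import SequenceRecord, VirusAssembly

__all__ = ["gc_content", "virus_gc", "composition_table"]


def _gc_count(residues: str) -> int:
    return residues.count("G") + residues.count("C")


def gc_content(record: SequenceRecord, acgt_only: bool = False) -> float:
    """GC fraction of one record, in [0, 1].

    With ``acgt_only=False`` (default) the denominator is the full length;
    with ``acgt_only=True`` it is the number of unambiguous A/C/G/T residues.
    """
    gc = _gc_count(record.residues)
    if acgt_only:
        denom = sum(record.residues.count(b) for b in "ACGT")
        if denom == 0:
            return 0.0
    else:
        denom = record.length
    return gc / denom


def virus_gc(assembly: VirusAssembly, acgt_only: bool = False) -> float:
    """Length-weighted GC of a whole virus: total GC count / total length."""
    gc = sum(_gc_count(seg.residues) for seg in assembly.segments)
    if acgt_only:
        denom = sum(seg.residues.count(b) for seg in assembly.segments for b in "ACGT")
        if denom == 0:
            return 0.0
    else:
        denom = assembly.total_length
    return gc / denom


def composition_table(assemblies: Sequence[VirusAssembly], acgt_only: bool = False) -> pd.DataFrame:
    """One row per virus: total length, GC, ranks, host, completeness.

    Columns: species, total_length, gc_fraction, host_category, genus, family,
    order, segment_count, is_complete.
    """
    if not assemblies:
        raise ValueError("no assemblies given")
    rows = [
        {
            "species": a.species,
            "total_length": a.total_length,
            "gc_fraction": virus_gc(a, acgt_only=acgt_only),
            "host_category": a.taxonomy.host_category,
            "genus": a.taxonomy.genus,
            "family": a.taxonomy.family,
            "order": a.taxonomy.order,
            "segment_count": a.segment_count,
            "is_complete": a.taxonomy.is_complete,
        }
        for a in assemblies
    ]
    return pd.DataFrame(rows)
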