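"""Seeded synthetic cohorts with the statistical structure of real RNA-virus deposits.

The generator emulates, by construction, the genome-scale regularities the
analysis modules measure:

* genus-clustered genome lengths — within a genus, total lengths are
  ``mean * (1 + Normal(0, sigma_rel))`` (truncated positive), so the
  within-genus relative deviation is approximately ``Normal(0, sigma_rel)``
  and the expected share of genomes within a deviation threshold ``tau`` has
  the closed form ``2*Phi(tau/sigma_rel) - 1``;
* host-dependent GC — each genus is assigned one host category and its
  background bases are drawn at that host's target GC;
* fixed multi-segment architectures — segmented genera carry one of a menu
  of segment-length layouts (by default a bipartite ~7,500 + ~3,700 nt
  layout and a tripartite ~3,500 + 2,800 + 2,800 nt layout), and the genus
  mean total length is the architecture sum, so single-segment lengths
  cluster at the layout's characteristic sizes;
* ORF density proportional to length — each segment carries
  ``round(orf_density * kb)`` embedded non-overlapping complete ORFs
  (start codon, stop-free codons, stop codon);
* protein-conserved / nucleotide-diverged homolog pairs — synonymous
  recoding replaces every codon by a uniformly chosen synonymous codon,
  preserving the translation while scrambling the k-mer content.

All randomness flows from the single config seed; identical configs yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .records import SequenceRecord, TaxonomyAnnotation, VirusAssembly

__all__ = [
    "SyntheticConfig",
    "generate",
    "synonymous_recode",
    "recoded_family_cohort",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = tuple(_STANDARD.stop_codons)

# amino acid -> tuple of codons (standard code)
_AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in _STANDARD.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, tuple())
    _AA_TO_CODONS[aa] = _AA_TO_CODONS[aa] + (codon,)

_AMINO_ACIDS = tuple(sorted(_AA_TO_CODONS))

DEFAULT_HOST_PROBS = {
    "fungi": 0.10,
    "plants": 0.30,
    "plants+invertebrates": 0.05,
    "invertebrates": 0.20,
    "invertebrates+vertebrates": 0.10,
    "vertebrates": 0.25,
}

DEFAULT_GC_BY_HOST = {
    "fungi": 0.55,
    "plants": 0.44,
    "plants+invertebrates": 0.46,
    "invertebrates": 0.48,
    "invertebrates+vertebrates": 0.47,
    "vertebrates": 0.50,
}

_PHYLA = (
    "Duplornaviricota",
    "Kitrinoviricota",
    "Lenarviricota",
    "Negarnaviricota",
    "Pisuviricota",
)
_COMPOSITIONS = ("+ssRNA", "-ssRNA", "dsRNA", "ssRNA-RT")


@dataclass
class SyntheticConfig:
    """Full parameterization of the cohort generator.

    Lengths are nucleotides; ``orf_density`` is embedded ORFs per kb;
    ``sigma_rel`` is the within-genus relative length standard deviation.
    """

    seed: int = 0
    n_genera: int = 40
    members_per_genus: int | tuple[int, int] = (4, 12)
    genus_length_median: float = 6000.0
    genus_length_log_sd: float = 0.5
    sigma_rel: float = 0.08
    host_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HOST_PROBS))
    gc_by_host: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GC_BY_HOST))
    segmented_fraction: float = 0.3
    segment_architectures: tuple[tuple[int, ...], ...] = ((7500, 3700), (3500, 2800, 2800))
    orf_density: float = 1.0
    orf_length_range: tuple[int, int] = (90, 300)
    recode_pairs: int = 0

    def validate(self) -> None:
        probs = np.array(list(self.host_probs.values()))
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("host_probs must sum to 1")
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")
        lo, hi = self.orf_length_range
        if lo < 9 or lo % 3 or hi % 3 or hi < lo:
            raise ValueError("orf_length_range must be multiples of 3, >= 9, lo <= hi")
        for host in self.host_probs:
            if host not in self.gc_by_host:
                raise ValueError(f"no GC target for host {host!r}")
        # infeasible ORF packing: worst-case footprint per kb must leave room
        if self.orf_density * (hi + 6) > 900:
            raise ValueError(
                "orf_density too high for orf_length_range: embedded ORFs would "
                "exceed 90% of sequence length"
            )


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """n random bases (as a char array) with the given expected GC."""
    return rng.choice(
        np.array(list("GCAT")), size=n, p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    )


def _random_orf(rng: np.random.Generator, length_nt: int, gc: float) -> str:
    """A complete ORF: ATG + stop-free codons at the target GC + stop codon."""
    n_internal = length_nt // 3 - 2
    bases = _draw_bases(rng, 3 * n_internal, gc)
    codons = bases.reshape(-1, 3)
    joined = ["".join(c) for c in codons]
    for idx, codon in enumerate(joined):
        if codon in _STOPS:
            joined[idx] = codon[0] + "C" + codon[2]  # TAA->TCA etc: stop removed
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(joined) + stop


def _build_segment(
    rng: np.random.Generator, length: int, gc: float, orf_density: float,
    orf_range: tuple[int, int],
) -> tuple[str, list[tuple[int, int]]]:
    """Background bases at the target GC with embedded non-overlapping ORFs.

    Returns the sequence and the 1-based inclusive ORF spans.
    """
    n_orfs = int(round(orf_density * length / 1000.0))
    lo, hi = orf_range
    orf_lens = []
    for _ in range(n_orfs):
        n_codons = rng.integers(lo // 3, hi // 3 + 1)
        orf_lens.append(int(n_codons) * 3)
    # each ORF is preceded by an in-frame guard stop so its six-frame
    # translation fragment is exactly the encoded peptide
    total_orf = sum(orf_lens) + 3 * n_orfs
    if total_orf > length:
        raise ValueError(f"segment of {length} nt cannot hold {total_orf} nt of ORFs")
    free = length - total_orf
    if n_orfs:
        gaps = rng.multinomial(free, [1.0 / (n_orfs + 1)] * (n_orfs + 1))
    else:
        gaps = np.array([free])
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    for i, gap in enumerate(gaps):
        parts.append("".join(_draw_bases(rng, int(gap), gc)))
        pos += int(gap)
        if i < n_orfs:
            guard = _STOPS[rng.integers(len(_STOPS))]
            orf = _random_orf(rng, orf_lens[i], gc)
            parts.append(guard)
            pos += 3
            spans.append((pos + 1, pos + len(orf)))
            parts.append(orf)
            pos += len(orf)
    return "".join(parts), spans


def generate(
    config: SyntheticConfig,
) -> tuple[list[SequenceRecord], list[TaxonomyAnnotation], pd.DataFrame]:
    """Generate a cohort: FASTA-ready records, taxonomy annotations, ground truth.

    The ground-truth table has one row per virus with the drawn genus mean,
    host, GC target, architecture, per-segment lengths and embedded ORF
    spans (the latter as a python-literal string, per segment).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    hosts = list(config.host_probs)
    probs = [config.host_probs[h] for h in hosts]

    records: list[SequenceRecord] = []
    annotations: list[TaxonomyAnnotation] = []
    truth_rows: list[dict] = []

    for g in range(1, config.n_genera + 1):
        genus = f"Genus{g:03d}"
        family = f"Family{(g - 1) // 3 + 1:03d}"
        order = f"Order{(g - 1) // 9 + 1:02d}"
        phylum = _PHYLA[(g - 1) % len(_PHYLA)]
        composition = _COMPOSITIONS[(g - 1) % len(_COMPOSITIONS)]
        host = hosts[rng.choice(len(hosts), p=probs)]
        gc = config.gc_by_host[host]
        segmented = rng.random() < config.segmented_fraction
        if segmented and config.segment_architectures:
            arch = config.segment_architectures[
                rng.integers(len(config.segment_architectures))
            ]
            # segmented genera have a fixed architecture: the genus mean total
            # length is the architecture sum, not a fresh lognormal draw
            mean_total = float(sum(arch))
        else:
            arch = (1,)
            segmented = False
            mean_total = config.genus_length_median * float(
                np.exp(rng.normal(0.0, config.genus_length_log_sd))
            )
        if isinstance(config.members_per_genus, int):
            n_members = config.members_per_genus
        else:
            lo, hi = config.members_per_genus
            n_members = int(rng.integers(lo, hi + 1))

        arch_total = float(sum(arch))
        for m in range(1, n_members + 1):
            total = 0.0
            while total <= 0:
                total = mean_total * (1.0 + rng.normal(0.0, config.sigma_rel))
            seg_lengths = [int(round(total * a / arch_total)) for a in arch]
            species = f"{genus} virus {m}"
            seg_accessions, seg_spans = [], []
            for s, seg_len in enumerate(seg_lengths, start=1):
                seq, spans = _build_segment(
                    rng, seg_len, gc, config.orf_density, config.orf_length_range
                )
                accession = f"SYN{g:03d}M{m:02d}S{s}"
                label = f"RNA{s}" if len(seg_lengths) > 1 else ""
                records.append(
                    SequenceRecord(
                        accession=accession,
                        description=f"{accession} {species} segment {s}",
                        residues=seq,
                    )
                )
                annotations.append(
                    TaxonomyAnnotation(
                        accession=accession,
                        species=species,
                        genus=genus,
                        family=family,
                        order=order,
                        phylum=phylum,
                        kingdom="Orthornavirae",
                        realm="Riboviria",
                        host_category=host,
                        genome_composition=composition,
                        is_complete=True,
                        segment_label=label,
                    )
                )
                seg_accessions.append(accession)
                seg_spans.append(spans)
            truth_rows.append(
                {
                    "species": species,
                    "genus": genus,
                    "family": family,
                    "order": order,
                    "host_category": host,
                    "gc_target": gc,
                    "genus_mean_length": mean_total,
                    "drawn_total_length": sum(seg_lengths),
                    "segment_count": len(seg_lengths),
                    "segment_lengths": repr(seg_lengths),
                    "segment_accessions": repr(seg_accessions),
                    "orf_spans": repr(seg_spans),
                    "n_orfs_embedded": sum(len(sp) for sp in seg_spans),
                    "is_recode_pair": False,
                }
            )

    for p in range(1, config.recode_pairs + 1):
        genus = f"RecodePair{p:03d}"
        gc = 0.5
        seq, spans = _build_segment(rng, 1200, gc, 3.0, (150, 240))
        original = SequenceRecord(
            accession=f"RCP{p:03d}A",
            description=f"RCP{p:03d}A {genus} original",
            residues=seq,
        )
        recode = synonymous_recode(original, spans, rng)
        recode = SequenceRecord(
            accession=f"RCP{p:03d}B",
            description=f"RCP{p:03d}B {genus} recode",
            residues=recode.residues,
        )
        for rec, tag in ((original, "original"), (recode, "recode")):
            species = f"{genus} {tag}"
            annotations.append(
                TaxonomyAnnotation(
                    accession=rec.accession,
                    species=species,
                    genus=genus,
                    family="RecodeFamily",
                    order="RecodeOrder",
                    host_category="unknown",
                    genome_composition="+ssRNA",
                    is_complete=True,
                )
            )
            truth_rows.append(
                {
                    "species": species,
                    "genus": genus,
                    "family": "RecodeFamily",
                    "order": "RecodeOrder",
                    "host_category": "unknown",
                    "gc_target": gc,
                    "genus_mean_length": float(len(seq)),
                    "drawn_total_length": len(rec.residues),
                    "segment_count": 1,
                    "segment_lengths": repr([len(rec.residues)]),
                    "segment_accessions": repr([rec.accession]),
                    "orf_spans": repr([spans]),
                    "n_orfs_embedded": len(spans),
                    "is_recode_pair": True,
                }
            )
        records.extend([original, recode])

    return records, annotations, pd.DataFrame(truth_rows)


def synonymous_recode(
    record: SequenceRecord,
    orf_spans: Sequence[tuple[int, int]],
    rng: np.random.Generator | int,
) -> SequenceRecord:
    """Recode a record so every ORF translates identically but codons differ.

    Within each (1-based inclusive, in-frame) ORF span, every codon is
    replaced by a codon drawn uniformly from its amino acid's codon set (the
    stop codon likewise from the stop set).  Outside the spans, bases are
    resampled at the realized GC of the non-ORF region.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    seq = list(record.residues)
    n = len(seq)
    in_orf = np.zeros(n, dtype=bool)
    for start, end in orf_spans:
        if (end - start + 1) % 3 != 0:
            raise ValueError(f"ORF span ({start}, {end}) is not in frame")
        if start < 1 or end > n:
            raise ValueError(f"ORF span ({start}, {end}) outside record of length {n}")
        in_orf[start - 1 : end] = True
        for i in range(start - 1, end, 3):
            codon = "".join(seq[i : i + 3])
            if codon in _STOPS:
                choices: tuple[str, ...] = _STOPS
            else:
                aa = _STANDARD.forward_table.get(codon)
                if aa is None:  # ambiguous codon: leave untouched
                    continue
                choices = _AA_TO_CODONS[aa]
            new = choices[rng.integers(len(choices))]
            seq[i : i + 3] = list(new)
    outside_idx = np.flatnonzero(~in_orf)
    if len(outside_idx):
        outside = [record.residues[i] for i in outside_idx]
        gc = (outside.count("G") + outside.count("C")) / len(outside)
        fresh = _draw_bases(rng, len(outside_idx), gc)
        for pos, base in zip(outside_idx, fresh):
            seq[pos] = base
    return SequenceRecord(
        accession=record.accession + "_recode",
        description=record.description + " synonymous recode",
        residues="".join(seq),
    )


def recoded_family_cohort(
    n_genera: int = 6,
    members_per_genus: int = 5,
    orf_length_nt: int = 900,
    flank_nt: int = 60,
    aa_drift: float = 0.05,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[list[VirusAssembly], dict[str, str]]:
    """Families of protein-conserved, nucleotide-diverged genomes.

    Each genus descends from one random ancestral peptide; members carry the
    ancestor's protein with a per-site substitution probability ``aa_drift``,
    re-encoded with uniformly random synonymous codons, plus short non-coding
    flanks.  Within a genus, protein identity is therefore high while
    nucleotide k-mer similarity is low — the structure that makes
    protein-level matrices cluster where nucleotide-level ones do not.

    Returns assemblies and a label->genus mapping for clustering contrasts.
    """
    rng = np.random.default_rng(seed)
    n_aa = orf_length_nt // 3 - 2
    assemblies: list[VirusAssembly] = []
    groups: dict[str, str] = {}
    for g in range(1, n_genera + 1):
        genus = f"DriftGenus{g:02d}"
        ancestor = rng.choice(len(_AMINO_ACIDS), size=n_aa)
        for m in range(1, members_per_genus + 1):
            peptide = ancestor.copy()
            drift = rng.random(n_aa) < aa_drift
            peptide[drift] = rng.choice(len(_AMINO_ACIDS), size=int(drift.sum()))
            codons = ["ATG"]
            for aa_idx in peptide:
                choices = _AA_TO_CODONS[_AMINO_ACIDS[aa_idx]]
                codons.append(choices[rng.integers(len(choices))])
            codons.append(_STOPS[rng.integers(len(_STOPS))])
            seq = (
                "".join(_draw_bases(rng, flank_nt, gc))
                + "".join(codons)
                + "".join(_draw_bases(rng, flank_nt, gc))
            )
            accession = f"DRF{g:02d}M{m:02d}"
            species = f"{genus} virus {m}"
            record = SequenceRecord(accession, f"{accession} {species}", seq)
            ann = TaxonomyAnnotation(
                accession=accession,
                species=species,
                genus=genus,
                family=f"DriftFamily{(g - 1) // 2 + 1:02d}",
                order="DriftOrder",
                host_category="unknown",
                genome_composition="+ssRNA",
            )
            assemblies.append(VirusAssembly(species=species, taxonomy=ann, segments=(record,)))
            groups[species] = genus
    return assemblies, groups
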