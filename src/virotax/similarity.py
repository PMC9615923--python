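"""Pairwise genome similarity at the nucleotide and protein levels.

Nucleotide similarity is a Dice coefficient over distinct k-mer sets
(default k = 10)::

    sim(a, b) = 2 * |K_a & K_b| / (|K_a| + |K_b|)

Protein similarity approximates a translated-vs-translated BLAST search:
each genome is translated in all six frames, translations are split at stop
codons into peptide fragments, every cross-genome fragment pair is aligned
locally (BLOSUM62, gap open 11, extend 1), and the maximum percent identity
over all pairs — identity measured over the aligned columns, gaps included,
of each pair's best-scoring alignment — is the genome-pair similarity.

Multi-segment genomes contribute the union of their segments' k-mer sets
(windows never span segment junctions) and the pool of all segments'
peptide fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq, reverse_complement

from .records import SequenceRecord, TaxonomyAnnotation, VirusAssembly

__all__ = [
    "KmerProfile",
    "SimilarityMatrix",
    "kmer_profile",
    "kmer_similarity",
    "six_frame_fragments",
    "protein_max_identity",
    "similarity_matrix",
    "taxonomy_order",
    "clustering_contrast",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 10
DEFAULT_MIN_FRAGMENT_AA = 20
DEFAULT_MIN_ALIGN_COLUMNS = 20

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class KmerProfile:
    """Distinct k-length windows of one sequence, restricted to A/C/G/T."""

    accession: str
    k: int
    kmers: frozenset[str]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with labeled rows/columns.

    ``scale`` is ``(0, 1)`` for the k-mer metric and ``(0, 100)`` for percent
    protein identity; the diagonal is filled with the scale maximum.
    """

    labels: list[str]
    values: np.ndarray
    metric: str  # "nucleotide-kmer" | "protein-identity"
    k: int | None = None

    @property
    def scale_max(self) -> float:
        return 1.0 if self.metric == "nucleotide-kmer" else 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def kmer_profile(record_or_segments, k: int = DEFAULT_K) -> KmerProfile:
    """Distinct k-mers of a record (or several segments, unioned).

    Windows containing any non-ACGT character are skipped; a sequence
    shorter than k contributes nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(record_or_segments, SequenceRecord):
        segments = [record_or_segments]
    else:
        segments = list(record_or_segments)
    kmers: set[str] = set()
    for seg in segments:
        s = seg.residues
        if set(s) <= _ACGT:
            kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
        else:
            for i in range(len(s) - k + 1):
                window = s[i : i + k]
                if set(window) <= _ACGT:
                    kmers.add(window)
    accession = segments[0].accession if segments else ""
    return KmerProfile(accession=accession, k=k, kmers=frozenset(kmers))


def kmer_similarity(a: KmerProfile, b: KmerProfile) -> float:
    """Dice coefficient of two k-mer sets; 0.0 when both are empty."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    denom = len(a.kmers) + len(b.kmers)
    if denom == 0:
        return 0.0
    return 2.0 * len(a.kmers & b.kmers) / denom


def six_frame_fragments(
    record: SequenceRecord, min_fragment_aa: int = DEFAULT_MIN_FRAGMENT_AA
) -> list[str]:
    """Peptide fragments from all six reading frames.

    Each frame is translated with the standard code (ambiguous codons give
    X), split at stop codons, and fragments shorter than ``min_fragment_aa``
    are discarded.
    """
    if min_fragment_aa < 1:
        raise ValueError("min_fragment_aa must be >= 1")
    fragments: list[str] = []
    for strand_seq in (record.residues, reverse_complement(record.residues)):
        for offset in range(3):
            frame = strand_seq[offset:]
            frame = frame[: len(frame) - len(frame) % 3]
            if not frame:
                continue
            peptide = str(Seq(frame).translate(table=1))
            fragments.extend(
                frag for frag in peptide.split("*") if len(frag) >= min_fragment_aa
            )
    return fragments


def _make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _alignment_identity(alignment) -> tuple[float, int]:
    """(identity fraction over aligned columns incl. gaps, n columns)."""
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        return 0.0, 0
    return counts.identities / columns, columns


def protein_max_identity(
    a: SequenceRecord | Sequence[SequenceRecord],
    b: SequenceRecord | Sequence[SequenceRecord],
    min_fragment_aa: int = DEFAULT_MIN_FRAGMENT_AA,
    min_align_columns: int = DEFAULT_MIN_ALIGN_COLUMNS,
    max_fragments: int | None = None,
    _aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Maximum percent identity between translated fragments of two genomes.

    Returns a value in [0, 100]; 0 (with a warning) when either genome has no
    qualifying fragment or no fragment pair aligns over at least
    ``min_align_columns`` columns.  ``max_fragments`` optionally keeps only
    the longest fragments of each genome to bound the all-pairs cost.
    """
    frags_a = _pooled_fragments(a, min_fragment_aa, max_fragments)
    frags_b = _pooled_fragments(b, min_fragment_aa, max_fragments)
    if not frags_a or not frags_b:
        logger.warning("no qualifying peptide fragments; protein identity defined as 0")
        return 0.0
    aligner = _aligner if _aligner is not None else _make_aligner()
    best = 0.0
    for fa in frags_a:
        for fb in frags_b:
            alignments = aligner.align(fa, fb)
            try:
                aln = alignments[0]
            except IndexError:
                continue
            identity, columns = _alignment_identity(aln)
            if columns < min_align_columns:
                continue
            if identity > best:
                best = identity
                if best >= 1.0:
                    return 100.0
    return 100.0 * best


class _Pool:
    """Pre-pooled fragment list accepted by protein_max_identity."""

    def __init__(self, fragments: list[str]):
        self.fragments = fragments


def _pooled_fragments(genome, min_fragment_aa: int, max_fragments: int | None) -> list[str]:
    if isinstance(genome, _Pool):
        return genome.fragments
    if isinstance(genome, SequenceRecord):
        segments = [genome]
    elif isinstance(genome, VirusAssembly):
        segments = list(genome.segments)
    else:
        segments = list(genome)
    fragments: list[str] = []
    for seg in segments:
        fragments.extend(six_frame_fragments(seg, min_fragment_aa))
    if max_fragments is not None and len(fragments) > max_fragments:
        fragments = sorted(fragments, key=len, reverse=True)[:max_fragments]
    return fragments


def similarity_matrix(
    assemblies: Sequence[VirusAssembly],
    metric: str = "nucleotide-kmer",
    k: int = DEFAULT_K,
    min_fragment_aa: int = DEFAULT_MIN_FRAGMENT_AA,
    min_align_columns: int = DEFAULT_MIN_ALIGN_COLUMNS,
    max_fragments: int | None = None,
) -> SimilarityMatrix:
    """All-pairs similarity matrix over virus assemblies, labeled by species.

    Each unordered pair is computed once and mirrored; the diagonal is the
    scale maximum (1.0 for k-mer, 100 for protein identity).
    """
    if len(assemblies) < 2:
        raise ValueError("need at least 2 assemblies")
    if metric not in {"nucleotide-kmer", "protein-identity"}:
        raise ValueError(f"unknown metric {metric!r}")
    labels = [a.species for a in assemblies]
    n = len(assemblies)
    if metric == "nucleotide-kmer":
        profiles = [kmer_profile(a.segments, k=k) for a in assemblies]
        values = np.full((n, n), 1.0)
        for i, j in combinations(range(n), 2):
            values[i, j] = values[j, i] = kmer_similarity(profiles[i], profiles[j])
        return SimilarityMatrix(labels=labels, values=values, metric=metric, k=k)
    # protein identity: pool fragments once per genome, share one aligner
    pooled = [_pooled_fragments(a, min_fragment_aa, max_fragments) for a in assemblies]
    aligner = _make_aligner()
    values = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        sim = protein_max_identity(
            _Pool(pooled[i]), _Pool(pooled[j]),
            min_fragment_aa=min_fragment_aa,
            min_align_columns=min_align_columns,
            _aligner=aligner,
        )
        values[i, j] = values[j, i] = sim
    return SimilarityMatrix(labels=labels, values=values, metric=metric, k=None)


def taxonomy_order(
    matrix: SimilarityMatrix, annotations: Mapping[str, TaxonomyAnnotation]
) -> SimilarityMatrix:
    """Reorder rows/columns by (order, family, genus, species), stably.

    ``annotations`` maps each matrix label (species) to its annotation.
    Unannotated labels raise a ValueError naming the label.
    """
    for label in matrix.labels:
        if label not in annotations:
            raise ValueError(f"label {label!r} has no taxonomy annotation")

    def sort_key(item):
        idx, label = item
        ann = annotations[label]
        return (ann.order, ann.family, ann.genus, label, idx)

    order = [idx for idx, _ in sorted(enumerate(matrix.labels), key=sort_key)]
    values = matrix.values[np.ix_(order, order)]
    return SimilarityMatrix(
        labels=[matrix.labels[i] for i in order],
        values=values,
        metric=matrix.metric,
        k=matrix.k,
    )


def clustering_contrast(
    matrix: SimilarityMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
    normalize: bool = True,
) -> tuple[float, float]:
    """Within-group minus between-group mean similarity, with permutation p.

    ``groups`` maps each label to its group (e.g. genus).  With
    ``normalize=True`` (default) percent matrices are divided by 100 so
    contrasts are comparable across metrics.  The p-value is the share of
    label permutations (plus the observed labeling) whose contrast is at
    least the observed one.
    """
    labels = matrix.labels
    group_ids = np.array([groups[lab] for lab in labels])
    uniq, counts = np.unique(group_ids, return_counts=True)
    if len(uniq) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    values = matrix.values / matrix.scale_max if normalize else matrix.values

    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same = group_ids[iu[0]] == group_ids[iu[1]]
    if same.sum() == 0 or (~same).sum() == 0:
        raise ValueError("degenerate grouping: no within- or no between-group pairs")
    pair_vals = values[iu]

    def contrast(assignment: np.ndarray) -> float:
        s = assignment[iu[0]] == assignment[iu[1]]
        return float(pair_vals[s].mean() - pair_vals[~s].mean())

    observed = contrast(group_ids)
    rng = np.random.default_rng(seed)
    hits = 1  # observed labeling counts
    for _ in range(n_permutations):
        perm = rng.permutation(group_ids)
        if contrast(perm) >= observed:
            hits += 1
    p = hits / (n_permutations + 1)
    return observed, p
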