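"""Genus-level genome-length consistency, host contrasts, and segment summaries.

The central statistic is the per-genome relative length deviation within its
genus::

    d_i = (L_i - mean_g(L)) / mean_g(L)

where ``L_i`` is the genome's total length (all segments summed) and the mean
is taken over all complete-genome members of the genus, the focal genome
included.  A genus-level consistency screen then reports the share of genomes
with ``|d_i|`` below a threshold (20% by default).

Host contrasts use the two-sided Wilcoxon rank-sum (Mann-Whitney) test —
exact null enumeration for small tie-free groups, normal approximation with
tie and continuity correction otherwise — with significance codes
**** p<=1e-4, *** p<=1e-3, ** p<=0.01, * p<=0.1, ns otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import HOST_CATEGORIES, VirusAssembly

__all__ = [
    "GroupComparison",
    "SegmentClassSummary",
    "genus_deviations",
    "fraction_within",
    "host_groups",
    "wilcoxon_rank_sum",
    "pairwise_wilcoxon",
    "significance_code",
    "segment_class_summaries",
    "genus_segment_architecture",
]

logger = logging.getLogger(__name__)

# (threshold, code), checked in order; "* p <= 0.1" follows the convention of
# the source analysis, the inner thresholds are the usual 0.01/0.001 fill-in.
DEFAULT_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.1, "*"))

SEGMENT_CLASSES = ("single-segment", "multiple-segments", "non-segmented")


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    rank_sum_statistic: float
    p_value: float
    significance_code: str


@dataclass(frozen=True)
class SegmentClassSummary:
    """Lengths and a Gaussian-kernel density estimate for one segment class."""

    class_label: str
    values: np.ndarray
    grid: np.ndarray | None
    density: np.ndarray | None

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.n else float("nan")

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.n else float("nan")


def genus_deviations(
    assemblies: Sequence[VirusAssembly],
    min_members: int = 2,
    complete_only: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-genome relative length deviation within each genus.

    Only genera with at least ``min_members`` complete-genome members are
    evaluated; smaller (or unnamed) genera are returned as skipped.  Within a
    genus the signed deviations sum to zero by construction.

    Returns
    -------
    (deviations, skipped)
        ``deviations`` has columns species, genus, length, genus_mean,
        deviation, abs_deviation; ``skipped`` lists genera excluded by the
        membership rule.
    """
    if min_members < 2:
        raise ValueError("min_members must be >= 2")
    members: dict[str, list[VirusAssembly]] = {}
    for a in assemblies:
        if complete_only and not a.taxonomy.is_complete:
            continue
        members.setdefault(a.taxonomy.genus, []).append(a)

    rows = []
    skipped: list[str] = []
    for genus in sorted(members):
        group = members[genus]
        if not genus or len(group) < min_members:
            skipped.append(genus)
            continue
        mean_len = float(np.mean([a.total_length for a in group]))
        for a in group:
            d = (a.total_length - mean_len) / mean_len
            rows.append(
                {
                    "species": a.species,
                    "genus": genus,
                    "length": a.total_length,
                    "genus_mean": mean_len,
                    "deviation": d,
                    "abs_deviation": abs(d),
                }
            )
    if skipped:
        logger.info("skipped %d genera below %d members", len(skipped), min_members)
    return pd.DataFrame(rows, columns=["species", "genus", "length", "genus_mean", "deviation", "abs_deviation"]), skipped


def fraction_within(deviations: pd.DataFrame, tau: float = 0.20) -> tuple[float, int]:
    """Share of genomes whose |deviation| is strictly below ``tau``.

    Returns ``(fraction, n_exceeding)`` where a boundary value |d| == tau
    counts as exceeding.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if len(deviations) == 0:
        raise ValueError("empty deviation collection")
    abs_d = deviations["abs_deviation"].to_numpy()
    n_within = int((abs_d < tau).sum())
    return n_within / len(abs_d), len(abs_d) - n_within


def host_groups(
    rows: pd.DataFrame,
    min_n: int = 40,
    measure: str = "length",
) -> dict[str, np.ndarray]:
    """Per-host value groups for contrasts, after the size screen.

    Only complete genomes are counted; the ``unknown`` host is always
    dropped; a host group survives only if its count is strictly greater
    than ``min_n``.  Groups come back in fixed display order
    (fungi .. vertebrates).
    """
    if measure not in {"length", "gc"}:
        raise ValueError("measure must be 'length' or 'gc'")
    col = "total_length" if measure == "length" else "gc_fraction"
    df = rows[rows["is_complete"]] if "is_complete" in rows.columns else rows
    groups: dict[str, np.ndarray] = {}
    for host in HOST_CATEGORIES:
        if host == "unknown":
            continue
        vals = df.loc[df["host_category"] == host, col].to_numpy(dtype=float)
        if len(vals) > min_n:
            groups[host] = vals
        elif len(vals):
            logger.info("host group %s dropped (n=%d <= %d)", host, len(vals), min_n)
    if len(groups) < 2:
        raise ValueError(
            f"fewer than 2 host groups exceed n={min_n}; no contrast possible"
        )
    return groups


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank_sum_of_a, p).

    Uses exact null enumeration when n_a + n_b <= 16 and the pooled sample is
    tie-free, otherwise the normal approximation with tie and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate test: all values identical across both groups")
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 16 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    rank_sum = float(res.statistic) + len(a) * (len(a) + 1) / 2.0
    return rank_sum, float(res.pvalue)


def significance_code(
    p: float, thresholds: Sequence[tuple[float, str]] = DEFAULT_STAR_THRESHOLDS
) -> str:
    for cutoff, code in thresholds:
        if p <= cutoff:
            return code
    return "ns"


def pairwise_wilcoxon(
    groups: Mapping[str, np.ndarray],
    thresholds: Sequence[tuple[float, str]] = DEFAULT_STAR_THRESHOLDS,
) -> list[GroupComparison]:
    """All pairwise two-sided rank-sum contrasts between labeled groups."""
    comparisons = []
    for (name_a, vals_a), (name_b, vals_b) in combinations(groups.items(), 2):
        if len(vals_a) < 3 or len(vals_b) < 3:
            raise ValueError("each group needs n >= 3")
        w, p = wilcoxon_rank_sum(vals_a, vals_b)
        comparisons.append(
            GroupComparison(
                group_a=name_a,
                group_b=name_b,
                n_a=len(vals_a),
                n_b=len(vals_b),
                rank_sum_statistic=w,
                p_value=p,
                significance_code=significance_code(p, thresholds),
            )
        )
    return comparisons


def comparisons_table(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


def segment_class_summaries(
    assemblies: Sequence[VirusAssembly],
    grid_points: int = 512,
) -> tuple[dict[str, SegmentClassSummary], GroupComparison | None]:
    """Length distributions of the three segment classes, plus a contrast.

    Classes: ``single-segment`` — each individual segment length of segmented
    viruses; ``multiple-segments`` — per-virus segment totals of segmented
    viruses; ``non-segmented`` — totals of one-segment viruses.  Densities
    are Gaussian KDEs with Silverman bandwidth on one shared grid.  The
    returned comparison is multiple-segments totals vs non-segmented lengths
    (None, with a warning, if either class is empty).
    """
    single, multiple, nonseg = [], [], []
    for a in assemblies:
        if a.is_segmented:
            single.extend(seg.length for seg in a.segments)
            multiple.append(a.total_length)
        else:
            nonseg.append(a.total_length)
    values = {
        "single-segment": np.asarray(single, dtype=float),
        "multiple-segments": np.asarray(multiple, dtype=float),
        "non-segmented": np.asarray(nonseg, dtype=float),
    }
    all_vals = np.concatenate([v for v in values.values() if len(v)])
    kdes = {}
    for label, vals in values.items():
        if len(vals) >= 2 and np.ptp(vals) > 0:
            kdes[label] = stats.gaussian_kde(vals, bw_method="silverman")
    # pad the shared grid past the data range so edge classes keep their
    # kernel tails and each density integrates to ~1 over the grid
    pad = 3.0 * max(
        (float(k.factor * np.std(v)) for v, k in
         ((values[lab], kde) for lab, kde in kdes.items())),
        default=0.0,
    )
    grid = np.linspace(all_vals.min() - pad, all_vals.max() + pad, grid_points)
    summaries = {}
    for label, vals in values.items():
        if label in kdes:
            summaries[label] = SegmentClassSummary(label, vals, grid, kdes[label](grid))
        else:
            summaries[label] = SegmentClassSummary(label, vals, None, None)

    comparison = None
    if len(multiple) >= 3 and len(nonseg) >= 3:
        w, p = wilcoxon_rank_sum(values["multiple-segments"], values["non-segmented"])
        comparison = GroupComparison(
            "multiple-segments", "non-segmented",
            len(multiple), len(nonseg), w, p, significance_code(p),
        )
    else:
        logger.warning("segment-class comparison skipped: need >=3 segmented and non-segmented viruses")
    return summaries, comparison


def density_modes(summary: SegmentClassSummary, min_rel_height: float = 0.05) -> list[float]:
    """Locations of local maxima of a class density, tallest first.

    Peaks below ``min_rel_height`` of the tallest peak are discarded.
    """
    if summary.density is None:
        return []
    d = summary.density
    idx = [i for i in range(1, len(d) - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1]]
    if not idx:
        return []
    tallest = max(d[i] for i in idx)
    idx = [i for i in idx if d[i] >= min_rel_height * tallest]
    idx.sort(key=lambda i: -d[i])
    return [float(summary.grid[i]) for i in idx]


def genus_segment_architecture(assemblies: Sequence[VirusAssembly]) -> pd.DataFrame:
    """Per-genus segment-count mode and per-rank mean segment lengths.

    Segments within each virus are ranked by descending length; per-rank
    means are taken over the genus members that have the modal segment
    count.  Columns: genus, n_members, segment_count_mode, share_at_mode,
    rank_mean_lengths (tuple, longest rank first).
    """
    by_genus: dict[str, list[VirusAssembly]] = {}
    for a in assemblies:
        by_genus.setdefault(a.taxonomy.genus, []).append(a)
    rows = []
    for genus in sorted(by_genus):
        group = by_genus[genus]
        counts = pd.Series([a.segment_count for a in group])
        mode = int(counts.mode().min())  # ties broken toward fewer segments
        at_mode = [a for a in group if a.segment_count == mode]
        ranked = np.array(
            [sorted((seg.length for seg in a.segments), reverse=True) for a in at_mode],
            dtype=float,
        )
        rows.append(
            {
                "genus": genus,
                "n_members": len(group),
                "segment_count_mode": mode,
                "share_at_mode": len(at_mode) / len(group),
                "rank_mean_lengths": tuple(float(x) for x in ranked.mean(axis=0)),
            }
        )
    return pd.DataFrame(rows)
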