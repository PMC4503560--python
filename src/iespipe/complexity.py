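"""Coverage-based sequence complexity and comparative set/size analyses.

The complexity stage asks how much germline-restricted sequence requires a
given factor for its elimination.  Reads from a knockdown sample, a reference
knockdown (whose retained DNA approximates the unrearranged germline, e.g. an
excision-dead sample) and a control are mapped to the reference-knockdown
contigs; a contig counts as covered when its RPKM (reads per kb of contig per
million mapped reads) exceeds a threshold (default 2) and the contig is
longer than a length cutoff (default 1 kb).  The "private" complexity of a
dataset is the summed length of contigs it covers but the control does not —
the germline-restricted (MIC-limited) portion — and the headline fraction is
the share of the reference-private complexity that the factor-of-interest
also fails to eliminate.

The comparative helpers summarize retention-call results across IES sets
(overlap/Venn partitions with marginal percentages), across size or
retention-score bins (type-7 quartiles), and test neighbouring size groups
with the Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .retention_stats import bh_adjust


# ---------------------------------------------------------------------------
# RPKM coverage and private complexity
# ---------------------------------------------------------------------------

def rpkm(length_bp: int, reads: int, total_mapped: int) -> float:
    """Reads per kilobase of contig per million mapped reads in the library."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return reads / (length_bp / 1000.0) / (total_mapped / 1e6)


def coverage_table(
    counts: pd.DataFrame,
    total_mapped: int | None = None,
    min_len: int = 1000,
    min_rpkm: float = 2.0,
) -> pd.DataFrame:
    """Annotate a ``contig_id length reads`` frame with RPKM and covered flag.

    ``total_mapped`` defaults to the sum of the reads column (every mapped
    read of the library hits some contig).  ``covered`` requires RPKM
    strictly above ``min_rpkm`` *and* length strictly above ``min_len``.
    """
    missing = {"contig_id", "length", "reads"} - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks columns {missing}")
    if total_mapped is None:
        total_mapped = int(counts["reads"].sum())
    out = counts.copy()
    out["rpkm"] = [
        rpkm(int(l), int(r), total_mapped)
        for l, r in zip(out["length"], out["reads"])
    ]
    out["covered"] = (out["rpkm"] > min_rpkm) & (out["length"] > min_len)
    return out


def covered_set(
    coverages: pd.DataFrame,
    min_len: int = 1000,
    min_rpkm: float = 2.0,
    total_mapped: int | None = None,
) -> set[str]:
    """Ids of contigs strictly longer than ``min_len`` with RPKM strictly
    above ``min_rpkm``.  Accepts a raw counts frame or one already annotated
    by :func:`coverage_table`; ``total_mapped`` overrides the library size
    when the table does not hold every mapped read of the library."""
    if "rpkm" not in coverages.columns:
        coverages = coverage_table(
            coverages, total_mapped=total_mapped, min_len=min_len, min_rpkm=min_rpkm
        )
    keep = (coverages["rpkm"] > min_rpkm) & (coverages["length"] > min_len)
    return set(coverages.loc[keep, "contig_id"])


def private_complexity(
    covered_a: set[str],
    covered_control: set[str],
    lengths: Mapping[str, int],
) -> tuple[int, set[str]]:
    """Summed length of contigs covered by A but not by the control.

    This is the sequence complexity private to dataset A — for a germline-like
    reference sample, the MIC-restricted regions absent from the somatic
    genome.  Returns (total bp, the private contig-id set).
    """
    private = covered_a - covered_control
    missing = [c for c in private if c not in lengths]
    if missing:
        raise KeyError(f"no length for contigs: {sorted(missing)[:5]}")
    return sum(int(lengths[c]) for c in private), private


def complexity_fraction(
    covered_x: set[str],
    covered_reference: set[str],
    covered_control: set[str],
    lengths: Mapping[str, int],
) -> float:
    """Fraction of the reference-private complexity also private to X.

    ``sum(len over (X \\ control) ∩ (ref \\ control)) / sum(len over ref \\
    control)`` — e.g. the share of MIC-restricted sequence that needs the
    silenced factor for its elimination.
    """
    ref_bp, ref_private = private_complexity(
        covered_reference, covered_control, lengths
    )
    if ref_bp == 0:
        raise ZeroDivisionError("reference-private complexity is zero")
    _, x_private = private_complexity(covered_x, covered_control, lengths)
    shared = x_private & ref_private
    return sum(int(lengths[c]) for c in shared) / ref_bp


# ---------------------------------------------------------------------------
# Set overlaps
# ---------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    """Venn partition of named id sets.

    ``regions`` maps each non-empty membership signature (tuple of set names
    an element belongs to, sorted) to the number of elements with exactly
    that signature; region counts partition the union.  ``pairwise_pct``
    holds |A ∩ B| / |B| × 100 for every ordered pair (A, B).
    """

    set_sizes: dict[str, int]
    regions: dict[tuple[str, ...], int]
    pairwise_pct: dict[tuple[str, str], float]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def overlap_counts(sets: Mapping[str, set[str]]) -> OverlapSummary:
    """Cardinality of every region of the Venn partition plus marginal
    percentages, for two or more named sets."""
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            )
            regions[combo] = len(inside - outside)
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in itertools.permutations(names, 2):
        denom = len(sets[b])
        pairwise[(a, b)] = (
            100.0 * len(sets[a] & sets[b]) / denom if denom else float("nan")
        )
    return OverlapSummary(
        set_sizes={n: len(sets[n]) for n in names},
        regions=regions,
        pairwise_pct=pairwise,
    )


# ---------------------------------------------------------------------------
# Binned summaries and rank tests
# ---------------------------------------------------------------------------

def quartile_edges(values: Sequence[float]) -> np.ndarray:
    """Quartile bin edges [min, Q1, Q2, Q3, max] by linear interpolation
    between order statistics (the common 'type 7' convention)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    return np.percentile(v, [0, 25, 50, 75, 100])


def binned_summary(
    bin_values: Sequence[float],
    stat_values: Sequence[float],
    edges: Sequence[float],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-bin n, median, Q1 and Q3 of a companion variable.

    Elements are binned on ``bin_values`` into ``[e0, e1[, [e1, e2[, ...,
    [e_{m-1}, e_m]`` (last bin right-closed); the summary statistics describe
    ``stat_values`` within each bin.  Empty bins are reported with n = 0 and
    NA statistics.  Used in both directions: IES length per retention-score
    quartile, and retention score per length group.
    """
    b = np.asarray(bin_values, dtype=float)
    s = np.asarray(stat_values, dtype=float)
    if b.shape != s.shape:
        raise ValueError("bin_values and stat_values differ in length")
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) < 0):
        raise ValueError("edges must be non-decreasing with >= 2 entries")
    n_bins = edges.size - 1
    if labels is None:
        labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n_bins - 1)]
        labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    rows = []
    for i in range(n_bins):
        if i < n_bins - 1:
            mask = (b >= edges[i]) & (b < edges[i + 1])
        else:
            mask = (b >= edges[i]) & (b <= edges[i + 1])
        inside = s[mask]
        if inside.size:
            q1, med, q3 = np.percentile(inside, [25, 50, 75])
        else:
            q1 = med = q3 = float("nan")
        rows.append(
            {
                "bin": labels[i],
                "n": int(inside.size),
                "median": med,
                "q1": q1,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p-value between two samples.

    Uses the exact null distribution when both groups have n <= 8 and the
    pooled sample is tie-free, and the tie-corrected normal approximation
    (with continuity correction) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = a.size <= 8 and b.size <= 8 and np.unique(pooled).size == pooled.size
    method = "exact" if exact else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def sequential_group_tests(
    groups: Sequence[Sequence[float]],
    group_names: Sequence[str] | None = None,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum comparisons of each group against its predecessor.

    Mirrors the size-group view of the retention-score distribution: group i
    is tested against group i-1, p-values are BH-adjusted across the
    sequential comparisons and flagged significant at ``threshold``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if group_names is None:
        group_names = [f"group_{i + 1}" for i in range(len(groups))]
    pvalues = [
        rank_sum_test(groups[i - 1], groups[i]) for i in range(1, len(groups))
    ]
    padj = bh_adjust(pvalues)
    return pd.DataFrame(
        {
            "group": list(group_names[1:]),
            "versus": list(group_names[:-1]),
            "pvalue": pvalues,
            "padj": padj,
            "significant": [p < threshold for p in padj],
        }
    )


def ies_set_summary(
    name: str,
    member_ids: set[str],
    lengths: Mapping[str, int],
    retention_scores: Mapping[str, float],
) -> dict:
    """Count, mean length and mean retention score of one named IES set."""
    members = sorted(member_ids)
    mean_len = (
        float(np.mean([lengths[i] for i in members])) if members else float("nan")
    )
    scores = [
        retention_scores[i]
        for i in members
        if i in retention_scores and not np.isnan(retention_scores[i])
    ]
    mean_rs = float(np.mean(scores)) if scores else float("nan")
    return {
        "set": name,
        "n": len(members),
        "mean_length": mean_len,
        "mean_rs": mean_rs,
    }
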