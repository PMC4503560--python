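"""Small-RNA population profiling: length selection, contaminant subtraction,
hierarchical exact-unique assignment and per-million normalization.

During *Paramecium* autogamy two sRNA classes matter for genome rearrangement:
25-nt scnRNAs scanned against the maternal genome and 26–30 nt iesRNAs
produced from IESs.  The profiling stage reproduces the standard library
triage: keep 20–30 nt reads, drop reads matching contaminant references
(rDNA, food-bacteria genomes, mitochondrial genome, feeding-vector sequence)
with up to one substitution, then assign the survivors to an ordered list of
reference tiers (silencing target, rest of MAC, IESs) by exact matching at a
unique location, first tier wins.  Counts are normalized per million reads
mapped to a *Paramecium* reference so that libraries of different depths are
comparable, and the IES/MAC ratio between an early and a late time point
quantifies the enrichment of germline-restricted sequences in the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_model import reverse_complement

Read = tuple[str, str]

_BYTE = {b: np.uint8(i) for i, b in enumerate("ACGTN")}


def length_select(
    reads: Iterable[Read], min_len: int = 20, max_len: int = 30
) -> list[Read]:
    """Keep reads with length in [min_len, max_len], order preserved."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [(rid, seq) for rid, seq in reads if min_len <= len(seq) <= max_len]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _matches_with_mismatches(
    read_arr: np.ndarray, ref_windows: np.ndarray, max_mismatch: int
) -> bool:
    """True when any window of the reference is within ``max_mismatch``
    substitutions of the read (windows: P x L uint8)."""
    if ref_windows.shape[0] == 0:
        return False
    mismatches = (ref_windows != read_arr).sum(axis=1)
    return bool((mismatches <= max_mismatch).any())


def subtract_contaminants(
    reads: Sequence[Read],
    contaminants: Sequence[str],
    max_mismatch: int = 1,
) -> list[Read]:
    """Remove reads matching any contaminant reference on either strand.

    A read is removed when it occurs as a substring of a contaminant (or of
    its reverse complement) with at most ``max_mismatch`` substitutions.
    Survivors keep their input order.  Matching is a vectorized Hamming scan
    over all reference windows of the read's length.
    """
    if not contaminants:
        raise ValueError("contaminant reference list is empty")
    refs = [c.upper() for c in contaminants]
    refs = refs + [reverse_complement(c) for c in refs]
    encoded_refs = [_encode(c) for c in refs]

    # one sliding-window view per (reference, read length)
    window_cache: dict[tuple[int, int], np.ndarray] = {}

    def windows(ref_idx: int, length: int) -> np.ndarray:
        key = (ref_idx, length)
        if key not in window_cache:
            arr = encoded_refs[ref_idx]
            if len(arr) < length:
                window_cache[key] = np.empty((0, length), dtype=np.uint8)
            else:
                window_cache[key] = np.lib.stride_tricks.sliding_window_view(
                    arr, length
                )
        return window_cache[key]

    survivors: list[Read] = []
    for rid, seq in reads:
        read_arr = _encode(seq.upper())
        hit = any(
            _matches_with_mismatches(windows(i, len(seq)), read_arr, max_mismatch)
            for i in range(len(encoded_refs))
        )
        if not hit:
            survivors.append((rid, seq))
    return survivors


@dataclass
class SrnaProfile:
    """Per-category read counts of one sRNA library.

    ``raw`` holds assigned counts per tier plus the reads discarded within a
    tier for matching at more than one location (``discarded``) and the reads
    matching no tier (``unmapped``).  ``normalized`` rescales mapped-category
    counts to reads per million mapped to a *Paramecium* reference
    (``total_mapped``); raw counts plus discards plus unmapped always sum to
    ``total``.
    """

    tiers: list[str]
    raw: dict[str, int]
    discarded: dict[str, int]
    unmapped: int
    total: int

    @property
    def total_mapped(self) -> int:
        return sum(self.raw.values())

    @property
    def normalized(self) -> dict[str, float]:
        tm = self.total_mapped
        if tm == 0:
            return {name: float("nan") for name in self.tiers}
        return {name: self.raw[name] * 1e6 / tm for name in self.tiers}

    def to_frame(self) -> pd.DataFrame:
        norm = self.normalized
        rows = [
            {
                "category": name,
                "raw": self.raw[name],
                "per_million_mapped": norm[name],
                "discarded_nonunique": self.discarded[name],
            }
            for name in self.tiers
        ]
        rows.append(
            {
                "category": "unmapped",
                "raw": self.unmapped,
                "per_million_mapped": float("nan"),
                "discarded_nonunique": 0,
            }
        )
        return pd.DataFrame(rows)


def _count_occurrences(needle: str, haystacks: Sequence[str], limit: int = 2) -> int:
    """Occurrences of ``needle`` on either strand across ``haystacks``,
    overlaps allowed, early exit at ``limit``."""
    total = 0
    rc = reverse_complement(needle)
    patterns = [needle] if rc == needle else [needle, rc]
    for hay in haystacks:
        for pat in patterns:
            start = hay.find(pat)
            while start != -1:
                total += 1
                if total >= limit:
                    return total
                start = hay.find(pat, start + 1)
    return total


def hierarchical_assign(
    reads: Sequence[Read],
    tiers: Sequence[tuple[str, Sequence[str]]],
    cascade_nonunique: bool = False,
) -> SrnaProfile:
    """Assign each read to the first tier where it matches exactly and uniquely.

    Tiers are tried in order (the conventional layout: silencing target, rest
    of MAC, IES).  A read matching a tier at exactly one location (across the
    tier's sequences, both strands, overlaps allowed) is assigned there; a
    read matching at two or more locations is discarded as non-unique and —
    unless ``cascade_nonunique`` — not passed to later tiers, because it does
    match the earlier reference.  Reads matching no tier are unmapped.
    """
    if not tiers:
        raise ValueError("need at least one tier")
    names = [name for name, _ in tiers]
    if len(set(names)) != len(names):
        raise ValueError("duplicate tier names")
    uppercased = [(name, [s.upper() for s in refs]) for name, refs in tiers]

    raw = {name: 0 for name in names}
    discarded = {name: 0 for name in names}
    unmapped = 0
    for _, seq in reads:
        read = seq.upper()
        assigned = False
        first_nonunique: str | None = None
        for name, refs in uppercased:
            occurrences = _count_occurrences(read, refs)
            if occurrences == 1:
                raw[name] += 1
                assigned = True
                break
            if occurrences >= 2:
                if first_nonunique is None:
                    first_nonunique = name
                if not cascade_nonunique:
                    discarded[name] += 1
                    assigned = True
                    break
        if not assigned:
            if first_nonunique is not None:
                discarded[first_nonunique] += 1
            else:
                unmapped += 1
    return SrnaProfile(
        tiers=names,
        raw=raw,
        discarded=discarded,
        unmapped=unmapped,
        total=len(reads),
    )


def enrichment_ratio(
    early: SrnaProfile,
    late: SrnaProfile,
    ies: str = "ies",
    mac: str = "mac",
) -> float:
    """Fold change of the IES/MAC ratio between two time points.

    Returns ``[(IES/MAC)_late] / [(IES/MAC)_early]`` on normalized counts —
    the scanning-model signature of progressive enrichment of
    germline-restricted sequences in the scnRNA population.
    """
    for profile, label in ((early, "early"), (late, "late")):
        for key in (ies, mac):
            if key not in profile.raw:
                raise ValueError(f"{label} profile lacks category {key!r}")
    e_mac, l_mac = early.normalized[mac], late.normalized[mac]
    e_ies = early.normalized[ies]
    if not e_mac or not l_mac or not e_ies or np.isnan(e_mac) or np.isnan(l_mac):
        raise ZeroDivisionError("undefined IES/MAC ratio (zero denominator)")
    return (late.normalized[ies] / l_mac) / (e_ies / e_mac)
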