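"""Classify reads against IES boundary/junction probes and tally IES+ / IES- counts.

A read supports the unexcised (IES+) form of an IES when it contains one of
the two boundary probes (flank + IES end) and the excised (IES-) form when it
contains the junction probe (flank + TA + flank).  Matching is exact and
strand-symmetric; every read receives exactly one verdict, and reads whose
probe hits are ambiguous (shared probes, cross-IES mixtures, or a plus/minus
conflict) are never counted.  Counting at IES ends rather than across whole
IESs keeps long and short IESs on the same footing.

Two counting modes are provided: probe mode scans raw reads directly;
alignment mode consumes SAM produced against the MAC and/or MAC+IES
references and applies the same spanning rule to aligned coordinates.
"""

from __future__ import annotations

import enum
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

from .reference_model import (
    GenomeSequence,
    IesAnnotation,
    ProbeUnavailableError,
    ies_spans,
    make_probes,
    reverse_complement,
)

logger = logging.getLogger(__name__)


class Verdict(enum.Enum):
    PLUS = "PLUS"
    MINUS = "MINUS"
    AMBIGUOUS = "AMBIGUOUS"
    NONE = "NONE"


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    verdict: Verdict
    ies_id: str | None = None


@dataclass(frozen=True)
class JunctionCounts:
    """Per-IES tally of reads supporting the unexcised (+) and excised (-) forms."""

    ies_id: str
    n_plus: int
    n_minus: int

    def __post_init__(self) -> None:
        if self.n_plus < 0 or self.n_minus < 0:
            raise ValueError("counts must be non-negative")


_AMBIGUOUS = object()  # sentinel for probes shared by several (ies, kind) pairs


@dataclass
class ProbeIndex:
    """Exact-match lookup from probe strings (both strands) to their origin.

    ``lookup`` maps each probe string to a ``(ies_id, kind)`` pair, or to
    ``None`` when the string is shared by two or more distinct pairs and is
    therefore ambiguous.  IESs whose probes cannot be built (too close to a
    scaffold edge, too short for the flank width, or internally degenerate)
    are listed in ``excluded`` and take no part in counting.
    """

    k: int
    lookup: dict[str, tuple[str, str] | None] = field(default_factory=dict)
    ies_ids: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)
    collisions: list[str] = field(default_factory=list)

    @property
    def probe_length(self) -> int:
        return 2 * self.k + 2


def build_probe_index(
    annotations: Sequence[IesAnnotation],
    mac: GenomeSequence,
    k: int = 5,
) -> ProbeIndex:
    """Build the probe lookup for a catalog at flank width ``k``.

    Probes containing N are dropped (they never match).  An IES whose three
    probes are not pairwise distinct is classification-ambiguous by
    construction and is excluded with a warning.  Probe strings shared across
    IESs (or probe kinds) are kept but marked ambiguous.
    """
    index = ProbeIndex(k=k)
    for ann in annotations:
        try:
            probes = make_probes(mac, ann, k)
        except ProbeUnavailableError as exc:
            index.excluded[ann.ies_id] = str(exc)
            logger.warning("excluding %s from counting: %s", ann.ies_id, exc)
            continue
        triple = probes.all_probes()
        if len(set(triple.values())) < 3:
            index.excluded[ann.ies_id] = f"degenerate probes at k={k}"
            logger.warning(
                "excluding %s from counting: probes not distinct at k=%d",
                ann.ies_id,
                k,
            )
            continue
        index.ies_ids.append(ann.ies_id)
        for kind, probe in triple.items():
            if "N" in probe:
                continue
            target = (ann.ies_id, kind)
            for variant in {probe, reverse_complement(probe)}:
                existing = index.lookup.get(variant, target)
                if existing is not None and existing != target:
                    index.lookup[variant] = None
                    index.collisions.append(variant)
                else:
                    index.lookup[variant] = target
    return index


def classify_read(sequence: str, index: ProbeIndex) -> ReadClassification:
    """Assign one verdict to a read sequence.

    PLUS/MINUS when the read contains probes of exactly one IES and one sign;
    a read holding both boundary (plus) probes of the same IES is PLUS and is
    counted once.  Any hit on an ambiguity-marked probe, any cross-IES
    mixture, or a plus/minus conflict within one IES yields AMBIGUOUS;
    otherwise NONE.
    """
    return _classify(sequence, index, read_id="")


def _classify(sequence: str, index: ProbeIndex, read_id: str) -> ReadClassification:
    m = index.probe_length
    seq = sequence.upper()
    if len(seq) < m:
        logger.debug("read %s shorter than probe length %d", read_id, m)
        return ReadClassification(read_id, Verdict.NONE)
    lookup = index.lookup
    hit_ambiguous = False
    hits: set[tuple[str, str]] = set()
    for i in range(len(seq) - m + 1):
        target = lookup.get(seq[i : i + m], _AMBIGUOUS)
        if target is _AMBIGUOUS:
            continue
        if target is None:
            hit_ambiguous = True
            break
        hits.add(target)
    if hit_ambiguous:
        return ReadClassification(read_id, Verdict.AMBIGUOUS)
    if not hits:
        return ReadClassification(read_id, Verdict.NONE)
    ies_set = {ies for ies, _ in hits}
    if len(ies_set) > 1:
        return ReadClassification(read_id, Verdict.AMBIGUOUS)
    ies_id = ies_set.pop()
    kinds = {kind for _, kind in hits}
    if "minus" in kinds and kinds != {"minus"}:
        return ReadClassification(read_id, Verdict.AMBIGUOUS)
    if kinds == {"minus"}:
        return ReadClassification(read_id, Verdict.MINUS, ies_id)
    return ReadClassification(read_id, Verdict.PLUS, ies_id)


@dataclass
class CountResult:
    """Counts table plus the run report of uncounted reads."""

    counts: pd.DataFrame  # ies_id, n_plus, n_minus
    ambiguous: int
    none: int
    total: int
    excluded: dict[str, str] = field(default_factory=dict)

    def as_junction_counts(self) -> list[JunctionCounts]:
        return [
            JunctionCounts(row.ies_id, int(row.n_plus), int(row.n_minus))
            for row in self.counts.itertuples()
        ]


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with pysam.FastxFile(str(path)) as handle:
        for entry in handle:
            yield entry.name, entry.sequence


def _fragment_id(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def count_reads(
    reads: str | Path | Iterable[tuple[str, str]],
    index: ProbeIndex,
    paired: bool = False,
) -> CountResult:
    """Tally PLUS/MINUS verdicts per IES over a read stream.

    ``reads`` is a FASTQ path (plain or gzip) or an iterable of
    ``(read_id, sequence)``.  With ``paired=True``, mates sharing a fragment
    id (read id stripped of a ``/1``/``/2`` suffix) are classified
    independently but the fragment contributes at most one count per IES;
    mates giving conflicting signs for the same IES cancel and are reported
    ambiguous.
    """
    stream: Iterable[tuple[str, str]]
    if isinstance(reads, (str, Path)):
        stream = _iter_fastq(reads)
    else:
        stream = reads

    plus: dict[str, int] = {i: 0 for i in index.ies_ids}
    minus: dict[str, int] = {i: 0 for i in index.ies_ids}
    ambiguous = 0
    none = 0
    total = 0

    if not paired:
        for read_id, seq in stream:
            total += 1
            result = _classify(seq, index, read_id)
            if result.verdict is Verdict.PLUS:
                plus[result.ies_id] += 1
            elif result.verdict is Verdict.MINUS:
                minus[result.ies_id] += 1
            elif result.verdict is Verdict.AMBIGUOUS:
                ambiguous += 1
            else:
                none += 1
    else:
        fragments: dict[str, dict[str, str]] = {}
        for read_id, seq in stream:
            total += 1
            result = _classify(seq, index, read_id)
            if result.verdict is Verdict.AMBIGUOUS:
                ambiguous += 1
                continue
            if result.verdict is Verdict.NONE:
                none += 1
                continue
            frag = fragments.setdefault(_fragment_id(read_id), {})
            sign = "+" if result.verdict is Verdict.PLUS else "-"
            prev = frag.get(result.ies_id)
            if prev is None:
                frag[result.ies_id] = sign
            elif prev != sign:
                frag[result.ies_id] = "!"  # conflicting mates: drop
        for frag in fragments.values():
            for ies_id, sign in frag.items():
                if sign == "+":
                    plus[ies_id] += 1
                elif sign == "-":
                    minus[ies_id] += 1
                else:
                    ambiguous += 1

    counts = pd.DataFrame(
        {
            "ies_id": index.ies_ids,
            "n_plus": [plus[i] for i in index.ies_ids],
            "n_minus": [minus[i] for i in index.ies_ids],
        }
    )
    return CountResult(
        counts=counts,
        ambiguous=ambiguous,
        none=none,
        total=total,
        excluded=dict(index.excluded),
    )


# ---------------------------------------------------------------------------
# Alignment (SAM) mode
# ---------------------------------------------------------------------------

def _detect_reference(
    header_lengths: Mapping[str, int],
    mac: GenomeSequence,
    mac_plus_ies: GenomeSequence,
) -> str:
    mac_lengths = {n: len(s) for n, s in mac.items()}
    mpi_lengths = {n: len(s) for n, s in mac_plus_ies.items()}
    unknown = set(header_lengths) - set(mac_lengths)
    if unknown:
        raise ValueError(f"SAM references unknown scaffolds: {sorted(unknown)[:5]}")
    if all(header_lengths[n] == mac_lengths[n] for n in header_lengths):
        return "mac"
    if all(header_lengths[n] == mpi_lengths[n] for n in header_lengths):
        return "mac_ies"
    raise ValueError(
        "SAM header scaffold lengths match neither the MAC nor the MAC+IES genome"
    )


def _windows_for_reference(
    annotations: Sequence[IesAnnotation],
    index: ProbeIndex,
    reference: str,
    k: int,
) -> dict[str, list[tuple[int, int, str, str]]]:
    """Per-scaffold sorted probe footprints: (start, end, ies_id, sign)."""
    spans = ies_spans(annotations)
    windows: dict[str, list[tuple[int, int, str, str]]] = {}
    for ann in annotations:
        if ann.ies_id in index.excluded:
            continue
        if reference == "mac":
            t = ann.junction_index
            windows.setdefault(ann.scaffold, []).append(
                (t - k, t + k + 2, ann.ies_id, "-")
            )
        else:
            scaffold, s, e = spans[ann.ies_id]
            windows.setdefault(scaffold, []).append((s - k, s + k + 2, ann.ies_id, "+"))
            windows.setdefault(scaffold, []).append((e - k - 2, e + k, ann.ies_id, "+"))
    for lst in windows.values():
        lst.sort()
    return windows


def count_from_alignments(
    sam_paths: str | Path | Sequence[str | Path],
    annotations: Sequence[IesAnnotation],
    mac: GenomeSequence,
    mac_plus_ies: GenomeSequence,
    k: int = 5,
    references: Sequence[str] | None = None,
) -> CountResult:
    """Count IES+/IES- support from alignments to the two references.

    A primary, non-supplementary alignment with MAPQ >= 1 counts as IES- for
    IES *i* when it covers the MAC junction window of *i* with >= ``k``
    aligned bases on each side, and as IES+ when it covers either boundary
    window on the MAC+IES reference the same way.  Each fragment (query name)
    contributes at most one count per IES; conflicting signs across files or
    mates cancel as ambiguous.  Unmapped, secondary, supplementary and MAPQ-0
    records are ignored (MAPQ 0 marks multi-mappers, i.e. ambiguous
    alignments).

    ``sam_paths`` may name one or several SAM files; which reference each was
    aligned to is detected from the header scaffold lengths unless
    ``references`` gives it explicitly (entries ``"mac"`` / ``"mac_ies"``).
    """
    if isinstance(sam_paths, (str, Path)):
        sam_paths = [sam_paths]
    sam_paths = [Path(p) for p in sam_paths]
    if references is not None and len(references) != len(sam_paths):
        raise ValueError("references must parallel sam_paths")

    index = build_probe_index(annotations, mac, k)
    seen: dict[tuple[str, str], str] = {}
    ambiguous = 0
    none = 0
    total = 0

    for file_no, path in enumerate(sam_paths):
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            header_lengths = dict(zip(sam.references, sam.lengths))
            if references is not None:
                reference = references[file_no]
                if reference not in ("mac", "mac_ies"):
                    raise ValueError(f"unknown reference label {reference!r}")
            else:
                reference = _detect_reference(header_lengths, mac, mac_plus_ies)
            genome = mac if reference == "mac" else mac_plus_ies
            for name in header_lengths:
                if name not in genome:
                    raise ValueError(f"SAM references unknown scaffold {name!r}")
            windows = _windows_for_reference(annotations, index, reference, k)
            starts = {
                scaffold: [w[0] for w in lst] for scaffold, lst in windows.items()
            }
            for aln in sam:
                total += 1
                if (
                    aln.is_unmapped
                    or aln.is_secondary
                    or aln.is_supplementary
                    or aln.mapping_quality < 1
                ):
                    continue
                scaffold = aln.reference_name
                lst = windows.get(scaffold)
                if not lst:
                    none += 1
                    continue
                positions = aln.get_reference_positions()
                if not positions:
                    none += 1
                    continue
                covered = set(positions)
                lo, hi = positions[0], positions[-1]
                hit = False
                first = bisect_left(starts[scaffold], lo)
                for w_start, w_end, ies_id, sign in lst[first:]:
                    if w_start > hi:
                        break
                    if w_end - 1 > hi:
                        continue
                    if all(p in covered for p in range(w_start, w_end)):
                        hit = True
                        key = (_fragment_id(aln.query_name), ies_id)
                        prev = seen.get(key)
                        if prev is None:
                            seen[key] = sign
                        elif prev != sign:
                            seen[key] = "!"
                if not hit:
                    none += 1

    plus: dict[str, int] = {i: 0 for i in index.ies_ids}
    minus: dict[str, int] = {i: 0 for i in index.ies_ids}
    for (_, ies_id), sign in seen.items():
        if sign == "+":
            plus[ies_id] += 1
        elif sign == "-":
            minus[ies_id] += 1
        else:
            ambiguous += 1
    counts = pd.DataFrame(
        {
            "ies_id": index.ies_ids,
            "n_plus": [plus[i] for i in index.ies_ids],
            "n_minus": [minus[i] for i in index.ies_ids],
        }
    )
    return CountResult(
        counts=counts,
        ambiguous=ambiguous,
        none=none,
        total=total,
        excluded=dict(index.excluded),
    )


def write_counts(result: CountResult, path: str | Path) -> None:
    """Write the tab-separated counts table ``ies_id  n_plus  n_minus``."""
    result.counts.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts table written by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t")
    expected = {"ies_id", "n_plus", "n_minus"}
    if not expected.issubset(df.columns):
        raise ValueError(f"counts table {path} lacks columns {expected}")
    return df
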