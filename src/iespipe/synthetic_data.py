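"""Seeded generators for genomes, IES catalogs, read libraries and coverage designs.

Every generator is a pure function of its configuration and seed: rerunning
with identical arguments yields byte-identical output, and every simulated
read id encodes its origin so that downstream results can be checked against
the generated truth.

The generators emulate the statistical structure the analysis assumes:

* an AT-rich somatic (MAC) genome (*P. tetraurelia* is ~72% AT);
* a catalog of TA-bounded IESs with lengths drawn from a periodic size
  distribution whose first peak starts at 26 bp;
* paired DNA samples — a control that is essentially fully excised and an
  experiment in which each IES is retained with its own probability ``r`` —
  with Poisson junction coverage and uniform read placement across each
  junction/boundary;
* sRNA libraries of 20–30 nt exact substrings drawn from a four-way source
  mixture (silencing target / rest of MAC / IES / contaminant);
* per-contig read-count profiles with planted covered/uncovered designs for
  the coverage-complexity stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_model import (
    GenomeSequence,
    IesAnnotation,
    ies_spans,
    insert_ies,
    reverse_complement,
    validate_annotations,
)

BASES = np.array(list("ACGT"))

# Stage ids used to derive independent per-stage random streams from one
# top-level seed: rng = default_rng([seed, STAGE_IDS[stage]]).
STAGE_IDS = {
    "genome": 1,
    "catalog": 2,
    "reads": 3,
    "srna": 4,
    "contigs": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent random stream for a named pipeline stage."""
    return np.random.default_rng([int(seed), STAGE_IDS[stage]])


class PlacementError(RuntimeError):
    """The requested number of IES junctions cannot be placed."""


# ---------------------------------------------------------------------------
# Genome and IES catalog
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, at_fraction: float) -> str:
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    return "".join(rng.choice(BASES, size=n, p=p))


def simulate_genome(
    n_scaffolds: int,
    scaffold_length: int,
    at_fraction: float = 0.72,
    seed: int = 0,
) -> GenomeSequence:
    """I.i.d. background genome with P(A) = P(T) = ``at_fraction`` / 2."""
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError("at_fraction must lie in [0, 1]")
    if n_scaffolds < 1 or scaffold_length < 200:
        raise ValueError("need n_scaffolds >= 1 and scaffold_length >= 200")
    rng = stage_rng(seed, "genome")
    return GenomeSequence(
        {
            f"scaffold_{i + 1}": _random_bases(rng, scaffold_length, at_fraction)
            for i in range(n_scaffolds)
        }
    )


def periodic_length_sampler(
    peaks: Sequence[int] = (28, 38, 48, 58, 68, 78),
    weights: Sequence[float] = (0.40, 0.25, 0.15, 0.10, 0.06, 0.04),
    jitter: int = 2,
) -> Callable[[np.random.Generator], int]:
    """IES length sampler mimicking the periodic size distribution.

    IES lengths cluster in ~10-bp periodic peaks, the first one at 26–32 bp;
    weights decay with peak rank.  Lengths are clamped to >= 26.
    """
    peaks = np.asarray(peaks)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()

    def sample(rng: np.random.Generator) -> int:
        peak = rng.choice(peaks, p=weights)
        return max(26, int(peak + rng.integers(-jitter, jitter + 1)))

    return sample


@dataclass
class IesCatalog:
    """Result of :func:`simulate_ies_catalog`.

    ``mac`` may differ from the input genome by the planted junction TAs.
    """

    mac: GenomeSequence
    annotations: list[IesAnnotation]
    mac_plus_ies: GenomeSequence


def simulate_ies_catalog(
    mac: GenomeSequence,
    n: int,
    length_sampler: Callable[[np.random.Generator], int] | None = None,
    min_spacing: int = 300,
    edge_margin: int = 150,
    at_fraction: float = 0.72,
    seed: int = 0,
    max_tries_per_ies: int = 200,
) -> IesCatalog:
    """Place ``n`` TA junctions and generate their IESs.

    Junction sites are drawn uniformly on each scaffold (at least
    ``edge_margin`` from the ends and ``min_spacing`` apart); a TA is planted
    at each site, IES internal bases are random with the configured AT
    fraction, and both the catalog and the MAC+IES genome are returned.
    """
    if length_sampler is None:
        length_sampler = periodic_length_sampler()
    rng = stage_rng(seed, "catalog")
    scaffold_names = list(mac.scaffolds)
    lengths = np.array([len(mac[s]) for s in scaffold_names], dtype=float)
    usable = lengths - 2 * edge_margin
    if n > 0 and (usable <= 0).all():
        raise PlacementError("scaffolds too short for the requested edge margin")
    weights = np.clip(usable, 0, None)
    weights = weights / weights.sum() if weights.sum() else weights

    accepted: dict[str, list[int]] = {s: [] for s in scaffold_names}
    placed = 0
    tries = 0
    while placed < n:
        tries += 1
        if tries > max_tries_per_ies * max(n, 1):
            raise PlacementError(
                f"could only place {placed}/{n} junctions with spacing "
                f"{min_spacing}; use a longer genome or fewer IESs"
            )
        sidx = rng.choice(len(scaffold_names), p=weights)
        name = scaffold_names[sidx]
        pos = int(rng.integers(edge_margin, len(mac[name]) - edge_margin))
        if all(abs(pos - q) >= min_spacing for q in accepted[name]):
            accepted[name].append(pos)
            placed += 1

    scaffolds = {name: list(seq) for name, seq in mac.items()}
    annotations: list[IesAnnotation] = []
    serial = 0
    for name in scaffold_names:
        for pos in sorted(accepted[name]):
            serial += 1
            scaffolds[name][pos : pos + 2] = ["T", "A"]
            length = length_sampler(rng)
            internal = _random_bases(rng, length - 4, at_fraction)
            annotations.append(
                IesAnnotation(
                    ies_id=f"IES_{serial:05d}",
                    scaffold=name,
                    junction_pos=pos + 1,
                    sequence="TA" + internal + "TA",
                )
            )
    planted_mac = GenomeSequence({n_: "".join(s) for n_, s in scaffolds.items()})
    annotations = validate_annotations(annotations, planted_mac)
    return IesCatalog(
        mac=planted_mac,
        annotations=annotations,
        mac_plus_ies=insert_ies(planted_mac, annotations),
    )


# ---------------------------------------------------------------------------
# Excision/retention read libraries
# ---------------------------------------------------------------------------

@dataclass
class RetentionTruth:
    """Ground truth for one simulated DNA sample.

    Attributes
    ----------
    r
        Per-IES true retention fraction in [0, 1] (mapping ies_id -> r).
    coverage
        Expected number of junction-spanning fragments per IES (Poisson mean).
    read_length
        Length of each simulated read; must be >= 2 * overhang + 2.
    overhang
        Minimal number of bases a read keeps on each side of a junction or
        boundary (the counting module's ``k``).
    seed
        Seed for the read-generation stream.
    """

    r: Mapping[str, float]
    coverage: float = 100.0
    read_length: int = 101
    overhang: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for ies_id, value in self.r.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"retention fraction for {ies_id} outside [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length < 2 * self.overhang + 2:
            raise ValueError("read_length must be >= 2 * overhang + 2")


@dataclass
class ReadSet:
    """Simulated reads plus the truth table describing each read's origin."""

    reads: list[tuple[str, str]]
    truth: pd.DataFrame

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for read_id, seq in self.reads:
                handle.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_excision_reads(
    mac: GenomeSequence,
    mac_plus_ies: GenomeSequence,
    annotations: Sequence[IesAnnotation],
    truth: RetentionTruth,
    background_fraction: float = 0.3,
    substitution_rate: float = 0.0,
    fastq: str | Path | None = None,
    truth_out: str | Path | None = None,
) -> ReadSet:
    """Simulate a junction-spanning DNA library for one sample.

    For each IES independently, ``N ~ Poisson(coverage)`` fragments span the
    locus; each is IES+ with probability ``r`` (drawn from the MAC+IES
    haplotype across one of the two boundaries, chosen evenly) and IES-
    otherwise (drawn across the MAC junction).  Start offsets are uniform
    subject to keeping >= ``overhang`` bases on each side of the junction or
    boundary, and strands are flipped with probability 1/2.  Background reads
    from non-junction MAC regions make up ``background_fraction`` of the
    library.  Qualities are fixed at 'I' when writing FASTQ.
    """
    missing = [a.ies_id for a in annotations if a.ies_id not in truth.r]
    if missing:
        raise ValueError(f"truth.r does not cover IESs: {missing[:5]}")
    if not 0.0 <= background_fraction < 1.0:
        raise ValueError("background_fraction must lie in [0, 1)")
    rng = stage_rng(truth.seed, "reads")
    L = truth.read_length
    k = truth.overhang
    spans = ies_spans(annotations)

    reads: list[tuple[str, str]] = []
    rows: list[dict] = []

    def emit(
        read_id: str,
        genome: GenomeSequence,
        scaffold: str,
        start: int,
        category: str,
        ies_id: str,
        reference: str,
    ) -> None:
        seq = genome[scaffold][start : start + L]
        strand = "-" if rng.random() < 0.5 else "+"
        out = reverse_complement(seq) if strand == "-" else seq
        out = _apply_errors(out, substitution_rate, rng)
        reads.append((read_id, out))
        rows.append(
            {
                "read_id": read_id,
                "category": category,
                "ies_id": ies_id,
                "reference": reference,
                "scaffold": scaffold,
                "start": start,
                "strand": strand,
                "length": L,
            }
        )

    n_junction = 0
    serial = 0
    for ann in annotations:
        t = ann.junction_index
        mac_len = len(mac[ann.scaffold])
        scaffold_ies, s, e = spans[ann.ies_id]
        mpi_len = len(mac_plus_ies[scaffold_ies])
        n_frag = int(rng.poisson(truth.coverage))
        r_i = truth.r[ann.ies_id]
        for _ in range(n_frag):
            serial += 1
            is_plus = rng.random() < r_i
            if is_plus:
                side = "left" if rng.random() < 0.5 else "right"
                if side == "left":
                    lo, hi = s + k + 2 - L, s - k  # window must hold flank+IES start
                else:
                    lo, hi = e + k - L, e - (k + 2)
                lo = max(lo, 0)
                hi = min(hi, mpi_len - L)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                emit(
                    f"sim:plus:{ann.ies_id}:{serial}",
                    mac_plus_ies,
                    scaffold_ies,
                    start,
                    "plus",
                    ann.ies_id,
                    "mac_ies",
                )
            else:
                lo = max(t + k + 2 - L, 0)
                hi = min(t - k, mac_len - L)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                emit(
                    f"sim:minus:{ann.ies_id}:{serial}",
                    mac,
                    ann.scaffold,
                    start,
                    "minus",
                    ann.ies_id,
                    "mac",
                )
            n_junction += 1

    # Background reads avoid every start that would let the read contain a
    # full minus-probe window, so a background-only library yields zero counts
    # up to chance k-mer collisions.
    if background_fraction > 0 and n_junction > 0:
        n_background = round(
            background_fraction / (1 - background_fraction) * n_junction
        )
        forbidden: dict[str, list[tuple[int, int]]] = {
            name: [] for name in mac.scaffolds
        }
        for ann in annotations:
            t = ann.junction_index
            forbidden[ann.scaffold].append((t + k + 2 - L, t - k))
        names = list(mac.scaffolds)
        lens = np.array([len(mac[s]) for s in names], dtype=float)
        weights = lens / lens.sum()
        emitted = 0
        attempts = 0
        while emitted < n_background and attempts < 100 * n_background:
            attempts += 1
            name = names[rng.choice(len(names), p=weights)]
            start = int(rng.integers(0, len(mac[name]) - L + 1))
            if any(lo <= start <= hi for lo, hi in forbidden[name]):
                continue
            serial += 1
            emit(
                f"sim:background:{name}:{serial}",
                mac,
                name,
                start,
                "background",
                "",
                "mac",
            )
            emitted += 1

    truth_df = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "category",
            "ies_id",
            "reference",
            "scaffold",
            "start",
            "strand",
            "length",
        ],
    )
    readset = ReadSet(reads=reads, truth=truth_df)
    if fastq is not None:
        readset.write_fastq(fastq)
    if truth_out is not None:
        readset.write_truth(truth_out)
    return readset


def write_sam(
    readset: ReadSet,
    path: str | Path,
    genome: GenomeSequence,
    reference: str,
) -> int:
    """Write perfect alignments for the reads drawn from ``reference``.

    ``reference`` is ``"mac"`` or ``"mac_ies"``; only reads whose truth row
    names that reference are emitted (each read aligns to the haplotype it was
    sampled from).  Alignments are primary, ungapped (all-match CIGAR), MAPQ
    60, with flag 16 for reads sampled from the reverse strand.  Returns the
    number of records written.
    """
    import pysam

    names = list(genome.scaffolds)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(genome[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    rows = readset.truth
    seqs = dict(readset.reads)
    written = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in rows.itertuples():
            if row.reference != reference:
                continue
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = row.read_id
            read_seq = seqs[row.read_id]
            # SEQ is stored on the forward reference strand.
            aln.query_sequence = (
                reverse_complement(read_seq) if row.strand == "-" else read_seq
            )
            aln.flag = 16 if row.strand == "-" else 0
            aln.reference_id = tid[row.scaffold]
            aln.reference_start = int(row.start)
            aln.mapping_quality = 60
            aln.cigartuples = [(0, int(row.length))]
            out.write(aln)
            written += 1
    return written


def simulate_junction_counts(
    ies_ids: Sequence[str],
    truth: RetentionTruth,
) -> pd.DataFrame:
    """Count-level view of the read model: the per-IES IES+/IES- tallies.

    Draws ``N ~ Poisson(coverage)`` and ``n_plus ~ Binomial(N, r)`` per IES —
    the exact distribution of probe counts from an error-free library — and
    returns a counts table ``ies_id  n_plus  n_minus``.
    """
    rng = stage_rng(truth.seed, "reads")
    n = rng.poisson(truth.coverage, size=len(ies_ids))
    r = np.array([truth.r[i] for i in ies_ids])
    n_plus = rng.binomial(n, r)
    return pd.DataFrame(
        {"ies_id": list(ies_ids), "n_plus": n_plus, "n_minus": n - n_plus}
    )


# ---------------------------------------------------------------------------
# Small RNA mixtures
# ---------------------------------------------------------------------------

@dataclass
class SrnaMixture:
    """Composition of a simulated 20–30 nt sRNA library.

    ``proportions`` maps category name (e.g. ``target``, ``mac``, ``ies``,
    ``contaminant``) to its expected fraction; fractions must be non-negative
    and sum to 1.  Lengths are drawn from ``length_weights`` over
    [``min_len``, ``max_len``] (uniform when None).
    """

    proportions: Mapping[str, float]
    n_reads: int
    min_len: int = 20
    max_len: int = 30
    length_weights: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        values = np.array(list(self.proportions.values()), dtype=float)
        if (values < 0).any() or not math.isclose(values.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("proportions must be >= 0 and sum to 1")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if self.length_weights is not None and len(self.length_weights) != (
            self.max_len - self.min_len + 1
        ):
            raise ValueError("length_weights must cover min_len..max_len")


def simulate_srna(
    mixture: SrnaMixture,
    pools: Mapping[str, Sequence[str]],
    fastq: str | Path | None = None,
    truth_out: str | Path | None = None,
) -> ReadSet:
    """Draw sRNA reads as exact substrings of their source pools.

    Each read's category of origin is recorded in the truth table; strands are
    flipped with probability 1/2.
    """
    for category, p in mixture.proportions.items():
        if p > 0 and not pools.get(category):
            raise ValueError(f"category {category!r} has proportion > 0 but no pool")
    rng = stage_rng(mixture.seed, "srna")
    categories = list(mixture.proportions)
    probs = np.array([mixture.proportions[c] for c in categories], dtype=float)
    lengths = np.arange(mixture.min_len, mixture.max_len + 1)
    lw = (
        np.array(mixture.length_weights, dtype=float)
        if mixture.length_weights is not None
        else np.ones(len(lengths))
    )
    lw = lw / lw.sum()

    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    for i in range(mixture.n_reads):
        category = categories[rng.choice(len(categories), p=probs)]
        length = int(rng.choice(lengths, p=lw))
        pool = pools[category]
        src = int(rng.integers(0, len(pool)))
        source = pool[src]
        if length > len(source):
            raise ValueError(
                f"requested length {length} exceeds a {category!r} source sequence"
            )
        start = int(rng.integers(0, len(source) - length + 1))
        seq = source[start : start + length]
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        read_id = f"srna:{category}:{i}"
        reads.append((read_id, seq))
        rows.append(
            {
                "read_id": read_id,
                "category": category,
                "source_index": src,
                "start": start,
                "strand": strand,
                "length": length,
            }
        )
    readset = ReadSet(reads=reads, truth=pd.DataFrame(rows))
    if fastq is not None:
        readset.write_fastq(fastq)
    if truth_out is not None:
        readset.write_truth(truth_out)
    return readset


# ---------------------------------------------------------------------------
# Contig coverage designs
# ---------------------------------------------------------------------------

@dataclass
class ContigCoverageDesign:
    """Planted covered/uncovered design over a shared contig set.

    ``tables`` maps dataset name to a frame with columns
    ``contig_id  length  reads`` plus the emitted ``library_size``.
    """

    lengths: pd.DataFrame  # contig_id, length
    tables: dict[str, pd.DataFrame]
    library_sizes: dict[str, int]
    covered: dict[str, list[bool]]


def simulate_contig_coverage(
    covered_flags: Mapping[str, Sequence[bool]],
    contig_lengths: Sequence[int] | None = None,
    n_contigs: int | None = None,
    length_sampler: Callable[[np.random.Generator], int] | None = None,
    library_size: int = 1_000_000,
    min_rpkm: float = 2.0,
    seed: int = 0,
) -> ContigCoverageDesign:
    """Emit per-dataset contig read counts realizing a planted coverage design.

    Contigs flagged covered receive counts giving RPKM drawn uniformly in
    (2.5 * min_rpkm, 25 * min_rpkm); uncovered contigs get RPKM in
    [0, 0.75 * min_rpkm], so the design is recoverable exactly at the
    ``min_rpkm`` threshold.
    """
    rng = stage_rng(seed, "contigs")
    flag_lists = {k: list(v) for k, v in covered_flags.items()}
    sizes = {len(v) for v in flag_lists.values()}
    if len(sizes) != 1:
        raise ValueError("all datasets must flag the same number of contigs")
    n = sizes.pop()
    if n_contigs is not None and n_contigs != n:
        raise ValueError("n_contigs inconsistent with covered_flags")
    if contig_lengths is None:
        if length_sampler is None:
            def length_sampler(r: np.random.Generator) -> int:  # noqa: E731-ish
                return int(r.integers(400, 8000))
        contig_lengths = [length_sampler(rng) for _ in range(n)]
    if len(contig_lengths) != n:
        raise ValueError("contig_lengths inconsistent with covered_flags")

    ids = [f"contig_{i + 1:04d}" for i in range(n)]
    lengths_df = pd.DataFrame({"contig_id": ids, "length": list(contig_lengths)})
    tables: dict[str, pd.DataFrame] = {}
    library_sizes: dict[str, int] = {}
    for dataset, flags in flag_lists.items():
        is_covered = np.array(flags, dtype=bool)
        rpkm = np.where(
            is_covered,
            rng.uniform(2.5 * min_rpkm, 25 * min_rpkm, size=n),
            rng.uniform(0.0, 0.75 * min_rpkm, size=n),
        )
        exact = rpkm * (np.array(contig_lengths) / 1000.0) * (library_size / 1e6)
        # ceil for covered / floor for uncovered: rounding never crosses the
        # threshold under total_mapped = library_size
        reads = np.where(is_covered, np.ceil(exact), np.floor(exact)).astype(int)
        tables[dataset] = pd.DataFrame(
            {"contig_id": ids, "length": list(contig_lengths), "reads": reads}
        )
        library_sizes[dataset] = library_size
    return ContigCoverageDesign(
        lengths=lengths_df,
        tables=tables,
        library_sizes=library_sizes,
        covered=flag_lists,
    )
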