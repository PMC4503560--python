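"""Data model and I/O for somatic (MAC) genomes, IES annotations and junction probes.

In *Paramecium tetraurelia* the somatic macronuclear (MAC) genome is produced
from the germline genome by programmed DNA elimination, which includes the
precise excision of tens of thousands of short Internal Eliminated Sequences
(IESs).  Each IES is bounded by a TA dinucleotide on both sides; excision
removes the IES and leaves a single TA at the macronuclear junction.  The
"MAC+IES" genome — the MAC assembly with every annotated IES reinserted at its
junction — serves as a proxy for the unrearranged germline sequence at IES
loci.

Conventions used throughout the package:

* **Coordinates** — GFF3 files and :attr:`IesAnnotation.junction_pos` are
  1-based inclusive; all internal arithmetic is 0-based half-open.  The
  conversion happens only in the parser/writer layer of this module.
* **IES sequence** — includes *both* terminal TA dinucleotides.  Inserting an
  IES replaces the single junction TA of the MAC sequence with the full IES
  (which supplies both copies); excision is the exact inverse and restores the
  single TA.  The shortest legal IES is therefore 6 bp ("TA" + 2 + "TA").
* **Alphabet** — uppercase ``A C G T N`` only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
IES_FEATURE_TYPE = "internal_eliminated_sequence"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """A FASTA record or genome container violates the model invariants."""


class AnnotationError(ValueError):
    """An IES annotation is inconsistent with the MAC sequence it targets."""


class ProbeUnavailableError(ValueError):
    """Probes of the requested flank width cannot be built for an IES."""


# ---------------------------------------------------------------------------
# Genome container
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """An ordered collection of named scaffolds.

    Parameters
    ----------
    scaffolds
        Ordered mapping of scaffold id to nucleotide string.  Ids must be
        unique and non-empty, sequences non-empty and restricted to
        ``A C G T N`` (uppercase).
    """

    scaffolds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scaffolds = dict(self.scaffolds)
        for name, seq in self.scaffolds.items():
            if not name:
                raise GenomeError("empty scaffold id")
            if not seq:
                raise GenomeError(f"scaffold {name!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeError(
                    f"scaffold {name!r} contains illegal characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def __getitem__(self, name: str) -> str:
        return self.scaffolds[name]

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self.scaffolds.items())

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-)FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; duplicate ids, empty records and characters
    outside ``A C G T N`` are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scaffolds: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in scaffolds:
            raise GenomeError(f"duplicate record id {record.id!r} in {path}")
        scaffolds[record.id] = str(record.seq).upper()
    if not scaffolds:
        raise GenomeError(f"no FASTA records found in {path}")
    return GenomeSequence(scaffolds)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    """Write scaffolds in input order, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# IES annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IesAnnotation:
    """One IES anchored to its macronuclear excision junction.

    Attributes
    ----------
    ies_id
        Unique identifier.
    scaffold
        Scaffold id on the MAC reference.
    junction_pos
        1-based position of the first base of the junction TA on the MAC
        sequence.
    sequence
        Full IES sequence including both terminal TA dinucleotides.
    """

    ies_id: str
    scaffold: str
    junction_pos: int
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def junction_index(self) -> int:
        """0-based index of the junction TA on the MAC scaffold."""
        return self.junction_pos - 1

    def validate(self, mac: GenomeSequence) -> None:
        if self.length < 6:
            raise AnnotationError(
                f"IES {self.ies_id}: sequence shorter than 6 bp ({self.length})"
            )
        if not (self.sequence.startswith("TA") and self.sequence.endswith("TA")):
            raise AnnotationError(f"IES {self.ies_id}: sequence is not TA-bounded")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise AnnotationError(
                f"IES {self.ies_id}: illegal characters {sorted(bad)}"
            )
        if self.scaffold not in mac:
            raise AnnotationError(
                f"IES {self.ies_id}: unknown scaffold {self.scaffold!r}"
            )
        seq = mac[self.scaffold]
        j = self.junction_index
        if j < 0 or j + 2 > len(seq):
            raise AnnotationError(
                f"IES {self.ies_id}: junction_pos {self.junction_pos} outside scaffold"
            )
        if seq[j : j + 2] != "TA":
            raise AnnotationError(
                f"IES {self.ies_id}: MAC site at {self.junction_pos} is "
                f"{seq[j:j + 2]!r}, expected 'TA'"
            )


def validate_annotations(
    annotations: Iterable[IesAnnotation], mac: GenomeSequence
) -> list[IesAnnotation]:
    """Validate each annotation against ``mac`` and check pairwise overlaps.

    Returns the annotations sorted by (scaffold, junction_pos).  Junction TA
    intervals of distinct IESs on one scaffold must not overlap.
    """
    anns = sorted(annotations, key=lambda a: (a.scaffold, a.junction_pos))
    seen_ids: set[str] = set()
    for ann in anns:
        if ann.ies_id in seen_ids:
            raise AnnotationError(f"duplicate ies_id {ann.ies_id!r}")
        seen_ids.add(ann.ies_id)
        ann.validate(mac)
    for prev, cur in zip(anns, anns[1:]):
        if prev.scaffold == cur.scaffold and cur.junction_pos - prev.junction_pos < 2:
            raise AnnotationError(
                f"overlapping junctions: {prev.ies_id} at {prev.junction_pos} and "
                f"{cur.ies_id} at {cur.junction_pos} on {cur.scaffold}"
            )
    return anns


def read_ies_annotations(
    path: str | Path, mac: GenomeSequence
) -> list[IesAnnotation]:
    """Parse a GFF3 IES catalog and validate it against the MAC genome.

    Expected records have feature type ``internal_eliminated_sequence``,
    1-based inclusive coordinates covering the junction TA, and attributes
    ``ID=<ies_id>;sequence=<ACGT...>``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    annotations: list[IesAnnotation] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feature = feature_from_line(line)
            if feature.featuretype != IES_FEATURE_TYPE:
                continue
            try:
                ies_id = feature.attributes["ID"][0]
                sequence = feature.attributes["sequence"][0].upper()
            except KeyError as exc:
                raise AnnotationError(
                    f"GFF3 record missing attribute {exc} in {path}"
                ) from exc
            annotations.append(
                IesAnnotation(
                    ies_id=ies_id,
                    scaffold=feature.seqid,
                    junction_pos=feature.start,
                    sequence=sequence,
                )
            )
    return validate_annotations(annotations, mac)


def write_ies_annotations(
    annotations: Iterable[IesAnnotation], path: str | Path
) -> None:
    """Write a deterministic GFF3 IES catalog (sorted by scaffold, position)."""
    anns = sorted(annotations, key=lambda a: (a.scaffold, a.junction_pos))
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for ann in anns:
            handle.write(
                "\t".join(
                    [
                        ann.scaffold,
                        "iespipe",
                        IES_FEATURE_TYPE,
                        str(ann.junction_pos),
                        str(ann.junction_pos + 1),
                        ".",
                        "+",
                        ".",
                        f"ID={ann.ies_id};sequence={ann.sequence}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genome surgery: insertion and excision
# ---------------------------------------------------------------------------

def insert_ies(
    mac: GenomeSequence, annotations: Iterable[IesAnnotation]
) -> GenomeSequence:
    """Build the MAC+IES (germline-like) genome.

    For each IES, the junction TA at ``junction_pos`` is replaced by the full
    IES sequence (which supplies both terminal TAs); downstream coordinates on
    the scaffold shift by ``len(sequence) - 2``.  Scaffolds without IESs are
    returned unchanged.
    """
    anns = validate_annotations(annotations, mac)
    by_scaffold: dict[str, list[IesAnnotation]] = {}
    for ann in anns:
        by_scaffold.setdefault(ann.scaffold, []).append(ann)
    out: dict[str, str] = {}
    for name, seq in mac.items():
        here = by_scaffold.get(name)
        if not here:
            out[name] = seq
            continue
        parts: list[str] = []
        cursor = 0
        for ann in here:
            j = ann.junction_index
            parts.append(seq[cursor:j])
            parts.append(ann.sequence)
            cursor = j + 2  # skip the junction TA, replaced by the IES
        parts.append(seq[cursor:])
        out[name] = "".join(parts)
    return GenomeSequence(out)


def ies_spans(
    annotations: Iterable[IesAnnotation],
) -> dict[str, tuple[str, int, int]]:
    """0-based half-open span of each IES on the MAC+IES coordinate system.

    Returns ``{ies_id: (scaffold, start, end)}`` where ``start`` is the index
    of the IES's first base (its leading TA) in the MAC+IES scaffold built by
    :func:`insert_ies` with the same annotations.
    """
    anns = sorted(annotations, key=lambda a: (a.scaffold, a.junction_pos))
    spans: dict[str, tuple[str, int, int]] = {}
    shift = 0
    current_scaffold: str | None = None
    for ann in anns:
        if ann.scaffold != current_scaffold:
            current_scaffold = ann.scaffold
            shift = 0
        start = ann.junction_index + shift
        spans[ann.ies_id] = (ann.scaffold, start, start + ann.length)
        shift += ann.length - 2
    return spans


def excise_ies(
    mac_plus_ies: GenomeSequence, annotations: Iterable[IesAnnotation]
) -> GenomeSequence:
    """Invert :func:`insert_ies`: replace each IES by a single junction TA.

    Raises :class:`AnnotationError` if an IES sequence is not found at its
    expected coordinate, which guards the round-trip identity
    ``excise_ies(insert_ies(G, A), A) == G``.
    """
    anns = sorted(annotations, key=lambda a: (a.scaffold, a.junction_pos))
    spans = ies_spans(anns)
    by_scaffold: dict[str, list[IesAnnotation]] = {}
    for ann in anns:
        by_scaffold.setdefault(ann.scaffold, []).append(ann)
    out: dict[str, str] = {}
    for name, seq in mac_plus_ies.items():
        here = by_scaffold.get(name)
        if not here:
            out[name] = seq
            continue
        parts: list[str] = []
        cursor = 0
        for ann in here:
            _, start, end = spans[ann.ies_id]
            if seq[start:end] != ann.sequence:
                raise AnnotationError(
                    f"IES {ann.ies_id}: sequence not found at expected "
                    f"coordinate {start} on {name}"
                )
            parts.append(seq[cursor:start])
            parts.append("TA")
            cursor = end
        parts.append(seq[cursor:])
        out[name] = "".join(parts)
    return GenomeSequence(out)


# ---------------------------------------------------------------------------
# Junction probes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionProbes:
    """The three diagnostic sequence windows of one IES at flank width ``k``.

    ``minus_probe`` is the MAC window centred on the junction TA (excised
    form); the two plus probes straddle the left and right IES boundaries on
    the MAC+IES haplotype (unexcised form).  All three have length ``2k + 2``.
    Counting reads against boundary windows rather than whole IESs avoids
    length biases from the wide IES size distribution.
    """

    ies_id: str
    minus_probe: str
    plus_left_probe: str
    plus_right_probe: str
    k: int

    def all_probes(self) -> dict[str, str]:
        return {
            "minus": self.minus_probe,
            "plus_left": self.plus_left_probe,
            "plus_right": self.plus_right_probe,
        }


def make_probes(mac: GenomeSequence, ies: IesAnnotation, k: int) -> JunctionProbes:
    """Extract the minus/plus-left/plus-right probes for one IES.

    Raises :class:`ProbeUnavailableError` when the IES sits within ``k`` bases
    of a scaffold end (no full flank) or is shorter than ``k + 2`` (its two
    boundary windows would run past the opposite end).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = mac[ies.scaffold]
    j = ies.junction_index
    if j - k < 0 or j + 2 + k > len(seq):
        raise ProbeUnavailableError(
            f"IES {ies.ies_id}: junction within {k} bases of a scaffold end"
        )
    if ies.length < k + 2:
        raise ProbeUnavailableError(
            f"IES {ies.ies_id}: IES length {ies.length} < k + 2 = {k + 2}"
        )
    left = seq[j - k : j]
    right = seq[j + 2 : j + 2 + k]
    return JunctionProbes(
        ies_id=ies.ies_id,
        minus_probe=left + "TA" + right,
        plus_left_probe=left + ies.sequence[: k + 2],
        plus_right_probe=ies.sequence[-(k + 2) :] + right,
        k=k,
    )
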