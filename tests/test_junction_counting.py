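"""Probe index construction, single-read verdicts, library counting, and
agreement between probe-mode and alignment-mode counting."""

from __future__ import annotations

import pandas as pd
import pytest

import iespipe as ip
from iespipe.junction_counting import Verdict, _classify
from iespipe.reference_model import reverse_complement


def brute_force_counts(reads, annotations, mac, k):
    """Independent oracle: search every probe (both strands) in every read
    with substring scans and apply the counting rules directly."""
    probe_map: dict[str, set[tuple[str, str]]] = {}
    countable = []
    for ann in annotations:
        try:
            probes = ip.make_probes(mac, ann, k)
        except ip.ProbeUnavailableError:
            continue
        triple = probes.all_probes()
        if len(set(triple.values())) < 3:
            continue
        countable.append(ann.ies_id)
        for kind, probe in triple.items():
            if "N" in probe:
                continue
            for variant in {probe, reverse_complement(probe)}:
                probe_map.setdefault(variant, set()).add((ann.ies_id, kind))
    plus = {i: 0 for i in countable}
    minus = {i: 0 for i in countable}
    ambiguous = none = 0
    for _, seq in reads:
        seq = seq.upper()
        hits: set[tuple[str, str]] = set()
        hit_shared = False
        for probe, targets in probe_map.items():
            if probe in seq:
                if len(targets) > 1:
                    hit_shared = True
                hits |= targets
        if hit_shared or len({i for i, _ in hits}) > 1:
            ambiguous += 1
        elif not hits:
            none += 1
        else:
            ies = next(iter(hits))[0]
            kinds = {kind for _, kind in hits}
            if kinds == {"minus"}:
                minus[ies] += 1
            elif "minus" in kinds:
                ambiguous += 1
            else:
                plus[ies] += 1
    return plus, minus, ambiguous, none


class TestProbeIndex:
    def test_index_size_is_six_per_ies_minus_palindromic_merges(
        self, small_catalog, small_index
    ):
        n = len(small_index.ies_ids)
        palindromic = sum(
            1
            for probe, target in small_index.lookup.items()
            if target is not None and probe == reverse_complement(probe)
        )
        assert len(small_index.lookup) == 6 * n - palindromic

    def test_empty_catalog_gives_empty_index(self, small_catalog):
        index = ip.build_probe_index([], small_catalog.mac, 5)
        assert index.lookup == {} and index.ies_ids == []

    def test_shared_probe_marked_ambiguous(self):
        # two IESs with identical flanks and identical ends on one scaffold
        flank = "GGCCG"
        block = flank + "TA" + flank
        mac = ip.GenomeSequence(
            {"s": "A" * 20 + block + "A" * 20 + block + "A" * 20}
        )
        ies_seq = "TACGTTGCAGTA"
        anns = [
            ip.IesAnnotation("i1", "s", 26, ies_seq),
            ip.IesAnnotation("i2", "s", 58, ies_seq),
        ]
        index = ip.build_probe_index(anns, mac, 5)
        assert index.collisions
        probes = ip.make_probes(mac, anns[0], 5)
        assert index.lookup[probes.minus_probe] is None

    def test_degenerate_toy_probes_excluded(self, toy_mac, toy_ies):
        index = ip.build_probe_index([toy_ies], toy_mac, 2)
        assert "i1" in index.excluded
        assert index.ies_ids == []


class TestClassifyRead:
    def test_embedded_minus_probe(self, small_catalog, small_index):
        ann = small_catalog.annotations[0]
        probes = ip.make_probes(small_catalog.mac, ann, 5)
        read = "GGGGG" + probes.minus_probe + "CCCCC"
        result = ip.classify_read(read, small_index)
        assert (result.verdict, result.ies_id) == (Verdict.MINUS, ann.ies_id)

    def test_read_with_both_plus_probes_counted_once_as_plus(
        self, small_catalog, small_index
    ):
        # a read spanning the whole IES holds both boundary probes
        ann = small_catalog.annotations[0]
        j = ann.junction_index
        seq = small_catalog.mac[ann.scaffold]
        read = seq[j - 10 : j] + ann.sequence + seq[j + 2 : j + 12]
        result = ip.classify_read(read, small_index)
        assert (result.verdict, result.ies_id) == (Verdict.PLUS, ann.ies_id)

    def test_reverse_complement_of_plus_probe_is_plus(
        self, small_catalog, small_index
    ):
        ann = small_catalog.annotations[1]
        probes = ip.make_probes(small_catalog.mac, ann, 5)
        read = reverse_complement("AAAA" + probes.plus_left_probe + "TTTT")
        result = ip.classify_read(read, small_index)
        assert (result.verdict, result.ies_id) == (Verdict.PLUS, ann.ies_id)

    def test_short_read_is_none(self, small_index):
        assert ip.classify_read("ACGT", small_index).verdict is Verdict.NONE

    def test_plus_minus_mixture_is_ambiguous(self, small_catalog, small_index):
        ann = small_catalog.annotations[2]
        probes = ip.make_probes(small_catalog.mac, ann, 5)
        read = probes.minus_probe + "G" + probes.plus_left_probe
        assert ip.classify_read(read, small_index).verdict is Verdict.AMBIGUOUS

    def test_cross_ies_mixture_is_ambiguous(self, small_catalog, small_index):
        p1 = ip.make_probes(small_catalog.mac, small_catalog.annotations[0], 5)
        p2 = ip.make_probes(small_catalog.mac, small_catalog.annotations[1], 5)
        read = p1.plus_left_probe + "G" + p2.plus_left_probe
        assert ip.classify_read(read, small_index).verdict is Verdict.AMBIGUOUS


class TestCountReads:
    def test_generator_truth_recovered_at_high_coverage(self, small_catalog):
        ids = [a.ies_id for a in small_catalog.annotations]
        truth = ip.RetentionTruth(r={i: 0.5 for i in ids}, coverage=300, seed=13)
        rs = ip.simulate_excision_reads(
            small_catalog.mac,
            small_catalog.mac_plus_ies,
            small_catalog.annotations,
            truth,
            background_fraction=0.0,
        )
        index = ip.build_probe_index(small_catalog.annotations, small_catalog.mac, 5)
        result = ip.count_reads(rs.reads, index)
        frac = result.counts.n_plus / (result.counts.n_plus + result.counts.n_minus)
        assert ((frac - 0.5).abs() < 0.12).all()

    def test_background_only_library_counts_zero(self, small_catalog, small_index):
        ids = [a.ies_id for a in small_catalog.annotations]
        truth = ip.RetentionTruth(r={i: 0.5 for i in ids}, coverage=20, seed=21)
        rs = ip.simulate_excision_reads(
            small_catalog.mac,
            small_catalog.mac_plus_ies,
            small_catalog.annotations,
            truth,
            background_fraction=0.5,
        )
        background = [
            (rid, seq)
            for (rid, seq), cat in zip(rs.reads, rs.truth.category)
            if cat == "background"
        ]
        result = ip.count_reads(background, small_index)
        assert result.counts.n_plus.sum() == 0
        assert result.counts.n_minus.sum() == 0

    def test_counts_equal_brute_force_oracle(self, small_catalog, small_readset):
        _, rs = small_readset
        reads = rs.reads[:1000]
        index = ip.build_probe_index(small_catalog.annotations, small_catalog.mac, 5)
        result = ip.count_reads(reads, index)
        plus, minus, ambiguous, none = brute_force_counts(
            reads, small_catalog.annotations, small_catalog.mac, 5
        )
        for row in result.counts.itertuples():
            assert row.n_plus == plus[row.ies_id]
            assert row.n_minus == minus[row.ies_id]
        assert result.ambiguous == ambiguous
        assert result.none == none

    def test_verdict_partition_sums_to_total(self, small_readset, small_index):
        _, rs = small_readset
        result = ip.count_reads(rs.reads, small_index)
        assert (
            result.counts.n_plus.sum()
            + result.counts.n_minus.sum()
            + result.ambiguous
            + result.none
            == result.total
            == len(rs.reads)
        )

    def test_adding_reads_never_decreases_counts(self, small_readset, small_index):
        _, rs = small_readset
        half = ip.count_reads(rs.reads[:500], small_index)
        full = ip.count_reads(rs.reads[:1000], small_index)
        merged = half.counts.merge(full.counts, on="ies_id", suffixes=("_h", "_f"))
        assert (merged.n_plus_f >= merged.n_plus_h).all()
        assert (merged.n_minus_f >= merged.n_minus_h).all()

    def test_strand_symmetry(self, small_readset, small_index):
        _, rs = small_readset
        reads = rs.reads[:800]
        flipped = [(rid, reverse_complement(seq)) for rid, seq in reads]
        a = ip.count_reads(reads, small_index)
        b = ip.count_reads(flipped, small_index)
        assert a.counts.equals(b.counts)
        assert (a.ambiguous, a.none) == (b.ambiguous, b.none)

    def test_paired_fragment_counts_once_per_ies(self, small_catalog, small_index):
        ann = small_catalog.annotations[0]
        probes = ip.make_probes(small_catalog.mac, ann, 5)
        mates = [
            ("frag1/1", "AA" + probes.plus_left_probe + "AA"),
            ("frag1/2", "TT" + probes.plus_right_probe + "TT"),
        ]
        result = ip.count_reads(mates, small_index, paired=True)
        assert int(result.counts.set_index("ies_id").loc[ann.ies_id, "n_plus"]) == 1

    def test_fastq_stream_matches_in_memory(self, small_readset, small_index, tmp_path):
        _, rs = small_readset
        fq = tmp_path / "reads.fastq"
        ip.ReadSet(rs.reads[:300], rs.truth.iloc[:300]).write_fastq(fq)
        assert ip.count_reads(fq, small_index).counts.equals(
            ip.count_reads(rs.reads[:300], small_index).counts
        )


class TestAlignmentMode:
    def test_sam_counts_equal_probe_counts(
        self, small_catalog, small_readset, small_index, tmp_path
    ):
        _, rs = small_readset
        mac_sam = tmp_path / "mac.sam"
        mpi_sam = tmp_path / "mpi.sam"
        ip.write_sam(rs, mac_sam, small_catalog.mac, "mac")
        ip.write_sam(rs, mpi_sam, small_catalog.mac_plus_ies, "mac_ies")
        probe_mode = ip.count_reads(rs.reads, small_index)
        sam_mode = ip.count_from_alignments(
            [mac_sam, mpi_sam],
            small_catalog.annotations,
            small_catalog.mac,
            small_catalog.mac_plus_ies,
            5,
        )
        assert probe_mode.counts.equals(sam_mode.counts)

    def test_low_mapq_and_unmapped_records_ignored(self, small_catalog, tmp_path):
        import pysam

        ann = small_catalog.annotations[0]
        header = {
            "HD": {"VN": "1.6"},
            "SQ": [
                {"SN": n, "LN": len(s)} for n, s in small_catalog.mac.items()
            ],
        }
        tid = {n: i for i, n in enumerate(small_catalog.mac.scaffolds)}
        path = tmp_path / "x.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for name, mapq in (("good", 37), ("multi", 0)):
                aln = pysam.AlignedSegment(out.header)
                aln.query_name = name
                start = ann.junction_index - 25
                aln.query_sequence = small_catalog.mac[ann.scaffold][
                    start : start + 50
                ]
                aln.reference_id = tid[ann.scaffold]
                aln.reference_start = start
                aln.mapping_quality = mapq
                aln.cigartuples = [(0, 50)]
                out.write(aln)
        result = ip.count_from_alignments(
            path,
            small_catalog.annotations,
            small_catalog.mac,
            small_catalog.mac_plus_ies,
            5,
        )
        row = result.counts.set_index("ies_id").loc[ann.ies_id]
        assert int(row.n_minus) == 1  # only the MAPQ-37 record counts
        assert int(row.n_plus) == 0

    def test_unknown_scaffold_rejected(self, small_catalog, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("@SQ\tSN:mystery\tLN:5000\n")
        with pytest.raises(ValueError, match="unknown scaffold"):
            ip.count_from_alignments(
                path,
                small_catalog.annotations,
                small_catalog.mac,
                small_catalog.mac_plus_ies,
                5,
            )

    def test_counts_io_round_trip(self, small_readset, small_index, tmp_path):
        _, rs = small_readset
        result = ip.count_reads(rs.reads[:200], small_index)
        path = tmp_path / "counts.tsv"
        ip.write_counts(result, path)
        assert ip.read_counts(path).equals(result.counts)
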