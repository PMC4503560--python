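"""Shared fixtures: toy genomes and a small simulated catalog with reads.

Everything is generated programmatically from fixed seeds; the heavier
catalog/read fixtures are session-scoped so the counting tests share one
simulation.
"""

from __future__ import annotations

import pytest

import iespipe as ip


@pytest.fixture
def toy_mac() -> ip.GenomeSequence:
    return ip.GenomeSequence({"s1": "CCTAGG"})


@pytest.fixture
def toy_ies() -> ip.IesAnnotation:
    return ip.IesAnnotation("i1", "s1", 3, "TAGGGTA")


@pytest.fixture(scope="session")
def small_catalog() -> ip.IesCatalog:
    """15 IESs on a 2 x 20 kb genome (moderate AT to keep probes distinct)."""
    genome = ip.simulate_genome(2, 20_000, 0.6, seed=3)
    return ip.simulate_ies_catalog(genome, 15, at_fraction=0.6, seed=3)


@pytest.fixture(scope="session")
def small_readset(small_catalog: ip.IesCatalog) -> tuple[ip.RetentionTruth, ip.ReadSet]:
    ids = [a.ies_id for a in small_catalog.annotations]
    truth = ip.RetentionTruth(
        r={i: 0.4 for i in ids}, coverage=40, read_length=80, overhang=5, seed=7
    )
    readset = ip.simulate_excision_reads(
        small_catalog.mac,
        small_catalog.mac_plus_ies,
        small_catalog.annotations,
        truth,
    )
    return truth, readset


@pytest.fixture(scope="session")
def small_index(small_catalog: ip.IesCatalog) -> ip.ProbeIndex:
    return ip.build_probe_index(small_catalog.annotations, small_catalog.mac, 5)
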