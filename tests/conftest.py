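import pytest

from eclipquant.simulate import (
    GenomeRef,
    SimConfig,
    SimulatedLibrary,
    build_reference,
    simulate_reads,
)
from eclipquant.sitefilter import AlignedRead


def sam_line_to_read(line: str) -> AlignedRead:
    """Minimal SAM line -> AlignedRead converter for in-memory tests."""
    fields = line.split("\t")
    md = None
    for tag in fields[11:]:
        if tag.startswith("MD:Z:"):
            md = tag[5:]
    return AlignedRead(
        read_id=fields[0],
        contig=fields[2],
        start=int(fields[3]) - 1,
        cigar=fields[5],
        md=md,
        strand="-" if int(fields[1]) & 16 else "+",
        mapq=int(fields[4]),
    )


def library_reads(library: SimulatedLibrary) -> list[AlignedRead]:
    return [sam_line_to_read(line) for line in library.sam_lines]


@pytest.fixture(scope="session")
def ref() -> GenomeRef:
    return build_reference(11)


@pytest.fixture(scope="session")
def small_library(ref) -> SimulatedLibrary:
    cfg = SimConfig(
        seed=11,
        n_background=60,
        n_site_truncation=40,
        n_site_span=30,
        pcr_duplication_rate=0.7,
        substitution_rate_at_crosslink=0.2,
    )
    return simulate_reads(ref, cfg)
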