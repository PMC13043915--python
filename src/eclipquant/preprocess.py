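"""Read preprocessing: 3' adapter trimming, 5' UMI extraction, UMI dedup.

The trimming stage removes the 3' sequencing adapter using exact-match
semantics with terminal-overlap support: a full adapter occurrence anywhere
in the read, or a prefix of the adapter of at least ``min_overlap`` bases
ending exactly at the read's 3' end, is removed together with everything
downstream of it. ``N`` in the read matches any adapter base when wildcard
matching is on. Reads shorter than ``min_length`` after trimming are
discarded.

UMI extraction moves the first ``umi_length`` bases of each read into the
read identifier (separator ``_``, the convention consumed downstream by
position+UMI deduplication), so PCR duplicates of one molecule share both
their mapping position and their identifier suffix.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .sitefilter import AlignedRead

logger = logging.getLogger(__name__)

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_VALID_BASES = frozenset("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class RawRead:
    """One FASTQ record."""

    id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence and qualities differ in length"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimConfig:
    """Adapter-trimming parameters (defaults match single-end eCLIP)."""

    adapter: str = DEFAULT_ADAPTER
    min_length: int = 18
    min_overlap: int = 5
    match_wildcards: bool = True
    max_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_overlap < 1 or self.min_length < 1:
            raise ValueError("min_overlap and min_length must be >= 1")
        if not 0.0 <= self.max_error_rate < 1.0:
            raise ValueError("max_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class UmiConfig:
    umi_length: int = 8
    id_separator: str = "_"

    def __post_init__(self) -> None:
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")


def _bases_match(read_base: str, adapter_base: str, wildcards: bool) -> bool:
    if wildcards and (read_base == "N" or adapter_base == "N"):
        return True
    return read_base == adapter_base


def _matches_at(seq: str, start: int, adapter: str, cfg: TrimConfig) -> bool:
    """Does the adapter occur at seq[start:], either fully (internal match)
    or as a >= min_overlap prefix reaching the read's 3' end?"""
    avail = len(seq) - start
    span = min(avail, len(adapter))
    if span < len(adapter) and span < cfg.min_overlap:
        return False
    mismatch_budget = int(cfg.max_error_rate * span)
    mismatches = 0
    for i in range(span):
        if not _bases_match(seq[start + i], adapter[i], cfg.match_wildcards):
            mismatches += 1
            if mismatches > mismatch_budget:
                return False
    return True


def trim_adapter(read: RawRead, cfg: TrimConfig = TrimConfig()) -> Optional[RawRead]:
    """Trim the 3' adapter; return the trimmed read, the read unchanged
    when no qualifying occurrence exists, or None when the trimmed read is
    shorter than ``cfg.min_length`` (discarded).
    """
    seq = read.sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"read {read.id}: non-IUPAC characters {sorted(bad)} in sequence"
        )
    adapter = cfg.adapter.upper()
    cut = None
    for start in range(len(seq)):
        if _matches_at(seq, start, adapter, cfg):
            cut = start
            break
    if cut is None:
        trimmed = read
    else:
        trimmed = RawRead(read.id, read.sequence[:cut], read.qualities[:cut])
    if len(trimmed) < cfg.min_length:
        return None
    return trimmed


def extract_umi(read: RawRead, cfg: UmiConfig = UmiConfig()) -> Optional[RawRead]:
    """Move the first ``umi_length`` bases into the read id; None when the
    read has no insert left (discarded)."""
    if len(read) < cfg.umi_length + 1:
        return None
    umi = read.sequence[: cfg.umi_length]
    return RawRead(
        id=f"{read.id}{cfg.id_separator}{umi}",
        sequence=read.sequence[cfg.umi_length:],
        qualities=read.qualities[cfg.umi_length:],
    )


def preprocess_reads(
    reads: Iterable[RawRead],
    trim_cfg: TrimConfig = TrimConfig(),
    umi_cfg: UmiConfig = UmiConfig(),
) -> tuple[list[RawRead], dict]:
    """Trim then UMI-extract a read stream; returns kept reads and stage counts."""
    stats = {"input": 0, "trim_discarded": 0, "umi_discarded": 0, "output": 0}
    kept: list[RawRead] = []
    for read in reads:
        stats["input"] += 1
        trimmed = trim_adapter(read, trim_cfg)
        if trimmed is None:
            stats["trim_discarded"] += 1
            continue
        extracted = extract_umi(trimmed, umi_cfg)
        if extracted is None:
            stats["umi_discarded"] += 1
            continue
        kept.append(extracted)
        stats["output"] += 1
    return kept, stats


# ---------------------------------------------------------------------------
# UMI deduplication


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("UMIs of unequal length")
    return sum(x != y for x, y in zip(a, b))


def _directional_clusters(counts: dict[str, int]) -> list[list[str]]:
    """umi_tools-style directional clustering of UMIs at one position.

    A directed edge runs from UMI a to UMI b when they differ at exactly
    one base and count(a) >= 2 * count(b) - 1; clusters are grown from
    high-count UMIs along such edges.
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    adjacency: dict[str, list[str]] = {u: [] for u in counts}
    umis = list(counts)
    for i, a in enumerate(umis):
        for b in umis[i + 1:]:
            if hamming(a, b) == 1:
                if counts[a] >= 2 * counts[b] - 1:
                    adjacency[a].append(b)
                if counts[b] >= 2 * counts[a] - 1:
                    adjacency[b].append(a)
    assigned: set[str] = set()
    clusters: list[list[str]] = []
    for root in order:
        if root in assigned:
            continue
        cluster = [root]
        assigned.add(root)
        frontier = [root]
        while frontier:
            node = frontier.pop()
            for nxt in adjacency[node]:
                if nxt not in assigned and counts[node] >= 2 * counts[nxt] - 1:
                    assigned.add(nxt)
                    cluster.append(nxt)
                    frontier.append(nxt)
        clusters.append(cluster)
    return clusters


def _five_prime_position(read: AlignedRead) -> int:
    """5' alignment coordinate on the read's strand (dedup grouping key)."""
    return read.start if read.strand == "+" else read.end


def dedup(reads: list[AlignedRead], method: str = "exact") -> list[AlignedRead]:
    """Collapse PCR duplicates among UMI-tagged alignments.

    Reads are grouped by (contig, 5' position, strand); within a group,
    ``exact`` keeps one representative per distinct UMI while
    ``directional`` additionally merges UMIs one substitution apart when
    the larger family's count is at least 2x(smaller) - 1 (sequencing-error
    tolerant collapsing). The representative is the first read in
    coordinate-sorted order, so output is deterministic.
    """
    if method not in ("exact", "directional"):
        raise ValueError(f"unknown dedup method {method!r}")
    ordered = sorted(
        range(len(reads)),
        key=lambda i: (reads[i].contig, reads[i].start, reads[i].strand, reads[i].read_id),
    )
    rank = {idx: pos for pos, idx in enumerate(ordered)}
    groups: dict[tuple, dict[str, list[int]]] = defaultdict(lambda: defaultdict(list))
    for idx in ordered:
        read = reads[idx]
        key = (read.contig, _five_prime_position(read), read.strand)
        groups[key][read.umi].append(idx)
    keep: list[int] = []
    for umi_map in groups.values():
        if method == "exact":
            clusters = [[u] for u in umi_map]
        else:
            counts = {u: len(ix) for u, ix in umi_map.items()}
            clusters = _directional_clusters(counts)
        for cluster in clusters:
            members = [i for u in cluster for i in umi_map[u]]
            keep.append(min(members, key=rank.__getitem__))
    keep_set = set(keep)
    return [reads[i] for i in ordered if i in keep_set]


def dedup_sam(
    in_path: str | Path,
    out_path: str | Path,
    method: str = "exact",
) -> dict:
    """File-level dedup: read a coordinate-sorted SAM/BAM, write the
    deduplicated records in coordinate order, return in/out counts."""
    import pysam

    in_path, out_path = str(in_path), str(out_path)
    mode_in = "rb" if in_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(in_path, mode_in) as fh:
        alignments = [a for a in fh if not a.is_unmapped]
        header = fh.header
    reads = [
        AlignedRead(
            read_id=a.query_name,
            contig=a.reference_name,
            start=a.reference_start,
            cigar=a.cigarstring,
            md=a.get_tag("MD") if a.has_tag("MD") else None,
            strand="-" if a.is_reverse else "+",
            mapq=a.mapping_quality,
        )
        for a in alignments
    ]
    kept = dedup(reads, method=method)
    kept_ids = {(r.read_id, r.contig, r.start) for r in kept}
    mode_out = "wb" if out_path.endswith(".bam") else "w"
    n_out = 0
    with pysam.AlignmentFile(out_path, mode_out, header=header) as out:
        for a in sorted(alignments, key=lambda a: (a.reference_id, a.reference_start)):
            if (a.query_name, a.reference_name, a.reference_start) in kept_ids:
                out.write(a)
                n_out += 1
    stats = {"input": len(alignments), "output": n_out}
    logger.info("dedup %s -> %s: %d in, %d out", in_path, out_path, *stats.values())
    return stats


# ---------------------------------------------------------------------------
# FASTQ I/O (plain text, 4-line records)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ near {header.strip()!r}")
            yield RawRead(id=header.strip()[1:].split()[0], sequence=seq, qualities=qual)


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{read.qualities}\n")
            n += 1
    return n
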