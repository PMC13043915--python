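"""Synthetic eCLIP library generator with ground truth.

Builds a random minigene-style reference (alternating exons and introns on
one contig, emulating a genomic splicing-reporter construct, plus a plain
host contig for off-target background) and simulates single-end eCLIP
molecules of three classes around a designated intronic binding window:

``site_truncation``
    reverse transcription stopped at a crosslink inside the window, so the
    molecule's 5' alignment terminus sits inside the (padded) window;
``site_span``
    the molecule reads through the window and carries at least one
    crosslink-induced substitution inside it;
``background``
    molecules whose termini avoid the window and which carry no
    substitutions, so they never satisfy a filter criterion.

Each molecule receives a random UMI and a Poisson number of extra PCR
copies; emitted FASTQ reads are UMI + insert + 3' adapter (truncated to the
configured read length), and emitted SAM records are the ground-truth
alignments (coordinate-sorted, with CIGAR, MD and NM computed from truth),
so the downstream pipeline can be exercised without an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .preprocess import DEFAULT_ADAPTER
from .sitefilter import WindowSpec

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CLASS_BACKGROUND = "background"
CLASS_TRUNCATION = "site_truncation"
CLASS_SPAN = "site_span"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One annotated interval, 1-based inclusive."""

    contig: str
    start: int
    end: int
    kind: str  # exon | intron


@dataclass(frozen=True)
class ReferenceLayout:
    """Feature lengths for the minigene contig plus a host contig.

    ``features`` lists (kind, length) pairs laid head-to-tail on the
    minigene contig; the binding window of ``window_length`` nt starts
    ``window_offset`` bases into feature ``window_feature`` (which must be
    an intron). The default emulates an amelogenin-style genomic minigene:
    exons 2-7 with intervening introns, ~5.7 kb total, an 18-nt window
    inside the fourth intron, and a 10-kb featureless host contig.
    """

    minigene_contig: str = "minigene"
    host_contig: str = "host1"
    host_length: int = 10_000
    features: tuple[tuple[str, int], ...] = (
        ("exon", 54),
        ("intron", 1000),
        ("exon", 48),
        ("intron", 800),
        ("exon", 45),
        ("intron", 600),
        ("exon", 150),
        ("intron", 900),
        ("exon", 1600),
        ("intron", 400),
        ("exon", 150),
    )
    window_feature: int = 5  # 0-based index into features; the 4th intron
    window_offset: int = 200
    window_length: int = 18
    window_pad: int = 2

    def __post_init__(self) -> None:
        if any(length <= 0 for _, length in self.features):
            raise ValueError("all feature lengths must be positive")
        if self.host_length <= 0:
            raise ValueError("host_length must be positive")


@dataclass(frozen=True)
class GenomeRef:
    """Synthetic reference: sequences, annotation, binding window."""

    contigs: dict[str, str]
    features: tuple[Feature, ...]
    binding_window: WindowSpec

    def __post_init__(self) -> None:
        for feat in self.features:
            if feat.contig not in self.contigs:
                raise ValueError(f"feature on unknown contig {feat.contig}")
            if not 1 <= feat.start <= feat.end <= len(self.contigs[feat.contig]):
                raise ValueError(f"feature {feat} outside contig bounds")
        per_contig: dict[str, list[Feature]] = {}
        for feat in self.features:
            per_contig.setdefault(feat.contig, []).append(feat)
        for feats in per_contig.values():
            feats.sort(key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping features {a} and {b}")
        win = self.binding_window
        if not any(
            f.kind == "intron"
            and f.contig == win.contig
            and f.start <= win.start
            and win.end <= f.end
            for f in self.features
        ):
            raise ValueError("binding window must lie inside an annotated intron")

    def fasta(self) -> str:
        lines = []
        for name, seq in self.contigs.items():
            lines.append(f">{name}")
            for i in range(0, len(seq), 70):
                lines.append(seq[i:i + 70])
        return "\n".join(lines) + "\n"

    def write_fasta(self, path: str | Path) -> None:
        Path(path).write_text(self.fasta())


@dataclass(frozen=True)
class SimConfig:
    """Library-simulation parameters.

    ``occupancy`` thins the configured site-molecule counts per molecule
    (Bernoulli), so a mutant condition is simulated simply by scaling it
    down; ``pcr_duplication_rate`` is the Poisson mean number of extra
    exact PCR copies per molecule; ``substitution_rate_at_crosslink`` is
    the per-position probability of crosslink-induced substitutions beyond
    the one guaranteed substitution of every spanning molecule.
    """

    seed: int = 0
    n_background: int = 1000
    n_site_truncation: int = 400
    n_site_span: int = 200
    occupancy: float = 1.0
    read_length: int = 100
    umi_length: int = 8
    adapter: str = DEFAULT_ADAPTER
    pcr_duplication_rate: float = 0.0
    substitution_rate_at_crosslink: float = 0.1
    min_insert: int = 24

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_site_truncation, self.n_site_span) < 0:
            raise ValueError("molecule counts must be >= 0")
        for name in ("occupancy", "substitution_rate_at_crosslink"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pcr_duplication_rate < 0:
            raise ValueError("pcr_duplication_rate must be >= 0")
        if self.read_length <= self.umi_length:
            raise ValueError("read_length must exceed umi_length")

    @property
    def max_insert(self) -> int:
        return self.read_length - self.umi_length


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated molecule."""

    molecule_id: str
    klass: str
    contig: str
    start: int  # 1-based inclusive alignment start
    end: int  # 1-based inclusive alignment end
    strand: str
    umi: str
    copies: int
    mismatch_positions: tuple[int, ...]  # 1-based reference coordinates

    @property
    def insert_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimulatedLibrary:
    """One simulated library: FASTQ records, SAM lines, truth table."""

    fastq: list  # of preprocess.RawRead
    sam_header: list[str]
    sam_lines: list[str]
    truth: list[TruthRecord]

    def write(self, out_dir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        from .preprocess import write_fastq

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": out_dir / f"{prefix}.fastq",
            "sam": out_dir / f"{prefix}.sam",
            "truth": out_dir / f"{prefix}.truth.tsv",
        }
        write_fastq(self.fastq, paths["fastq"])
        with open(paths["sam"], "w") as fh:
            for line in self.sam_header + self.sam_lines:
                fh.write(line + "\n")
        write_truth_tsv(self.truth, paths["truth"])
        return paths


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    cols = (
        "molecule_id\tclass\tcontig\tstart\tend\tstrand\tumi\tcopies\t"
        "mismatch_positions"
    )
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        for rec in truth:
            mm = ",".join(map(str, rec.mismatch_positions))
            fh.write(
                f"{rec.molecule_id}\t{rec.klass}\t{rec.contig}\t{rec.start}\t"
                f"{rec.end}\t{rec.strand}\t{rec.umi}\t{rec.copies}\t{mm}\n"
            )


def build_reference(seed: int, layout: ReferenceLayout = ReferenceLayout()) -> GenomeRef:
    """Generate a deterministic random reference for a given seed.

    Sequence composition is uniform over A/C/G/T; coordinates are fixed by
    the layout alone, so different seeds share identical annotation.
    """
    rng = np.random.default_rng(seed)
    minigene_len = sum(length for _, length in layout.features)
    contigs = {
        layout.minigene_contig: "".join(
            rng.choice(_BASES, size=minigene_len)
        ),
        layout.host_contig: "".join(rng.choice(_BASES, size=layout.host_length)),
    }
    features = []
    pos = 1
    for kind, length in layout.features:
        features.append(
            Feature(layout.minigene_contig, pos, pos + length - 1, kind)
        )
        pos += length
    if not 0 <= layout.window_feature < len(features):
        raise ValueError("window_feature index out of range")
    host_feat = features[layout.window_feature]
    if host_feat.kind != "intron":
        raise ValueError("binding window must be placed inside an intron feature")
    win_start = host_feat.start + layout.window_offset
    win_end = win_start + layout.window_length - 1
    if win_end > host_feat.end:
        raise ValueError("binding window extends past its intron")
    window = WindowSpec(
        contig=layout.minigene_contig,
        start=win_start,
        end=win_end,
        pad=layout.window_pad,
    )
    return GenomeRef(contigs=contigs, features=tuple(features), binding_window=window)


def _random_umi(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _substitute(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def _md_and_seq(
    ref_insert: str, mismatch_offsets: list[int], rng: np.random.Generator
) -> tuple[str, str]:
    """Apply substitutions at the given 0-based offsets; return (seq, MD)."""
    seq = list(ref_insert)
    for off in mismatch_offsets:
        seq[off] = _substitute(ref_insert[off], rng)
    md_parts: list[str] = []
    run = 0
    for i, (r, s) in enumerate(zip(ref_insert, seq)):
        if r == s:
            run += 1
        else:
            md_parts.append(str(run))
            md_parts.append(r)
            run = 0
    md_parts.append(str(run))
    return "".join(seq), "".join(md_parts)


def simulate_reads(
    ref: GenomeRef, cfg: SimConfig
) -> SimulatedLibrary:
    """Simulate one library; deterministic for a given (ref, cfg)."""
    from .preprocess import RawRead

    rng = np.random.default_rng(cfg.seed)
    win = ref.binding_window
    win_lo, win_hi = win.padded()
    contig_seq = ref.contigs[win.contig]
    contig_len = len(contig_seq)
    if win_lo - cfg.max_insert < 0 or win_hi + cfg.max_insert > contig_len:
        raise ValueError(
            "binding window too close to a contig edge for the requested "
            "read length"
        )
    padded_len = win_hi - win_lo + 1
    if cfg.min_insert > cfg.max_insert:
        raise ValueError("min_insert exceeds read_length - umi_length")

    contig_names = list(ref.contigs)
    contig_lengths = np.array([len(ref.contigs[c]) for c in contig_names], float)
    contig_probs = contig_lengths / contig_lengths.sum()

    truth: list[TruthRecord] = []
    mol_counter = 0

    def new_molecule(
        klass: str,
        contig: str,
        start1: int,
        insert_len: int,
        strand: str,
        mismatch_offsets: list[int],
    ) -> TruthRecord:
        nonlocal mol_counter
        mol_id = f"mol{mol_counter:06d}"
        mol_counter += 1
        copies = 1 + int(rng.poisson(cfg.pcr_duplication_rate))
        rec = TruthRecord(
            molecule_id=mol_id,
            klass=klass,
            contig=contig,
            start=start1,
            end=start1 + insert_len - 1,
            strand=strand,
            umi=_random_umi(rng, cfg.umi_length),
            copies=copies,
            mismatch_positions=tuple(start1 + off for off in mismatch_offsets),
        )
        truth.append(rec)
        return rec

    # --- background molecules: termini outside the padded window, no subs
    for _ in range(cfg.n_background):
        while True:
            contig = contig_names[rng.choice(len(contig_names), p=contig_probs)]
            clen = len(ref.contigs[contig])
            insert_len = int(rng.integers(cfg.min_insert, cfg.max_insert + 1))
            if insert_len > clen:
                continue
            start1 = int(rng.integers(1, clen - insert_len + 2))
            end1 = start1 + insert_len - 1
            if contig == win.contig and (
                win_lo <= start1 <= win_hi or win_lo <= end1 <= win_hi
            ):
                continue
            break
        strand = "+" if rng.random() < 0.5 else "-"
        new_molecule(CLASS_BACKGROUND, contig, start1, insert_len, strand, [])

    # --- truncation molecules: 5' terminus at a crosslink inside the window
    for _ in range(cfg.n_site_truncation):
        if rng.random() >= cfg.occupancy:
            continue
        crosslink = int(rng.integers(win_lo, win_hi + 1))
        insert_len = int(rng.integers(cfg.min_insert, cfg.max_insert + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start1 = crosslink
        else:
            start1 = crosslink - insert_len + 1
        offsets: list[int] = []
        if rng.random() < cfg.substitution_rate_at_crosslink:
            offsets.append(crosslink - start1)
        new_molecule(CLASS_TRUNCATION, win.contig, start1, insert_len, strand, offsets)

    # --- spanning molecules: strict containment of the window, >=1 window sub
    span_min_insert = max(cfg.min_insert, padded_len + 2)
    if span_min_insert > cfg.max_insert and cfg.n_site_span > 0:
        raise ValueError(
            "read_length too short for spanning molecules to contain the window"
        )
    for _ in range(cfg.n_site_span):
        if rng.random() >= cfg.occupancy:
            continue
        insert_len = int(rng.integers(span_min_insert, cfg.max_insert + 1))
        start1 = int(rng.integers(win_hi + 2 - insert_len, win_lo))
        strand = "+" if rng.random() < 0.5 else "-"
        guaranteed = int(rng.integers(win_lo, win_hi + 1)) - start1
        offsets = {guaranteed}
        for pos in range(win_lo, win_hi + 1):
            off = pos - start1
            if off != guaranteed and rng.random() < cfg.substitution_rate_at_crosslink:
                offsets.add(off)
        new_molecule(
            CLASS_SPAN, win.contig, start1, insert_len, strand, sorted(offsets)
        )

    # --- emit reads
    fastq: list[RawRead] = []
    sam_records: list[tuple[str, int, str]] = []  # (contig, pos0, line)
    for rec in truth:
        seq_ref = ref.contigs[rec.contig][rec.start - 1:rec.end]
        offsets = [p - rec.start for p in rec.mismatch_positions]
        aligned_seq, md = _md_and_seq(seq_ref, offsets, rng)
        biological = aligned_seq if rec.strand == "+" else revcomp(aligned_seq)
        fq_seq = (rec.umi + biological + cfg.adapter)[: cfg.read_length]
        flag = 0 if rec.strand == "+" else 16
        nm = len(rec.mismatch_positions)
        for copy in range(rec.copies):
            base_id = f"{rec.molecule_id}.{copy}"
            fastq.append(
                RawRead(id=base_id, sequence=fq_seq, qualities="I" * len(fq_seq))
            )
            qname = f"{base_id}_{rec.umi}"
            line = "\t".join(
                [
                    qname,
                    str(flag),
                    rec.contig,
                    str(rec.start),
                    "255",
                    f"{rec.insert_length}M",
                    "*",
                    "0",
                    "0",
                    aligned_seq,
                    "I" * rec.insert_length,
                    f"NM:i:{nm}",
                    f"MD:Z:{md}",
                ]
            )
            sam_records.append((rec.contig, rec.start - 1, line))

    order = {name: i for i, name in enumerate(contig_names)}
    sam_records.sort(key=lambda t: (order[t[0]], t[1], t[2]))
    header = ["@HD\tVN:1.6\tSO:coordinate"] + [
        f"@SQ\tSN:{name}\tLN:{len(seq)}" for name, seq in ref.contigs.items()
    ]
    return SimulatedLibrary(
        fastq=fastq,
        sam_header=header,
        sam_lines=[line for _, _, line in sam_records],
        truth=truth,
    )


def simulate_condition_pair(
    ref: GenomeRef,
    base_cfg: SimConfig,
    *,
    wt_occupancy: float,
    mutant_occupancy: float,
    mutant_seed_offset: int = 10_000,
) -> tuple[SimulatedLibrary, SimulatedLibrary]:
    """Simulate matched WT and mutant libraries differing only in site
    occupancy (and RNG stream)."""
    wt_cfg = replace(base_cfg, occupancy=wt_occupancy)
    mut_cfg = replace(
        base_cfg,
        occupancy=mutant_occupancy,
        seed=base_cfg.seed + mutant_seed_offset,
    )
    return simulate_reads(ref, wt_cfg), simulate_reads(ref, mut_cfg)
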