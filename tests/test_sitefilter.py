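"""MD parsing, window classification and the region filter."""

import subprocess

import pytest
from hypothesis import given, settings, strategies as st

from conftest import library_reads

from eclipquant.simulate import SimConfig, simulate_reads
from eclipquant.sitefilter import (
    AlignedRead,
    MdParseError,
    WindowSpec,
    classify_read,
    filter_reads,
    filter_region,
    parse_md,
    window_from_bed_line,
)


class TestParseMd:
    def test_perfect_match_has_no_events(self):
        assert parse_md("20").substitutions == ()

    def test_single_substitution(self):
        events = parse_md("10A9")
        assert [(s.offset, s.ref_base) for s in events.substitutions] == [(10, "A")]

    def test_adjacent_substitutions(self):
        events = parse_md("3C0T14")
        assert [(s.offset, s.ref_base) for s in events.substitutions] == [
            (3, "C"),
            (4, "T"),
        ]

    def test_deletions_reported_separately(self):
        events = parse_md("5^ACG10T2")
        assert [(d.offset, d.ref_bases) for d in events.deletions] == [(5, "ACG")]
        # the substitution offset counts the 3 deleted reference bases
        assert [(s.offset, s.ref_base) for s in events.substitutions] == [(18, "T")]

    def test_malformed_md_names_the_token(self):
        with pytest.raises(MdParseError, match="\\$"):
            parse_md("10$5")

    def test_substitution_count_matches_base_comparison(self, ref, small_library):
        """MD substitution count equals direct read-vs-reference comparison."""
        for read in library_reads(small_library):
            seq = next(
                line.split("\t")[9]
                for line in small_library.sam_lines
                if line.startswith(read.read_id + "\t")
            )
            ref_seq = ref.contigs[read.contig][read.start:read.start + len(seq)]
            direct = sum(a != b for a, b in zip(seq, ref_seq))
            assert len(parse_md(read.md).substitutions) == direct


def _read_at(start1: int, length: int, md: str = None, contig: str = "minigene"):
    md = md if md is not None else str(length)
    return AlignedRead(
        read_id=f"r{start1}_AAAAAAAA", contig=contig, start=start1 - 1,
        cigar=f"{length}M", md=md, strand="+",
    )


WINDOW = WindowSpec(contig="minigene", start=102, end=119, pad=2)  # padded 101-120


class TestClassifyRead:
    def test_end_inside_window(self):
        assert classify_read(_read_at(95, 16), WINDOW) == "end_in"  # spans 95-110

    def test_start_inside_window(self):
        assert classify_read(_read_at(110, 40), WINDOW) == "start_in"

    def test_span_without_mismatch_rejected(self):
        assert classify_read(_read_at(90, 41, md="41"), WINDOW) is None

    def test_span_with_mismatch_retained(self):
        assert classify_read(_read_at(90, 41, md="20A20"), WINDOW) == "span_mismatch"

    def test_other_contig_is_none(self):
        read = _read_at(110, 30, contig="chr1")
        assert classify_read(read, WINDOW) is None

    def test_precedence_start_in_wins(self):
        # read starting and ending inside the window is start_in
        assert classify_read(_read_at(105, 10), WINDOW) == "start_in"

    def test_mismatch_in_window_option(self):
        outside = _read_at(90, 41, md="5A35")  # substitution at ref pos 95
        assert classify_read(outside, WINDOW) == "span_mismatch"
        assert classify_read(outside, WINDOW, mismatch_in_window=True) is None

    def test_deletion_counts_only_when_enabled(self):
        read = _read_at(90, 41, md="20^A21")
        assert classify_read(read, WINDOW) is None
        assert classify_read(read, WINDOW, count_deletions=True) == "span_mismatch"

    def test_agrees_with_brute_force_over_exhaustive_grid(self):
        """Independent re-evaluation of the three predicates on every
        placement of reads around the window, with and without a
        mismatch."""
        lo, hi = WINDOW.padded()
        n_cases = 0
        for start1 in range(60, 161):
            for length in (5, 15, 25, 45, 70):
                for with_mismatch in (False, True):
                    md = f"2A{length - 3}" if with_mismatch else str(length)
                    read = _read_at(start1, length, md=md)
                    end1 = start1 + length - 1
                    if lo <= start1 <= hi:
                        expected = "start_in"
                    elif lo <= end1 <= hi:
                        expected = "end_in"
                    elif start1 < lo and end1 > hi and with_mismatch:
                        expected = "span_mismatch"
                    else:
                        expected = None
                    assert classify_read(read, WINDOW) == expected
                    n_cases += 1
        assert n_cases <= 10_000

    @given(pad=st.integers(0, 12))
    @settings(max_examples=13, deadline=None, derandomize=True)
    def test_pad_monotonicity(self, pad):
        """Enlarging the pad never loses reads."""
        reads = [_read_at(s, l, md=f"1A{l - 2}")
                 for s in range(80, 140, 3) for l in (10, 30, 50)]
        narrow = WindowSpec("minigene", 102, 119, pad=pad)
        wide = WindowSpec("minigene", 102, 119, pad=pad + 2)
        kept_narrow = {r.read_id for r in filter_reads(reads, narrow)}
        kept_wide = {r.read_id for r in filter_reads(reads, wide)}
        assert kept_narrow <= kept_wide

    def test_asymmetric_pad_override(self):
        window = WindowSpec("minigene", 102, 119, pad=2, pad_left=2, pad_right=0)
        assert window.padded() == (100, 119)


class TestWindowSpec:
    def test_default_pad_split_floor_left_ceil_right(self):
        assert WindowSpec("c", 100, 117, pad=2).padded() == (99, 118)
        assert WindowSpec("c", 100, 117, pad=3).padded() == (99, 119)

    def test_published_interval_is_18_nt(self):
        from eclipquant.constants import AMELX_INTRON4_WINDOW

        assert AMELX_INTRON4_WINDOW.length == 18
        lo, hi = AMELX_INTRON4_WINDOW.padded()
        assert hi - lo + 1 == 20

    def test_bed_line_conversion(self):
        window = window_from_bed_line("chrX\t167965538\t167965556\n")
        assert (window.start, window.end) == (167_965_539, 167_965_556)


class TestFilterRegion:
    def _write_sam(self, library, tmp_path, name="lib.sam"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for line in library.sam_header + library.sam_lines:
                fh.write(line + "\n")
        return path

    def test_no_site_molecules_yields_no_records(self, ref, tmp_path):
        cfg = SimConfig(seed=2, n_background=80, n_site_truncation=0, n_site_span=0)
        library = simulate_reads(ref, cfg)
        sam = self._write_sam(library, tmp_path)
        records, summary = filter_region(sam, ref.binding_window)
        assert records == [] and summary.n_retained == 0

    def test_record_count_matches_truth(self, ref, tmp_path):
        cfg = SimConfig(seed=3, n_background=100, n_site_truncation=50,
                        n_site_span=25, pcr_duplication_rate=0.0)
        library = simulate_reads(ref, cfg)
        sam = self._write_sam(library, tmp_path)
        n_site = sum(1 for t in library.truth if t.klass != "background")
        records, _ = filter_region(sam, ref.binding_window)
        assert len(records) == n_site

    def test_truncation_only_run_classifies_termini(self, ref, tmp_path):
        cfg = SimConfig(seed=4, n_background=0, n_site_truncation=50,
                        n_site_span=0, pcr_duplication_rate=0.0)
        library = simulate_reads(ref, cfg)
        sam = self._write_sam(library, tmp_path)
        records, _ = filter_region(sam, ref.binding_window)
        assert len(records) == 50
        assert {r.category for r in records} <= {"start_in", "end_in"}

    def test_reads_on_other_contig_ignored(self, tmp_path):
        window = WindowSpec("minigene", 102, 119)
        sam = tmp_path / "other.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr9\tLN:1000\n"
            "r1_AAAAAAAA\t0\tchr9\t105\t255\t30M\t*\t0\t0\t"
            + "A" * 30 + "\t" + "I" * 30 + "\tMD:Z:30\n"
        )
        records, _ = filter_region(sam, window)
        assert records == []

    def test_missing_md_skipped_and_counted(self, tmp_path):
        window = WindowSpec("c1", 102, 119)
        sam = tmp_path / "nomd.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:c1\tLN:1000\n"
            "r1_AAAAAAAA\t0\tc1\t105\t255\t30M\t*\t0\t0\t"
            + "A" * 30 + "\t" + "I" * 30 + "\n"
        )
        records, summary = filter_region(sam, window)
        assert records == [] and summary.n_missing_md == 1

    def test_unsorted_input_rejected(self, tmp_path):
        sam = tmp_path / "unsorted.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:1000\n"
        )
        with pytest.raises(ValueError, match="sort"):
            filter_region(sam, WindowSpec("c1", 102, 119))

    def test_retained_set_invariant_to_input_order(self, ref, small_library, tmp_path):
        window = ref.binding_window
        reads = library_reads(small_library)
        forward = {r.read_id for r in filter_reads(reads, window)}
        backward = {r.read_id for r in filter_reads(reads[::-1], window)}
        assert forward == backward

    def test_md_tags_agree_with_samtools_calmd(self, ref, small_library, tmp_path):
        """samtools calmd recomputes identical MD/NM tags from the FASTA."""
        sam = self._write_sam(small_library, tmp_path)
        fasta = tmp_path / "ref.fa"
        ref.write_fasta(fasta)
        out = subprocess.run(
            ["samtools", "calmd", str(sam), str(fasta)],
            capture_output=True, text=True, check=True,
        )
        recomputed = {}
        for line in out.stdout.splitlines():
            if line.startswith("@"):
                continue
            fields = line.split("\t")
            tags = {t.split(":")[0]: t.split(":", 2)[2] for t in fields[11:]}
            recomputed[fields[0]] = tags["MD"]
        for line in small_library.sam_lines:
            fields = line.split("\t")
            ours = next(t[5:] for t in fields[11:] if t.startswith("MD:Z:"))
            assert recomputed[fields[0]] == ours
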