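"""Published coordinates and sequences for the amelogenin (Amelx) system.

These are the real-genome values the toolkit's defaults mirror: the
predicted 18-nt miR-exon4 binding region at the Amelx intron4 branch
point (mouse X chromosome, GRCm39), filtered with 2 nt of padding, and
the mature miR-exon4 sequence used as a synthetic mimic.
"""

from .sitefilter import WindowSpec

#: Predicted miR-exon4 binding region within Amelx intron4 (1-based
#: inclusive, GRCm39 chrX), padded by 2 nt when filtering.
AMELX_INTRON4_WINDOW = WindowSpec(contig="chrX", start=167_965_539, end=167_965_556, pad=2)

#: Mature miR-exon4 sequence (the synthetic mimic oligonucleotide).
MIR_EXON4_MATURE = "ACUGACAGGACUGCAUUA"

#: Relative minigene transfection rate, mutant/WT, measured from matched
#: input libraries (the WT/mutant ratio is 1/0.796).
DEFAULT_TRANSFECTION_RATE = 0.796
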