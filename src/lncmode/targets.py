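"""Build the per-promoter target sequences for the two interaction modes.

Co-transcriptional mode: the lncRNA is assumed to hybridise with the 5' end
of the nascent transcript, so the target is the first ``window_len`` bases
downstream of the TSS on the sense strand — introns included by
construction, since the nascent RNA is unspliced.

Post-transcriptional mode: the lncRNA meets the mature RNA, so the target
is the spliced sequence of the longest mature isoform expressed from the
promoter.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel, GenomeAssembly, PeakSet, revcomp

__all__ = [
    "TargetSequence",
    "build_cotx_target",
    "build_posttx_target",
    "build_target_sets",
    "promoter_intervals",
]


@dataclass
class TargetSequence:
    promoter_id: str
    mode: str  # "co" | "post"
    sequence: str  # sense strand of the transcript
    source_intervals: list[tuple[str, int, int]]  # genomic provenance

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_cotx_target(
    gene: GeneModel,
    promoter_id: str,
    genome: GenomeAssembly,
    window_len: int = 1000,
) -> TargetSequence:
    """The first ``window_len`` bp of the nascent transcript (strand-aware).

    One contiguous genomic window anchored at the TSS and extending in the
    direction of transcription, truncated at the chromosome edge and at the
    3'-most end of the promoter's transcripts (a nascent transcript of a
    short gene is itself short), returned in transcribed sense
    (reverse-complemented for minus-strand genes).
    """
    tss = gene.tss_of(promoter_id)
    chrom_len = genome.chrom_sizes[gene.chrom]
    transcripts = gene.transcripts_of(promoter_id)
    if gene.strand == "+":
        tx_end = max(t.span[1] for t in transcripts)
        start, end = tss, min(tss + window_len, chrom_len, tx_end)
        seq = genome.fetch(gene.chrom, start, end)
    else:
        tx_end = min(t.span[0] for t in transcripts)
        start, end = max(0, tss + 1 - window_len, tx_end), tss + 1
        seq = revcomp(genome.fetch(gene.chrom, start, end))
    return TargetSequence(promoter_id, "co", seq, [(gene.chrom, start, end)])


def build_posttx_target(
    gene: GeneModel, promoter_id: str, genome: GenomeAssembly
) -> TargetSequence:
    """The spliced sequence of the promoter's longest mature isoform.

    Longest means maximal mature (spliced) length, not genomic span; ties
    break to the lexicographically smallest transcript_id.
    """
    transcripts = gene.transcripts_of(promoter_id)
    if not transcripts:
        raise KeyError(f"promoter {promoter_id!r} has no transcripts")
    chosen = min(transcripts, key=lambda t: (-t.mature_length, t.transcript_id))
    pieces = [genome.fetch(gene.chrom, s, e) for s, e in chosen.exons]
    seq = "".join(pieces)
    if gene.strand == "-":
        seq = revcomp(seq)
    return TargetSequence(
        promoter_id, "post", seq, [(gene.chrom, s, e) for s, e in chosen.exons]
    )


def build_target_sets(
    genes: list[GeneModel], genome: GenomeAssembly, window_len: int = 1000
) -> tuple[dict[str, str], dict[str, str]]:
    """(co, post) promoter_id -> sequence mappings over all promoters."""
    co: dict[str, str] = {}
    post: dict[str, str] = {}
    for gene in genes:
        for pid, _ in gene.promoters:
            co[pid] = build_cotx_target(gene, pid, genome, window_len).sequence
            post[pid] = build_posttx_target(gene, pid, genome).sequence
    return co, post


def promoter_intervals(
    genes: list[GeneModel],
    flank: int,
    chrom_sizes: dict[str, int] | None = None,
    promoter_ids: set[str] | None = None,
) -> PeakSet:
    """One [TSS-flank, TSS+flank) interval per promoter, clipped to bounds."""
    if flank <= 0:
        raise ValueError("flank must be positive (intervals must be non-empty)")
    intervals = []
    for gene in genes:
        for pid, tss in gene.promoters:
            if promoter_ids is not None and pid not in promoter_ids:
                continue
            start = max(0, tss - flank)
            end = tss + flank
            if chrom_sizes is not None:
                end = min(end, chrom_sizes[gene.chrom])
            intervals.append((gene.chrom, start, end))
    return PeakSet(intervals)
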