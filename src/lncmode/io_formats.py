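"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open on the
forward genomic strand. GTF is the only 1-based closed dialect and is
converted at the boundary, in both directions. RNA alphabets (U) are
normalised to DNA (T) on read; all pairing logic downstream is defined on
A, C, G, T.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeAssembly",
    "GeneModel",
    "Promoter",
    "Transcript",
    "KnockdownTable",
    "PeakSet",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_knockdown_tsv",
    "write_knockdown_tsv",
    "write_hits_tsv",
    "write_results_tsv",
]

_VALID = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement on the DNA alphabet (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeAssembly:
    """A set of named chromosome sequences (uppercase DNA)."""

    sequences: dict[str, str]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start},{end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end]


@dataclass
class Transcript:
    transcript_id: str
    promoter_id: str
    exons: list[tuple[int, int]]  # sorted, non-overlapping, 0-based half-open

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    """A gene: promoters (strand-aware TSS positions) and their transcripts.

    Promoter identity is a shared exact TSS coordinate: transcripts whose
    strand-aware 5' ends coincide belong to one promoter (the CAGE view of
    a gene, where expression is measured per promoter).
    """

    gene_id: str
    chrom: str
    strand: str
    promoters: list[tuple[str, int]] = field(default_factory=list)
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")

    def tss_of(self, promoter_id: str) -> int:
        for pid, tss in self.promoters:
            if pid == promoter_id:
                return tss
        raise KeyError(f"unknown promoter {promoter_id!r} in gene {self.gene_id}")

    def transcripts_of(self, promoter_id: str) -> list[Transcript]:
        self.tss_of(promoter_id)  # raises if unknown
        return [t for t in self.transcripts if t.promoter_id == promoter_id]

    def validate(self) -> None:
        for t in self.transcripts:
            for (s0, e0), (s1, e1) in zip(t.exons, t.exons[1:]):
                if not (s0 < e0 <= s1 < e1):
                    raise ValueError(
                        f"exons of {t.transcript_id} not sorted/disjoint"
                    )
            tss = t.exons[-1][1] - 1 if self.strand == "-" else t.exons[0][0]
            if tss != self.tss_of(t.promoter_id):
                raise ValueError(
                    f"5' end of {t.transcript_id} does not match its promoter TSS"
                )
        for pid, _ in self.promoters:
            if not any(t.promoter_id == pid for t in self.transcripts):
                raise ValueError(f"promoter {pid} has no transcript")


@dataclass
class KnockdownTable:
    """One ASO knockdown: per-promoter log2 fold-change and DEG flag.

    The full row set is the tested background universe; DEG rows are the
    subset with deg_flag set.
    """

    aso_id: str
    lncrna_id: str
    rows: dict[str, tuple[float, bool]]

    @property
    def background(self) -> set[str]:
        return set(self.rows)

    @property
    def deg_set(self) -> set[str]:
        return {p for p, (_, flag) in self.rows.items() if flag}


@dataclass
class PeakSet:
    """Genomic intervals (0-based half-open), e.g. RNA-chromatin contact peaks."""

    intervals: list[tuple[str, int, int]]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered id -> uppercase DNA mapping.

    U is mapped to T; any residue outside A,C,G,T,N is rejected.
    Duplicate record ids are rejected.
    """
    records: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if rec.id in records:
            raise FormatError(f"duplicate FASTA header {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        records[rec.id] = seq
    if n == 0:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def read_genome_fasta(path) -> GenomeAssembly:
    return GenomeAssembly(read_fasta(path))


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF


def _gtf_attrs(raw: str) -> dict[str, str]:
    attrs = {}
    for part in raw.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> list[GeneModel]:
    """Parse exon features of a GTF into GeneModels.

    1-based closed GTF coordinates become 0-based half-open. Promoters are
    derived from transcript 5' ends (strand aware: the max end coordinate on
    the minus strand); transcripts sharing a TSS share a promoter.
    """
    # transcript_id -> (gene_id, chrom, strand, [(start,end)])
    tx: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr_raw = fields[:9]
            if feature != "exon":
                continue
            attrs = _gtf_attrs(attr_raw)
            try:
                gene_id = attrs.get("gene_id") or attrs["ID"]
                tx_id = attrs.get("transcript_id") or attrs["Parent"]
            except KeyError as exc:
                raise FormatError(
                    f"{path}:{lineno}: exon lacks gene_id/transcript_id"
                ) from exc
            iv = (int(start) - 1, int(end))  # GTF 1-based closed -> half-open
            if tx_id not in tx:
                tx[tx_id] = [gene_id, chrom, strand, []]
                order.append(tx_id)
            rec = tx[tx_id]
            if rec[2] != strand or rec[1] != chrom:
                raise FormatError(
                    f"{path}: transcript {tx_id} mixes strands or chromosomes"
                )
            rec[3].append(iv)
    if not tx:
        raise FormatError(f"no exon features found in {path}")

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tx_id in order:
        gene_id, chrom, strand, exons = tx[tx_id]
        if not exons:
            raise FormatError(f"transcript {tx_id} has no exons")
        exons.sort()
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, chrom, strand)
            gene_order.append(gene_id)
        gene = genes[gene_id]
        if gene.strand != strand or gene.chrom != chrom:
            raise FormatError(f"gene {gene_id} mixes strands or chromosomes")
        tss = exons[-1][1] - 1 if strand == "-" else exons[0][0]
        pid = None
        for existing_pid, existing_tss in gene.promoters:
            if existing_tss == tss:
                pid = existing_pid
                break
        if pid is None:
            pid = f"{gene_id}@p{len(gene.promoters) + 1}"
            gene.promoters.append((pid, tss))
        gene.transcripts.append(Transcript(tx_id, pid, exons))

    out = [genes[g] for g in gene_order]
    for g in out:
        g.validate()
    return out


def write_gtf(genes: list[GeneModel], path, source: str = "lncmode") -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                for s, e in t.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                source,
                                "exon",
                                str(s + 1),  # back to 1-based closed
                                str(e),
                                ".",
                                gene.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> PeakSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    bad = df[df.start >= df.end]
    if len(bad):
        row = bad.iloc[0]
        raise FormatError(
            f"{path}: BED interval with start >= end: {row.chrom}:{row.start}-{row.end}"
        )
    return PeakSet(list(df.itertuples(index=False, name=None)))


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(peaks.intervals):
            line = f"{chrom}\t{start}\t{end}"
            if peaks.scores is not None:
                line += f"\tpeak_{i}\t{peaks.scores[i]:g}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_knockdown_tsv(path, aso_id: str | None = None, lncrna_id: str | None = None) -> KnockdownTable:
    df = pd.read_csv(path, sep="\t", dtype={"promoter_id": str})
    for col in ("promoter_id", "log2fc", "deg_flag"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    rows: dict[str, tuple[float, bool]] = {}
    for idx, rec in df.iterrows():
        try:
            fc = float(rec["log2fc"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {idx}: unparseable log2fc") from exc
        flag_raw = str(rec["deg_flag"]).strip().lower()
        if flag_raw not in {"0", "1", "true", "false"}:
            raise FormatError(
                f"{path}: row {idx}: deg_flag must be one of 0/1/true/false"
            )
        rows[str(rec["promoter_id"])] = (fc, flag_raw in {"1", "true"})
    from pathlib import Path

    aso = aso_id or Path(path).stem
    lnc = lncrna_id or "query"
    return KnockdownTable(aso, lnc, rows)


def write_knockdown_tsv(kd: KnockdownTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("promoter_id\tlog2fc\tdeg_flag\n")
        for pid in sorted(kd.rows):
            fc, flag = kd.rows[pid]
            fh.write(f"{pid}\t{fc:.6g}\t{int(flag)}\n")


def write_hits_tsv(hits, path) -> None:
    """Write duplex hits, one row per query-target pair, sorted for determinism."""
    cols = [
        "query_id",
        "target_id",
        "q_start",
        "q_end",
        "t_start",
        "t_end",
        "energy",
        "score",
        "p_raw",
        "p_adj",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in sorted(hits, key=lambda h: (h.p_adj, h.target_id)):
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.query_interval[0]}\t"
                f"{h.query_interval[1]}\t{h.target_interval[0]}\t"
                f"{h.target_interval[1]}\t{h.energy:.3f}\t{h.score:.3f}\t"
                f"{h.p_raw:.6g}\t{h.p_adj:.6g}\n"
            )


def write_results_tsv(records: list[dict], path) -> None:
    """Write a list of flat dict records with a header, sorted by first key."""
    if not records:
        with open(path, "w") as fh:
            fh.write("\n")
        return
    cols = list(records[0])
    df = pd.DataFrame(records, columns=cols).sort_values(cols[0])
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
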