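"""Synthetic datasets with known ground truth for the whole pipeline.

The generator emulates the study conditions the pipeline is built for: an
ASO knockdown screen read out at promoter level (mostly down-regulated true
targets plus false-positive DEGs at the nominal rate), a query lncRNA
carrying planted antisense complementarity to its true targets, and
RNA-chromatin contact peaks concentrated near true-target promoters.

The mode distinction is planted structurally:

* ``co``   — each planted window lies wholly inside the first intron,
  within the 1 kb nascent 5' window, so the complementary segment exists in
  the nascent target but is absent from the mature transcript;
* ``post`` — each planted window spans the first exon-exon junction with
  only a small part (~1/5) in exon 1, so it is contiguous in the mature
  transcript but broken (and mostly missing) in the 1 kb genomic window,
  because the generator guarantees exon1+intron1 >= 1 kb.

Every generator consumes its own RNG stream derived from the master seed by
a fixed offset, so regenerating one artifact leaves the others untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .io_formats import (
    GeneModel,
    GenomeAssembly,
    KnockdownTable,
    PeakSet,
    Transcript,
    revcomp,
    write_bed,
    write_fasta,
    write_gtf,
    write_knockdown_tsv,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "simulate_genome",
    "plant_lncrna",
    "simulate_knockdown",
    "simulate_contacts",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults are the study conditions."""

    n_genes: int = 40
    n_chroms: int = 2
    gene_length_range: tuple[int, int] = (2200, 5000)
    exon_count_range: tuple[int, int] = (2, 4)
    gc_content: float = 0.5
    planted_mode: str = "co"  # co | post | none
    n_true_targets: int = 8
    planted_match_len: int = 40
    planted_mutation_rate: float = 0.05
    effect_log2fc_mean: float = -1.5  # negative: knockdown down-regulates targets
    effect_log2fc_sd: float = 0.5
    null_log2fc_sd: float = 0.3
    deg_alpha: float = 0.05
    peak_true_frac: float = 0.8
    peak_window: int = 300
    peak_width: int = 200
    n_background_peaks: int = 50
    lncrna_length: int = 2000
    chrom_length: int | None = None  # None: auto-sized to fit the genes
    seed: int = 0

    # structural ranges that make the two planted modes separable; the first
    # exon plus first intron always reaches past the 1 kb nascent window
    first_exon_range: tuple[int, int] = (150, 300)
    first_intron_range: tuple[int, int] = (850, 1400)
    exon_range: tuple[int, int] = (150, 400)
    intron_range: tuple[int, int] = (200, 600)

    def validate(self) -> None:
        for name in ("gc_content", "planted_mutation_rate", "deg_alpha", "peak_true_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.planted_mode not in {"co", "post", "none"}:
            raise ValueError(f"bad planted_mode {self.planted_mode!r}")
        if self.n_true_targets > self.n_genes:
            raise ValueError("n_true_targets cannot exceed n_genes")
        if self.planted_match_len < 8:
            raise ValueError("planted_match_len must be >= 8 (the seed word length)")


@dataclass
class SimTruth:
    """Ground truth: which promoters are targets and where the signal sits."""

    planted_mode: str
    true_target_ids: list[str]
    # promoter_id -> dict(query_interval, target_interval, target_mode_coords)
    planted: dict[str, dict] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: GenomeAssembly
    genes: list[GeneModel]
    lncrna: str
    truth: SimTruth
    knockdown: KnockdownTable
    peaks: PeakSet

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.sequences, out / "genome.fa")
        write_gtf(self.genes, out / "genes.gtf")
        write_fasta({self.knockdown.lncrna_id: self.lncrna}, out / "lncrna.fa")
        write_knockdown_tsv(self.knockdown, out / "knockdown.tsv")
        write_bed(self.peaks, out / "peaks.bed")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "planted_mode": self.truth.planted_mode,
                    "true_target_ids": self.truth.true_target_ids,
                    "planted": self.truth.planted,
                    "config": asdict(self.config),
                },
                fh,
                indent=2,
            )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _gene_structure(rng: np.random.Generator, config: SimConfig) -> list[int]:
    """Alternating exon/intron lengths e1,i1,e2,i2,...,ek (odd count)."""
    lo, hi = config.exon_count_range
    n_exons = int(rng.integers(lo, hi + 1))
    parts = [int(rng.integers(*config.first_exon_range))]
    for j in range(1, n_exons):
        intron_range = config.first_intron_range if j == 1 else config.intron_range
        parts.append(int(rng.integers(*intron_range)))
        parts.append(int(rng.integers(*config.exon_range)))
    total = sum(parts)
    gmin, gmax = config.gene_length_range
    if total > gmax:
        parts[-1] = max(50, parts[-1] - (total - gmax))
    elif total < gmin:
        parts[-1] += gmin - total
    return parts


def simulate_genome(config: SimConfig) -> tuple[GenomeAssembly, list[GeneModel]]:
    """I.i.d.-base chromosomes with non-overlapping randomly-stranded genes."""
    config.validate()
    rng = _rng(config, 0)
    structures = [_gene_structure(rng, config) for _ in range(config.n_genes)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(config.n_genes)]
    # round-robin assignment to chromosomes, sequential placement with gaps
    gap = 1500
    per_chrom: list[list[int]] = [[] for _ in range(config.n_chroms)]
    for gi in range(config.n_genes):
        per_chrom[gi % config.n_chroms].append(gi)
    genes: list[GeneModel] = []
    sequences: dict[str, str] = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = gap
        placements = []
        for gi in per_chrom[ci]:
            length = sum(structures[gi])
            placements.append((gi, cursor, cursor + length))
            cursor += length + gap
        needed = cursor + gap
        chrom_len = config.chrom_length or needed
        if chrom_len < needed:
            raise ValueError(
                f"cannot place {len(per_chrom[ci])} genes in {chrom_len} bp on "
                f"{chrom}; need >= {needed} bp (use larger chromosomes)"
            )
        sequences[chrom] = _random_seq(rng, chrom_len, config.gc_content)
        for gi, g0, g1 in placements:
            parts, strand = structures[gi], strands[gi]
            gene_id = f"g{gi + 1:03d}"
            # exon intervals in transcribed coordinates (0 at TSS)
            tx_exons = []
            off = 0
            for j, span in enumerate(parts):
                if j % 2 == 0:
                    tx_exons.append((off, off + span))
                off += span
            length = g1 - g0
            if strand == "+":
                exons = [(g0 + s, g0 + e) for s, e in tx_exons]
                tss = g0
            else:
                exons = sorted((g1 - e, g1 - s) for s, e in tx_exons)
                tss = g1 - 1
            pid = f"{gene_id}@p1"
            gene = GeneModel(
                gene_id,
                chrom,
                strand,
                promoters=[(pid, tss)],
                transcripts=[Transcript(f"{gene_id}.t1", pid, exons)],
            )
            gene.validate()
            genes.append(gene)
    return GenomeAssembly(sequences), genes


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def _nascent_window(gene: GeneModel, genome: GenomeAssembly, length: int) -> str:
    from .targets import build_cotx_target  # local import avoids a cycle

    return build_cotx_target(gene, gene.promoters[0][0], genome, length).sequence


def _mature_seq(gene: GeneModel, genome: GenomeAssembly) -> str:
    from .targets import build_posttx_target

    return build_posttx_target(gene, gene.promoters[0][0], genome).sequence


def plant_lncrna(
    genome: GenomeAssembly, genes: list[GeneModel], config: SimConfig
) -> tuple[str, SimTruth]:
    """A background lncRNA carrying one planted antisense segment per target.

    Each planted segment is the (mutated) reverse complement of a window of
    the target chosen by the planted mode's structural rule (intronic for
    ``co``; junction-spanning for ``post``). The lncRNA is partitioned into
    one block per target and each segment is placed at a random offset
    inside its own block, so segments never overlap.
    """
    config.validate()
    rng = _rng(config, 1)
    lnc = list(_random_seq(rng, config.lncrna_length, config.gc_content))
    mode = config.planted_mode
    if mode == "none":
        return "".join(lnc), SimTruth("none", [])

    ell = config.planted_match_len
    order = sorted(range(len(genes)), key=lambda i: genes[i].gene_id)
    chosen = rng.choice(len(order), size=config.n_true_targets, replace=False)
    target_idx = sorted(order[i] for i in chosen)
    truth = SimTruth(mode, [])
    block = config.lncrna_length // config.n_true_targets
    if block < ell + 2:
        raise ValueError("lncrna_length too small for the requested targets")

    for slot, gi in enumerate(target_idx):
        gene = genes[gi]
        tx = gene.transcripts[0]
        exon_lens = [e - s for s, e in tx.exons]
        if gene.strand == "-":
            exon_lens = exon_lens[::-1]  # transcribed order
        e1 = exon_lens[0]
        if mode == "co":
            # wholly intronic window inside the 1 kb nascent region
            if len(exon_lens) < 2:
                raise ValueError(
                    f"{gene.gene_id}: co-mode planting needs an intron in the 5' 1 kb"
                )
            nascent = _nascent_window(gene, genome, 1000)
            intron_end_in_window = min(len(nascent), e1 + _intron1_len(gene))
            feasible = intron_end_in_window - ell - e1
            if feasible < 0:
                raise ValueError(
                    f"{gene.gene_id}: first intron too short for the planted window"
                )
            w0 = e1 + int(rng.integers(0, feasible + 1))
            window = nascent[w0 : w0 + ell]
            target_coords = ("co", w0, w0 + ell)
        else:  # post: junction-spanning window, mostly in exon 2
            if len(exon_lens) < 2:
                raise ValueError(
                    f"{gene.gene_id}: post-mode planting needs an exon-exon junction"
                )
            j1 = max(4, ell // 5)  # bases kept in exon 1
            mature = _mature_seq(gene, genome)
            w0 = e1 - j1
            if w0 < 0 or w0 + ell > len(mature):
                raise ValueError(
                    f"{gene.gene_id}: exons too short for a junction-spanning window"
                )
            window = mature[w0 : w0 + ell]
            target_coords = ("post", w0, w0 + ell)
        segment = _mutate(revcomp(window), config.planted_mutation_rate, rng)
        offset = slot * block + int(rng.integers(0, block - ell + 1))
        lnc[offset : offset + ell] = segment
        pid = gene.promoters[0][0]
        truth.true_target_ids.append(pid)
        truth.planted[pid] = {
            "query_interval": [offset, offset + ell],
            "target_interval": list(target_coords[1:]),
            "target_mode": target_coords[0],
        }
    return "".join(lnc), truth


def _intron1_len(gene: GeneModel) -> int:
    tx = gene.transcripts[0]
    exons = tx.exons if gene.strand == "+" else tx.exons[::-1]
    if len(exons) < 2:
        return 0
    if gene.strand == "+":
        return exons[1][0] - exons[0][1]
    return exons[0][0] - exons[1][1]


def simulate_knockdown(
    genes: list[GeneModel], truth: SimTruth, config: SimConfig
) -> KnockdownTable:
    """Per-promoter log2FC with DEG flags at a common null-quantile threshold.

    True targets draw from Normal(effect_mean, effect_sd); the rest from
    Normal(0, null_sd). One threshold — the (1 - deg_alpha) quantile of
    |log2FC| under the null — flags both, so null promoters become
    false-positive DEGs at rate ~= deg_alpha.
    """
    config.validate()
    rng = _rng(config, 2)
    threshold = config.null_log2fc_sd * stats.norm.ppf(1 - config.deg_alpha / 2)
    true_set = set(truth.true_target_ids)
    rows: dict[str, tuple[float, bool]] = {}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        for pid, _ in gene.promoters:
            if pid in true_set:
                fc = float(rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd))
            else:
                fc = float(rng.normal(0.0, config.null_log2fc_sd))
            rows[pid] = (fc, abs(fc) > threshold)
    return KnockdownTable(f"ASO_sim_{config.seed}", "lnc_sim", rows)


def simulate_contacts(
    genes: list[GeneModel], truth: SimTruth, config: SimConfig,
    chrom_sizes: dict[str, int],
) -> PeakSet:
    """Contact peaks near true-target promoters plus uniform background."""
    config.validate()
    rng = _rng(config, 3)
    tss_by_pid = {
        pid: (g.chrom, tss) for g in genes for pid, tss in g.promoters
    }
    intervals: list[tuple[str, int, int]] = []
    half = config.peak_width // 2
    for pid in truth.true_target_ids:
        if rng.random() >= config.peak_true_frac:
            continue
        chrom, tss = tss_by_pid[pid]
        center = tss + int(rng.integers(-config.peak_window, config.peak_window + 1))
        start = max(0, center - half)
        end = min(chrom_sizes[chrom], center + half)
        if start < end:
            intervals.append((chrom, start, end))
    chroms = sorted(chrom_sizes)
    for _ in range(config.n_background_peaks):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max(1, chrom_sizes[chrom] - config.peak_width)))
        intervals.append((chrom, start, start + config.peak_width))
    return PeakSet(intervals)


def simulate_dataset(config: SimConfig, outdir=None) -> SimulatedDataset:
    """Run all four generators on their seed-derived streams."""
    genome, genes = simulate_genome(config)
    lncrna, truth = plant_lncrna(genome, genes, config)
    kd = simulate_knockdown(genes, truth, config)
    peaks = simulate_contacts(genes, truth, config, genome.chrom_sizes)
    ds = SimulatedDataset(config, genome, genes, lncrna, truth, kd, peaks)
    if outdir is not None:
        ds.write(outdir)
    return ds
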