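"""Per-knockdown orchestration and the mode-decision rule.

For one knockdown the pipeline builds both target sets, predicts antisense
duplexes against each, tests enrichment of strong hits among the DEGs in
each mode, and — when both modes come out significant — disambiguates with
the co-localization of DEG-with-hit promoters against the lncRNA's
chromatin contact peaks:

    call = co            co significant, post not
    call = post          post significant, co not
    call = co_via_coloc  both significant and coloc p < alpha
    call = ambiguous     both significant, coloc unavailable or p >= alpha
    call = none          neither significant

Cross-experiment helpers compute exact hypergeometric overlap p-values
against the annotated gene universe and the fraction of shared DEGs
down-regulated in every experiment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

from scipy import stats

from .coloc import ColocResult, permutation_test
from .duplex import DuplexParams, predict_interactions
from .enrichment import EnrichmentResult, evaluate_knockdown_mode
from .io_formats import (
    GeneModel,
    GenomeAssembly,
    KnockdownTable,
    PeakSet,
    write_hits_tsv,
    write_results_tsv,
)
from .targets import build_target_sets, promoter_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "GENCODE_V35_GENE_COUNTS",
    "GENE_UNIVERSE",
    "ModeCall",
    "OverlapReport",
    "decide_mode",
    "overlap_pvalue",
    "concordance_summary",
    "PipelineConfig",
    "run_pipeline",
]

# Annotated human gene universe for overlap tests: protein-coding, long
# non-coding and small non-coding gene counts of GENCODE v35.
GENCODE_V35_GENE_COUNTS = {
    "protein_coding": 19954,
    "long_noncoding": 17957,
    "small_noncoding": 7569,
}
GENE_UNIVERSE = sum(GENCODE_V35_GENE_COUNTS.values())  # 45480


@dataclass
class ModeCall:
    aso_id: str
    lncrna_id: str
    co: EnrichmentResult
    post: EnrichmentResult
    coloc: ColocResult | None
    call: str  # co | post | co_via_coloc | ambiguous | none


@dataclass
class OverlapReport:
    set_sizes: dict[str, int]
    intersections: dict[str, int]
    pvalues: dict[str, float]
    universe_size: int
    concordant_down_count: int | None = None
    concordant_down_pct: float | None = None


def decide_mode(
    co: EnrichmentResult,
    post: EnrichmentResult,
    coloc: ColocResult | None = None,
    alpha: float = 0.01,
    lncrna_id: str = "query",
) -> ModeCall:
    """Apply the deterministic mode-decision rule (total over all inputs)."""
    if co.aso_id != post.aso_id:
        raise ValueError(f"mismatched ASOs: {co.aso_id!r} vs {post.aso_id!r}")
    if co.significant and post.significant:
        if coloc is None:
            logger.warning(
                "%s: significant in both modes but no co-localization data; "
                "call stays ambiguous",
                co.aso_id,
            )
            call = "ambiguous"
        elif coloc.perm_p_reldist < alpha:
            call = "co_via_coloc"
        else:
            call = "ambiguous"
    elif co.significant:
        call = "co"
    elif post.significant:
        call = "post"
    else:
        call = "none"
    return ModeCall(co.aso_id, lncrna_id, co, post, coloc, call)


def overlap_pvalue(
    k: int,
    size_a: int,
    size_b: int,
    universe: int = GENE_UNIVERSE,
    tail: str = "gt",
) -> float:
    """Exact hypergeometric overlap p-value between two gene sets.

    ``tail='gt'`` gives P(X > k) — R's phyper(k, ..., lower.tail=FALSE)
    calling pattern; ``tail='ge'`` gives the conventional P(X >= k).
    """
    if tail not in {"gt", "ge"}:
        raise ValueError("tail must be 'gt' or 'ge'")
    if not (0 <= k <= min(size_a, size_b) and size_a <= universe and size_b <= universe):
        raise ValueError(
            f"inconsistent counts k={k}, sizes=({size_a},{size_b}), universe={universe}"
        )
    q = k if tail == "gt" else k - 1
    if q < 0:
        return 1.0
    return float(stats.hypergeom.sf(q, universe, size_a, size_b))


def concordance_summary(
    tables: list[dict[str, float]], shared_ids: set[str]
) -> tuple[int, float | None]:
    """Shared genes down-regulated (log2FC strictly < 0) in every table.

    Returns (count, percentage rounded to one decimal); the percentage is
    None when there are no shared genes.
    """
    missing = [i for i, t in enumerate(tables) if shared_ids - set(t)]
    if missing:
        raise ValueError(f"shared_ids missing from table(s) {missing}")
    if not shared_ids:
        return 0, None
    count = sum(
        1 for g in shared_ids if all(t[g] < 0 for t in tables)
    )
    pct = round(100.0 * count / len(shared_ids), 1)
    return count, pct


@dataclass
class PipelineConfig:
    """Everything one per-knockdown run needs, with the shared alpha."""

    alpha: float = 0.01
    hit_alpha: float = 0.01
    window_len: int = 1000
    promoter_flank: int = 500
    coloc_n_perm: int = 100
    coloc_d: int = 0
    gsea_n_perm: int = 1000
    duplex: DuplexParams | None = None
    seed: int = 0


def run_pipeline(
    genome: GenomeAssembly,
    genes: list[GeneModel],
    lncrna: str,
    kd: KnockdownTable,
    peaks: PeakSet | None = None,
    config: PipelineConfig | None = None,
    outdir=None,
) -> ModeCall:
    """targets(co,post) -> predict(x2) -> enrich(x2) -> coloc (if dual) -> decide.

    Writes every intermediate table plus a JSON manifest when ``outdir`` is
    given; fully deterministic given the seed.
    """
    cfg = config or PipelineConfig()
    dp = cfg.duplex or DuplexParams(alpha=cfg.hit_alpha)
    co_targets, post_targets = build_target_sets(genes, genome, cfg.window_len)
    results = {}
    hits = {}
    for mode, target_set in (("co", co_targets), ("post", post_targets)):
        mode_hits = predict_interactions(
            lncrna,
            target_set,
            params=dp,
            seed=cfg.seed,
            query_id=kd.lncrna_id,
        )
        hits[mode] = mode_hits
        results[mode] = evaluate_knockdown_mode(
            mode_hits,
            kd,
            mode,
            alpha=cfg.alpha,
            hit_alpha=cfg.hit_alpha,
            n_perm=cfg.gsea_n_perm,
            seed=cfg.seed,
        )

    coloc_res = None
    if results["co"].significant and results["post"].significant and peaks is not None:
        deg_hit_promoters = {
            h.target_id for h in hits["co"] if h.p_adj < cfg.hit_alpha
        } & kd.deg_set
        if deg_hit_promoters and len(peaks):
            query = promoter_intervals(
                genes,
                cfg.promoter_flank,
                genome.chrom_sizes,
                promoter_ids=deg_hit_promoters,
            )
            coloc_res = permutation_test(
                query,
                peaks,
                genome.chrom_sizes,
                n_perm=cfg.coloc_n_perm,
                d=cfg.coloc_d,
                seed=cfg.seed,
                aso_id=kd.aso_id,
            )
    call = decide_mode(
        results["co"], results["post"], coloc_res, cfg.alpha, kd.lncrna_id
    )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for mode in ("co", "post"):
            write_hits_tsv(hits[mode], out / f"hits_{mode}.tsv")
        write_results_tsv(
            [asdict(results[m]) for m in ("co", "post")], out / "enrichment.tsv"
        )
        if coloc_res is not None:
            write_results_tsv([asdict(coloc_res)], out / "coloc.tsv")
        manifest = {
            "aso_id": kd.aso_id,
            "lncrna_id": kd.lncrna_id,
            "call": call.call,
            "alpha": cfg.alpha,
            "hit_alpha": cfg.hit_alpha,
            "window_len": cfg.window_len,
            "promoter_flank": cfg.promoter_flank,
            "coloc_n_perm": cfg.coloc_n_perm,
            "gsea_n_perm": cfg.gsea_n_perm,
            "seed": cfg.seed,
            "word_len": dp.word_len,
            "xdrop": dp.xdrop,
            "n_null": dp.n_null,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return call
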