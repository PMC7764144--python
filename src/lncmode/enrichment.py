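"""Per-knockdown enrichment of strong antisense hits among the DEGs.

Two tests, per interaction mode: an exact hypergeometric over-representation
test of hit promoters within the DEG set against the tested background, and
a preranked GSEA (weighted Kolmogorov-Smirnov running sum with DEG-label
permutation). A knockdown counts as significant in a mode when either test
falls below alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .duplex import DuplexHit
from .io_formats import KnockdownTable

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hgd_enrichment",
    "gsea_enrichment",
    "evaluate_knockdown_mode",
]


@dataclass
class EnrichmentResult:
    aso_id: str
    mode: str
    n_background: int
    n_deg: int
    n_hits_background: int
    n_hits_in_deg: int
    hgd_p: float
    gsea_es: float
    gsea_p: float
    significant: bool


def hgd_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Exact summation (scipy's hypergeometric survival function); no normal
    approximation.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _es_curve(is_hit: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximal deviation of the weighted KS running sum."""
    hit_w = weights * is_hit
    total_hit = hit_w.sum()
    n_miss = len(is_hit) - int(is_hit.sum())
    if total_hit > 0:
        p_hit = np.cumsum(hit_w) / total_hit
    else:
        p_hit = np.cumsum(is_hit) / max(1, int(is_hit.sum()))
    p_miss = np.cumsum(~is_hit) / max(1, n_miss)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def gsea_enrichment(
    scores: dict[str, float],
    deg_set: set[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Preranked GSEA of the DEG set on descending scores.

    Promoters are ranked by score (ties broken by promoter_id); the running
    sum gains |score|^weight at DEGs and loses uniformly elsewhere. The
    enrichment score is the signed extremum; significance comes from
    permuting the DEG labels: p = (1 + #{ES_perm >= ES_obs}) / (1 + n_perm).
    """
    if not deg_set:
        raise ValueError("deg_set is empty")
    if not deg_set <= set(scores):
        raise ValueError("deg_set contains unscored promoters")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = sorted(scores, key=lambda p: (-scores[p], p))
    vals = np.array([scores[p] for p in ranked], dtype=float)
    if np.ptp(vals) == 0:
        logger.warning("all scores equal; GSEA falls back to uniform increments")
        weights = np.ones_like(vals)
    else:
        weights = np.abs(vals) ** weight
    is_hit = np.array([p in deg_set for p in ranked])
    es_obs = _es_curve(is_hit, weights)
    rng = np.random.default_rng(seed)
    n_hit = int(is_hit.sum())
    count = 0
    for _ in range(n_perm):
        perm = np.zeros(len(ranked), dtype=bool)
        perm[rng.choice(len(ranked), size=n_hit, replace=False)] = True
        if _es_curve(perm, weights) >= es_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return es_obs, p


def evaluate_knockdown_mode(
    hits: list[DuplexHit],
    kd: KnockdownTable,
    mode: str,
    alpha: float = 0.01,
    hit_alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Both enrichment tests for one knockdown in one interaction mode.

    Hit promoters are those whose best duplex has adjusted p below
    ``hit_alpha``; the background universe is the knockdown table itself.
    GSEA scores are -log10(p_adj), zero for promoters without a hit.
    """
    background = kd.background
    hit_targets = {h.target_id for h in hits if h.p_adj < hit_alpha}
    stray = hit_targets - background
    if stray:
        raise ValueError(
            f"hit targets not in the tested background: {sorted(stray)[:5]}"
        )
    deg = kd.deg_set
    k = len(hit_targets & deg)
    hgd_p = hgd_enrichment(k, len(deg), len(hit_targets), len(background))

    scores = {pid: 0.0 for pid in background}
    for h in hits:
        if h.target_id in scores:
            scores[h.target_id] = max(
                scores[h.target_id], -math.log10(max(h.p_adj, 1e-300))
            )
    if deg:
        es, gsea_p = gsea_enrichment(scores, deg, n_perm=n_perm, seed=seed)
    else:
        es, gsea_p = 0.0, 1.0
    return EnrichmentResult(
        aso_id=kd.aso_id,
        mode=mode,
        n_background=len(background),
        n_deg=len(deg),
        n_hits_background=len(hit_targets),
        n_hits_in_deg=k,
        hgd_p=hgd_p,
        gsea_es=es,
        gsea_p=gsea_p,
        significant=(hgd_p < alpha) or (gsea_p < alpha),
    )
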