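"""Antisense RNA:RNA duplex prediction with calibrated significance.

The engine follows the classic ungapped seed-and-extend design: exact
reverse-complement word matches seed antiparallel x-drop extensions scored
with match/wobble/mismatch increments; surviving candidates are rescored
with a nearest-neighbor hybridisation energy, and the best candidate per
query-target pair is assigned a p-value from an extreme-value (Gumbel) null
fitted to dinucleotide-preserving shuffles, stratified by GC content and
corrected for the search space (the product of the two sequence lengths).
Benjamini-Hochberg adjustment is applied across the targets of a run.

Scores reported to the statistics are continuous (-energy, kcal/mol); the
integer alignment score only drives candidate discovery.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "DuplexHit",
    "NullCalibration",
    "DuplexParams",
    "find_seed_matches",
    "extend_seed",
    "classify_pairing",
    "duplex_energy",
    "dinucleotide_shuffle",
    "calibrate_null",
    "hit_pvalue",
    "predict_interactions",
    "best_hit_bruteforce",
]

# --- alignment scoring (candidate discovery) -------------------------------

WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}  # G:U in the RNA alphabet

DEFAULT_SCORES = {"WC": 2, "wobble": 1, "mismatch": -3}

# --- nearest-neighbor hybridisation energy ---------------------------------
#
# Watson-Crick RNA/RNA stack free energies (ΔG°37, kcal/mol) from the
# unified nearest-neighbor set, written in the DNA alphabet (T stands for U).
# In an all-WC stack the partner strand is the reverse complement of the
# query dinucleotide, so the table keys on the query dinucleotide 5'->3'
# alone; the 16 entries come from the 10 unique stacks plus the 180-degree
# rotational symmetry dG(XY) = dG(revcomp(XY)). Stacks containing a wobble
# pair use one bundled milder constant; a mismatch breaks stacking and costs
# a fixed destabilising term. This is a deliberately simple, monotone
# parameterisation: duplex stability, not chemistry-grade folding, is what
# the downstream statistics consume.

_WC_STACK = {
    "AA": -0.93, "TT": -0.93,
    "AT": -1.10,
    "TA": -1.33,
    "CT": -2.08, "AG": -2.08,
    "CA": -2.11, "TG": -2.11,
    "GT": -2.24, "AC": -2.24,
    "GA": -2.35, "TC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

DUPLEX_INITIATION = 4.09  # kcal/mol, per duplex
WOBBLE_STACK = -1.0  # kcal/mol, any stack containing a G:U pair
MISMATCH_PENALTY = 0.5  # kcal/mol per mismatched position


def _stack_energy(q_dinuc: str, classes: tuple[str, str]) -> float:
    """Free energy of stacking two adjacent paired positions."""
    if "mismatch" in classes:
        return 0.0  # mismatches break stacking; handled by the caller
    if "wobble" in classes:
        return WOBBLE_STACK
    return _WC_STACK[q_dinuc]


@dataclass
class DuplexHit:
    """One predicted antisense interaction (ungapped).

    Intervals are 0-based half-open on each molecule; the alignment is
    antiparallel, so query position q_start+i pairs with target position
    t_end-1-i. ``pairing`` holds the per-position class in query order.
    """

    query_id: str
    target_id: str
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    pairing: list[str]
    energy: float  # kcal/mol, negative = stable
    score: float  # -energy
    p_raw: float = 1.0
    p_adj: float = 1.0
    align_score: int = 0

    def __post_init__(self) -> None:
        qlen = self.query_interval[1] - self.query_interval[0]
        tlen = self.target_interval[1] - self.target_interval[0]
        if qlen != tlen:
            raise ValueError("ungapped hit must have equal-length intervals")


@dataclass
class DuplexParams:
    """All tunable constants of the engine in one place."""

    word_len: int = 6
    xdrop: int = 12
    scores: dict = field(default_factory=lambda: dict(DEFAULT_SCORES))
    n_null: int = 500
    gc_edges: tuple[float, float] = (0.4, 0.6)
    alpha: float = 0.01


def classify_pairing(q: str, t: str) -> str:
    if (q, t) in WC_PAIRS:
        return "WC"
    if (q, t) in WOBBLE_PAIRS:
        return "wobble"
    return "mismatch"


def find_seed_matches(query: str, target: str, word_len: int = 6) -> list[tuple[int, int]]:
    """All (q_pos, t_pos) with query[q_pos:q_pos+w] == revcomp(target[t_pos:t_pos+w]).

    Sequences shorter than the word length yield an empty list. Output is
    sorted by (q_pos, t_pos).
    """
    if word_len < 4:
        raise ValueError("word_len must be >= 4")
    w = word_len
    if len(query) < w or len(target) < w:
        return []
    index: dict[str, list[int]] = {}
    for q_pos in range(len(query) - w + 1):
        index.setdefault(query[q_pos : q_pos + w], []).append(q_pos)
    rc_target = revcomp(target)
    n = len(target)
    matches = []
    for i in range(n - w + 1):
        word = rc_target[i : i + w]
        if word in index:
            t_pos = n - w - i  # position of the word on the forward target
            for q_pos in index[word]:
                matches.append((q_pos, t_pos))
    matches.sort()
    return matches


def _pair_class_at(query: str, target: str, qi: int, ti: int) -> str:
    return classify_pairing(query[qi], target[ti])


def extend_seed(
    query: str,
    target: str,
    seed: tuple[int, int],
    word_len: int = 6,
    scores: dict | None = None,
    xdrop: int = 12,
) -> DuplexHit:
    """Ungapped antiparallel x-drop extension of a seed word.

    Advancing on the query recedes on the target. Extension on each side
    stops once the running score falls more than ``xdrop`` below its running
    maximum; the maximal-scoring segment over the scanned span is returned.
    """
    sc = scores or DEFAULT_SCORES
    q_pos, t_pos = seed
    w = word_len

    def step_score(qi: int, ti: int) -> int:
        return sc[_pair_class_at(query, target, qi, ti)]

    # seed itself is all-WC by construction when produced by find_seed_matches,
    # but score it explicitly so arbitrary seeds behave sensibly
    seed_score = sum(step_score(q_pos + i, t_pos + w - 1 - i) for i in range(w))

    def extend(direction: int) -> tuple[int, int]:
        """Best extra score and extension length on one side."""
        best, best_len = 0, 0
        running = 0
        k = 1
        while True:
            if direction > 0:  # rightwards on query, leftwards on target
                qi, ti = q_pos + w - 1 + k, t_pos - k
            else:  # leftwards on query, rightwards on target
                qi, ti = q_pos - k, t_pos + w - 1 + k
            if qi < 0 or qi >= len(query) or ti < 0 or ti >= len(target):
                break
            running += step_score(qi, ti)
            if running > best:
                best, best_len = running, k
            if running < best - xdrop:
                break
            k += 1
        return best, best_len

    right_gain, right_len = extend(+1)
    left_gain, left_len = extend(-1)

    q_start = q_pos - left_len
    q_end = q_pos + w + right_len
    t_start = t_pos - right_len
    t_end = t_pos + w + left_len
    length = q_end - q_start
    pairing = [
        _pair_class_at(query, target, q_start + i, t_end - 1 - i)
        for i in range(length)
    ]
    q_sub = query[q_start:q_end]
    t_sub = target[t_start:t_end]
    energy = duplex_energy(q_sub, t_sub, pairing)
    return DuplexHit(
        query_id="query",
        target_id="target",
        query_interval=(q_start, q_end),
        target_interval=(t_start, t_end),
        pairing=pairing,
        energy=energy,
        score=-energy,
        align_score=seed_score + right_gain + left_gain,
    )


def duplex_energy(query_sub: str, target_sub: str, pairing: list[str]) -> float:
    """Nearest-neighbor free energy of an ungapped duplex (kcal/mol).

    ``query_sub`` is the query 5'->3'; ``target_sub`` the target 5'->3'
    (antiparallel, so query_sub[i] faces target_sub[-1-i]). Energy is the
    duplex initiation penalty plus stack terms over adjacent paired
    positions; a mismatch contributes no stacks and a fixed penalty.
    """
    if len(query_sub) != len(target_sub) or len(query_sub) != len(pairing):
        raise ValueError("query, target and pairing lengths must match")
    energy = DUPLEX_INITIATION
    n = len(pairing)
    for i in range(n - 1):
        classes = (pairing[i], pairing[i + 1])
        if "mismatch" in classes:
            continue
        energy += _stack_energy(query_sub[i : i + 2], classes)
    energy += MISMATCH_PENALTY * sum(c == "mismatch" for c in pairing)
    return energy


# ---------------------------------------------------------------------------
# Null model


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts.

    Builds the multigraph of dinucleotide transitions, samples a random
    Eulerian arrangement by the last-edge/arborescence method.
    """
    if len(seq) < 3:
        return seq
    alphabet = sorted(set(seq))
    edges: dict[str, list[str]] = {a: [] for a in alphabet}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # choose a random last edge out of every vertex (except the terminal one)
    # such that the chosen edges form a tree pointing at the terminal vertex
    while True:
        last_edges = {}
        for a in alphabet:
            if a == last or not edges[a]:
                continue
            last_edges[a] = edges[a][rng.integers(len(edges[a]))]
        # connectivity check: every vertex must reach `last` through last_edges
        ok = True
        for a in last_edges:
            seen = {a}
            cur = a
            while cur != last:
                cur = last_edges.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    out_lists: dict[str, list[str]] = {}
    for a in alphabet:
        rest = list(edges[a])
        if a in last_edges:
            rest.remove(last_edges[a])
        perm = rng.permutation(len(rest))
        shuffled = [rest[i] for i in perm]
        if a in last_edges:
            shuffled.append(last_edges[a])
        out_lists[a] = shuffled
    pos = {a: 0 for a in alphabet}
    result = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = out_lists[cur][pos[cur]]
        pos[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


# --- vectorized batch extension --------------------------------------------
#
# The scalar extend_seed is the reference implementation; _batch_extend
# reproduces it exactly (same x-drop semantics, same tie-breaks) across all
# seeds of a pair at once, which is what makes null calibration affordable.
# Alignment position p maps to query index qp+p and target index tp+w-1-p.

_CODE = {b: i for i, b in enumerate("ACGTN")}

_E2 = np.zeros((5, 5, 5, 5))  # stack energy of adjacent columns (qa,ta),(qb,tb)
_MISMATCH = np.zeros((5, 5))
for _qa in "ACGTN":
    for _ta in "ACGTN":
        ca = classify_pairing(_qa, _ta)
        if ca == "mismatch":
            _MISMATCH[_CODE[_qa], _CODE[_ta]] = MISMATCH_PENALTY
        for _qb in "ACGTN":
            for _tb in "ACGTN":
                cb = classify_pairing(_qb, _tb)
                if "mismatch" in (ca, cb):
                    e = 0.0
                elif "wobble" in (ca, cb):
                    e = WOBBLE_STACK
                else:
                    e = _WC_STACK[_qa + _qb]
                _E2[_CODE[_qa], _CODE[_ta], _CODE[_qb], _CODE[_tb]] = e


def _encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), _CODE["N"], dtype=np.int64)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _step_matrix(scores: dict) -> np.ndarray:
    S = np.full((5, 5), scores["mismatch"], dtype=np.int64)
    for (a, b) in WC_PAIRS:
        S[_CODE[a], _CODE[b]] = scores["WC"]
    for (a, b) in WOBBLE_PAIRS:
        S[_CODE[a], _CODE[b]] = scores["wobble"]
    S[4, :] = S[:, 4] = scores["mismatch"]  # N never pairs
    return S


_BIG = 10**6


def _side_arrays(qc, tc, qp, tp, w, window, direction):
    ks = np.arange(1, window + 1)
    if direction > 0:
        qi = qp[:, None] + (w - 1) + ks
        ti = tp[:, None] - ks
    else:
        qi = qp[:, None] - ks
        ti = tp[:, None] + (w - 1) + ks
    valid = (qi >= 0) & (qi < len(qc)) & (ti >= 0) & (ti < len(tc))
    qi_c = np.clip(qi, 0, len(qc) - 1)
    ti_c = np.clip(ti, 0, len(tc) - 1)
    return qi_c, ti_c, valid


def _best_side(steps: np.ndarray, xdrop: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-seed best cumulative gain, its length, and 'ran off the window' flag."""
    C = np.cumsum(steps, axis=1)
    # running max of the gain, with the scalar loop's zero baseline included
    R = np.maximum(np.maximum.accumulate(C, axis=1), 0)
    dead = C < R - xdrop
    n_dead = np.cumsum(dead, axis=1)
    seen_dead = n_dead > 0
    # scan up to and including the FIRST dead position, as the scalar loop does
    allowed = (n_dead == 0) | ((n_dead == 1) & dead)
    C_masked = np.where(allowed, C, -_BIG)
    gain = C_masked.max(axis=1)
    length = np.where(gain > 0, C_masked.argmax(axis=1) + 1, 0)
    gain = np.maximum(gain, 0)
    truncated = ~seen_dead[:, -1]  # never stopped inside the window
    return gain, length, truncated


def _batch_extend(
    query: str,
    target: str,
    seeds: list[tuple[int, int]],
    word_len: int,
    scores: dict,
    xdrop: int,
    window: int = 64,
):
    """Vectorized extend_seed over all seeds; falls back to scalar on overflow.

    Returns (align_scores, energies, q_intervals, t_intervals) as arrays and
    lists aligned with ``seeds``.
    """
    w = word_len
    qc = _encode_seq(query)
    tc = _encode_seq(target)
    qp = np.array([s[0] for s in seeds], dtype=np.int64)
    tp = np.array([s[1] for s in seeds], dtype=np.int64)
    S = _step_matrix(scores)

    sides = {}
    for direction in (+1, -1):
        qi, ti, valid = _side_arrays(qc, tc, qp, tp, w, window, direction)
        steps = np.where(valid, S[qc[qi], tc[ti]], -_BIG)
        gain, length, truncated = _best_side(steps, xdrop)
        # energy increments of adding each successive position to the segment;
        # the stack key is ordered by alignment position, so the new position
        # comes second on the right side and first on the left side
        if direction > 0:
            qprev, tprev = qi - 1, ti + 1
        else:
            qprev, tprev = qi + 1, ti - 1
        qprev_c = np.clip(qprev, 0, len(qc) - 1)
        tprev_c = np.clip(tprev, 0, len(tc) - 1)
        if direction > 0:
            stack = _E2[qc[qprev_c], tc[tprev_c], qc[qi], tc[ti]]
        else:
            stack = _E2[qc[qi], tc[ti], qc[qprev_c], tc[tprev_c]]
        add = np.where(valid, stack + _MISMATCH[qc[qi], tc[ti]], 0.0)
        ecum = np.cumsum(add, axis=1)
        egain = np.where(
            length > 0, np.take_along_axis(ecum, np.maximum(length - 1, 0)[:, None], 1)[:, 0], 0.0
        )
        sides[direction] = (gain, length, truncated, egain)

    r_gain, r_len, r_trunc, r_e = sides[+1]
    l_gain, l_len, l_trunc, l_e = sides[-1]

    # seed score and internal seed energy (seeds are all-WC words)
    seed_score = np.full(len(seeds), scores["WC"] * w, dtype=np.int64)
    idx = qp[:, None] + np.arange(w - 1)
    seed_stacks = _E2[
        qc[idx], tc[tp[:, None] + w - 1 - np.arange(w - 1)],
        qc[idx + 1], tc[tp[:, None] + w - 2 - np.arange(w - 1)],
    ].sum(axis=1)
    align = seed_score + r_gain + l_gain
    energy = DUPLEX_INITIATION + seed_stacks + r_e + l_e

    overflow = np.where(r_trunc | l_trunc)[0]
    q_iv = np.stack([qp - l_len, qp + w + r_len], axis=1)
    t_iv = np.stack([tp - r_len, tp + w + l_len], axis=1)
    for i in overflow:
        hit = extend_seed(query, target, seeds[i], w, scores, xdrop)
        align[i] = hit.align_score
        energy[i] = hit.energy
        q_iv[i] = hit.query_interval
        t_iv[i] = hit.target_interval
    return align, energy, q_iv, t_iv


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def _gc_bin(gc: float, edges: tuple[float, float]) -> int:
    return bisect.bisect_right(list(edges), gc)


@dataclass
class NullCalibration:
    """Per GC-bin Gumbel parameters for the max pair score under shuffles.

    P(S_max >= s) = 1 - exp(-K * m * n * exp(-lambda * s)), with m, n the
    sequence lengths. Bins are (query GC bin, target GC bin); untrained bins
    fall back to the nearest trained bin.
    """

    gc_edges: tuple[float, float]
    params: dict[tuple[int, int], tuple[float, float]]  # bin -> (lambda, K)
    n_null: int
    seed: int

    def lookup(self, gc_q: float, gc_t: float) -> tuple[float, float]:
        key = (_gc_bin(gc_q, self.gc_edges), _gc_bin(gc_t, self.gc_edges))
        if key in self.params:
            return self.params[key]
        nearest = min(
            self.params,
            key=lambda b: abs(b[0] - key[0]) + abs(b[1] - key[1]),
        )
        logger.warning(
            "GC bin %s not trained; falling back to nearest bin %s", key, nearest
        )
        return self.params[nearest]


def best_pair_score(query: str, target: str, params: DuplexParams) -> float:
    """Max -energy over seed-extend candidates; 0.0 if no stable hit."""
    seeds = find_seed_matches(query, target, params.word_len)
    if not seeds:
        return 0.0
    _, energy, _, _ = _batch_extend(
        query, target, seeds, params.word_len, params.scores, params.xdrop
    )
    return max(0.0, float(-energy.min()))


def _best_pair_hit(query: str, target: str, params: DuplexParams) -> DuplexHit | None:
    """The pair's best candidate as a full DuplexHit (None when nothing stable)."""
    seeds = find_seed_matches(query, target, params.word_len)
    if not seeds:
        return None
    align, energy, q_iv, t_iv = _batch_extend(
        query, target, seeds, params.word_len, params.scores, params.xdrop
    )
    i = int(energy.argmin())
    if -energy[i] <= 0:
        return None
    q_start, q_end = int(q_iv[i][0]), int(q_iv[i][1])
    t_start, t_end = int(t_iv[i][0]), int(t_iv[i][1])
    pairing = [
        classify_pairing(query[q_start + k], target[t_end - 1 - k])
        for k in range(q_end - q_start)
    ]
    return DuplexHit(
        query_id="query",
        target_id="target",
        query_interval=(q_start, q_end),
        target_interval=(t_start, t_end),
        pairing=pairing,
        energy=float(energy[i]),
        score=float(-energy[i]),
        align_score=int(align[i]),
    )


def _candidate_hits(query: str, target: str, params: DuplexParams) -> list[DuplexHit]:
    seeds = find_seed_matches(query, target, params.word_len)
    best_by_span: dict[tuple[int, int, int, int], DuplexHit] = {}
    for seed in seeds:
        hit = extend_seed(
            query, target, seed, params.word_len, params.scores, params.xdrop
        )
        key = (*hit.query_interval, *hit.target_interval)
        if key not in best_by_span:
            best_by_span[key] = hit
    # merge overlapping candidates on the same diagonal, keeping the best score
    hits = sorted(
        best_by_span.values(),
        key=lambda h: (-h.score, h.query_interval, h.target_interval),
    )
    kept: list[DuplexHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if (
                h.query_interval[0] < k.query_interval[1]
                and k.query_interval[0] < h.query_interval[1]
                and h.target_interval[0] < k.target_interval[1]
                and k.target_interval[0] < h.target_interval[1]
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def calibrate_null(
    query: str,
    targets: dict[str, str],
    n_null: int = 500,
    seed: int = 0,
    params: DuplexParams | None = None,
) -> NullCalibration:
    """Fit the Gumbel null per GC bin on dinucleotide-preserving shuffles.

    For each GC bin populated by the target set, representative targets are
    cycled, both members of each pair are shuffled, and the max hit score is
    recorded; (lambda, K) come from a Gumbel fit to those maxima with the
    search-space term m*n factored out at the bin's mean size.
    """
    if n_null < 50:
        raise ValueError("n_null must be >= 50 for a stable extreme-value fit")
    params = params or DuplexParams()
    rng = np.random.default_rng(seed)
    by_bin: dict[tuple[int, int], list[str]] = {}
    q_bin = _gc_bin(gc_content(query), params.gc_edges)
    for tid in sorted(targets):
        t = targets[tid]
        by_bin.setdefault((q_bin, _gc_bin(gc_content(t), params.gc_edges)), []).append(t)
    fitted: dict[tuple[int, int], tuple[float, float]] = {}
    for key in sorted(by_bin):
        pool = by_bin[key]
        maxima = np.empty(n_null)
        sizes = np.empty(n_null)
        for i in range(n_null):
            t = pool[i % len(pool)]
            sq = dinucleotide_shuffle(query, rng)
            st = dinucleotide_shuffle(t, rng)
            maxima[i] = best_pair_score(sq, st, params)
            sizes[i] = len(sq) * len(st)
        if np.ptp(maxima) == 0:
            raise ValueError(
                "degenerate null (all maxima equal); increase n_null or sequence sizes"
            )
        loc, scale = stats.gumbel_r.fit(maxima)
        lam = 1.0 / scale
        K = math.exp(lam * loc) / float(np.mean(sizes))
        fitted[key] = (lam, K)
    return NullCalibration(params.gc_edges, fitted, n_null, seed)


def hit_pvalue(
    score: float,
    len_q: int,
    len_t: int,
    calibration: NullCalibration,
    gc_q: float | None = None,
    gc_t: float | None = None,
) -> float:
    """Karlin-Altschul style tail probability of the pair's best score."""
    if score <= 0:
        return 1.0
    lam, K = calibration.lookup(
        gc_q if gc_q is not None else 0.5, gc_t if gc_t is not None else 0.5
    )
    ev = K * len_q * len_t * math.exp(-lam * score)
    p = -math.expm1(-ev)
    return min(1.0, max(p, 5e-324))


def predict_interactions(
    query: str,
    target_set: dict[str, str],
    params: DuplexParams | None = None,
    calibration: NullCalibration | None = None,
    seed: int = 0,
    query_id: str = "query",
) -> list[DuplexHit]:
    """Best antisense hit per target with raw and BH-adjusted p-values.

    BH adjustment is computed over all targets in the run (targets without
    a stable hit enter as p=1) so that the adjusted values reflect the full
    family of comparisons, then rows are reported for targets with hits,
    sorted by (p_adj, target_id).
    """
    params = params or DuplexParams()
    if not target_set:
        return []
    if calibration is None:
        calibration = calibrate_null(
            query, target_set, n_null=params.n_null, seed=seed, params=params
        )
    gc_q = gc_content(query)
    target_ids = sorted(target_set)
    best_hits: dict[str, DuplexHit] = {}
    p_raw = []
    for tid in target_ids:
        t = target_set[tid]
        best = _best_pair_hit(query, t, params)
        if best is not None:
            best.query_id = query_id
            best.target_id = tid
            best.p_raw = hit_pvalue(
                best.score, len(query), len(t), calibration, gc_q, gc_content(t)
            )
            best_hits[tid] = best
            p_raw.append(best.p_raw)
        else:
            p_raw.append(1.0)
    if not best_hits:
        return []
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    for tid, adj in zip(target_ids, p_adj):
        if tid in best_hits:
            best_hits[tid].p_adj = float(adj)
    return sorted(best_hits.values(), key=lambda h: (h.p_adj, h.target_id))


# ---------------------------------------------------------------------------
# Brute-force oracle (exact, for short sequences and tests)


def best_hit_bruteforce(
    query: str, target: str, scores: dict | None = None
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Exact best ungapped antisense segment by scanning every anti-diagonal.

    Returns (align_score, query_interval, target_interval); score 0 with
    empty intervals when no positive-scoring segment exists. Intended as an
    independent check of the seed-and-extend path on small inputs.
    """
    sc = scores or DEFAULT_SCORES
    m, n = len(query), len(target)
    best = (0, (0, 0), (0, 0))
    for qi0 in range(m):
        for tj0 in (range(n) if qi0 == 0 else [n - 1]):
            # walk the anti-diagonal starting at (qi0, tj0): q increases, t decreases
            length = min(m - qi0, tj0 + 1)
            running, run_start = 0, 0
            for k in range(length):
                s = sc[classify_pairing(query[qi0 + k], target[tj0 - k])]
                if running <= 0:
                    running, run_start = s, k
                else:
                    running += s
                if running > best[0]:
                    q_iv = (qi0 + run_start, qi0 + k + 1)
                    t_iv = (tj0 - k, tj0 - run_start + 1)
                    best = (running, q_iv, t_iv)
    return best
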