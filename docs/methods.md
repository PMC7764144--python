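# Methods

## Problem and model

A lncRNA knockdown produces a promoter-level table of expression changes
(log2 fold-change plus a DEG flag over the tested background). If the
lncRNA regulates those targets by direct RNA:RNA base-pairing, its sequence
should be complementary to the targets' transcripts — and *which* transcript
form it is complementary to carries mechanistic information. Two hypotheses
are scored per promoter:

* **Co-transcriptional**: the lncRNA pairs with the 5′ end of the nascent
  transcript at the locus. Target = the genomic window `[TSS, TSS+1 kb)` on
  the sense strand (introns included, because pairing is assumed to precede
  splicing), truncated at the chromosome edge and at the 3′-most transcript
  end of the promoter — a nascent transcript of a short gene is itself
  short. The truncation also yields the correct limit: for an intronless
  gene under 1 kb the co and post targets coincide.
* **Post-transcriptional**: the lncRNA pairs with the mature RNA. Target =
  the spliced sequence of the promoter's longest mature isoform (longest by
  spliced length, not genomic span; ties break to the smallest
  transcript_id).

Promoter identity is an exact shared strand-aware TSS coordinate: CAGE
measures expression per promoter, and transcripts whose 5′ ends coincide
share one. All internal coordinates are 0-based half-open; GTF (1-based
closed) is converted at the boundary in both directions, and RNA alphabets
are normalised to DNA (U→T) on read.

## Duplex engine

Ungapped seed-and-extend with hybridisation-energy rescoring:

1. **Seeds** — all positions where a query word equals the reverse
   complement of a target word (default word length 6; see *Numerical
   choices*).
2. **Extension** — antiparallel x-drop extension (advancing on the query
   recedes on the target) with match +2, G:U wobble +1, mismatch −3 and
   x-drop 12; each side stops when the running score falls more than the
   x-drop below its maximum, and the maximal-scoring segment is kept.
   A numpy batch implementation processes all seeds of a pair at once; the
   scalar routine is the reference and a property test pins exact
   equivalence between the two.
3. **Energy** — each candidate is rescored as ΔG°37 = duplex initiation
   (+4.09 kcal/mol) + nearest-neighbor stack terms over adjacent paired
   positions. Watson–Crick stacks use the standard unified RNA/RNA values
   (−0.93 … −3.42 kcal/mol, keyed by the query dinucleotide); any stack
   containing a wobble pair uses one bundled value (−1.0 kcal/mol); a
   mismatch breaks stacking and adds +0.5 kcal/mol. This is a deliberately
   simple monotone parameterisation — duplex stability feeding a calibrated
   statistic, not chemistry-grade folding (no bulges, loops, accessibility
   or intramolecular structure).
4. **Significance** — the pair score is the best candidate's −ΔG
   (continuous, which keeps the null p-value lattice fine). Under the null,
   maxima of dinucleotide-preserving shuffles (Altschul–Erickson) of both
   molecules follow an extreme-value law; per GC bin (3×3 bins with edges
   0.4/0.6, nearest-bin fallback with a warning) a Gumbel fit of the null
   maxima gives (λ, K) and
   `p = 1 − exp(−K·m·n·e^(−λs))` with m, n the sequence lengths. The
   Benjamini–Hochberg adjustment runs over all targets of the run (targets
   without a stable hit enter as p = 1).

**Why word length 6 and 500 null shuffles.** With word length 8 a null pair
of realistic size produces only a handful of seed candidates, the max-score
distribution is visibly non-Gumbel, and calibrated p-values fail their own
uniformity check. At word length 6 the candidate count is an order of
magnitude larger, the Gumbel fit is excellent (KS distance ≈ 0.015 against
the fitted law), and null p-values on fresh shuffled pairs are uniform. 500
calibration shuffles keep the (λ, K) estimation error well below the KS
detection threshold at the validation sample sizes used here; the
uniformity experiment itself uses 800 for a stable reference fit.

## Enrichment per knockdown and mode

Hit promoters are those with adjusted p < 0.01 ("strong hits"). Against the
background universe — defined as all promoters in the knockdown table —
two tests are run per mode:

* **Hypergeometric** upper tail P(X ≥ k) of k hit-DEGs among n DEGs, K hits,
  N background (exact summation; an enumeration oracle checks it for
  N ≤ 30).
* **Preranked GSEA**: promoters ranked by −log10(adjusted p) (0 without a
  hit, ties broken by id); running sum gains |score|^1 at DEGs, loses
  uniformly otherwise; ES = signed extremum; p by DEG-label permutation,
  `p = (1+#{ES_perm ≥ ES_obs})/(1+n_perm)`, n_perm = 1000. When every score
  is equal the increments fall back to uniform with a logged warning.

A mode is significant when either test has p < alpha (0.01). The either-test
union keeps the type-I rate within [alpha/2, 2·alpha]: the permutation test
contributes almost exactly alpha, the discrete hypergeometric tail at most
alpha, and the two are positively correlated.

## Co-localization disambiguation

When both modes are significant, promoters of DEGs-with-co-hits (± 500 bp
default flank) are compared with the lncRNA's contact peaks. Two statistics:

* **Relative distance**: each query midpoint's distance to the nearest
  flanking reference midpoint divided by the flanking gap, folded into
  [0, 0.5]; under independence r ~ Uniform[0, 0.5], so the statistic is the
  mean |ECDF(r) − 2r| deviation. Queries not flanked by two reference
  midpoints are dropped.
* **Proximity count**: query intervals within d bp of a reference interval
  (d = 0: overlap).

The null re-places each query interval uniformly within its own chromosome
(lengths and per-chromosome counts preserved; the reference stays fixed),
100 permutations, one-sided attraction alternative,
`p = (1+#{null ≥ obs})/(1+n)`. The relative-distance p is the headline
value compared against 0.01. Permuting the query set rather than resampling
the reference is simpler than full ECDF-permutation machinery and is valid
(conservative) under the uniform-placement null.

## Decision rule

`co` iff only the co mode is significant; `post` iff only post; both
significant → `co_via_coloc` when the co-localization p < 0.01, else
`ambiguous` (also when no peak data is available, with a warning); neither →
`none`. The rule is total and deterministic; an exhaustive case test covers
it.

## Cross-experiment statistics

Overlap p-values are exact hypergeometric tails over a universe of 45 480
genes — the sum of the GENCODE v35 protein-coding (19 954), long non-coding
(17 957) and small non-coding (7 569) gene counts. The default tail is the
strictly-greater convention `P(X > k)` matching R's
`phyper(k, ..., lower.tail=FALSE)` calling pattern used for the published
2-of-7 overlap (p = 0.0136); `tail="ge"` gives the conventional P(X ≥ k).
Concordance counts shared DEGs with log2FC strictly below zero in every
experiment (126 of 219 → 57.5 %).

## Synthetic data: what it emulates and what it does not

The generator emulates an ASO-knockdown screen with promoter-level readout:

* **Genome/genes** — i.i.d. bases at a configurable GC content (default
  0.5); non-overlapping genes on random strands; first exon 150–300 bp and
  first intron ≥ 850 bp so that exon1+intron1 spans the 1 kb nascent
  window — the structural fact that makes the two planted modes separable;
  later exons 150–400 bp, introns 200–600 bp.
* **Planted signal** — the lncRNA (default 2 000 nt) carries, per true
  target (default 8), a segment that is the reverse complement (per-base
  mutation rate 0.05) of a 40 nt window of the target: wholly intronic
  inside the first 1 kb for co mode (present in the nascent target, absent
  from the mature transcript), junction-spanning with only ~1/5 in exon 1
  for post mode (contiguous in the mature transcript, broken — and mostly
  outside — the 1 kb genomic window). Segments are placed in disjoint
  blocks of the lncRNA.
* **Knockdown table** — true targets draw log2FC ~ N(−1.5, 0.5) (knockdown
  of an activator: targets go down), others ~ N(0, 0.3); one threshold (the
  1−0.05 null quantile of |log2FC|) flags both, so false-positive DEGs
  contaminate the table at the nominal 5 % rate. The effect-size defaults
  are calibration choices for a clearly-detectable screen, not measured
  values.
* **Contact peaks** — one 200 bp peak within ±300 bp of the TSS for a
  fraction (default 0.8) of true targets, plus 50 uniform background peaks.

Each of the four generators consumes its own RNG stream derived from the
master seed by a fixed offset, so regenerating one artifact never perturbs
the others; all outputs are byte-deterministic given the seed.

Not emulated: real genome composition (repeats, isochores, GC structure),
CAGE count noise, ASO off-target effects, multi-promoter genes and
alternative isoform usage (the simulator writes one transcript per gene;
multi-isoform logic is exercised by hand-built fixtures), and any
cell-type specificity of contacts. Passing tests therefore demonstrate the
statistical machinery is calibrated and the mode separation works when the
signal is as planted — not that real screens carry signal of that strength.

## Numerical choices and degenerate inputs

* Significance is attached to the single best hit per pair; downstream
  statistics are per-promoter.
* Scores ≤ 0 (or pairs without seeds) get p = 1; p-values are floored at
  the smallest positive double.
* A degenerate calibration (all null maxima equal) is an error advising a
  larger sample.
* Hypergeometric inputs are validated (k ≤ min(n, K), K, n ≤ N).
* GSEA requires a non-empty DEG subset of the scored promoters and
  n_perm ≥ 100; permutation co-localization requires n_perm ≥ 10 and
  intervals no longer than their chromosome.
* Result tables are written with headers in sorted order; the run manifest
  records every parameter and seed, making output trees byte-reproducible.

## Problem sizes used in the checks

The planted-mode recovery experiment runs 50 co- and 50 post-planted
knockdowns at 25 genes / 6 true targets each with 60-shuffle calibration and
500 GSEA permutations; the type-I experiment permutes DEG labels 500 times
over a 120-promoter null screen; null-uniformity uses an 800-shuffle
calibration validated on 500 fresh pairs; oracle agreement uses 200 planted
pairs ≤ 60 nt; co-localization uses 10 fully-planted targets (floor 1/101)
and 100 independent-peak replicates. These sizes were chosen to give the
binomial/KS checks comfortable resolution on a single CPU.

## Known limitations

* Gapless duplexes only: bulged or looped hybrids are approximated by their
  best ungapped core, and the brute-force oracle is exact only under that
  restriction.
* The wobble stack constant and mismatch penalty are bundled simplifications;
  absolute ΔG values should not be compared against folding software, only
  ranks and calibrated p-values consumed downstream.
* The background universe is the knockdown table itself; if the caller's
  table omits untested promoters, enrichment is conditional on that choice.
* Exact-TSS promoter grouping does not merge CAGE clusters a few bases
  apart; the caller's GTF is expected to encode the intended grouping.
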