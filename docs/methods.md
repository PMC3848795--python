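# Methods

## Problem setting

Given an undirected PPI graph G = (V, E, W) whose vertices are proteins
(weights w_{i,j} > 0 are interaction confidences), a table of pairwise
sequence-similarity scores s_{x,i} ≥ 0 (self-similarity fixed to zero),
and multi-label annotations y_i over m function terms (y_{ij} = 1 when
protein P_i carries function F_j), the task is to produce, for each
unannotated query protein, a full ranking of the m candidate functions.
Function prediction is treated as multi-label throughout: a neighbour
carrying three functions votes for all three, and the output is a
ranking rather than a single call.

## Network enrichment

For each protein x, the k proteins with the highest strictly positive
similarity scores become x's *implicit* neighbours, with the scores as
edge weights. Design choices:

- **Directed neighbourhoods.** x's implicit neighbourhood is exactly
  x's own top-k: an incoming relation (x in y's top-k) does not add y to
  x's list, keeping |N_x^s| ≤ k and the per-query weight vector well
  defined. `enrich(..., reciprocal=True)` provides the undirected
  variant (lists may then exceed k).
- **Zero-score neighbours are never added**, even when fewer than k
  positive scores exist: a zero-weight edge casts no vote and would only
  distort the normalizer.
- **Ties at the k-th rank** break by ascending protein identifier —
  arbitrary but reproducible.
- **Channel separation.** An implicit edge duplicating an explicit edge
  is kept in both channels; the λ mixture (below) handles the overlap,
  whereas merging would silently change both normalizers.
- Implicit edges may reach proteins absent from the PPI graph; the
  enriched network is defined over the union of identifiers.

k = 0 ("Origin") reproduces the bare network exactly; this equivalence
is asserted bit-for-bit against an independent explicit-only voting
implementation in the test suite.

## Weighted voting

The probability that query x carries function F_j combines the two
channels with a mixture weight λ ∈ (0, 1):

    P_x^j = λ (1/Z_x^s) Σ_i f_{i,j} s_{x,i}  +  (1−λ) (1/Z_x^w) Σ_i f_{i,j} w_{x,i}

with each sum over the *currently assigned* neighbours of that channel
and each Z normalizing its channel's term to sum to one over the m
functions — the only normalization under which a_x = [P_x^1 … P_x^m] is
a probability distribution. Multi-label neighbours contribute their
full weight to every function they carry (f_{i,j} is a per-function
indicator, not a share); a per-neighbour normalization variant was
rejected because it changes what Z measures.

**Degenerate channels.** If a channel has no assigned neighbours its
term is dropped and the other channel's coefficient renormalized to 1;
if both are empty, a_x is set to a fallback prior and flagged. The
default prior is the empirical function frequency among labeled
proteins — the better-calibrated null when label frequencies are skewed,
as they are in real annotation corpora — with a uniform option.

## Gibbs-sampling collective classification

1. **Bootstrap**: every query's a_x is computed from its *labeled*
   neighbours only, then (hard-sample mode) one function is drawn from
   a_x as the query's provisional assignment.
2. **Burn-in**: B sweeps. Queries are visited in ascending identifier
   order; each recomputes a_x from the current assignments (annotated
   proteins clamped to their true labels, never resampled) and redraws
   its assignment immediately, so later queries in the same sweep see
   the update — standard sequential Gibbs.
3. **Sampling**: S further sweeps; after each query's update its rank
   vector (functions by descending P_x^j, exact ties permuted uniformly
   at random) is appended to its rank matrix M_x.
4. **Aggregation**: rank r of the final c_x is the most frequent
   function in column r of M_x excluding functions already chosen, ties
   by ascending function index; its support is the mode count / S. In
   the degenerate case where every function in a column is already
   chosen, the lowest-index unchosen function fills the slot with
   support 0.

Defaults: λ = 0.3, k = 5, B = 20, S = 100 — the operating point at
which this family of predictors performs best on real yeast and mouse
interaction data, and deliberately not re-tuned here.

Two semantics questions are genuinely open in this construction and
resolved as follows: rank vectors are recorded from the *freshly
updated* a_x within the sweep (recording before the update would lag
the chain by one sweep for no benefit), and the chain runs continuously
from bootstrap through sampling with no re-initialization between
phases. An optional **soft mode** replaces sampled assignments by the
full distribution (neighbours see fractional f values) for users who
prefer deterministic relaxation labeling; the default hard-sample mode
is the faithful Gibbs scheme.

All randomness — assignment draws and tie-breaks — flows through a
single seeded generator, making every run bit-reproducible; draws use
inverse-CDF sampling and tie-breaks use per-entry uniform keys inside a
lexicographic sort, so the exact random-stream consumption is part of
the package's reproducibility contract (the test suite replays it in an
independent step-by-step trace).

## Baselines

- **Majority**: functions ranked by the summed edge weights of labeled
  immediate PPI neighbours carrying them (unit weights recover the
  classic occurrence count).
- **Sequence kNN**: the k most similar *labeled* proteins vote with
  their similarity scores; the PPI graph plays no role. Selection is
  restricted to labeled proteins because an unlabeled near-neighbour
  casts no vote and would only displace usable ones. The kNN k defaults
  to 5, mirroring the enrichment k.

## Evaluation protocols

The quality measure is the rank-wise TP/FP ratio. At rank i, TP_i
counts queries whose i-th ranked call is a true function, FP_i the
rest, so TP_i + FP_i is always the number of queries — every query is
scored at every evaluated rank, and a query with fewer true functions
than the depth necessarily contributes false positives at the deeper
ranks. FP = 0 yields an explicit +inf sentinel (undefined ratio, never
silently dropped; NaN when TP = 0 too). The number of evaluated ranks
is ⌊mean functions per annotated protein⌋ + 1.

- **Leave-one-out**: each annotated protein is held out and
  re-predicted via the bootstrap step only (with the same seeded
  tie-break machinery as the main path). The iterative phase is
  omitted because a single held-out label cannot feed back into its
  own prediction; running the chain would add sampling noise without
  information.
- **Sparsely-labeled experiments**: for each fraction p ∈ (0, 1), a
  uniform sample of ⌊p·n⌉ annotated proteins keeps its labels
  (unstratified — nothing more is specified by the protocol), all
  remaining annotated proteins are queried with the full algorithm, and
  the per-rank ratios are averaged over R seeded repeats (default 10).
  Per-run seeds derive from the base seed via seed sequences, so
  reports are reproducible and splits distinct.
- Runs are per annotation namespace: to evaluate several ontologies,
  run the tool once per annotation file.
- External predictions can be scored by reading their TSV with
  `read_predictions` and passing them to `rank_tp_fp`.

## Synthetic benchmark

The generator plants the structure the method assumes. Each of n
proteins draws 1–3 functions (count uniform in a configurable range)
from a geometric-decay frequency profile (decay 0.7 by default —
skewed, to exercise the frequency prior and tie-breaks). Explicit
edges are independent Bernoulli draws: probability p_in when the pair
shares ≥ 1 function, p_out otherwise (an overlapping planted-partition
model). Similarity scores are symmetric gamma draws with shape
`sim_dispersion` and mean `sim_signal` for sharing pairs, `sim_noise`
otherwise; only ordering and rough magnitude matter to the method, so
no attempt is made to imitate an aligner's score distribution — real
BLAST tabular output substitutes file-for-file.

Two configurations are used in the tests:

- **Recovery config** (the generator defaults): n = 200, m = 5,
  p_in = 0.3, p_out = 0.01, signal 50 vs noise 5 (shape 2). Strong
  planted structure; the full pipeline at 50% labeling recovers rank-1
  functions with mean accuracy well above 0.8 over 10 seeds.
- **Balanced benchmark** (`benchmark_config()`): n = 150, m = 8, 1–2
  labels, p_in = 0.15, p_out = 0.01 (mean degree ≈ 8, comparable to
  curated physical-interaction networks), signal 25 vs noise 5 with
  exponential dispersion. This places the experiment in the regime the
  method targets: labeled explicit neighbourhoods alone are inadequate
  under sparse labeling, and the similarity channel is informative but
  imperfect, so the two channels are complementary. On it, k = 5
  enrichment beats the unenriched network on the rank-1 ratio in ≥ 70%
  of seeded 20%-labeling runs, and λ = 0.3 outperforms both λ = 0.05
  and λ = 0.95 — neither channel alone suffices. Problem sizes
  (n = 150/200, 30 seeds for the paired studies, 20 for the λ sweep)
  keep the full statistical suite around a minute while leaving the
  effects far from the decision thresholds.

**What the synthetic data does not emulate**: scale-free degree
distributions, hub proteins, correlated experimental noise between
interaction detection and annotation quality, hierarchical term
structure, or homology that is *not* reflected in shared function.
Passing these tests therefore demonstrates the machinery is correct
and behaves as designed in its intended regime — not that any given
real dataset will show the same margins.

**Known property worth stating plainly**: when the similarity signal is
destroyed (signal mean = noise mean), the top-k edges are random yet a
populated implicit channel still receives its fixed λ share of the
vote, so enrichment with uninformative similarity consistently *hurts*
(it never helps; the paired benefit disappears). The mixture weight is
not adaptive; users whose similarity data may be uninformative should
run the Origin configuration (k = 0) or lower λ.

## Numerical choices and edge cases

- Distributions are validated to sum to 1 within 1e-9.
- Duplicate edges merge by max weight; duplicate similarity records
  (multiple HSPs per pair) collapse to the max score; self-loops and
  self-similarity are dropped on load.
- The blast6 dialect reads the bit score (column 12), which is
  non-negative and monotone in alignment quality — e-values would need
  an inverse transform to serve as voting weights.
- The informative-term filter (≥ 30 annotations, no child with ≥ 30)
  counts direct annotations by default; no true-path up-propagation is
  applied because flat annotation tables are usually already resolved.
  `propagate=True` enables GO-style up-propagation.
- Proteins lacking either interaction data or sequence information can
  be removed up front with `restrict_to_common`, which reports what it
  dropped.
- Unlabeled non-query proteins never acquire assignments and never
  vote; annotated proteins are clamped throughout.

## Limitations

- Fixed B and S with no convergence diagnostics; the chain is assumed
  equilibrated after the burn-in.
- λ and k are global constants, not learned per protein or per dataset.
- The informative-term filter understands only a flat child→parent
  table, not full OBO ontologies or evidence codes (IEA exclusion and
  vague-term removal are upstream data-preparation steps).
- Alternative implicit-edge miners (e.g. random-walk proximity) and
  flow- or module-based predictors are out of scope; the evaluation
  harness accepts their predictions as TSV for comparison.
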