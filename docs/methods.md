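# Methods

This note records the models, numerical choices and known limitations
behind `slicerank`, in the order a reader meets them: the rating engine,
the scheduler, the discretization step, the simulated-annotator
benchmark, and the statistics module.

## Rating engine

Each image carries four quantities. The *rating* is a continuous
basal–apical score on [0, 3000] (3000 = most basal pole), initialised at
1500 for every image. The *rank* is the image's ordinal position 1..N by
descending rating (ties broken by item id, so ranking is deterministic);
at initialisation, when all ratings are equal, ranks are a seeded random
permutation. The *view count* is the number of submitted batches
containing the image, and the *volatility* ∈ [0, 1] measures how much
raters have disagreed about it (0 = agreement; see below for why this
orientation was chosen).

A submitted batch of n images ordered most-basal → most-apical is
decomposed into all n(n−1)/2 unordered pairs, the earlier item of each
pair treated as the winner. Updates are classical Elo with logistic
expectation

    E = 1 / (1 + 10^((r_loser − r_winner) / s)),   s = 400,

and step K·(1−E) added to the winner and subtracted from the loser. All
pair expectations in a batch are computed from the pre-batch ratings and
then applied in a fixed lexicographic order, so the result does not
depend on the order pairs are processed (absent clipping); each pair
update is zero-sum before clipping to [0, 3000]. K is the mean of the
two items' K-factors, K(v) = K₀ / (1 + v/min_views) with K₀ = 32 — early
views move an image quickly, settled images move slowly. The *surprise*
of a pair, 1−E, is large exactly when the observed order contradicts the
current ratings, which realises the intended behaviour that a divergent
opinion produces a larger rating jump. Each member's volatility is
updated as an exponentially weighted moving average (α = 0.3) of its
batch's surprises, so unanimous re-rankings decay volatility toward 0
and contradictions drive it toward 1.

**Volatility orientation.** We use 0 = raters agree, 1 = maximal
disagreement. This is the orientation the scheduler needs (high
volatility ⇒ shown again until disagreement subsides) and the one under
which "initialised at 0" is coherent for a fresh, never-disputed image.

**Batch refit.** The online pass is a single stochastic sweep over the
comparison stream: ideal for real-time feedback, but early updates are
made against opponents whose ratings are still uninformative, and a
one-pass estimate wastes much of the ordering information in the log.
`refit_ratings` therefore re-estimates all ratings from the accumulated
event log as a Bradley–Terry maximum-likelihood fit, using Hunter's MM
iteration with a small pseudo-count ridge (0.02 fictitious wins and
losses per item) so that items with perfect records remain finite. The
fitted log₁₀-strengths are mapped back to the rating scale affinely —
centred at 1500, `elo_scale` points per decade of odds, compressed just
enough to fit inside (0, 3000). The fit is *never clipped at the
bounds*: clipping piles the most extreme items onto a single value and
destroys order resolution precisely in the basal tail where a class
boundary lives (we measured a substantial label-quality regression with
clipping). A final local-Kemenization pass sweeps adjacent pairs of the
fitted order and swaps any pair whose directly-logged majority outcome
contradicts it; this strictly reduces disagreement with the log and
settles near-ties the smooth likelihood leaves arbitrary. The refit
changes only ratings and ranks; view counts, volatilities and the event
log are untouched, and the online updates remain the engine's real-time
behaviour between refits.

## Scheduler

Batch composition balances three aims: reach the required number of
views everywhere (the stopping rule is ≥ `min_views` = 3 views per
image), revisit disputed images, and make every comparison count.

Phase 1 serves under-viewed images, lowest view-count tier first. Within
a tier the batch takes a *contiguous window of the tier in current-rank
order* at a uniformly random start, rather than a uniform subset: a
ranking batch resolves at most log₂(8!) ≈ 15.3 bits, and comparisons
between images that are already known to be far apart resolve almost
nothing, so windows spend the comparison budget on local order. At the
start of a pass the current ranks are uninformative and a window is
equivalent to a uniform draw, so nothing is assumed that is not yet
known. While under-viewed images remain, a fraction
`revisit_fraction` = 0.25 of each batch is reserved for phase 2 — this
interleaving of revisits with first passes matches the observed
operating point of pooled labelling sessions, which submit roughly a
quarter more batches than the bare minimum the stopping rule implies.

Phase 2 fills the remaining slots by weighted sampling without
replacement with weight w_unseen/(1+views) + w_volatile·volatility
(defaults 1.0 and 2.0 — volatile images need repeat views until their
label settles), multiplied by rank-proximity to the phase-1 window.
When the session is already complete there is no phase-1 seed; a pivot
is then drawn by the same weights and the batch gathers tightly around
it (proximity exponent 3). This keeps post-completion batches local,
which matters more than it may seem: with arbitrary distant batches,
specific rank-adjacent pairs can go forever without a direct
comparison, and no aggregation method can order a pair of latent
neighbours that the data never compare — with local pivots, continued
labelling eventually covers every adjacent relation.

Weighted sampling without replacement uses Efraimidis–Spirakis
exponential keys; zero-weight items are drawn (uniformly) only when
positive-weight items run out. Completion is `is_complete`: every view
count ≥ `min_views`.

## Discretization

The final ordinal ranking is converted to the three classes by two cut
points, expressed as counts: ranks 1..c₁ are too-basal, c₁+1..c₂ LV,
the rest too-apical (0 ≤ c₁ ≤ c₂ ≤ N). Cuts are calibrated from anchor
items with known absolute labels by exact minimisation of the number of
misclassified anchors. Under the contiguity rule the anchor error is
separable, errors(c₁, c₂) = F(c₁) + G(c₂), and each term is piecewise
constant with breakpoints at anchor ranks, so each cut is optimised
exactly in O(A²) for A anchors. The minimising cuts form intervals;
each boundary is placed at the *midpoint of the widest minimising
interval* (maximum margin). Flank-hugging placements systematically
shrink one class whenever anchors are sparse; the midpoint is unbiased
when anchor positions are symmetric about the true boundary. If
heavily inconsistent anchors make the two unconstrained optima cross, a
joint constrained search over breakpoints is used instead (ties: widest
LV band, then smallest c₁).

## Simulated annotators and the strategy benchmark

**Generator.** A dataset is a set of scans; a scan of n slices has
latent positions u = (i + r·jitter)/n, i = 0..n−1, with one offset
r ~ U(0,1) per scan — equally spaced slices, strictly increasing within
a scan, approximately uniform pooled. True classes come from global
boundaries at the cumulative target prevalences, default
20.0% / 72.6% / 7.4% (too-basal / LV / too-apical), matching the class
mix reported for curated short-axis stacks. Scans have 9–13 slices
(realistic stack depths averaging ~11).

**Annotators.** A rater perceives u + bias + ε with ε ~ N(0, σ²) drawn
fresh per view, and lapses with probability 0.01 (a random class in
absolute labelling; a random adjacent transposition in ranking). The
two scales are identified by the published agreement of expert
clinicians doing the absolute task: within-rater noise σ = 0.013
reproduces intra-rater κ ≈ 0.90 (two passes, same rater), and a
per-rater systematic offset with spread 0.035 lowers inter-rater
agreement to κ ≈ 0.77–0.79. A noise-only model cannot reproduce both
numbers (it forces intra = inter), which is why the bias term exists;
it encodes each rater's personal placement of the class thresholds —
about half a slice thickness at these scales. Crucially, a constant
offset shifts every image in a batch equally and therefore cancels in
orderings: absolute labels inherit each rater's bias in full, while
ranking inherits it only through the anchor calibration (where the
three raters' biases partially average out). This asymmetry, plus the
averaging of perceptual noise over ~3.8 views per image, is the
mechanism by which the ranking strategy wins the benchmark.

**Budget model.** Per-action costs are fixed by observed throughput:
5.4 s per absolute label (3,323 labels in 5 pooled hours) and 11.4 s
per ranked batch of eight (≈1,575 batches in 5 pooled hours). Both
strategies receive the same total budget. The absolute arm labels each
image exactly once (never repeated), the pool split evenly across the
raters; the ranking arm submits batches round-robin until the budget is
exhausted — the pooled sessions being modelled used their full
standardised time, with the ≥3-views rule as a floor passed along the
way (a `stop_when_complete` switch halts at the floor instead). During
the run, ratings are refitted every 20 batches and once at the end.

**Benchmark.** `run_strategy_comparison` runs both arms per replicate
on a fresh dataset with freshly drawn rater biases, discretizes the
final ranking with anchors sampled from 5% of the absolute-arm labels
(stratified so every observed class has at least one anchor), and
scores both label sets against the latent truth (Cohen's κ, per-class
accuracy, plus Spearman ρ of the recovered ranking). The default
experiment is a half-scale replica of the motivating study: 150 scans
(~1,650 slices) at a 2.5-hour pooled budget, preserving per-item
throughput of both arms (absolute arm: one view per image exactly fills
the budget; ranking arm: ≈3.8 views per image). At these calibrated
conditions the ranking arm's labels agree better with the truth (mean
κ ≈ 0.87 vs ≈ 0.85, a stable ≈ +0.02 advantage across seed batches at
100 replicates, se ≈ 0.007).

**What the simulation does and does not show.** The generator captures
the features the method is sensitive to — a shared latent axis,
contiguous classes with strong imbalance, boundary-concentrated
disagreement, rater-specific thresholds, time-limited budgets. It does
not model image content, scan-to-scan appearance differences,
within-rater drift over a session, rater skill differences, or the
downstream effect of label quality on model training; passing
benchmarks here show the labelling mechanics work as designed, not that
any particular clinical model will improve.

## Statistics

Cohen's κ is unweighted, returns exactly 1.0 for identical vectors, and
0.0 as the sentinel when chance agreement is 1. McNemar's test uses the
two-sided exact binomial on the discordant counts when b + c < 25 and
the continuity-corrected χ² statistic (|b−c|−1)²/(b+c) on 1 df
otherwise (`method` overrides the automatic choice). Note the two
branches agree closely wherever the test approaches significance, but
for balanced discordants the exact two-sided p is 1.0 while the
corrected χ² saturates near 0.84 — an intrinsic property of the
continuity correction, not a defect. Binary AUC is the normalised
Mann–Whitney U with ties counting ½. Precision/recall/F1 report 0.0
with a warning flag on empty denominators rather than raising.
Accuracy/precision confidence intervals are not computed; published
intervals for the motivating tables are reproduced only as point
values.

## Numerical and reproducibility choices

- One RNG per session (PCG64, seeded from `rng_seed`); every stochastic
  choice in the engine draws from it. Session files serialize the
  generator state, so a reloaded session continues bit-identically.
  Simulations derive all their seeds from a master seed via
  `SeedSequence`.
- Replaying a session's event log against a fresh session with the same
  config reproduces ratings bit-identically (pair order within a batch
  is fixed; expectations use pre-batch ratings).
- Rating clipping applies to online updates only (a zero-sum violation
  accepted as boundary behaviour); the batch refit rescales instead of
  clipping (see above).
- Ties in rating order are broken by item id everywhere.
- Problem sizes used in the shipped tests and the acceptance script —
  300-item noiseless recovery runs, 100-replicate half-scale
  comparisons, 150-replicate agreement calibrations — were chosen to
  exercise the full pipeline at stable statistical resolution on a
  single CPU.

## Known limitations

- The exact-recovery guarantee is empirical, not theoretical: noiseless
  annotators at the default budget recover the latent order exactly in
  every seed we tested, but a pathological schedule could in principle
  leave an adjacent pair uncompared.
- The Bradley–Terry refit assumes pairwise outcomes are independent,
  while the 28 pairs of one batch share a single perceptual draw per
  image; the fit is therefore modestly overconfident within batches.
  A Plackett–Luce fit of whole orderings was evaluated and produced
  indistinguishable rankings at higher cost, so the simpler model is
  kept.
- Anchor-based discretization inherits the mean of the anchor-raters'
  systematic offsets; with few anchors in a rare class (the apical
  class is 7.4%) the corresponding boundary estimate is the noisiest
  part of the pipeline.
- Concurrency is modelled by serialising submissions through the event
  log; there is no locking for simultaneous writers of a session file.
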