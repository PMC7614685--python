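# slicerank

Batch-ranking ground-truth labelling for ordinal image data, with a
simulated-annotator benchmark against conventional one-image-at-a-time
labelling.

## The problem

Expert labelling time is the scarcest resource in clinical machine
learning. For tasks where images lie on a single ordinal axis — the
motivating case is deciding whether each cardiac MRI short-axis slice is
*too basal*, *in the LV*, or *too apical* — the conventional approach
shows an expert one image at a time and asks for an absolute class.
An alternative is to show small batches of images and ask the expert to
*order* them along the axis. One ordering of eight images yields
8·7/2 = 28 pairwise comparisons in a few seconds, images are seen by
several experts repeatedly, and systematic differences between experts'
class thresholds cancel (ordering is invariant to a rater's personal
offset). `slicerank` is the engine for this workflow, plus everything
needed to evaluate it:

- **rating engine** (`slicerank.rating`) — per-image state
  (rating ∈ [0, 3000] with 3000 = most basal, rank, view count,
  volatility). Each submitted batch is decomposed into its unordered
  pairs and scored with classical Elo updates: the item judged more
  basal gains K·(1−E) points, its partner loses the same, where
  E = 1/(1+10^(Δr/400)) and K decays with view count. The *surprise*
  1−E of each outcome feeds an exponentially weighted *volatility*
  (0 = raters agree so far, 1 = maximal disagreement). A
  Bradley–Terry refit (`refit_ratings`) re-estimates all ratings from
  the accumulated comparison log when a better global fit is wanted
  than the one-pass online updates provide.
- **scheduler** (`slicerank.scheduler`) — composes the next batch:
  under-viewed images first (in rank-local windows, because comparisons
  between plausible neighbours carry the most information), remaining
  slots filled by weighted sampling that favours rarely seen and
  high-volatility images. Labelling is complete when every image has
  been viewed at least `min_views` times (default 3).
- **discretize** (`slicerank.discretize`) — converts the final ranking
  into the three classes by calibrating the two inflection points
  (too-basal→LV, LV→too-apical) against a small set of anchor labels:
  exact minimisation of anchor misclassifications, boundaries placed at
  the midpoint of the optimal interval.
- **simulate** (`slicerank.simulate`) — synthetic short-axis stacks
  (latent position per slice, contiguous true classes at
  20.0% / 72.6% / 7.4% prevalence) and noisy annotators (Gaussian
  perceptual noise, per-rater systematic offset, lapses), calibrated so
  simulated raters reproduce the intra-rater κ ≈ 0.90 and inter-rater
  κ ≈ 0.77 reported for expert clinicians on this task; plus the
  matched-budget comparison of the two labelling strategies.
- **metrics** (`slicerank.metrics`) — confusion matrices,
  accuracy/precision/recall/F1, Cohen's κ, McNemar's paired test
  (exact and continuity-corrected χ²), binary ROC AUC.
- **CLI** (`slicerank`) — `init`, `next-batch`, `submit`, `status`,
  `finalize`, `simulate`, `evaluate` for running real labelling
  sessions from a shell against a JSON session file.

## Worked example

```python
import slicerank as sr

# a synthetic bank of 150 scans (~1,650 slices) with known latent order
dataset = sr.generate_dataset(n_scans=150, seed=0)

# three simulated experts rank batches of 8 for a 2.5-hour pooled budget
annotators = [sr.AnnotatorModel(f"rater{i}", bias=b)
              for i, b in enumerate((-0.02, 0.01, 0.04))]
run = sr.simulate_ranking_labeller(dataset, annotators,
                                   sr.BudgetModel(total_budget=9000.0), seed=0)
print(run.n_batches, run.pairwise_comparisons,
      round(sr.ranking_spearman(dataset, run.session), 4))
# 789 22092 0.9979
```

789 batches fit the budget at 11.4 s per batch, producing
789 × 28 = 22,092 pairwise comparisons; the recovered ranking correlates
with the latent slice order at Spearman ρ = 0.9979 despite calibrated
perceptual noise. The full strategy comparison at the same budget:

```python
per_rep, summary = sr.run_strategy_comparison(sr.SimExperiment(n_replicates=20, seed=0))
print(summary[["strategy", "kappa_mean"]].to_string(index=False))
# strategy  kappa_mean
#  ranking    0.865809
#   single    0.836578
```

Label quality against the latent truth: ranking-derived labels reach
mean Cohen's κ ≈ 0.87 versus κ ≈ 0.84 for one-image-at-a-time labels at
identical annotator time — the pooled-ranking advantage the tool is
built around.

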