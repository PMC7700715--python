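# Methods

## The stopping test

Screening without replacement is hypergeometric: if `N` documents remain
when random sampling starts and `K` of them are relevant, the number `k` of
relevant documents in `n` uniform draws follows `Hypergeometric(N, K, n)`.
The reviewer sets a target recall `τ_tar` and confidence level `α`. Writing
`ρ_AL` for the relevant documents found before sampling and
`ρ_seen = ρ_AL + k`, the null hypothesis "final recall < τ_tar" holds iff
at least

    K_tar = ⌊ ρ_seen/τ_tar − ρ_AL + 1 ⌋

relevant documents remained at the start of sampling. `K_tar` is
equivalently the smallest integer `K` with `ρ_seen/(ρ_AL + K) < τ_tar`;
the package computes the floor in exact rational arithmetic
(`fractions.Fraction`) so floating-point rounding can never perturb the
boundary case where `ρ_seen/τ_tar` is an integer. At that boundary recall
exactly equal to the target counts as achieved (the alternative hypothesis
is `τ ≥ τ_tar`).

Since `P(X ≤ k)` decreases in `K`, evaluating the CDF at `K = K_tar`
maximises the p-value over the whole null region `K ≥ K_tar`; the test is
therefore valid without knowing `K`. Screening stops when `p < 1 − α`.

Conventions:

- **Degenerate nulls.** `K_tar ≤ 0` (target provably met) and `K_tar > N`
  (null posits more relevant documents than exist) leave an empty null
  region; both return `p = 0` and stop immediately.
- **Ties continue.** Both thresholds use strict `<`. Thresholds are
  `1 − α` and, for the phase switch, `1 − α/2` (0.525 at α = 0.95 — a laxer
  bar suited to a heuristic hand-over decision, not an inference). They
  are rounded to 12 decimals so that a p-value equal to the threshold at
  printed precision is treated as a tie rather than decided by binary
  representation error.
- **α is a confidence level** (0.95), not a significance level; the
  rejection condition `p < 1 − α` only makes sense under that reading.

No formal correction for the sequential application of the test is
attempted; the calibration experiment below measures the realised error
rate of the sequential procedure directly.

## Ranked quasi-sampling

For a prioritised screening sequence of length `t`, every suffix window is
scored as if it were a random sample: look-back start `i` treats the first
`i` documents as the pre-sampling phase (`N_AL = i`, `ρ_AL` = relevant
among them) and the remaining `t − i` as the sample. The decision statistic
is the minimum `p_min` over `i = 1..t−1`; windows that would begin inside
the initial random seed sample are included (they are samples too, just not
ranked ones). The public `quasi_sampling_p_sequence` computes the whole
vector in one vectorised pass and is tested against a naive per-window
loop.

Inside the simulator the criterion is evaluated after every document, so
recomputing the full vector each time would be quadratic in corpus size.
The simulator instead uses the fact that moving the window start forward
across an *irrelevant* document can only raise that window's p-value (the
sample loses one irrelevant member while the posited relevant count is
unchanged, weakening the evidence); consequently the minimum is always
attained at a window beginning immediately after a relevant document (or at
the first window). Only those candidates are evaluated — cost proportional
to the number of relevant documents seen — plus an explicit check for
windows whose posited relevant count exceeds their size (p = 0). The
incremental monitor is asserted equal to the full vector in the test suite.

## The screening workflow

`run_screening` follows the standard prioritised-screening loop:

1. **Seed sample** — `seed_sample_size` (default 200) documents drawn
   uniformly. If it contains a single class, random screening continues
   until both classes are present (classifier training is undefined
   otherwise).
2. **Active learning** — a linear SVM on term-frequency uni/bigram counts
   of the abstracts (TF-IDF available as an option) ranks the unscreened
   pool; the top `batch_size` (default 20) are screened one by one and the
   model is refit after each batch. The deliberately basic model matches
   how such criteria should be validated: their guarantees must not depend
   on ranker quality.
3. **Switch** — when `p_min < 1 − α/2`, the ranking is abandoned
   (mid-batch if need be) and the remaining documents are drawn uniformly
   without replacement. The random-sampling test's validity requires true
   random draws, so the classifier is not consulted again.
4. **Exhaustion** — the simulation screens to the last document, recording
   the first index at which each enabled criterion fired (hypergeometric
   test, quasi-sampling stop, BIR, consecutive-irrelevant heuristics) and
   the index at which the recall target was truly reached. One pass
   therefore evaluates every criterion under identical conditions.

All criteria are evaluated after every single revealed label, and recall at
a stop is computed at the exact document index, not a batch boundary.

## Metrics

For each criterion: *actual recall* at its stop, *work saved*
(`WS-SC = unscreened/N_tot` at the stop) and *additional burden* = work
saved at the true target index minus work saved at the stop, so positive
values mean screening continued beyond the target and negative values mean
a premature stop. A criterion that never fires contributes zero work saved
and recall 1. The identity `WS(target) = WS(stop) + burden` holds exactly
and is asserted on every simulated trace. Benchmark summaries (mean WS-SC,
recall-miss rate, 5th/95th WS percentiles) pool over runs within each
dataset × criterion group; miss rates quoted across datasets are pooled
over runs rather than averaged per dataset.

## Baseline-inclusion-rate analysis

The BIR procedure estimates the total relevant count as
`est = (k/n_s)·N_tot` from an initial sample of `n_s` and stops once
`τ_tar·est` relevant documents have been seen. The stop count is kept
real-valued (no rounding; the screener stops at the first integer count at
or above it), so the procedure's outcome is a deterministic function of the
sample count `k` and the three-way outcome partition can be computed by
exact summation of the hypergeometric mass of `k`:

- *recall miss*: the relevant count at the stop falls short of
  `τ_tar·K_pop` (exact attainment counts as ok);
- *no savings*: the stop count is too large to allow early stopping;
- *ok*: the rest.

Two conventions are provided for the no-savings boundary. The default
(`"symmetric"`) classes a draw as no-savings when the stop count exceeds
`K_pop/τ_tar`, making the acceptable band `[τ_tar·K_pop, K_pop/τ_tar]`
symmetric around the truth on the stop-count axis; this is the convention
under which the published three-way partition of this distribution is
reproduced. It is, however, generous at the top of the band: stop counts in
`(K_pop, K_pop/τ_tar]` strictly exceed the number of relevant documents
that exist and an end-to-end run of the procedure would screen to
exhaustion. The `"unreachable"` option uses that strict feasibility bound
(`stop count > K_pop`) and is the convention validated against a 100,000-run
Monte-Carlo of the full procedure in the test suite. For the reference
configuration (20,000 documents, 500 relevant, sample of 1,000, τ = 0.95)
the partitions are 47.0 / 29.4 / 23.5 (symmetric) and 47.0 / 36.8 / 16.2
(unreachable) percent.

## Calibration experiment

The random-sampling criterion depends only on label counts, so its error
rate is measured on simulated label streams: a scenario fixes
`(N_tot, ρ_tot, ρ_AL, N_AL)`, each replication draws the residual
population in uniform random order, the test is applied after every draw,
and the run stops at the first rejection (exhaustion guarantees one). The
false-stop rate is the fraction of replications stopping with recall below
target. The default grid uses a 20,000-document corpus with 500 relevant,
4,000 documents pre-screened, and starting recalls 0.50–0.90; 100,000
replications per scenario run in a few seconds thanks to a precomputed
rejection boundary (for each possible relevant count `j`, the smallest
sample size at which the test rejects, found by bisection) and a
segment-wise scan over the positions of the relevant documents.

Measured behaviour: the sequential procedure is *conservative* — false-stop
rates of roughly 3–4% at the 5% nominal level across the default grid,
approaching (and with very small residual relevant counts slightly
exceeding) the nominal level only when sampling starts just below the
target. The 5th percentile of achieved recall sits within 0.2 percentage
points of the target. The test suite asserts the one-sided bound
`false-stop ≤ (1 − α) + 3·SE` and the 5th-percentile property, not a
two-sided pin at 5%, since the realised rate depends on the scenario's
discreteness.

## Synthetic corpus generator

Documents are bags of tokens over a shared Zipf-weighted vocabulary
(default 500 terms); relevant documents tilt the first tenth of the
vocabulary by `exp(separability)`. `separability = 0` therefore makes the
classes identical (ranking at chance) and the default 1.0 yields the
moderate classifier quality typical of abstract screening. Prevalence is
realised exactly (`round(prevalence·N_tot)` relevant documents), abstract
lengths are Poisson with mean 40, and everything is reproducible from the
seed. What the generator does *not* emulate: duplicated and near-duplicate
records, topic drift within the relevant class, label noise, and the very
low prevalences (<1%) of some real review corpora. Calibration results on
synthetic corpora transfer to real ones only insofar as the criteria's
guarantees are distribution-free (the hypergeometric test's are; the
baselines' failure modes are structural); work-saved magnitudes do not
transfer.

## Benchmark scale

The built-in benchmark conditions are a 2,000-document corpus at 10%
prevalence with 100 independent runs — large enough that a 5% miss-rate
bound is meaningful (Monte-Carlo SE ≈ 2pp) while a full run of the suite
stays in the minutes range. The calibration experiment defaults to 10⁵
replications per scenario (SE of the false-stop rate ≈ 0.07pp); the
`--replications` flag scales this in either direction.

## Known limitations

- Sequential testing is uncorrected; the measured conservatism substitutes
  for a formal guarantee and could in principle fail for scenario shapes
  far outside the grid studied (very few residual relevant documents).
- The quasi-sampling criterion's conservatism rests on the assumption that
  ranked windows are at least as relevant-dense as random ones; an actively
  *anti*-predictive ranker would break it.
- The BIR partition's default boundary follows the published convention
  rather than strict feasibility; both are exposed and documented above.
- `train_and_rank` is a deliberately basic ranker; work-saved figures are
  lower bounds on what a tuned model could achieve, by design.
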