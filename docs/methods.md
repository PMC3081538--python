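# Methods

## The evaluation protocol

The pipeline quantifies how the composition of a classifier-combination
affects prediction of mitochondrial localization. Its unit of work is one
*tool combination*: a non-empty subset of the predictor columns of a labeled
feature table (one row per protein, values in [0, 1], mitochondrial = 1).
For each combination the protocol repeats, `n_runs` times:

1. draw a stratified test set of exactly `n_test_pos` mitochondrial and
   `n_test_neg` non-mitochondrial proteins without replacement (defaults
   100/630 out of 467/6352, i.e. a ~10% hold-out leaving 6089 training
   rows);
2. train the SVM on the complement, restricted to the combination's columns;
3. score the held-out proteins and record the confusion counts and the
   support-vector count.

Run-level sensitivity, specificity, FDR and corrected FDR are aggregated as
mean and sample (n−1) SD. The exhaustive sweep applies this to all
2ⁿ − 1 combinations, ordered by (size, bitmask).

Exact-count stratification (rather than a Bernoulli ~10% sample) is
deliberate: it fixes the test composition so run-to-run metric variance
reflects sampling of *which* proteins are held out, not how many.

## The classifier

A soft-margin RBF SVM without a bias term: f(x) = Σᵢ αᵢ yᵢ K(x, xᵢ) with
K(x, x′) = exp(−γ‖x − x′‖²). Dropping the intercept removes the equality
constraint from the dual, leaving the box-constrained QP

    max_α Σα − ½ αᵀ(yyᵀ∘K)α,  0 ≤ αᵢ ≤ C,

solved by cyclic coordinate ascent with the closed-form update
αᵢ ← clip(αᵢ + (1 − yᵢ f(xᵢ))/Kᵢᵢ, 0, C), terminating when the largest KKT
violation over a full pass drops below `epsilon`. The inner loop is
numba-compiled; f is maintained incrementally, so a pass costs O(n²). Because
scikit-learn's SVC cannot drop the intercept for kernel machines, the
unbiased solver is implemented natively; `SVMConfig(biased=True)` delegates
to `sklearn.svm.SVC` for the conventional biased formulation. The test suite
cross-checks the native solver against an independent reference: scipy's
L-BFGS-B applied to the same dual (identical labels on all points of 20
seeded ≤ 200-row instances).

Defaults (`SVMConfig`): `c = 10` (margin-violation penalty; larger C
penalizes training errors more), `gamma = 0.1` (RBF width; with ≤ 11
features in [0, 1] squared distances are O(1–10), so the kernel is smooth but
not degenerate), `epsilon = 1.0` (a deliberately loose termination
tolerance that is part of the protocol being studied; tests of solver
correctness tighten it to 1e−5 so that conclusions never hinge on
convergence slack), no class weighting despite the ~13:1 imbalance, and
`sv_fraction_limit = 0.1`: a model whose support vectors reach 10% of the
training set is flagged as overfit. Flagged runs stay in the summaries but
are counted (`n_overfit_runs`); `exclude_overfit_runs=True` drops them
instead, since discarding versus flagging is a genuinely open protocol
choice. At the degenerate limit 1.0 the gate admits even an
all-support-vector model. A decision score of exactly 0 is classified
negative.

## Metrics

Per run, from the confusion counts: SN = TP/(TP+FN), SP = TN/(TN+FP),
FDR = FP/(FP+TP), and the corrected FDR

    cFDR = (1 − SP) / ((1 − SP) + SN·q),    q = 1500/21000 by default,

which rescales the discovery error to a genome-wide prior of roughly 1500
mitochondrial proteins among 21,000 nuclear genes instead of the test
sample's much richer 100:630 mix. Conventions chosen so that aggregates over
100 runs are never poisoned: FDR := 0 when no protein is predicted positive;
cFDR := 0 when SP = 1. Note that cFDR equals the plain sample FDR exactly
when q is set to the *class odds* (positives/negatives) of the evaluation
population, not the positive fraction; the default q ≈ 1500/21000 carries
the same ≈ 7% approximation (1500/19500 would be the exact odds), which is
immaterial at these magnitudes.

Group comparisons use a Welch-type z on run-level values:
z = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂) with a two-sided Gaussian p. With 100 runs
per group the Gaussian reference is adequate and the choice of z over t is
inconsequential (t₉₈ and z differ in the third decimal of p at these
magnitudes). `gaussian_ci_halfwidth(sd)` returns the 95% half-width
1.96·sd — with run SDs around 5 percentage points, the ±10% uncertainty band
that accompanies even the best combinations.

## Synthetic data

The generator emulates the *structure* of the study feature table, not its
marginal distributions. Per protein and tool: the cell is missing with
probability 1 − `coverage`; otherwise a binary core call is drawn (rate
`tpr` for mitochondrial rows, `fpr` otherwise) and jittered,
value = clip(call + N(0, `noise_sd`), 0, 1). Correlated tools share a
per-protein latent uniform: with probability `latent_strength` a tool in a
group uses the group's uniform instead of its own, which induces positive
call correlation while preserving each tool's marginals. All draws come from
one `numpy.random.Generator` seeded by the scenario, in a fixed order, so a
seed yields a byte-identical table.

The packaged `paradox_scenario` (11 tools, 467 + 6352 proteins; exact rates
in `src/mitosweep/data/paradox_scenario.json`) has three strong complementary
tools (TPR 0.55–0.68, FPR ≈ 0.01; the two Pfam-domain-based ones share a
correlation group with latent strength 0.4), four moderate tools (TPR ≈ 0.3,
FPR ≈ 0.05), and four *detrimental* tools tagged `role: detrimental`:
TPR ≤ 0.1 matched to FPR (no class signal), coverage ≤ 0.3 (imputed to 0
elsewhere), and heavy jitter (`noise_sd` 0.45) — emulating distant-orthology
and coexpression evidence whose calls are sparse and uninformative. Their
effect is purely dilutive: with the fixed-γ RBF kernel, each signal-free
column inflates within-class distances, which erodes the minority class's
margin first. This is the mechanism by which the sweep's sensitivity-by-size
frontier rises, peaks, and then falls.

`desk_scenario` is the same architecture at desk scale — 8 tools
(3 strong / 2 moderate / 3 detrimental), 150 + 1350 proteins, evaluated with
30/270 hold-outs and 10 runs — chosen so the full 255-subset sweep completes
in minutes on one CPU while preserving the ~1:9 class imbalance and a
paradox gap several combined standard errors wide. Scenario rates were fixed
once, at design time, and are part of the packaged study conditions.

What passing tests on synthetic data do **not** show: real predictor scores
are not clipped-Gaussian around binary calls, real inter-tool correlation is
not a single shared latent event, and real detrimental tools may carry weak
anti-signal rather than none. The synthetic results reproduce the
qualitative phenomena (the paradox, the contribution separation), not the
study's real-data magnitudes.

## Reproducibility and numerics

* Every run's RNG is `SeedSequence(base_seed, spawn_key=(salt, run_index))`
  with `salt` = the subset's bitmask — collision-free, order-independent,
  hence identical results under serial and process-parallel execution.
  `share_splits=True` sets `salt = 0` so every combination sees the same
  split sequence (whether the original protocol redrew splits per
  combination is ambiguous; redraw is the default).
* Feature-table TSVs serialize floats via `repr` (shortest round-trip), so
  write∘read is the identity and repeated writes are byte-identical; the
  summaries CSV does the same.
* Missing cells are imputed to 0, the no-evidence point of the [0, 1] scale.
* Ranking ties break by (smaller subset, smaller mask); binned contribution
  tables use half-open bins, report empty bins as NaN (undefined, not 0),
  and default to 20 equal-width bins over the observed range when no edges
  are given.

## Limitations

* The exhaustive sweep is exponential by design; the implementation guards
  at 24 tools. Heuristic subset search is out of scope.
* Only the RBF kernel is implemented natively; the unbiased solver assumes
  Kᵢᵢ > 0 (true for RBF).
* The pipeline evaluates *combinations of existing predictor outputs*; it
  does not run the underlying prediction tools, and real feature tables must
  be supplied as TSV.
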