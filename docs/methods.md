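# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the test suite does and does not establish.

## Synthetic degradation model

Real storage trials run for months under controlled chambers, and trial
datasets are rarely distributable, so every stage of this package is
exercised on simulated tables whose structure mirrors such trials: one
record per day per chamber, 210 days × 3 chambers = 630 records by
default, columns for day, chamber id, temperature, relative humidity and
the six quality indicators.

Each indicator follows a saturating exponential

    x(t) = A − (A − x₀) · exp(−r t),     r = base_rate × multiplier(T)

chosen because storage curves for these indicators are monotone,
temperature-ordered and decelerating: hydrolysis/oxidation products
(fatty acid, carbonyl, peroxide value, acid value) rise toward an
asymptote as substrate depletes, while the flavour volatile
(phenylacetaldehyde) and moisture decay. Chamber rate multipliers follow
a Q10-style factor (default 2 per 10 °C around 25 °C), giving
15 °C → 0.5×, 25 °C → 1×, 35 °C → 2×, which reproduces the qualitative
ordering that a hot chamber reaches any degradation level no later than a
cold one.

Parameter defaults are anchored to the five published per-grade indicator
means: initial values are the premium-grade profile, asymptotes sit
modestly beyond the worst-grade profile (e.g. fatty acid 90 %, peroxide
4.5 mmol/kg), and base rates are set once so that a 35 °C run leaves the
premium band after roughly 40–60 days while a 15 °C run stays premium for
most of 210 days — the phase structure the grading rule table encodes.
Observation noise is additive i.i.d. Gaussian per indicator (sd chosen at
roughly 1–3 % of each indicator's dynamic range), truncated at physical
bounds (moisture > 0, all concentrations ≥ 0). Cross-indicator
correlation is not imposed through a covariance matrix; it emerges from
the shared time–temperature drive, which already yields r ≈ 0.99 between
fatty acid and peroxide value and strong negative correlation with
phenylacetaldehyde.

What the generator does **not** emulate: within-day replicate dispersion
beyond the optional replicate count, humidity-driven mold dynamics,
autocorrelated sensor noise, regime changes (e.g. chamber failures), or
any mechanistic chemistry (enzyme kinetics, antioxidant depletion).
Passing tests therefore demonstrate that the algorithms recover structure
of this idealised form; they do not certify accuracy on trial data with
assay noise, missing days, or non-exponential kinetics.

## Forecaster

**Protocol.** Features are the six indicators plus temperature and
humidity (D = 8); targets are the six indicators. Standardization
(population σ, fitted on training rows only; constant features are
flagged and mapped to zero), chronological 8:1:1 split with floored
val/test sizes and the remainder to train, 16-day windows with stride 1
built per chamber inside each partition. The published window arithmetic
(504/63/63 days → 489/48/48 end-label windows) treats the 630 records as
one chronological series; the splitter operates on whatever day axis it
is given, so both the single-series and the per-chamber reading are
available, and the pooled counts are reproduced on a 630-day series.

**Architecture.** Three RevIN modules normalise the raw window and its
two statistical channels independently. The statistical channels are the
training-span per-day median and standard deviation across chamber
records, indexed by the window's days; days outside the fitted span clamp
to its edges, freezing training statistics at inference. A learned 1×1
convolution (3 → 1 channels) fuses the planes. DSW embedding cuts each
variable's window into L/L_seg contiguous segments (default 16/4 = 4),
projects each with a shared linear map and adds a distinct
(segment, variable) position embedding; the encoder is a pre-norm
Transformer (default d_model 64, 2 layers, 4 heads, feed-forward 128,
dropout 0.1) over the 32-token grid, and a linear head maps the flattened
encoding to horizon × 6 values, which are then inverse-RevIN'd. Loss and
reported metrics are on the standardized scale (a scaler inverse returns
original units in `forecast`).

Numerical choices worth knowing:

* RevIN's ε defaults to 1e-8 and the denormalizer divides by (λ + ε), so
  the round trip is exact to well below 1e-6 for any affine parameters.
* The per-window median and variance are treated as constants in the
  backward pass; only λ and β receive gradients. This is a deliberate
  simplification — the statistics are per-instance anyway, and it keeps
  the median (a sort-based statistic) out of the gradient path.
* All tensors are float64 and every random draw (init, batching, dropout)
  comes from one seeded generator per model/run, so two runs with one
  seed are bit-identical on one machine.

Training is Adam (lr 1e-3, batch 32), early stopping on validation MSE
with patience 10 and best-checkpoint restore, default seed 2021 and
stability seed set {2021, 2026, 2031, 2036, 2041}. The neural stack runs
on `peanutstore.nn`, a compact reverse-mode autograd engine over numpy
written for this package; model sizes here (tens of thousands of
parameters, hundreds of windows) train in seconds to minutes on one CPU.

**Problem sizes in tests.** The end-to-end recovery check trains on a
noiseless 300-day simulation (so the 8-day-horizon windows fit inside the
30-day validation/test partitions) for 20 epochs, reaching standardized
test MSE ≈ 5e-5 against a 0.05 qualification bar; the five-seed protocol
runs at 3 epochs per seed because it checks reporting structure, not
accuracy. These sizes are the package's default demonstration scale.

## Clustering and grading

The autoencoder is fully connected (D → 32 → 16 → latent 2, ReLU between
layers, linear outputs, symmetric decoder). DCN optimises
reconstruction + (λ/2)·‖f(x) − M s‖² by alternating gradient updates,
hard reassignment and centroid means, re-seeding empty clusters from the
farthest assigned point; λ = 0 degenerates exactly to pretraining plus
post-hoc k-means. DEC sharpens Student-t soft assignments toward the
squared/frequency-normalised target distribution under KL, refreshing the
target every 5 epochs; zero fine-tuning epochs reproduce k-means on the
pretrained codes. K-Means++ is scikit-learn's implementation.

Silhouette is computed in-package with the a = 0 convention for singleton
clusters (an isolated, well-separated point scores 1); scikit-learn's
convention scores singletons 0, so the two agree on all non-degenerate
inputs, which the tests verify along with a brute-force double-loop
oracle. Davies–Bouldin and Calinski–Harabasz come from scikit-learn.
`select_k` sweeps K = 2..8 over seeded restarts and picks the best mean
silhouette, breaking ties toward lower DB then higher CH. K = 5 is the
operating point for grading.

The quality score projects the six standardized indicators onto PC1 of
the training records, flips the sign if needed so the oxidation
indicators load negatively (fresher ⇒ higher), and min–max normalises to
[0, 1). The five grade intervals and the storage phase table
(15 °C: premium ≤ 100 d, good ≤ 150 d; 25 °C: ≤ 60/≤ 100;
35 °C: ≤ 40/≤ 90) are fixed constants of the scheme; out-of-range scores
clamp to the extreme grades with a warning rather than erroring, since a
warehouse pipeline should degrade gracefully on unseen inputs.

## Evaluation conventions

* R² is 1 − SS_res/SS_tot about the mean of the truth; constant truth
  yields a missing R² with a reason rather than a number.
* Per-class precision with an empty prediction column is reported as 0
  with an explicit flag — the conservative choice when the cost of a
  missed deterioration exceeds a false alarm.
* Macro scores are unweighted means over classes.
* The published five-grade confusion study releases per-grade TP/FP/FN,
  row totals and two merged-policy totals, not the full 5×5 matrix; the
  matrix in `peanutstore.reference` is a synthetic completion consistent
  with every released count, and all worked-example metrics are computed
  from it at run time.
* Pearson correlations carry Benjamini–Hochberg-adjusted two-tailed
  p-values across the upper-triangle tests; paired seed comparisons use
  two-tailed paired t-tests with Holm adjustment across configurations
  and the */** marking convention; zero-variance differences are flagged
  degenerate with p = 1 instead of a spurious t statistic.

## Known limitations

* The Transformer backbone uses joint attention over the segment×variable
  token grid; factorised cross-time/cross-dimension attention is not
  implemented.
* The statistical channels assume the per-day median/std are taken across
  chambers; alternatives (rolling windows, replicates) are not built in.
* The grading thresholds are fixed constants; the percentile machinery
  that would re-derive them from new cluster structure is out of scope.
* Bit-reproducibility is per-machine (BLAS reduction order may differ
  across platforms); statistical behaviour is unaffected.
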