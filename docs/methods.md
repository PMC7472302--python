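# Methods

## Model

The estimator is a lazy (instance-based) regressor built on
Dempster–Shafer belief functions. The training set
`L = {(x_i, y_i)}_{i=1..n}` is the evidence; features are min–max
normalized to `[0, 1]` with training statistics (queries are normalized
with the same statistics and clipped), so the per-feature weights are
comparable across features. The target is assumed bounded by its observed
range `[y_inf, y_sup]`; that interval is the frame on which the ignorance
mass lives.

For a query `x`, only its `k` nearest neighbours under the weighted
Minkowski metric carry evidence (all other rows have mass exactly zero —
both a computational device, reducing a prediction from O(n^2 log n) to
O(nqk), and a locality assumption). Each neighbour's similarity is
`phi_i = exp(-d_i^2/gamma)`; Dempster combination of the simple support
functions yields the neighbour masses and the domain mass given in the
README, and the Pignistic expectation gives the point estimate with the
interval `[y_hat - m*(y_sup-y_inf)/2, y_hat + m*(y_sup-y_inf)/2]`.

Two discount variants are implemented. The default, `exp(-d^2/gamma)`, is
the form consistent with the analytic weight gradient (its derivative
contains the factor `-(2d/gamma) exp(-d^2/gamma)`); the alternative
`exp(-d/gamma^2)` is selectable as `phi_form="linear"`. The two appear
interchangeably in the evidential-regression literature; we default to the
one whose gradient we differentiate, so learning and prediction always use
the same phi.

## Weight learning

Weights start at 1 and are updated for a fixed number of epochs. Each
epoch predicts every training row from the other `n-1` rows (leave-one-out;
the target bounds are recomputed on each `n-1` subset), evaluates the MSE,
and applies the full-batch analytic gradient through the mass calculus and
the weighted metric:

    dL/dw = (2/n) sum_i (yhat_i - y_i) sum_{j in N(i)} (dyhat_i/dphi_ij) phi'(d_ij) dd_ij/dw,
    dyhat/dphi_j = (y_j - yhat) / ((1 + sum r) (1 - phi_j)^2),  r_j = phi_j/(1-phi_j),
    dd/dw_m = d^(1-p) w_m^(p-1) |x_m - x'_m|^p.

The update is a *descent* step (Adam with decay 0.9/0.999 and eps 1e-8 by
default; plain gradient descent selectable), weights are clipped to `>= 0`
after every step (the metric and the transform-space k-NN search require
nonnegative weights; zero is absorbing and means "feature removed"), and
neighbour sets are recomputed every epoch because the weights change the
metric. The loss of the all-ones start (epoch 0) and of the state after
the final update are both recorded, so `loss_history` has
`num_epochs + 1` entries and the returned weights are the evaluated state
with the smallest leave-one-out loss — the fit can never return something
worse than the untrained start.

The loss is piecewise smooth: it is differentiable wherever the neighbour
sets are locally constant and jumps when a weight perturbation swaps the
k-th neighbour. The analytic gradient is the within-piece derivative; the
finite-difference validation in the test suite therefore draws instances
whose k-th/(k+1)-th distance margin exceeds the probe step by two orders
of magnitude.

Feature selection reads the learned weights directly: features are ranked
by weight (ties by index) and those strictly above the initialization
value 1 are retained — any feature the optimizer pushed above its starting
importance earned its place.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `k` | 20 | neighbours used as evidence |
| `alpha` | 0.1 | learning rate |
| `num_epochs` | 100 | fixed epoch count (no early stopping except divergence) |
| `gamma` | auto | discount radius (squared-distance units); see below |
| `p` | 2 | Minkowski exponent, restricted to [1, 2] |
| `phi_form` | squared | `exp(-d^2/gamma)` vs `exp(-d/gamma^2)` |

`k=20`, `alpha=0.1`, `num_epochs=100` are the benchmark configuration and
serve as package defaults.

**Discount radius.** `gamma` has units of squared distance, and squared
distances between [0,1]-normalized rows grow linearly with the feature
count (about q/6 in expectation for uniform data, ~83 at q = 500), so no
absolute default can serve all tables. When `gamma` is unset it is chosen
by grid search on the training data alone: 10 log-spaced multipliers in
[1e-2, 10] of the median pairwise squared distance at unit weights (the
median heuristic familiar from RBF kernels; the median distance itself for
the raw-distance kernel), scored by leave-one-out MAE at `w = 1`, ties to
the smaller radius. The radius is then held fixed during weight learning;
as irrelevant weights shrink, effective distances contract and the
evidence sharpens, which is the intended dynamic.

## Numerical choices

- `phi` is clamped to `<= 1 - 1e-12`: two neighbours at distance zero
  would otherwise make every `(1 - phi)` factor — and hence the
  normalization constant K — exactly zero. Inside the clamp region the
  derivative is taken as 0 (the clamp is flat).
- The reference mass routine computes the exclusion products
  `prod_{h != i}(1 - phi_h)` with prefix/suffix cumulative products, never
  by dividing a total product, so a zero factor poisons only the terms it
  belongs to.
- The vectorized trainer uses the algebraically identical odds form
  `m_i = r_i / (1 + sum r)`, `r_i = phi_i/(1 - phi_i)`, which is
  well-defined under the clamp and gives the compact sensitivity
  `dyhat/dphi_j` above; agreement between the scalar and vectorized routes
  is asserted in the tests.
- The kernel baseline's weights `exp(-d_j/beta)` are computed relative to
  the row-minimum distance (the shift cancels in the normalized mean) so
  the normalizer cannot underflow.
- k-NN ties are broken by ascending row index (stable sort); search is
  exhaustive and exact. The `|delta|^p` tensor is precomputed per fit when
  it fits in ~2 GB and recomputed in row chunks otherwise.
- Training aborts with the last finite state only if the loss turns
  non-finite; otherwise exactly `num_epochs` updates run.

## Synthetic benchmarks

The generator emulates the two published benchmark families rather than
any real claims data: (a) a random sparse linear model — Gaussian design,
5 informative coefficients on the leading columns, additive N(0, 1) target
noise — via scikit-learn's `make_regression`; (b) Friedman #1 — all
features uniform on [0, 1], response
`10 sin(pi x0 x1) + 20 (x2 - 0.5)^2 + 10 x3 + 5 x4` plus N(0, 1) noise —
via `make_friedman1`. Presets cover 200 and 5000 samples with 500 total /
5 relevant features. With `scale_output` the target is min–max scaled to
[0, 1] over the generated sample; cross-validation folds reuse this
full-sample target scaling (so fold errors share units) while feature
normalization is re-derived per training fold.

What passing on these generators does *not* show: robustness to the
skewed, zero-inflated, partly categorical structure of real cost data
(log-transformed targets, median-imputed exams, ICD-coded flags). The
`--log-target` and `--impute-median` options exist for such tables, but no
real-data claim is made here.

## Evaluation protocol and problem sizes

Accuracy numbers use k-fold cross-validation repeated with fresh shuffles
(5 folds x 5 repetitions = 25 validations), reporting the median and
standard deviation across folds. All hyperparameter selection (the gamma
grid) happens inside each training fold. MAPE is available but undefined
at zero targets, which min–max-scaled targets always contain, so the
default metric set is MAE and R^2.

The reproduction script runs the 200-sample presets (500 features) — each
completes a full 5x5-fold run with 100-epoch weight learning in about half
a minute to a minute on one CPU. The 5000-sample presets are provided as
presets and CLI targets but are quadratic-memory/time heavier and are not
part of the scripted reproduction; the feature-recovery study uses
Friedman at n=200, q=50 over three seeds.

## Known limitations

- Predictions are bounded by the observed target range; extrapolation
  beyond `[y_inf, y_sup]` is impossible by construction.
- The leave-one-out objective is O(n^2 q) per epoch; beyond a few thousand
  rows, training cost grows steeply.
- The learned metric is diagonal: correlated or interacting features share
  no cross-terms.
- Interval calibration is not guaranteed: `m*` measures evidential
  sparsity, not a frequentist coverage level.
- On the Friedman family the weakest (quadratic, centred) signal `x2` is
  often assigned weight 0 at n=200 — a sample-size effect visible in the
  README example.
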