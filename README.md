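# wevreg — weighted evidential regression

`wevreg` implements an interpretable k-nearest-neighbour regressor grounded
in Dempster–Shafer belief-function theory, aimed at tabular prediction
problems — the motivating application is forecasting individual health-care
costs from claims histories — where practitioners need three things at
once: a point prediction, an honest per-query uncertainty interval, and a
ranking of which features actually drove the answer.

## The model

Training examples `e_i = (x_i, y_i)` form an evidence set. For a query `x`,
each of its `k` nearest neighbours contributes evidence discounted by
distance through an RBF similarity

    phi_i = exp( -d_w(x, x_i)^2 / gamma ),

where `d_w` is a per-feature weighted Minkowski distance
`d_w(x, x') = ( sum_j |w_j (x_j - x'_j)|^p )^(1/p)` with `p` in `[1, 2]`.
Combining the discounted evidence with Dempster's rule gives each neighbour
a mass

    m_i = (1/K) phi_i prod_{h != i} (1 - phi_h),

plus a *domain mass* `m* = (1/K) prod_i (1 - phi_i)` assigned to the whole
observed target interval `[y_inf, y_sup]` — the model's ignorance about the
query. The Pignistic transform turns the masses into a prediction with
bounds:

    y_hat   = sum_i m_i y_i + m* (y_inf + y_sup)/2,
    y_lower = sum_i m_i y_i + m* y_inf,      y_upper = ... + m* y_sup,

so the interval width `m* (y_sup - y_inf)` directly reports how far the
query sits from all available evidence.

The weights `w` (initialized at 1) are learned by minimizing the
leave-one-out mean squared error with its analytic gradient (Adam, fixed
epoch count); because a weight scales a feature's contribution to every
distance, the learned `w` doubles as a feature-importance profile, and
thresholding at the initialization value (`w_j > 1`) is an embedded
feature-selection rule. A kernel-weighted k-NN baseline
(`y_hat = sum_j y_j e^{-d_j/beta} / sum_j e^{-d_j/beta}`) shares the metric
and the learning loop, isolating the contribution of the mass calculus.

## Worked example

Generate a 200-sample Friedman benchmark (50 features, only the first five
enter the response, noise sd 1), fit the evidential model, and inspect the
learned feature ranking:

```bash
$ wevreg generate --family friedman --n 200 --q 50 --seed 0 --out friedman.csv
wrote 200 x 50 friedman table to friedman.csv
$ wevreg fit --data friedman.csv --estimator wevreg --out model.json
fitted wevreg (gamma=84.6918) on 200 rows; model written to model.json
$ wevreg select-features --model model.json --top 7
feature                       weight
f0                            3.2845
f1                            2.9543
f3                            2.5578
f4                            1.5751
f2                            0.0000
f5                            0.0000
f6                            0.0000
selected 4 of 50 features (weight > 1.0)
```

Four of the five truly relevant features (`f0, f1, f3, f4`) earn weights
well above 1 while all 45 noise features are driven to exactly 0; `f2`,
whose quadratic term contributes least signal, is the usual miss.
Cross-validated accuracy on the same table:

```bash
$ wevreg evaluate --data friedman.csv --estimator wevreg --repetitions 2
mae: median 0.0774 +/- sd 0.0051
r2: median 0.7545 +/- sd 0.0399
```

i.e. a median absolute error of about 0.08 on the [0, 1]-scaled target.
`wevreg predict` emits `y_hat, y_lower, y_upper, uncertainty` per row — the
interval is a first-class output, not an option.

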