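# Methods

This note documents the model and the numerical and design choices behind
`dbncs`, in the order the pipeline runs.

## Model and assumptions

The target object is a time-delayed GRN: a directed graph over genes plus an
integer delay per edge, interpreted as a dynamic Bayesian network whose
transition structure connects slice *t* to slice *t + delay* only (first- to
k-th-order Markov, stationary across the series). The data model throughout
is jointly Gaussian expression: all information-theoretic quantities are
computed through their Gaussian closed forms (correlation determinants and
traces), never through histogram or k-NN estimators. This is exact for
linear-Gaussian dynamics and a standard working approximation for log-scale
expression data. Time points must be equally spaced and chronological;
delays are integer multiples of the sampling interval. Replicates and
irregular sampling are out of scope.

## Gaussian information kernel

* `MI(X;Y) = −½ ln(1 − r²)`, natural log (all values in nats).
* `CMI(X;Y|Z) = ½ ln(|C(X,Z)||C(Y,Z)| / (|C(Z)||C(X,Y,Z)|))` on the sample
  correlation blocks.
* `CMI2(X;Y|Z)` is implemented from its defining decomposition
  `½[KL(P‖P_{X→Y}) + KL(P‖P_{Y→X})]`, where `P_{X→Y}(x,y,z) =
  P(x,z)·q(y|z)` and `q(y|z) = ∫P(y|x,z)P(x)dx` is the conditional with the
  X→Y edge severed. For a joint Gaussian, `q` is again Gaussian: its
  regression on z keeps only the z-coefficients of the joint (x,z)
  regression, and the variance explained by x moves into the conditional
  variance. Both KL terms therefore have closed forms in the joint
  covariance, yielding the familiar ¼(tr + tr + ln + ln − 2n) expression
  with the interventional covariances in the role of the inverse block
  matrices. The published typography of those block matrices is internally
  inconsistent (inverse exponents attached to whole blocks, covariance and
  correlation symbols mixed); the implementation is therefore anchored to an
  independent oracle — a Gauss–Hermite-quadrature + Monte-Carlo evaluation
  of the defining KL decomposition (`tests/oracles.py`) — and the test suite
  and acceptance script verify agreement within Monte-Carlo error on
  hundreds of random Gaussians.

Numerical choices: correlation matrices get a ridge of 1e−8 on the diagonal
before factorization; determinants are computed as log-determinants via
Cholesky; results are clamped at 0 against round-off; a constant input
raises an explicit degenerate-input error rather than returning 0, because a
silent zero would invisibly delete a true edge downstream. MI and CMI2 are
made *bit-exactly* symmetric in (x, y) by canonicalizing the argument order
before any floating-point work.

## Skeleton learning

Path-consistency over CMI2: order 0 thresholds plain MI at θ; order L ≥ 1
conditions on all C(T, L) subsets of the common neighbours of the two
endpoints, aggregated by maximum (default) or geometric mean, and removes
the edge when the aggregate falls below the same θ. Each order is swept to a
fixed point before L increments (the published loop statement is ambiguous
between per-order and global repetition; per-order is implemented as the
reproducible reading), edges are visited lexicographically, removal is
permanent, and the loop ends when no surviving edge has enough common
neighbours. When C(T, L) exceeds 10,000 the enumeration is capped to the
strongest-connected candidates with a warning.

θ is the method's per-dataset hand-set parameter. A practical calibration is
the ~90th percentile of the null MI for the series at hand, which depends
strongly on autocorrelation: for two independent smooth series the variance
of the sample correlation is ≈ (1 + 2a²/(1−a²))/T for AR(1)-like
autocorrelation a, so 50 smooth points behave like 5–15 independent ones.
The package default θ = 0.15 corresponds to that percentile for the 50-point
synthetic benchmark; long or weakly autocorrelated series warrant values an
order of magnitude smaller (hundredths of a nat).

## Recursive optimization

LAD + L1 regression per target gene, solved exactly as an LP (variables
u, v, ξ, η ≥ 0 with u−v the residual and ξ−η the coefficient; HiGHS
backend). Both the target and the regressor columns are z-scored first so
that the pruning threshold θ₀ is comparable across genes. Defaults: λ = 1.0
(the convention of the recursive-optimization literature this stage
follows), θ₀ = θ (the pair-clique rule), at most 20 threshold-and-refit
rounds (a termination guarantee; convergence is typically 1–3 rounds).
An undirected edge survives when *either* direction's strength is non-zero —
direction is decided later, and and-pruning would delete true edges whose
reverse fit happens to be weak. Dropped coordinates are exactly 0.

## Delays and the transcriptional regulation score

The delay for each ordered pair is the shift m ∈ {1..k} maximizing the MI of
the recombined pair `(x[0..T−m−1], y[m..T−1])`; ties break to the smallest m
(parsimony). Delays are estimated independently in both directions, so the
delay matrix is generally asymmetric. Default k = 5.

TRS is computed on the delay-recombined series. The printed summation range
of its definition indexes past the end of the series; the sum is truncated
to the T−2 steps where all terms exist. A zero target step contributes
nothing and does not count toward the normalizer N_IC (which counts target
changes only — the target-only reading of an ambiguous definition); if the
target never changes, the statistic is undefined and the caller substitutes
0 with a warning. A `change_eps` tolerance (default 0, exact inequality)
lets small fluctuations count as "no change" on noisy data. Note that
between two continuous noisy series every regulator step is a "change", so
TRS carries little directional information there; it earns its weight on
data with flat stretches (saturated or switch-like expression).

## Scoring and orientation

The three components entering the comprehensive score are min–max
standardized over the population of all 2D candidate ordered pairs (both
directions of every clique), computed once per run; an all-equal component
maps to 0.5. `CS = σ(ω|β^RO| + (1−ω)β^MI)² + (1−σ)TRS²` with σ = 0.6 and
ω = 0.5 by default (σ = 1 ignores dynamics — the static-data setting). The
MI component is the delay-aligned MI of the candidate direction, which is
what makes the two directions distinguishable. Cliques are gene pairs by
construction, so orientation is a two-way CS comparison; exact ties break to
the lexicographically smaller regulator and are flagged. Feedback pairs are
not representable within one run's prior network; ties and both-degenerate
cases are flagged in the output. For ROC ranking, removed pairs score 0 and
both directions of surviving pairs keep their pre-tie-break CS.

## Synthetic benchmark

`simulate` plants a uniformly random DAG (exact edge count over a random
topological order), delays uniform on {1..k_max}, signed coefficients with
|w| ∈ [0.4, 0.9] (the lower bound keeps planted edges away from the
identifiability boundary). Root genes follow AR(1) with coefficient 0.8 and
unit stationary variance; regulated genes are delayed weighted sums of their
parents plus N(0, 0.2²) noise; k_max + 10 burn-in steps are discarded.
Defaults: 10 genes, 10 edges, T = 50, k_max = 3.

The root smoothness embodies a sampling-design rule: a zero-lag skeleton
stage can only see a delayed edge through the regulator's autocorrelation at
that lag, so the signal should decorrelate over roughly the maximum
regulatory lag (0.8³ ≈ 0.5). Linear-Gaussian kinetics are chosen so the
Gaussian closed forms are exact in distribution and oracle tests are sharp;
a tanh variant exists behind the `dynamics` flag for robustness checks. What
the generator does **not** emulate: measurement error models, feedback
loops, perturbation/knockout designs, replicate structure, and non-Gaussian
marginals — passing tests show algorithmic correctness on the stated model,
not performance on microarray data.

## Known limitations

The binding constraint on recovery is the zero-lag MI screen of the skeleton
stage: on delayed data, true-edge zero-lag MI and spurious smooth-series MI
overlap heavily at T = 50 (separability worsens both when sampling is much
faster and much slower than the regulatory lags), and an edge removed at
order 0 can never return. Orientation and delay estimation, by contrast, are
reliable once a pair survives: on the default benchmark the pipeline's
direction accuracy on recovered true pairs and the delay accuracy on
correctly directed edges are both high (see `scripts/acceptance.py`
output), while overall edge recall — and hence MCC — is modest. Users with
longer series or sampling matched to the dominant lag can expect
substantially better recall; θ should always be re-calibrated to the
dataset.
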