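# Methods

## Model

The simulated circuit is a feedforward single-hidden-layer network. Inputs
`x` are `p`-dimensional (mossy-fiber channels), the hidden layer has `m`
units (granule cells, the resource constraint), and the output is a scalar
read out by a linear unit (Purkinje cell). Two hidden-layer families are
compared:

- **Kernel expansion.** Unit `j` evaluates an isotropic Gaussian kernel
  `k(x, x_j) = exp(-||x - x_j||^2 / (2 sigma_j^2)) / (sqrt(2 pi) sigma_j)`
  centered on a stored training sample `x_j`. The squared deviation is the
  squared Euclidean norm over *all* input dimensions, and the 1-D
  normaliser `1/(sqrt(2 pi) sigma)` is kept in every dimension; the
  normaliser is a positive constant per unit and is absorbed by the readout
  weights, so classification is invariant to this choice (serialised kernel
  values are not, which is why it is fixed and documented). All widths are
  `sigma_j = 1`.
- **Random projection (control).** Unit `j` computes
  `f(w_j . x + b_j)` with `w` entries i.i.d. N(0, 3^2) and `f` either the
  identity (linear control) or ReLU (nonlinear control; tanh available).
  Hidden biases are drawn from the same N(0, 3^2) family: without bias
  diversity every ReLU unit would hinge at the origin and the control would
  be artificially weak.

**Readout.** Weights are the closed-form solution of the ridge-stabilised
least-squares problem on mean-centered hidden features:
`alpha = (Hc' Hc + ridge I)^{-1} Hc' y`, `bias = mean(y)`, solved by
Cholesky factorisation of the normal equations (never an explicit inverse);
a rank-deficient system with `ridge = 0` raises instead of silently
pseudo-inverting. The default `ridge = 1e-8` exists purely for numerical
stability: Gram matrices of strongly overlapping Gaussian kernels are
routinely ill-conditioned at `m = 100`. Labels are coded {-1, +1} so the
sign decision rule is symmetric; a score of exactly 0 maps to +1.

## Synthetic task generator

Each task is a mixture of `2K` isotropic Gaussian clusters
(`K` per class, `K` in {2, 5, 25}) whose centers are drawn i.i.d. uniform
over the unit square — the simplest bounded layout; class entanglement is
controlled by `K`. Center classes are assigned uniformly at random with
both classes guaranteed present. A sample picks a cluster uniformly, adds
N(0, sigma^2 I) noise, and receives the label of the **nearest center**,
not of its generating cluster — this is what entangles the classes as
clusters crowd together. Labels are then flipped independently with
probability 0.05; irrelevant dimensions are appended as i.i.d. uniform
draws spanning the declared relevant range (a distributional statement, so
train and test stay exchangeable); the nearest-center metric is computed in
the relevant subspace *before* augmentation. The split is a 70/30 random
partition.

The cluster spread defaults to `sigma = 0.5 / sqrt(2K)`: the spread shrinks
with cluster count so that neighbouring clusters overlap moderately at
every `K` and task difficulty rises smoothly with `K`. The generating
cluster index is retained as diagnostics metadata but never shown to
models.

What the generator does *not* emulate: temporal structure in the inputs,
more than two classes, anisotropic or heteroscedastic clusters, and
structured (non-uniform) nuisance dimensions. Passing tests therefore
demonstrate regime behaviour on static, spatially clustered binary tasks
only.

## Selection regimes

All regimes return *row indices* into the training matrix, so every center
is bit-identical to a training sample, and all use Euclidean distance over
all input dimensions — regimes receive no oracle knowledge of which
dimensions are relevant; that asymmetry is the point of the experiment.

- **random** — `m` rows uniformly without replacement.
- **regular** — each dimension is binned into `ceil(m^(1/p))` equal bins
  (read as bins-per-dimension: the only reading that yields at least `m`
  Cartesian coordinates); bin midpoints form the coordinate pool;
  `n_subsets` random `m`-subsets of the pool are drawn and each coordinate
  snapped to its nearest training sample. Snapping is greedy in sorted
  coordinate order so colliding coordinates fall through to the
  next-nearest unused sample and each subset stays distinct. Evaluation
  averages accuracy over the subsets; the shared-Gram fast path computes
  kernel columns once for the union of snapped rows and solves each
  subset's readout from the corresponding Gram submatrix (algebraically
  identical to fitting each subset separately).
- **frequency** — an axis-aligned lattice with `v` bins per dimension
  (cells half-open, last cell closed, out-of-range samples clipped to the
  boundary cells; bounds are the declared relevant range extended to all
  dimensions); the `m` most populous cells win, ties broken by
  lexicographic cell index for determinism; within each winning cell the
  sample nearest the cell centroid becomes the center.
- **kmeans** — k-means with `m` clusters (k-means++ init, 300-iteration
  cap, tol 1e-4, labels unused), each centroid snapped to the nearest
  unused training row.
- **support_vector** — an RBF soft-margin SVM (C = 1, gamma matching the
  regime kernel width) is fit and its support vectors ranked by absolute
  dual coefficient (the samples most responsible for the margin); the top
  `m` become centers, with any shortfall filled by the unchosen samples
  nearest the decision surface. For training sets above 2,000 rows the SVM
  is fit on a seeded 2,000-row subsample (the solver cost is quadratic in
  rows); chosen centers are still exact rows of the full training set and
  the fill rule evaluates the decision function on all rows.
- **novelty** — the dictionary starts from one random training sample;
  samples stream in random order; the current model (kernel layer on the
  dictionary, readout refit on all samples seen so far) predicts each
  arrival, and the sample is admitted when its absolute prediction error
  exceeds `delta` (the stateless classical novelty criterion; the literal
  "error increased by more than delta since the previous sample" variant is
  available as `novelty_rule="error_increase"`). When the dictionary would
  exceed `m`, the center with the smallest |readout weight| is pruned. The
  readout is refit on every dictionary change via running Gram statistics
  (rank-1 updates per sample, one column update per admission), which is
  algebraically identical to refitting on all seen samples but keeps the
  stream linear-time in practice.

**Hyperparameter search.** `v` (frequency) and `delta` (novelty) are chosen
by grid search — `v` in {4, 8, 16, 32}, `delta` in {0.1, 0.25, 0.5, 1.0} —
on an 80/20 validation split carved from the training set; the test set is
never touched. Grid values that make the lattice degenerate are skipped;
ties go to the smaller value. The novelty search streams at most 1,000
samples per candidate to bound cost; the winning `delta` is then used on
the full training stream.

## Experiment grid and problem sizes

A condition crosses `K` in {2, 5, 25}, `m` in {5, 20, 100} and irrelevant
dimension counts {0, 2, 6} (relevant proportions 2/2, 2/4, 2/8, bracketing
the named 2-of-4 case). Two scales exist: `paper`
(n = 100,000, `n_subsets` = 1,000) and `desk` (n = 5,000,
`n_subsets` = 200), the package's scaled-down default for the test bench
and the acceptance script; the desk scale preserves every qualitative
contrast at workstation cost, and 10 replicate seeds are used wherever a
stochastic claim is made. All randomness flows through named substreams of
a master seed (CRC-tagged `SeedSequence`s), so the dataset draw at a given
seed is identical across regimes, and every run is exactly repeatable.

Rankings: within each condition group, regimes are ranked by mean test
accuracy across seeds (ties broken by lower across-seed variance, with the
mean rounded at 1e-12 so float noise cannot defeat the tie rule); the grand
mean rank averages a regime's rank over all groups.

Under 5% symmetric label noise on both splits, expected test accuracy is
bounded by `0.95 + 4 sqrt(0.95 * 0.05 / n_test)`; the experiment asserts no
run exceeds it.

## Known limitations and open choices

- Kernel widths are fixed, not adapted to local data density; adaptive
  widths would likely sharpen every regime on the high-`K` tasks.
- Full label inversion is *not* a usable probe of task-dependence: both
  task-dependent regimes are exactly invariant under it (sign symmetry of
  the SVM dual and of the readout error), so the tests probe
  task-dependence with label permutations instead.
- The regular regime's estimator-facing `fit` uses the first coordinate
  subset as its concrete model; the subset-averaged figure lives in the
  experiment runner, matching how the regime's published number is defined.
- Exact interpolation with `sigma = 1` kernels requires the data spread to
  be large relative to the width; on the unit square the full-dictionary
  Gram matrix is near-singular and only the ridge keeps it solvable.
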