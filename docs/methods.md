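# Methods

This note documents the models and numerical conventions behind
`smdqsar`: a library for designing compound sets by statistical molecular
design (SMD), screening descriptor covariance, fitting and validating PLS
structure–activity models, and benchmarking them against null models.

## Statistical molecular design

A candidate molecule is one fragment choice per variable position of a
combinatorial library (positions such as pIa/pIb/pII/pIII). Candidates are
encoded as binary fragment indicators ("conditional descriptors"), one
column per fragment. A D-optimal subset of size *n* maximises
det(Xsel′Xsel) on the indicator matrix after centering and unit-variance
scaling over the whole candidate set, which spreads the selected molecules
so that fragment effects vary as independently as possible.

Numerical conventions:

* **Encoding.** Under the full one-column-per-fragment encoding, each
  position's block sums to 1 in every row, so the centered blocks are
  exactly collinear and det(Xsel′Xsel) = 0 identically. Optimisation and
  the condition number therefore default to a *reduced* encoding that
  drops one reference fragment per position; this does not change the
  subset ranking, and reports keep full-encoding names. A `full` option
  uses the pseudo-determinant over eigenvalues above a relative tolerance
  of 1e−9 instead.
* **Search.** Classical Fedorov exchange: from a random subset, repeatedly
  apply the single swap with the largest determinant ratio
  (1 + d_jj)(1 − d_ii) + d_ij², where d_ab = x_a′M⁻¹x_b on the current
  information matrix M, until no swap improves; the best of `n_starts`
  restarts (default 50) wins, ties broken on the lexicographically
  smallest index set. A ridge of 1e−8 on M stabilises ranking during the
  search and is never part of the reported log-determinant (singular
  selections report −∞). One integer seed drives all restarts.
* **Diagnostics.** Condition number = ratio of largest to smallest
  singular value of the selected matrix, re-autoscaled over the selected
  rows (1 for an orthogonal design, below ~3 considered acceptable, +∞
  when singular); fragment balance = per-fragment occurrence counts with a
  pass verdict when every fragment appears at least `min_occurrence`
  times (default 2).

## Descriptor covariance

Pairwise descriptor correlation is computed on columns autoscaled with the
population divisor N, so that ρ = |Σᵢ x_{i,1} x_{i,2} / N| is exactly the
absolute Pearson correlation; the sample-scaled variant differs only by
(N−1)/N inside the scaling and is not exposed. Redundancy screening lists
pairs with |ρ| above a cutoff (default 0.7), optionally counted against
anchor descriptors (e.g. a surface-area column). The chance-correlation
risk over K pairwise comparisons at significance α is 1 − (1−α)^K; for the
91 pairs of 14 descriptors it is 0.99, which is why descriptor selection
must not peek at the response. Missing values fail fast here — imputation,
if any, is an explicit upstream step.

## PLS regression and validation

The engine is a from-scratch single-response NIPALS implementation. X and
y are centered and scaled to unit variance (population divisor; a uniform
rescaling of X does not change the model). Per component: weight
w ∝ E′f (unit norm, tolerance 1e−10 on the weight change, max 500
iterations), score t = Ew, loadings p = E′t/t′t, c = f′t/t′t, with X and y
deflation; scores are mutually orthogonal by construction. Coefficients
b = W(P′W)⁻¹c act on scaled X.

* **R²Y** = 1 − SS_res/SS_tot; **adjusted R²Y** = 1 − (1−R²Y)(N−1)/(N−1−A).
* **RMSEE** = √(Σ(y−ŷ)²/(N−1−A)); **RMSEP** = √(Σ(y−ŷ)²/N) for external
  predictions (no dof correction).
* **Q² = 1 − PRESS/SS** from leave-one-out cross-validation. Every fold
  re-estimates centering and scaling on its N−1 rows (honest CV, the
  behaviour of standard chemometrics software); PRESS sums squared
  out-of-fold errors, SS uses the all-row mean. A constant column arising
  inside a fold is a hard error, never a silently skipped fold.
* **Component count**: accept component a+1 only when it raises Q² by more
  than 0.05 (configurable), hard cap 3 — a single-response PLS model on
  near-linear data should need one, at most two to three, components.
* **Jack-knife CIs**: from the N leave-one-out submodels,
  SE_k = √((N−1)/N · Σᵢ(b_k^(−i) − b̄_k)²) and
  CI = b_k ± t_{0.95,N−1}·SE_k (90 % two-sided by default). A coefficient
  is significant when its CI excludes zero. The jack-knife literature
  admits variants; this one is fixed, documented and level-checked by
  simulation in the test suite.
* **Permutation (y-scrambling) test**: the response order is permuted
  n_perm times (default 200) and each scramble refit at the same A,
  recording R²Y and LOO Q² against |corr(y_perm, y)|. Verdict *pass* iff
  the intercepts of the regression lines of R²Y and Q² versus |corr| —
  fit through the permuted points plus the original model at |corr| = 1,
  the standard scrambling-plot read-out — lie below the original values
  and no permuted Q² reaches the original Q².
* **DModX applicability domain**: with X-residuals e of a row,
  DModX = v·√(Σ_k e_k²/(K−A)) / s0, where
  s0 = √(ΣΣe²/((N−A−1)(K−A))) pools the training residuals and
  v = √(N/(N−A−1)) corrects for training rows fitting themselves (with
  this v the training mean of DModX² is exactly 1). New rows use v = 1
  (DModXPS). The critical value at level α is
  DCrit = √(F⁻¹(1−α; K−A, (N−A−1)(K−A))); rows above it are flagged
  outside the applicability domain. Both v and DCrit are software
  conventions, isolated in one function.

## Reference (null) models

Seven simple baselines mirror the benchmarking scheme: training mean,
training median, nearest neighbour, three univariate least-squares
regressions on single descriptors, and a small PLS model on those three
descriptors (component count by the same Q²-gain rule). Each is evaluated
by RMSEP per external test set and on the pooled union, for which
RMSEP(union)² = Σ n_s·RMSEP_s²/Σ n_s holds exactly. The nearest-neighbour
assignment is, in the original workflow, an expert elicitation and cannot
be recomputed; the module accepts a curated `test_id → train_id` map, and
the computed fallback (arg-min Euclidean distance in autoscaled descriptor
space, ties to the lower id) is a labelled proxy.

## Statistical comparison of predictions

For each (model, test set) pair the null hypothesis is that predicted and
measured potencies share a distribution. Both samples are screened with
the Anderson–Darling normality test (estimated mean and variance,
small-sample-adjusted statistic, via `statsmodels`). If both pass, a
variance F test gates a paired two-tailed t test. The F statistic is
always oriented larger-over-smaller variance and its one-tailed p is
reported as such; because that orientation folds both tails into one, the
level-α equal-variance decision compares p to α/2 (the naive p < α rule
rejects at twice the nominal rate). The distribution-free tests run
regardless, subject to their sample-size rules: two-sample
Kolmogorov–Smirnov needs n > 10 and Mann–Whitney U n > 7 per sample.
Mann–Whitney uses the exact U distribution for tie-free samples up to
n = 25 — where it coincides with brute-force enumeration over rank
assignments — and the midrank normal approximation with tie correction
otherwise. Inapplicable cells carry a reason code (failed F / non-normal /
size rule) rather than disappearing. No multiple-testing correction is
applied across the grid.

## Synthetic data

The generator reproduces the statistical structure the pipeline consumes,
not chemistry. A study is: a building-block library (default four
positions with 4×3×3×4 = 144 combinations, 18 D-optimally selected — the
shape of the motivating design), additive fragment effects
y = intercept + Σβ(fragment) + ε with ε ~ N(0, σ²) i.i.d., β either given
or drawn N(0, 0.5²) and centered within each position (sum-to-zero
identifiability), intercept 4.0 (mid-micromolar baseline) and default
σ = 0.45 pIC50 units, a typical half-log-unit assay/model error.
Quantitative descriptor blocks are sampled from a Gaussian copula whose
block-structured target correlation matrix is validated positive
semi-definite first; realized correlations converge to target at the
1/√n Monte-Carlo rate. One master seed derives per-stage child streams
via `numpy` seed sequences, so regeneration is bit-identical.

What the generator does **not** emulate: real descriptor physics,
structure–descriptor coupling, non-additive (interaction) fragment
effects, heteroscedastic or censored assay noise, and distribution shift
between training and test chemistry beyond what the indicator space
expresses. Tests passing on this generator therefore demonstrate the
correctness and calibration of the machinery, not predictive validity on
any particular assay.

## Packaged data and scale choices

The 18-compound acetylcholinesterase training table (IC50 in µM with 95 %
confidence intervals and pIC50 = 6 − log10(IC50/µM)) ships with the
package; the one solubility-censored compound is stored with its published
pIC50 only. The quantitative descriptor matrices of the original study
were published only as a journal supplement and are not redistributed;
analyses and tests that would need them either consume user-supplied
copies or run on synthetic data, and the three published-value checks that
strictly require them fail with an explicit diagnosis when the files are
absent.

Simulation-based tests are sized for a single CPU: seed-sweep properties
(permutation verdicts, Q² on noise, coefficient-sign recovery) use 100
seeds with reduced permutation counts (30) and one full 200-permutation
run; the D-optimal exhaustive-equivalence sweep uses libraries small
enough for complete subset enumeration (≤ ~10³ subsets). These sizes are
stated in the relevant tests and are the package's own choices.

## Known limitations

* PLS1 only — no multi-response PLS2, OPLS, kernel PLS or VIP scores.
* The Fedorov exchange is a local search; global optimality is verified
  only on exhaustively enumerable libraries.
* Anderson–Darling p-values depend on the chosen small-sample adjustment;
  verdicts at α = 0.05, not exact p-values, are the supported surface.
* The reduced-vs-full indicator encoding changes the absolute value of the
  condition number; both options are exposed because published values
  rarely state the convention.
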