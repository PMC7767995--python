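# Methods

## Model

A cohort is a table of N samples by p taxa of relative abundances; each
row is a composition (non-negative, carrying only relative information,
normalized to sum to one). All geometry is done in the Aitchison sense:
the centered log-ratio transform `clr_i(x) = ln(x_i / g(x))` maps the
simplex isometrically onto the zero-sum hyperplane of R^p, and the
Aitchison distance is the Euclidean distance between CLR images. This
distance is permutation invariant, scale invariant (per-sample scaling —
library size — cancels exactly) and subcompositionally dominant, none of
which hold for Euclidean distance on raw or closed abundances.

t-SNE is implemented from first principles. For each sample i, a Gaussian
conditional distribution over the other samples is formed from squared
distances with a per-sample variance σ_i²; σ_i² is calibrated so that the
perplexity 2^H(P_i) (Shannon entropy H in bits) equals the user target
*per*, the effective number of neighbors. Conditionals are symmetrized to
p_ij = (p_{j|i} + p_{i|j})/2N. Map affinities q_ij use the Student-t
(Cauchy) kernel normalized over all pairs, and coordinates minimize
KL(P‖Q) by gradient descent. The metric is pluggable: `aitchison`
(default) operates on zero-imputed closed compositions, `euclidean` on
closed compositions directly — the latter is retained as the baseline the
Aitchison variant is compared against.

Out-of-sample extension: a new sample s_0 is closed and zero-imputed with
the policy stored at fit time, scored against every training sample by
sp_{0,i} = exp(−d²(s_0,s_i)/2σ_i²) / Z_i, where Z_i is the *training-time*
row normalizer Σ_{h≠i} exp(−d²(s_i,s_h)/2σ_i²). Z_i deliberately excludes
s_0 and is reused from fit time rather than recomputed, so transforming
new data can never perturb the fitted model. The k most probable training
samples become neighbors and z_0 is their probability-weighted mean; ties
in sp are broken by training order (first occurrence wins), making the
rule fully deterministic. z_0 therefore always lies in the convex hull of
the k neighbor coordinates.

Classification runs on the map coordinates with one of three families —
ridge-penalized logistic regression, RBF-kernel SVM, CART decision tree —
each tuned by exhaustive grid search minimizing mean stratified-CV
misclassification error and refit on all training samples. Evaluation
follows a stratified 80/20 split; pipeline parameters (*per*, *iter*,
*dim*, *k*) are tuned by fivefold CV on the training split only, with each
held-out fold embedded by the out-of-sample rule — the only mechanism the
method offers for unseen data, which also keeps the protocol leakage-free.
A flag for embedding folds into one global map is intentionally absent:
that variant leaks fold information into the map and is not supported.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `perplexity` (*per*) | effective neighbor count; sets σ_i² | 30 | middle of the commonly recommended 5–50 band |
| `max_iter` (*iter*) | gradient steps | 1000 | small-N maps converge well before this; no early stopping, so runs are reproducible step-for-step |
| `n_components` (*dim*) | map dimensionality | 2 | visualization default; classification sweeps {2,3,5,7} |
| `k_neighbors` (*k*) | out-of-sample neighbor count | 7 | matches the neighbor count that works well across the simulation studies |
| `zero_method`, `delta` | zero imputation | multiplicative, 0.65 × smallest nonzero abundance | preserves ratios among observed parts; imputed value below anything observed |
| `learning_rate`, momentum, exaggeration | optimizer schedule | 200; 0.5→0.8 at step 250; ×4 for 100 steps | the standard t-SNE schedule, with adaptive per-coordinate gains (min 0.01) |
| `random_state` | map initialization N(0, 1e-4) | 42 | all randomness flows from this one seed |

Perplexity is interpreted as 2^H with H in bits. Bandwidth search is a
bracketing binary search on the precision β_i = 1/(2σ_i²) (realized
perplexity is monotone in β), run to an entropy tolerance of 1e-9 with a
64-step cap; rows that fail to converge fall back to the last bracket
midpoint with a logged warning. The tight tolerance costs microseconds per
row and lets calibration agree with independent bisection oracles to 1e-6
in the probabilities themselves.

## Numerical choices

- KL uses natural log; the trace records KL(P‖Q) against the
  *unexaggerated* P every 50 steps plus the final step. Inside the
  optimizer Q is floored at 1e-12; the public `kl_divergence` instead
  raises on q_ij = 0 where p_ij > 0 (a degenerate embedding).
- Exponentials in the bandwidth search are max-shifted; the stored row
  normalizer is shifted back to the original scale for reuse by the
  out-of-sample rule.
- The scalar `aitchison_distance` uses exact (compensated) summation, so
  joint permutation of parts changes nothing at the bit level; the matrix
  path (`pairwise_distances`) uses vectorized BLAS and agrees to 1e-10.
- MCC with a zero denominator is defined as 0 (nMCC 0.5). Scores tied at
  the 0.5 threshold count as positive calls. AUC is trapezoidal over the
  ROC curve (equal to the Mann–Whitney pairwise statistic); AUPR uses
  step-wise interpolation, since trapezoidal PR interpolation is biased.
  With single-class labels AUC/AUPR are reported as missing, never 0.
- The SVM's case score is the sigmoid-squashed decision margin: monotone
  in the margin and exactly 0.5 on the decision boundary, so thresholded
  labels agree with the fitted decision function and the model stays
  deterministic. LR and DT report native class probabilities.
- Grid-search ties select the first point in grid order; CV folds are
  stratified and seeded. A failed pipeline grid point is recorded as
  missing in the CV table, never silently dropped.
- The fitted-mapper bundle is versioned JSON; floats serialize with
  shortest round-trip repr, so save/load reproduces out-of-sample
  coordinates bit-identically.

## Synthetic data

No public accessions exist for the two clinical cohorts this method was
designed around (an oropharyngeal infection cohort of 99 samples × 728
genera, 40 case / 59 control, and a gut cohort of 48 samples × 146
genera, 25 / 23, both at ≈30,000 tags per sample), so the generator
emulates their shape and statistical structure and all validation is
simulation-based.

The generative model is logistic-normal: a heavy-tailed baseline mean in
CLR space (sd 2.0 log units across taxa, giving the few-dominant-taxa
profiles typical of genus tables), a class effect of stated magnitude
(log-ratio units) along random orthonormal zero-sum directions, within-class
Gaussian noise, inverse-CLR to the simplex, multinomial resampling at the
sequencing depth, and abundance-correlated sparsity (each row's smallest
fractions are zeroed, as detection limits do, rather than independent
Bernoulli masking). With `n_effect_directions` = m > 1 the case class is a
mixture of m sub-populations shifted along orthogonal directions, so the
class boundary genuinely spans an m-dimensional subspace — the regime in
which a 2-D map under-performs a 5-D one. The optional scale confounder
multiplies each output row by a random power of two (log2-normal,
rounded): float arithmetic absorbs powers of two exactly, so closure and
log-ratios of a confounded table are bit-identical to the unconfounded
one while raw Euclidean distances differ — the compositional-invariance
mechanism in an exactly testable form. Stage-specific RNG streams mean
that toggling an optional stage (depth, confound) never shifts the draws
of the others.

Presets: `mp_like` (99 × 728, 40/59, effect 6 along one direction,
sparsity 0.6) separates cleanly in 2–3 dimensions; `icpp_like` (48 × 146,
25/23, effect 6 over four directions, sparsity 0.4) needs a higher map
dimension. Both accept size overrides for cheap simulation studies.

What the generator does *not* emulate: phylogenetic correlation among
taxa, overdispersion beyond multinomial, batch effects, and real
taxon-level zero-inflation structure. Passing simulation studies
therefore demonstrate the method's internal correctness and its
qualitative behavior under compositional distortions, not clinical-grade
accuracy on real cohorts.

## Study sizes

The two canned studies (`codatsne.experiments`) are sized for a single
CPU: the metric contrast uses the reduced preset (60 × 100, scale
confounder sd 2, *per* 15, *iter* 500, *dim* 3, *k* 7) over 10 seeds with
all three families; the dimension study uses 48 × 100 cohorts with the
four-direction effect (*per* 10, *iter* 400, *k* 5, dims {2, 5}) over 5
seeds with fivefold CV. These sizes keep each study in the low minutes
while leaving the contrasts far from the noise floor.

## Limitations

- Exact O(N²) t-SNE: appropriate for cohort sizes in the hundreds; no
  Barnes–Hut or interpolation acceleration, no PCA pre-reduction.
- Binary labels only; no probability calibration beyond the native score.
- Zero imputation is a documented assumption (multiplicative, delta =
  0.65 × smallest nonzero abundance); log-ratio results can be sensitive
  to it on very sparse tables, and both the method and delta are exposed.
- Taxa mismatches between a fitted mapper and new samples are a hard
  error by design; subset and re-close explicitly rather than relying on
  silent alignment.
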