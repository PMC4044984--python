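# Methods

## Model

`bvroctree` induces a binary oblique decision tree for an expression
matrix (samples × genes) with labels in {−1, +1}. Each internal node
tests a threshold on a *derived feature*: either one raw gene or a
least-squares combination of two genes. The three ingredients are

* **AUC as the node criterion.** A candidate feature is treated as a
  one-dimensional classifier; its quality is the area under the ROC curve
  against the labels. We compute the AUC through the rank-sum identity
  `(R⁺ − n⁺(n⁺+1)/2)/(n⁺n⁻)` with mid-ranks for ties, which equals the
  trapezoidal integral of the tie-grouped ROC curve (each tied
  positive–negative pair contributes ½). The rank form is preferred
  internally because mid-ranks are exact binary fractions: AUC values that
  are mathematically equal compare equal in floating point, which keeps
  the lowest-index tie-breaking during feature scans deterministic. The
  `roc_curve` function still returns the explicit operating points with
  the trapezoidal area for plotting and inspection.
* **Least-squares feature combination.** For a selected gene set the
  coefficients regress the numeric labels on the gene columns through the
  origin (no intercept; the {−1,+1} encoding is symmetric about zero, and
  AUC is unaffected by affine re-encodings of the target — only the
  coefficients change). Singular normal matrices (collinear genes) fall
  back to the minimum-norm solution with a warning rather than failing:
  collinearity is common in expression data and any minimizer yields the
  same fitted values; the minimum-norm choice makes the result canonical.
* **Hinge rank loss (HRL) for the split.** After sorting the derived
  values, a threshold θ predicts −1 for values ≤ θ and +1 above. A
  misclassified sample in the ≤ θ partition at 1-based position *i*
  (ascending) costs `|D_neg| − i + 1`; one in the > θ partition costs its
  position *i*. The split threshold is the observed derived value with
  minimal total penalty. Because only ranks enter, the loss — and hence
  the chosen partition — is invariant under strictly increasing
  transformations of the derived feature. Candidates are scanned in
  ascending order and the best-so-far is updated only on strict
  improvement after *both* partition penalties are summed, so ties go to
  the smallest θ and every candidate is judged on its full loss (the
  canonical eight-instance example: penalties 2 + 3 = 5 at θ = −0.4).

### Greedy search structure

Node selection is deliberately greedy: the best single gene is found
first, then extended by the partner that most improves the combined AUC,
and the pair is kept only on strict improvement. This costs O(genes) LSE
fits per node rather than O(genes²). The consequence — verified
empirically in the test suite — is that a pair is discoverable only when
one of its members already wins the singleton scan. With ~500 standard
Gaussian noise genes and 60 samples the best *chance* AUC is ≈ 0.72
(0.69–0.77 across replicates), so a pair whose members are both
genuinely near chance individually can never be reached even when its
combination separates the classes perfectly. This is an inherent
limitation of the greedy search, not of the implementation; the
symmetric planted-pair configuration in `synthetic.py` exists precisely
to demonstrate it.

### Tree growth and prediction

Partitioning sends derived > θ left (the predicted-positive side) and
derived ≤ θ right, exactly the rule the loss optimized; boundary samples
therefore go right. A node whose combination reaches `stop_auc` performs
its split and its children become majority leaves ("split once more,
then stop"); the alternative reading — do not split at all — is available
as `stop_mode="leaf"`. Genes used at a node are excluded from the whole
subtree beneath it, which (with the minimum node size) guarantees
termination. Leaf labels are the majority class; an exactly tied or empty
leaf inherits the parent's majority, with −1 as the final fallback. Tree
*size* counts internal decision nodes only.

Prediction recomputes each node's derived values with the same
vectorized matrix product used during induction and routes samples in
bulk. This matters at the split boundary: the sample whose derived value
*is* θ can land on the wrong side if re-evaluated with a differently
associated dot product (a 1-ulp discrepancy observed in practice), so
resubstitution consistency is maintained by construction. Leaf scores
(fraction of positive training samples) provide a graded output for ROC
analysis of the fitted tree; this is also how held-out AUC is computed in
cross-validation, with hard labels available via `predict`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `stop_auc` | 0.95 | node AUC at which growth below the node stops; curbs overfitting on small subsets |
| `limit` | 2 | max genes per node (the same greedy loop extends to larger limits, untested surface) |
| `min_samples_split` | 3 | nodes smaller than this become leaves |
| `max_depth` | 25 | hard depth cap |
| `stop_mode` | `"split"` | behaviour at `stop_auc` (see above) |
| `orient_features` | off | let the singleton scan flip inverted markers (score by max(AUC, 1−AUC)) |

AUC is otherwise reported raw — a feature with AUC 0.2 loses to one with
0.6 — matching the literal selection procedure.

## Synthetic data

The generator emulates the genes ≫ samples regime (default 500 × 60,
balanced classes): i.i.d. standard Gaussian noise genes, optional planted
single markers (`effect·label + N(0, noise_sd)`), and planted pairs built
around a shared latent confounder `u` with opposite loadings so that the
weighted sum cancels `u` and separates the classes by `2·margin` against
only the private noise (`noise_sd = 0.05`), while each member alone is
masked by `u` (`latent_sd = 3`). The `anchor_fraction` parameter splits
the pair's marginal signal between its members. The default (0.87) makes
the first member individually detectable (population AUC ≈ 0.89 — well
below separation) and the partner near chance (≈ 0.57): this is the
structure the greedy search can actually recover, and recovery of the
planted pair as a size-1 tree with 100 % training accuracy is exercised
across seeds in the tests. The symmetric setting (0.5, with a larger
latent) makes both members near chance and is used to characterize the
generator, not for recovery claims.

What the generator does *not* emulate: batch effects, heteroscedastic or
count-like noise, correlated co-expression modules, class-dependent
variance. Passing tests on these data show the algorithmic machinery is
correct and that the method behaves sensibly under its own assumptions;
they do not certify performance on real microarray or RNA-seq data.

## Numerical and degenerate-input choices

* AUC requires both classes; single-class nodes are pure and become
  leaves before any AUC is computed.
* All feature-scan ties break toward the lowest gene index; threshold
  ties toward the smallest θ; label ties toward the parent majority.
* A degenerate split (all derived values identical, or a threshold that
  puts every sample on one side) converts the node to a majority leaf.
* Serialized trees store coefficients, thresholds and scores as decimal
  strings with 17 significant digits, so JSON round-trips are bit-exact.
* Cross-validation reduces k to the minority-class count (with a
  warning), uses sample (n−1) standard deviations for the ± figures, and
  records a fold AUC of NaN when a test fold contains one class
  (leave-one-out); NaNs are excluded from the AUC aggregate.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on generated data: the
eight-instance worked example for the loss; oracle comparisons at n ≤ 12
(AUC), m ≤ 10 (threshold) and 4–6 genes (selection); recovery at
500 genes × 60 samples over 10 seeds; and 5 × 10-fold CV at 60 samples
with 200–500 genes. These sizes mirror the small-sample regime the
method targets while keeping the whole suite fast on one CPU.

## Known limitations

* Greedy pair search (see above): globally optimal pairs without a
  detectable member are unreachable.
* No pruning; the stopping AUC is the only complexity control beyond the
  safety stops.
* Binary classes only; no missing-value handling (an error by design —
  impute upstream if needed).
* The stopping rule can freeze impure children when the node AUC is high
  but the HRL threshold is imperfect; this is intended behaviour (it is
  what keeps trees small) but means training accuracy below 100 % is
  possible even on separable data when `stop_auc` < 1.
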