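# Methods

## Processing sequence

The pipeline is a fixed sequence: raw pairwise scores → dissimilarity
conversion → per-method sigmoid scaling → mirroring to the full ordered
matrix → per-method imputation → consensus schemes M1–M5 → per-pair
median. Scaling precedes imputation, so imputation operates on scaled
similarities in `(0, 1)`; this keeps imputed values commensurable across
methods and makes the global-mean fallback well defined.

Three evaluation views are assembled from the same run. *Original* keeps
missing scores missing (consensus per pair is computed over whichever
methods are available, with weights renormalized over that subset).
*Common* restricts to the pairs every method scored. *Imputed* is fully
filled, and all methods count as available for its per-pair weighting.
Coverage and divergence statistics are always computed on pre-imputation
data so that imputed values can never influence the weights.

## Score scaling

Dissimilarity conversion negates similarity-polarity raw scores rather
than using `1 − raw`: the subsequent autoscaling is invariant to any
positive-slope affine transform of a method's dissimilarities (a tested
property), so the two choices are equivalent and negation assumes nothing
about the raw score's range. `σ` is the population standard deviation; a
method with constant raw scores (`σ = 0`) maps every pair to the sigmoid
midpoint 0.5, which keeps downstream arithmetic finite while carrying no
ranking information, which is exactly what a constant scorer deserves.

## Imputation

The local-average fill for a missing ordered pair `(dᵢ, dⱼ)` merges the
multiset of present scores whose *first* domain is `dᵢ` with those whose
*second* domain is `dⱼ` and imputes the mean of the merged multiset; the
two record sets are disjoint by construction (their only possible common
record is the missing one itself), so "merge" is concatenation. Source
values are exclusively pre-imputation scores, making the fill independent
of the order in which missing pairs are visited. The directed
(first-domain / second-domain) neighborhoods are kept as literally
defined; a symmetrized variant would average the same information twice on
mirrored tables.

## Consensus weighting

* **M2** weights each method by coverage `sᵢ / P` counted on the mirrored
  ordered-pair matrix.
* **M3** multiplies M2's coverage weights by per-method expert priors
  (default 1.0; the bundled compression-based scorer carries 0.5, the
  conventional discount for a structure-agnostic method).
* **M4** computes, for each method pair, the RMS difference of their
  scaled scores over the pairs both cover; each method's weight is its
  mean divergence from the others, normalized by the maximum
  (`wᵢ = rᵢ / max r`). If the maximum divergence is ≤ 1e−12 the methods
  are numerically identical and the scheme falls back to equal weights —
  without the tolerance the weights would be ratios of floating-point
  noise.
* **M5** passes user weights through, or learns them: a logistic
  regression of same-vs-different class membership (level 1 by default) on
  the per-method scaled scores of a seeded random sample of pairs (default
  training fraction 0.10), returning normalized absolute coefficients.
  The feature construction (raw scaled scores, default scikit-learn L2
  regularization) is this package's own definition.

Per pair, the weights of the available methods are renormalized to sum to
one, making every scheme a convex combination of scaled scores — hence
all consensus values stay inside `[min Sᵢ, max Sᵢ]`, a tested invariant.
The median is the 3rd order statistic of M1–M5.

## Built-in scorers

The compression scorer serializes each Cα contact map (8 Å cutoff,
`|i − j| ≥ 2`) row-major and computes
`max(C(ab) − C(a), C(ba) − C(b)) / max(C(a), C(b))` with `C` the
zlib-compressed length (level 9; bz2 selectable, the choice is recorded in
run metadata because the values are compressor-dependent). The
superposition scorer truncates both traces to the common leading length,
finds the optimal proper rotation (reflections excluded), and maps RMSD to
`1/(1 + RMSD/R₀)` with `R₀ = 3.0 Å` — a soft scale of the same order as
typical within-fold Cα RMSDs, giving a bounded score that the sigmoid
autoscaling renormalizes anyway. Truncation rather than alignment is a
deliberate simplification; sequence/structure alignment is out of scope.

## Evaluation

ROC curves sweep the observed unique similarity values from high to low;
a pair counts as predicted-similar strictly above the threshold, and AUC
is the trapezoidal integral. Sweeping observed values is exact and
resolution-independent, and agrees with scikit-learn's AUC to 1e−12 in
tests. ROC uses unordered pairs (the mirrored orientation duplicates the
same information); pairs with no score in a view are excluded from its
ROC, whereas nearest-neighbor classification assigns them the maximum
distance 1 instead. Leave-one-out NN classification breaks distance ties
toward the lexicographically smallest neighbor ID, so results are
deterministic; domains whose distances are all at the missing-value
sentinel are still classified.

## Distance geometry

Distance matrices are `D = 1 − S` with missing entries set to 1 (maximum
dissimilarity), zero diagonal, and asymmetric leftovers averaged. MDS is
metric SMACOF (stress majorization) with seeded random restarts, followed
by a deterministic quasi-Newton polish of the raw-stress objective —
majorization alone has a slow tail near the optimum and stalls around
1e−6 normalized stress on exactly embeddable inputs. Reported stress is
`sqrt(Σ(d̂ − d)² / Σ d²)` over unordered pairs. Neighbor joining is the
canonical Saitou–Nei agglomeration; Q-criterion ties break to the first
(smallest-index) pair, and negative branch lengths are clamped to zero
(clamping never triggers on additive inputs, a tested property). Fold-level
heatmaps show mean pairwise distances between label groups; a singleton
group's diagonal entry is 0 by convention.

## Synthetic data

The planted generator emulates the statistical structure the evaluation
assumes: a balanced 4-level hierarchy in which the true dissimilarity of a
pair is the sum of per-level separations over the levels where the labels
diverge (default 1.0/0.5/0.25/0.125, so divergence at a coarser level
always dominates), per-method Gaussian noise on top, and independent
per-method thinning to a coverage fraction, mirroring the heterogeneous
coverage of real multi-method experiments. Defaults: 64 domains
(4 classes × 2 folds × 2 superfamilies × 2 families × 2 domains), three
methods with noise SD 0.02/0.05/0.10 and coverage 1.0/1.0/0.8 — noise
small against the family-level separation but not negligible, and one
method below full coverage so imputation and coverage weighting are
exercised. A noise SD of `inf` plants a signal-free method. The toy
structure generator writes minimal single-chain Cα-only PDB files whose
geometry (helical vs extended trace, fold-specific length, family-level
bend, per-domain 0.15 Å jitter) decays in similarity with label
divergence.

What the generator does **not** emulate: real side-chain packing,
insertions/deletions (scores are i.i.d. Gaussian around the planted truth,
whereas real PSC errors are structured), asymmetric external scorers, and
non-random missingness (real failures correlate with domain size/quality).
Passing tests therefore demonstrate the pipeline's arithmetic and its
behaviour under planted signal/noise/coverage regimes, not biological
accuracy of any particular PSC method.

## Problem sizes and determinism

Tests and the acceptance script use 16–64-domain planted datasets and
4–8-taxon trees; these sizes already exercise every code path, and all
pipeline stages scale straightforwardly (the quadratic pair enumeration is
the dominant cost for large N). All randomness flows through explicit
seeds; parallel scoring is keyed by (pair, method), never by completion
order, so outputs are bit-identical for any thread count.

## Known limitations

* No consensus-derived alignments; scorers return scalars only.
* `q ≠ 1` for the generalized mean is exposed but not validated against
  any reference behaviour.
* The M5 learning procedure is a reconstruction (see above), not a
  reproduction of any published coefficient set.
* mmCIF input, multi-chain domains, and insertion-code-aware parsing are
  out of scope; the PDB reader takes the first model/first chain/first
  altLoc.
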