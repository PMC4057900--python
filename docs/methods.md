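# Methods

## Skeleton graph and descriptor conventions

A PBDE congener is specified by its two sets of brominated ring locants
(positions 2–6 per ring; position 1/1′ is the ipso carbon carrying the
ether bridge and is never substituted). The heavy-atom skeleton is a unit
edge-length graph: two carbon 6-cycles, a pendant vertex per bromine, and
— the one non-obvious convention — the bridging ether **oxygen contracted**
so the two ipso carbons are directly bonded. This choice is forced by the
data: with the oxygen as a vertex the 2↔2′ bromine distance would be 6
rather than 5 and none of the tabulated descriptor values would be
reproduced; with contraction all 44 tabulated (μ1, μ2) values match at
4 decimals. Distances are topological shortest-path bond counts computed
by breadth-first search (networkx); "geometric" bond lengths play no role.

MDEV sums run over reciprocal squared distances between typed features:

* μ1 (M11): unordered **distinct** bromine pairs. Self-pairs are excluded
  — they would divide by zero, and monobromo congeners tabulate μ1 = 0.
* μ2 (M12): all (bromine, ring) cross pairs, with the bromine-to-ring
  distance taken to the *nearest* carbon of the target ring (1 for the
  bromine's own ring; 2 + cycle-distance(position, ipso) for the far
  ring). This is the only reading consistent with the tabulated values
  (e.g. μ2 = 1.0625 for the 3-monobromo congener requires a far-ring
  distance of 4). The published worked expansion for the tetra congener
  prints two 1/4² far-ring terms where the arithmetic requires 1/5²; the
  implementation follows the (self-consistent) summed value.
* μ3 (M22): the single ring–ring term, identically 1 for PBDEs because
  the contracted rings are adjacent. It is computed but excluded from all
  modelling, since a constant carries no information.
* Relative electronegativities of bromine and the benzene ring are both
  defined as 1, so no weighting enters the sums.

Canonicalisation maps each congener to a unique representative under the
molecular symmetries (ring swap; per-ring mirror p ↔ 8−p). Each ring's
locants are mirror-normalised to the lowest-locant tuple, and the more
substituted ring becomes the unprimed ring (ties broken
lexicographically), matching BDE nomenclature. Enumeration of the 2¹⁰
substitution patterns modulo these symmetries yields the classical 209
congeners, which is also the ceiling for duplicate-free synthetic
sampling. The descriptor itself is symmetry-invariant, so
canonicalisation affects only naming and deduplication.

## Regression model and diagnostics

The calibration model is OLS of lgK_OA on raw (μ1, μ2) with intercept
(statsmodels). Diagnostics follow the conventions that reproduce the
published triple: multiple correlation R = √(SS_reg/SS_tot), standard
error of the estimate √(SS_res/(n−3)), and F = (SS_reg/2)/(SS_res/(n−3))
on (2, n−3) degrees of freedom. No descriptor standardisation is applied;
the published coefficients are on the raw descriptor scale. The published
equation's typeset signs (+μ1 coefficient, negative intercept) cannot
reproduce any of the accompanying predictions; the refit signs
(−0.7593, +0.9883, +6.3471) are used, and they regenerate the published
prediction columns at 2 decimals. Exact refitting lands one unit off the
last printed digit of three published quantities (|b1| 0.7593 vs 0.7598,
R 0.9843 vs 0.9844, F 202.44 vs 202.46); μ2's coefficient and the SE match
exactly. Tests assert at the achievable precision.

## Linear network (L-ANN)

The network has two inputs and one linear output neuron, so it is an
affine map v = Σ xᵢwᵢ + b of z-scored inputs (z-scoring is the package's
choice of the unspecified "normalisation"; at the least-squares optimum
predictions are invariant to it). Training is one-shot SVD pseudo-inverse
on the training portion of the calibration set. The "use a verification
set to stop training early" idea has no literal counterpart in a
non-iterative solver; it is realised as model selection: candidate
networks are formed by truncating trailing singular values (ranks full,
full−1, …, 1) and the candidate with the lowest verification RMSE is
kept, ties preferring full rank. With two well-conditioned inputs this
selects the full-rank solution, whose de-normalised weights equal the OLS
coefficients to 1e-8 — which is why the network's external predictions
track the regression model so closely. The calibration split is seeded
(numpy `default_rng`); a verification fraction of 0.2 gives the 12/3
split on 15-sample leave-one-out folds and 13/3 on the full 16-record
group, and `verification_fraction=0` disables the split entirely,
returning the plain least-squares network used for the external-
validation headline number. The network is linear throughout; a stray
"RBF" label in the source description conflicts with the stated
architecture and equations and is not implemented.

## Validation protocols

Relative errors are signed percents, 100·(pred−exp)/exp, and RMSRE is
their quadratic mean — no extra scaling, as confirmed by recomputing the
published aggregate (2.82) from the published per-sample errors.
Leave-one-out CV refits on n−1 records per fold (deterministic for OLS;
for the network each fold draws a fresh split with the fold index added
to the seed). For OLS, the refit-based LOO predictions are checked
against the closed-form leverage identity ŷ₍ᵢ₎ = (ŷᵢ − hᵢyᵢ)/(1−hᵢ) to
1e-10. External validation is a single fit on a calibration set and
evaluation on a disjoint test set (disjointness enforced on canonical
congeners). Predicted-vs-experimental lines are simple OLS of predicted
on experimental with the Pearson correlation (scipy).

The packaged 22-congener dataset carries its published group split
(16 calibration / 6 external; the externally validated rows are 2, 6,
10, 14, 18, 22 of the descriptor table). One source paragraph swaps the
two group names; the 16/6 counts fix the intended reading. The published
external MLR prediction column is not exactly the refit equation applied
to the external descriptors (largest gap ≈0.1 log unit), so its printed
aggregate RMSRE 2.95 is reproduced from the published per-sample errors,
while a fresh fit-and-predict yields 2.68; both computations are exposed
(`published_predictions()` vs `external_validation`) and both are
reported by the `reproduce` command.

## Synthetic data

The generator emulates exactly the statistical structure the calibration
assumes: congeners drawn uniformly-ish over substitution patterns (each
of the 10 positions brominated independently with probability ½, empty
draws rejected, canonicalised, deduplicated by default) and lgK_OA linear
in (μ1, μ2) with additive i.i.d. Gaussian noise. Defaults are the study
conditions: generating coefficients (−0.7598, 0.9883, 6.3470) from the
calibration equation, noise SD 0.234 lgK_OA units (the fitted residual
SE), and n = 16 (the calibration-group size). What it does **not**
emulate: measurement-error structure in the underlying experimental
K_OA values (which are themselves literature-derived), congener-class
sampling bias of real monitoring campaigns, temperature dependence of
K_OA, and any nonlinearity in the true structure–property relationship.
Passing recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions, not validity of the linear
model for real PBDE partitioning.

## Numerical choices and problem sizes

Distances are exact integers; descriptor sums are double precision and
compared to tabulated values at their 4-decimal precision. OLS goes
through statsmodels' QR-based solver; the network solver truncates
singular values below `s_max · eps · max(m, n)`. Tie-breaks: equal
verification RMSE prefers the higher-rank candidate; ring-label ties in
canonicalisation go to the lexicographically smaller locant tuple.
Degenerate inputs (constant descriptors, collinear designs, empty
verification splits, overlapping train/test sets, zero experimental
values) raise typed errors rather than propagating NaNs. Monte-Carlo
tests use 100–500 replicates at n = 16–200 with fixed seeds — ample for
a 3-parameter linear model, and the whole suite runs in a few seconds.

## Known limitations

The model is congener-interpolative: calibrated on mono- through
hexa-brominated congeners, predictions for hepta–deca congeners are
extrapolations (the descriptor is defined for all 209). K_OA is treated
as temperature-free; no applicability-domain, bootstrap, or
y-randomisation analysis is provided. The scope is exactly the PBDE
skeleton — no general molecule parsing (SMILES/InChI) and no other
compound classes.
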