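# Methods

## Model

A QEX filter is a product-of-desirabilities score over eight
physicochemical descriptors computed per compound (canonical order: MW,
ALOGP, HBD, HBA, PSA, ROTB, AROM, ALERTS). The modelling assumptions are:

- the actives of one target have **unimodal, possibly skewed** marginal
  distributions in each property, adequately described by the asymmetric
  double sigmoidal (ADS) bump
  `Q(x) = a + b·σ((x−c+d/2)/e)·[1 − σ((x−c−d/2)/f)]`;
- typicality in each property is independently informative, so the joint
  desirability is a weighted geometric mean of the marginals;
- no inactive data are needed: the filter models actives only, and
  inactives appear solely in evaluation rankings.

Correlations between properties (MW–PSA, MW–ROTB and so on) are ignored by
construction; the score is a marginal-typicality product, not a density
estimate.

## Descriptors

RDKit computes all eight properties. MW is the average molecular weight,
ALOGP the Ghose–Crippen logP, PSA the topological polar surface area, ROTB
RDKit's rotatable-bond count, AROM the aromatic-ring count. HBD is the
per-atom Lipinski donor count (N/O atoms bearing at least one hydrogen,
SMARTS `[#7,#8;!H0]`) — chosen over RDKit's `NumHDonors`, whose SMARTS
excludes edge cases like water; HBA is RDKit's `Lipinski.NumHAcceptors`.
Both definitions are recorded in model metadata, since donor/acceptor
conventions differ between toolkits and models are only comparable within
one convention. ALERTS counts how many patterns of a structural-alert set
match at least once (patterns, not occurrences); the default set is the
Brenk collection as distributed inside RDKit's filter catalog (105
entries), overridable by any two-column (name, SMARTS) file. Multi-fragment
inputs (salts) are reduced to the largest fragment before descriptor
computation, and training sets can be deduplicated by canonical SMILES.
Descriptor values drift slightly across toolkit versions, so the toolkit
and version are stored in model metadata rather than pinned.

## Histograms and curve fitting

Count-valued properties (HBD, HBA, ROTB, AROM, ALERTS) are histogrammed in
unit-width bins centered on the integers. Continuous properties (MW,
ALOGP, PSA) use Freedman–Diaconis bin widths with a floor of 20 bins,
over the 0.5–99.5 percentile range to blunt outliers. At least five
non-empty bins are required; narrower distributions are rejected as
unfittable rather than silently producing a degenerate curve.

The ADS curve is least-squares fitted to the (bin center, raw count)
pairs with uniform weights, using scipy's bounded trust-region-reflective
least squares. Bounds `b ≥ 1e-9`, `d ≥ 0`, `e, f ≥ 1e-6` fix the sign
convention (rising edge before falling edge) and exclude mirrored
solutions; plain Levenberg–Marquardt cannot enforce bounds, and on this
objective the two methods agree wherever LM converges inside the feasible
region. Because the parameter surface is multimodal, a small deterministic
multi-start schedule is used: center at the modal bin, amplitude at the
max count, zero baseline, width `d₀ ∈ {0.5, 1, 2} × IQR`, slopes
`e₀ = f₀ = max(IQR/4, bin width/2)`; the converged start with the lowest
residual wins. Refitting identical samples is bit-identical.

## Normalization and peaks

The raw fitted curve is divided by its maximum so the desirability peaks
at 1. The maximum is located on a fixed grid of 20,001 points spanning the
fit domain padded by five domain-spans on each side, followed by one
2,001-point refinement around the coarse argmax; ties resolve to the
smallest abscissa. The wide padding matters: for count properties whose
mass piles up at zero only the falling flank of the bump is observed, and
the fitted argmax (the reported "peak") legitimately falls below zero —
often tens to hundreds of units negative. A curve that never rises above
zero, or with `b ≈ 0` (no bump), is rejected.

## Scoring and weight selection

Desirabilities are clamped to `[1e-6, 1]` before the log transform, so
scores are finite, positive and order-preserving even where the fitted
curve underflows. The score is `exp(Σ wᵢ ln Q̃ᵢ / Σ wᵢ)`; weight scale
cancels, and uniform weights reduce to the plain geometric mean.

Weights come from exhaustive search over all 5⁸ − 1 = 390,624 vectors with
components in {0, 0.25, 0.5, 0.75, 1} (the all-zero vector is excluded as
unusable). Each candidate's Shannon entropy `−Σₖ sₖ log₂ sₖ` is computed
over the raw training scores — deliberately *not* renormalized to a
probability distribution; only the induced ranking of candidates matters.
The adopted weight vector is the component-wise mean of the 1000
highest-entropy candidates, ties broken by enumeration order (odometer
order, last property fastest), making selection deterministic and
invariant to compound order. The search runs as a chunked dense matrix
product on the precomputed n×8 log-desirability table; `s·log₂s` is
evaluated as `exp(m)·m/ln 2` from the weighted mean-log `m`, so the full
grid over 1,000 compounds takes seconds on one CPU.

## Screening evaluation

ROC-AUC uses the Mann–Whitney convention (ties contribute ½), via
scikit-learn. EF(x%) counts actives in the top `⌈x%·n⌉` of the ranking and
divides by `N_actives · x%`; the ceiling guarantees a non-empty top set at
EF(1%) for pools of ≥ 100 compounds. Compounds tied at the cutoff score
are counted **fractionally** (the expectation over random tie orderings):
this is deterministic, invariant to input order, and gives an
uninformative constant scorer EF ≈ 1, which a stable-input-order
convention does not (it would rank whichever class is listed first into
the top). Stable-order and seeded-random tie modes remain available for
sensitivity checks. The EF denominator counts the actives present in the
ranking being evaluated.

Cross-validation splits the *actives* into k near-equal folds by a seeded
permutation with contiguous chunking; each fold's model is fitted on the
other k−1 folds (≥ 20 actives required per training split) and evaluated
on the held-out actives plus the **entire** inactive pool, which is never
split and never informs fitting. A pre-built model (e.g. a drug-set,
QED-style filter) can be evaluated on the same folds for comparability.
RO5 ranks compounds by the number of satisfied criteria (HBA ≤ 5, HBD ≤ 5,
MW < 500, logP < 5), evaluating the logP criterion with ALOGP since that
is the descriptor this stack computes; the substitution is recorded in
provenance.

## Synthetic data

The generator draws each property from a split normal: two half-normals
glued at the mode, with `spread` the mean of the two standard deviations
and `skew` their ratio, so the mode is exact by construction and the
asymmetry that motivates `e ≠ f` is present. Count properties are rounded
and clipped at zero (creating the boundary point-mass seen in real count
descriptors); MW is floored at 20 g/mol. Default modes (MW 269, ALogP 3.4,
HBD 1, HBA 4, PSA 54, ROTB 2.5, AROM 2, ALERTS 0) are chemically plausible
magnitudes for a small-molecule hit series; spreads are set so every
property yields enough non-empty histogram bins to fit. Inactive pools
reuse the active families with spreads multiplied by a separation factor
(optionally with shifted modes): separation 1 gives statistically
identical classes (pipeline AUC ≈ 0.5), larger factors give controllable
enrichment. `ads_reference_sample` rejection-samples from a stated ADS
curve restricted to a support interval, providing exact ground truth for
fit-recovery tests.

What the generator does **not** emulate: inter-property correlations,
multimodal chemotype mixtures, assay noise in labels, and any actual
chemical structure (it is property-space only). Passing tests therefore
demonstrate that the machinery recovers structure it is designed for, not
that any particular real target is this well behaved.

A note on peak recovery: fitted peaks of continuous properties land within
a fraction (≤ 15%) of the generating spread of the true mode at n = 5000.
For zero-clipped count properties the realized modal integer can sit at
the boundary, where the fitted peak falls at or below it — the same
negative-peak behaviour real count descriptors produce — so recovery there
is asserted directionally, not by distance.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run on synthetic benchmarks of
300 actives vs 2,000 inactives (5-fold CV at separations 1–3), n = 5,000
draws for curve-recovery checks, and the full 390,624-candidate weight
grid — sizes chosen so the complete pipeline, including five refits per
CV run, executes in minutes on a single CPU while keeping Monte-Carlo
noise well inside the asserted tolerances. Every stochastic step
(generation, fold assignment, optional tie randomization) flows from an
explicit seed; fitting and weight selection are deterministic given the
data.

## Known limitations

- Exact fitted coefficients depend on the binning and multi-start policy;
  only peak locations and downstream scores are stable targets across
  reasonable policies.
- The desirability floor (1e-6) makes extremely atypical compounds
  indistinguishable from one another (all score ≈ floor under any fully
  positive weighting).
- The entropy criterion selects weights for score spread on the training
  actives, not for discrimination; with very small training sets (tens of
  compounds) the selected weights are noisy.
- Property tables are held in memory; pools beyond ~10⁶ compounds should
  be scored in batches.
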