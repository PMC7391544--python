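# Methods

## Scope and data model

The package analyses a two-morph (planktivorous / benthivorous) fish
population through three independent data streams:

- **LandmarkSet** — 24 digitized (x, y) landmarks per specimen in the
  tpsDig2 file dialect. Landmarks 1–13 and 21–24 cover the head; 14–20
  the trunk and caudal region. Coordinates are kept in digitizing units;
  a TPS `SCALE=` factor is stored but never pre-multiplied, so centroid
  size units follow whichever system the user selects (shape results are
  invariant to the choice).
- **TraitTable** — seven ratio-normalized linear head traits per
  specimen (HeadL, SnoutL, Upper2, LowerL, JawD divided by standard
  length; HeadH by head length; UpperL1 by lower-jaw length) plus
  counts/flags (gill rakers, pharyngeal tooth rows, parasites, horny-edge
  width).
- **DietTable** — long-format gut contents: one row per (specimen, prey
  item) with wet weight; every item maps to exactly one of six
  categories (zooplankton, small fishes, hydrophilic insects, periphytic
  algae, zoobenthos, others). Guts containing only gelatinous material
  (zero total weight) are excluded before any composition statistic.
- **GrowthTable** — long-format otolith records: one row per annual
  ring, with capture length Lc, capture radius Oc and ring radius Oi,
  under the invariants 0 < O₁ < O₂ < … ≤ Oc.

## Morphometrics

**GPA.** Iterative superimposition: center, scale to unit centroid size,
rotate each configuration onto the running consensus by SVD (reflections
disallowed — all specimens are photographed from the same side), update
the consensus, and stop when it moves < 1e-10 (at most 100 iterations).
The final consensus is put in a canonical orientation (principal axes,
with the 180° ambiguity anchored by the landmark farthest from the
centroid) so results do not depend on how the inputs happened to be
oriented. For nearly isotropic consensus shapes this canonical frame is
ill-conditioned; fish outlines are strongly anisotropic, so this is not
a practical concern.

**Allometry.** Each of the 48 Procrustes coordinates is regressed on
centroid size by least squares and the residuals carried forward. The
default regressor is raw centroid size, with natural-log size as an
option (the common alternative in the literature); the percentage of
total shape variance explained by size is reported either way.

**Feature set and clustering.** The discriminating feature matrix is the
seven linear traits plus the first two PCs of residual shape, z-scored
by default: the traits and PC scores live on incommensurate scales, and
unstandardized mixing would let whichever variable has the largest raw
variance dominate the distance. UPGMA (average linkage) runs on
Euclidean distances of this matrix; morphs are defined by cutting the
dendrogram at two clusters, and the discriminant analysis is then run on
the cluster-defined groups, mirroring the field protocol of
cluster-first, validate-second.

**Discriminant analysis.** Fisher's two-group discriminant with
Wilks' λ = det(W)/det(W+B). Classification is a prior-free
nearest-centroid rule along the discriminant axis; the jackknife refits
the entire discriminant for each left-out specimen (no shortcut).
Because 48 raw Procrustes coordinates exceed the within-group rank, the
shape-only λ is computed on residual-shape PCs covering 95% of variance.
A ridge fallback (flagged in the result) handles singular within-group
scatter; it is off by default so rank problems surface as errors.

**Group tests.** Two-group one-way MANOVA uses the exact F transform of
Wilks' λ, F = ((1−λ)/λ)·(n−p−1)/p. With exactly two groups the Tukey HSD
post hoc contrast reduces to the pairwise t test, so the per-variable
table reports the univariate F = t². The parasite ANCOVA is an OLS model
trait ~ morph + parasite with type-II tests; a constant covariate is
dropped with a flag rather than an error.

## Diet

F% counts the guts containing a prey item among guts with food (sums
over items may exceed 100 because guts hold several items); W% divides
category wet weight by total wet weight and always sums to 100.
Schoener's proportional overlap C_xy = 1 − ½ Σ|P_xc − P_yc| is computed
by default from pooled per-morph W% shares (the W%-based definition),
with per-specimen-averaged shares as an option; inputs must already be
proportions summing to one — nothing is silently renormalized. The
literature uses both C_xy and D_xy for this statistic; one
implementation serves both names. Between-morph category tests are
Kruskal–Wallis on per-specimen W% values (the only level at which a
between-group test is defined), with tie correction; a category absent
from every gut is flagged undefined, and fully tied values yield a zero
statistic by convention.

## Growth

**Back-calculation.** The intercept a of the ln(SL)–ln(otolith radius)
regression at capture feeds the log-scale Fraser–Lee relation
ln L_i = a + (ln L_c − a)(ln O_i / ln O_c). The relation is singular
where ln O_c = 0 (capture radius exactly 1 in the measurement unit); the
implementation raises with advice to rescale units. Intercepts are
fitted per morph with sexes pooled, the standard choice when the
length–radius relation does not differ between sexes.

**VBGF.** Nonlinear least squares on the pooled back-calculated
age–length observations (unweighted; each ring is one observation).
Initialization is Ford–Walford regression of age-mean lengths, with a
multistart grid (L∞ ∈ {1.0, 1.2, 1.5}·max L; k ∈ {0.05, 0.1, 0.2, 0.4};
t₀ ∈ {−1, 0}) as fallback. φ′ = log₁₀k + 2·log₁₀L∞ is reported raw and
rounded half-up to two decimals for table comparison.

**ARSS.** F = ((RSSp − RSSs)/(DFp − DFs)) / (RSSs/DFs) comparing one
pooled curve against per-group curves. Two degrees-of-freedom
conventions are provided because published comparison tables and the
method's methodological source count differently:

- `printed` (default): DFp = n_individuals − 1, DFs = n_individuals − 2,
  reproducing published table arithmetic;
- `chen1992`: DFp = N_obs − 3, DFs = N_obs − 3K, the parameter-counting
  convention under which the statistic is a calibrated nested-model F
  test.

Two p-values accompany every F: `p` refers F to (DFp−DFs, DFs) degrees
of freedom (the standard nested-model reference), and `p_table` to
(DFp, DFs), which is the arithmetic behind published significance
bounds. Group fits are seeded from the pooled solution in addition to
their own initializations, which guarantees RSSs ≤ RSSp up to optimizer
tolerance (the nesting property the F test requires).

**Calibration caveat.** Back-calculated data violate the F test's
independence assumption twice over: rings within a fish are dependent
(growth histories are monotone, and measurement repair preserves that),
and the fitted back-calculation intercept is shared by every observation
of a morph, acting as a small group-level random effect. The test suite
demonstrates (as a characterization test) that the ARSS null rejection
rate on the full synthetic otolith chain exceeds its nominal level —
users should read very large published-style F values with that in mind.
Calibration checks of the statistic itself therefore simulate the model
the F test assumes: independent age–length observations with additive
Gaussian noise (sd = 5% of mean length), under which the empirical null
size is nominal and power for the two morphs' published parameter
contrast is essentially 1.

## Synthetic data generator

The generator's defaults are the study conditions the analyses expect:

- sample sizes 74/80 (morphology), 25/30 (diet), 66/74 (growth), with
  shared specimen ids across tables;
- morph mean shapes of unit centroid size differing only in head
  landmarks (longer head/snout/jaws and a terminal mouth for the
  planktivore), isotropic per-landmark Gaussian shape noise
  (sd 0.012 in unit-centroid-size space), a shared subtle trunk-depth
  allometry, lognormal sizes (median 190 mm, log-sd 0.15), and random
  rotation/translation/scaling so superimposition is exercised;
- the seven linear traits Gaussian around the published morph means with
  sd = SE·√n from the published standard errors; SEs printed as 0.00 are
  bounded only by rounding and are taken as 0.001, a value consistent
  with the printed precision that also preserves the observation that
  every trait contrast is significant at the study sample sizes;
- diets from a Dirichlet scheme (concentration 40 by default) centered
  on six-category profiles whose published entries are fixed
  (planktivore 43.7/34.98/17.08% zooplankton/small fishes/insects;
  benthivore 47.93/12.78% algae/zoobenthos) and whose unreported
  remainder is allocated on ecological grounds (trace benthic bycatch
  for the planktivore; detritus/sand plus planktonic bycatch for the
  benthivore), scaled by lognormal gut weights;
- growth from the published von Bertalanffy parameters (both-sexes fits:
  405.14 mm, 0.102/yr, −0.507 yr and 374.22 mm, 0.116/yr, −0.511 yr)
  with multiplicative lognormal length noise (cv 5% by default) made
  monotone on the log scale, ring radii obtained by exactly inverting
  the Fraser–Lee relation with the published intercepts (5.0789 and
  5.1594), capture-radius scatter about the length–radius line
  (log-sd = cv) and small ring measurement noise (log-sd = cv/10)
  repaired by isotonic projection. Ages are uniform integers on 2–10
  years, consistent with a slow-growing high-altitude fish and enough
  age spread to condition the VBGF fit. At zero noise every generator
  reduces exactly to its template (shapes identical up to similarity,
  W% equal to the profile, back-calculation an exact round trip of the
  growth curve).

Because ln L crosses the back-calculation intercept a within the
realistic length range, fish whose noisy capture length lands within
0.05 log units of the crossing are shifted to its edge: there the
relation amplifies intercept-estimation error without bound. The guard
engages only when noise is present, so the zero-noise limit stays exact.

**What the generator does not emulate:** measurement error in
landmarking, sex differences in growth (both sexes share a morph's
curve, so sex contrasts are true nulls), age-reading error, seasonal
growth, prey-taxon structure below the six categories, and any genetic
signal. Passing tests therefore validate the statistical machinery and
its behavior under the published effect sizes — not instrument-level
realism.

## Design notes and limitations

- Results JSON is written with numbers rounded to 10 significant digits
  and sorted keys; identical seed and inputs give byte-identical files.
- UPGMA tie-breaking and ordering follow the deterministic behavior of
  the underlying average-linkage implementation.
- The two-cluster dendrogram cut can isolate a gross outlier instead of
  splitting morphs; with the planted effect sizes this is vanishingly
  rare but worth checking on real data via the reported cluster sizes.
- Whether a published shape-discrimination λ was computed on Procrustes
  coordinates alone or on a combined feature set is often ambiguous;
  both are reported (`dfa_shape`, `dfa_features`) and neither is claimed
  to reproduce any particular published value, which would require the
  original specimens.
- No sliding semilandmarks, 3-D shapes, >2-group canonical variates,
  stable-isotope mixing, likelihood-ratio (Kimura) curve comparison, or
  sequence-based analyses.
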