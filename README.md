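# morphdiverge

Tools for establishing **trophic resource polymorphism** in a fish
population: do two discrete morphs — a planktivore feeding in open water
and a benthivore grazing the bottom — coexist within one species? The
package implements the three lines of evidence such studies combine, for
ecologists working with landmark photographs, gut contents and otoliths:

1. **Morphology** — generalized Procrustes analysis (GPA) of 24-landmark
   body shapes, allometric correction by regressing Procrustes
   coordinates on centroid size, shape PCA, UPGMA clustering of seven
   linear head traits plus the leading shape PCs, and Fisher discriminant
   analysis with Wilks' λ and leave-one-out jackknife validation.
2. **Diet** — occurrence rates (F%), wet-weight percentages (W%) over six
   food categories, Schoener's proportional overlap
   C_xy = 1 − ½ Σ_c |P_xc − P_yc| (values > 0.6 conventionally indicate
   biologically significant overlap), and per-category Kruskal–Wallis
   tests.
3. **Growth** — Fraser–Lee back-calculation on the log scale,
   ln L_i = a + (ln L_c − a)(ln O_i / ln O_c), von Bertalanffy growth
   function (VBGF) fits L_t = L∞(1 − e^(−k(t−t₀))), the growth
   performance index φ′ = log₁₀k + 2·log₁₀L∞, and ARSS
   (analysis of residual sums of squares) F tests comparing pooled vs
   group-specific growth curves.

A seeded synthetic-data generator (`simulate_study`) reproduces the
statistical structure of a real two-morph study — morph-specific mean
shapes differing only in head landmarks, published trait means, diet
profiles and growth parameters — so the whole pipeline is testable
without field data.

## Worked example

```python
import morphdiverge as md

study = md.simulate_study(seed=1)          # 74 + 80 fish, two morphs

shapes  = md.gpa(study.landmarks)
allom   = md.allometry_residuals(shapes)
pca     = md.shape_pca(allom.residuals)
feats, _ = md.feature_matrix(study.traits, pca, n_pcs=2)

print(md.cluster_agreement(md.upgma(feats).labels, study.labels))
print(md.lda_two_group(feats, study.labels).wilks_lambda)
print(md.overlap_from_table(study.diet).c_xy)
arss = md.compare_growth(study.growth, "morph")["arss"]
print(arss.f, arss.p)
```

Running the bundled scripts (`python examples/01_simulate_and_discriminate.py`
etc.) on seed 1 prints, among other lines:

```
UPGMA two-cluster agreement with the planted morphs: 99.4%
Wilks' lambda (traits + 2 shape PCs): 0.0791
jackknife correct classification, planktivorous: 100.0%
Schoener overlap C_xy = 0.26 (biologically significant above 0.6: False)
planktivorous: L_inf = 431.7 mm, k = 0.091/yr, t0 = -0.62 yr, phi = 4.23
ARSS: F = 7.26, p = 0.00793 (nested-model df)
```

Read: unsupervised clustering recovers the two planted morphs almost
perfectly and the discriminant separates them near-completely (λ close
to 0); the morphs' diets barely overlap (C_xy far below the 0.6
threshold); and a single shared growth curve fits significantly worse
than morph-specific curves — the planktivore tends toward a larger
asymptotic length at a lower growth rate.

A thin CLI mirrors the library:

```bash
morphdiverge simulate --n-plank 74 --n-benth 80 --seed 1 --out data/
morphdiverge report --tps data/landmarks.tps --traits data/traits.csv \
    --diet data/diet.csv --growth data/growth.csv --out results/
```

`results/results.json` is byte-identical across runs with the same seed
and inputs.

## Layout

- `src/morphdiverge/` — library (`tps`, `tables`, `simulate`,
  `morphometrics`, `diet`, `growth`, `pipeline`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices and known
  limitations
- `tests/` — pytest suite, including oracle-based checks of every core
  statistic
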