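"""Simulate a two-morph study and recover the morphs from morphology.

Builds a synthetic population of 74 planktivorous and 80 benthivorous
fish, superimposes the landmark configurations, removes allometry,
combines linear head traits with shape PCs, clusters with UPGMA and
validates the split with a jackknifed discriminant analysis.
"""

import morphdiverge as md

study = md.simulate_study(seed=1)

shapes = md.gpa(study.landmarks)
allom = md.allometry_residuals(shapes)
pca = md.shape_pca(allom.residuals)
features, names = md.feature_matrix(study.traits, pca, n_pcs=2)

clusters = md.upgma(features)
agreement = md.cluster_agreement(clusters.labels, study.labels)
dfa = md.lda_two_group(features, study.labels)

print(f"GPA converged in {shapes.iterations} iterations")
print(f"shape variance explained by size: {allom.pct_variance_explained:.2f}%")
print(f"PC1/PC2 of residual shape: "
      f"{100 * pca.variance_explained[0]:.1f}% / {100 * pca.variance_explained[1]:.1f}%")
print(f"UPGMA two-cluster agreement with the planted morphs: {100 * agreement:.1f}%")
print(f"Wilks' lambda (traits + 2 shape PCs): {dfa.wilks_lambda:.4f}")
for group, pct in dfa.jackknife_pct.items():
    print(f"jackknife correct classification, {group}: {pct:.1f}%")

# Agreement near 100% and lambda near 0 mean the planted head-shape and
# linear-trait differences are large enough to separate the two trophic
# morphs without using the true labels — the study's core morphology claim.
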