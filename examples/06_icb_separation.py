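"""Group separability of ICB responders in numTS space.

Simulates the four-group immunotherapy layout (responder/non-responder x
pre/post treatment) with a mean shift planted only in responder
post-treatment samples, projects the relevant numTS features onto two
principal components, and quantifies the separation of every group pair
with Mahalanobis distances.
"""

from numts import separation
from numts.simulate import SimConfig, simulate_icb_groups

cohort = simulate_icb_groups(SimConfig(seed=5))
numts = cohort.truth["numts_shifted"]
labels = cohort.truth["icb_labels"]

features = numts.loc[cohort.truth["planted_outcome_features"]]
prep = separation.preprocess_lcs(features)
scores, explained = separation.pca_project(prep, n_components=2)
dist = separation.mahalanobis_group_distance(scores, labels.loc[scores.index])

print(f"explained variance: PC1 {explained[0]:.0%}, PC2 {explained[1]:.0%}")
print("\npairwise Mahalanobis distances:")
print(dist.round(2))
print("\nsummed distance per group:")
print(dist.sum(axis=1).round(2).to_string())
print("\nThe responder/post group standing farthest from all others is the")
print("treatment-effect signature: ICB response shows up in target-site space.")
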