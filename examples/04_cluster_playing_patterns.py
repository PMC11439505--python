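"""Cluster participants by playing pattern from their GAF images.

Participants with similar patterns land in the same cluster; the cluster
then defines which participants may serve as domain-adaptation sources
for each other.
"""

import adherence_da as ad
from adherence_da.gaf import participant_gaf

cohort = ad.generate_cohort(ad.CohortSpec(n_participants=16, seed=21, shift=0.2))
mats = {lg.participant_id: participant_gaf(lg) for lg in cohort}
features = ad.extract_features(mats)          # flatten-pca extractor
assign = ad.cluster_participants(features, K=4, seed=0,
                                 study_ids={lg.participant_id: lg.study_id
                                            for lg in cohort})
print(f"K=4 clusters, silhouette={assign.silhouette:.2f}")
truth = {lg.participant_id: lg.archetype for lg in cohort}
for c in range(4):
    members = assign.members(c)
    print(f"cluster {c}: {[truth[m] for m in members]}")

target = cohort[0].participant_id
print(f"source pool for {target}:", ad.source_pool(assign, target))
# clusters should largely recover the archetypes; a target's sources are
# its cluster-mates, i.e. participants with similar adherence behavior.
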