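"""Build a clustered template library and run a two-stage profile search.

Generates a 4-fold synthetic library, clusters it greedily at TM 0.8,
then threads a smeared distance profile of one member back against the
library.  The query's source structure should come back at rank 1 with
alignScore near 1; unrelated folds score far lower.
"""

import dataclasses

from threadfold import greedy_cluster, make_fold_library, make_profile, search_templates

traces, truth, specs = make_fold_library(seed=3, n_folds=4, members_per_fold=3, length=60)
library = greedy_cluster(traces)
print(f"library: {library.n_structures} structures in {library.n_clusters} clusters")
for k, cluster in enumerate(library.clusters):
    folds = sorted({truth[m] for m in cluster.member_ids})
    print(f"  cluster {k}: seed {cluster.seed_id}, {len(cluster.member_ids)} members, "
          f"planted fold(s) {folds}")

query_source = traces[5]
spec = dataclasses.replace(specs[query_source.id], smear_sigma=0.5)
query_profile = make_profile(query_source, spec)
print(f"\nquery: smeared distance profile of {query_source.id} (sigma 0.5 A)")

ranked = search_templates(query_profile, library)
print("rank  template      alignScore  coverage")
for rank, (tid, res) in enumerate(ranked[:5], 1):
    print(f"{rank:>4}  {tid:<12}  {res.alignScore:>9.4f}  {res.coverage:>8}")
print("rank 1 is the planted source; its fold siblings follow, other folds trail.")
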