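"""Annotate anchors with genomic features and rank promoters by activity.

Each anchor gets a node class from a priority-ordered list of feature
sets (first overlap wins); interactions are then labelled by the pair of
classes, summarised per promoter, and ranked.
"""

from collections import Counter

from chromlink import (
    annotate,
    interaction_types,
    rank_features,
    summarize_by_features,
    summarize_dataset,
)
from chromlink.fixtures import (
    FixtureConfig,
    generate_feature_sets,
    generate_interactions,
)

cfg = FixtureConfig(seed=0, n_interactions=1_000)
feature_sets = generate_feature_sets(cfg)  # promoter > enhancer > ctcf
iset, _ = generate_interactions(cfg)

ann = annotate(iset, feature_sets)
print("interaction types:", dict(Counter(interaction_types(ann))))

summary = summarize_dataset(ann)
print(f"cis: {summary.pct_cis:.1f}%  trans: {summary.pct_trans:.1f}%")
print("cis distance quartiles:", summary.distance_quantiles)

promoter_summaries = summarize_by_features(ann, feature_sets[0])
top = rank_features(promoter_summaries, by="n_interactions_total", top_n=5)
print("\ntop promoters by total supporting counts:")
print(top[["feature_id", "n_interactions_total"]].to_string(index=False))
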