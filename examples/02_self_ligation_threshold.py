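"""Estimate the self-ligation distance threshold from raw tag pairs.

Self-ligation products in ChIA-PET are short-range and strand-skewed;
both estimators scan distance bins for the point where the same/opposite
strand ratio becomes statistically indistinguishable from balance.
"""

from chromlink import (
    remove_positional_duplicates,
    self_ligation_threshold_binomial,
    self_ligation_threshold_strand_composition,
)
from chromlink.fixtures import FixtureConfig, generate_tag_pairs

# synthetic library: 20 000 pairs, self-ligation products below 5 000 bp
pairs = generate_tag_pairs(FixtureConfig(seed=0))
pairs = remove_positional_duplicates(pairs)
print(f"{len(pairs)} tag pairs after deduplication")

thr_binom, table = self_ligation_threshold_binomial(pairs)
print(f"binomial-test threshold:          {thr_binom} bp")

thr_strand, _ = self_ligation_threshold_strand_composition(pairs)
print(f"strand-composition threshold:     {thr_strand} bp")

print("\nfirst bins of the distance/strand table:")
print(table.head(12).to_string(index=False))
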