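"""Import interaction data and apply the standard significance filter.

Generates a synthetic ChIA-PET-style dataset on disk, reads it back in
three dialects, keeps only well-supported significant interactions, and
drops everything touching the mitochondrial contig.
"""

import tempfile
from pathlib import Path

from chromlink import read_bedpe, read_chiapet_tool, read_homer_interactions, subset
from chromlink.fixtures import FixtureConfig, write_fixture_files

with tempfile.TemporaryDirectory() as td:
    manifest = write_fixture_files(
        FixtureConfig(seed=0, n_interactions=500), Path(td)
    )

    iset = read_bedpe(manifest["interactions_bedpe"])
    same_homer = read_homer_interactions(manifest["interactions_homer"])
    same_chiapet = read_chiapet_tool(manifest["interactions_chiapet"])
    assert same_chiapet == iset  # dialects describe the same interactions
    print(f"loaded {len(iset)} interactions; metadata: {sorted(iset.metadata)}")

    # keep interactions with more than two supporting counts at FDR < 0.05
    significant = subset(iset, "counts > 2 and fdr < 0.05")
    print(f"significant: {len(significant)} of {len(iset)}")

    # drop mitochondrial interactions (none in this synthetic genome)
    no_chrm = subset(significant, "chrom1 != 'chrM' and chrom2 != 'chrM'")
    print(f"after chrM filter: {len(no_chrm)}")
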