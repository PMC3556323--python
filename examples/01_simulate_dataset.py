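"""Generate a synthetic dataset with planted ground truth.

Writes a toy genome (FASTA), gene models (BED12), a mappability mask
(BED3), ChIP/input tag tracks (BED6), a log2 expression matrix (TSV) and
the truth manifest (JSON) for a 2x2 receptor-genotype x ligand design.
"""

from collections import Counter

from nrcistrome import SimulationConfig, write_simulation

config = SimulationConfig(seed=1)
paths = write_simulation("scratch/example_sim", config)

for name, path in sorted(paths.items()):
    print(f"{name:>14}: {path}")

from nrcistrome import TruthManifest

manifest = TruthManifest.from_json(paths["manifest"])
print(f"\n{config.n_genes} genes on {config.n_chroms} chromosomes of "
      f"{config.chrom_len_bp:,} bp; {len(manifest.sites)} planted binding sites "
      f"({Counter(s.presence for s in manifest.sites)}), "
      f"{len(manifest.artifact_sites)} knockout-null artifact sites.")
print("Planted response types:", dict(Counter(manifest.response_types.values())))
# 'presence' says in which ligand condition a planted site is occupied;
# artifact sites appear in every ChIP sample and must be filtered out.
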