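"""Generate a synthetic flower-opening study with planted ground truth.

Four stages x three replicates; a seed MYB at level 1 of an 8-level
planted cascade of TFs and flavonoid-pathway structural genes, with
metabolites responding to their producing enzymes and promoters carrying
binding sites of each true regulator's TF family.
"""

from collections import Counter

import petalnet as pn
from petalnet import io as pio

cfg = pn.SimConfig(n_tf=50, n_structural=30, n_metabolites=10, rng_seed=42, noise_sd=0.1)
ds = pn.generate_timecourse(cfg)

print(f"expression matrix: {ds.expression.values.shape[0]} genes x "
      f"{ds.expression.values.shape[1]} samples (FPKM)")
print(f"metabolite matrix: {ds.metabolites.values.shape[0]} metabolites "
      f"({len(ds.truth.differential_metabolites)} planted differential)")
levels = Counter(l for n, l in ds.truth.planted_level.items() if not n.startswith("M"))
print("genes per planted level:", dict(sorted(levels.items())))
print(f"planted regulator edges: {len(ds.truth.planted_edges)}; "
      f"planted promoter motifs: {len(ds.truth.planted_motifs)}")

paths = pio.write_dataset(ds, "scratch/example_dataset")
print("written:", ", ".join(p.name for p in paths.values()))
# The level counts show the cascade design: one seed TF at level 1, the
# remaining genes spread over levels 2-8, two levels peaking per stage.
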