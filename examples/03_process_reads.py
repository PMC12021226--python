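"""Per-sample reads -> filtered, rarefied ASV table.

Runs the order-fixed chain (exact dereplication, per-sample bimera
removal, strict 1% low-frequency filter, rarefaction to 1000 reads) and
prints the read accounting plus an exact (hypergeometric, not
Monte-Carlo) rarefaction curve for the first sample.
"""

import numpy as np

from dietbarcode import SimConfig, generate_flora, generate_samples, run_chain
from dietbarcode.asv import accounting_table, rarefaction_curve

cfg = SimConfig(seed=1)
sim = generate_samples(generate_flora(cfg), cfg)
stages = run_chain(sim.reads, depth=1000, lowfreq_threshold=0.01, seed=1)

acct = accounting_table(stages)
first = acct.iloc[0]
print(f"sample {first['sample']}: input {first['raw_input']}, "
      f"chimera-removed {first['nochim_chimera_removed']}, "
      f"low-frequency removed {first['lowfreq_filtered_lowfreq_removed']}")
print(f"ASVs: raw {len(stages['raw'].asvs)} -> "
      f"nochim {len(stages['nochim'].asvs)} -> "
      f"filtered {len(stages['lowfreq_filtered'].asvs)} -> "
      f"rarefied {len(stages['rarefied'].asvs)}")
# the raw stage is huge because every error read is its own exact
# sequence variant; the 1% filter removes them, leaving the true signal.

sample = stages["lowfreq_filtered"].samples[0]
col = stages["lowfreq_filtered"].counts[sample]
counts = col[col > 0].to_numpy()
sizes = np.linspace(1, counts.sum(), 6, dtype=int)
curve = rarefaction_curve(counts, sizes)
print("rarefaction curve (size -> expected ASV richness):")
for m, r in zip(sizes, curve):
    print(f"  {m:5d} -> {r:5.2f}")
# the plateau shows 1000 reads comfortably capture every retained ASV.
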