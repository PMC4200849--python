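"""Neighbor preferences of a self-clustering residue.

Builds a synthetic dataset in which alanine homopolymer runs are planted
into otherwise i.i.d. sequences (the pattern replication slippage leaves
in real proteomes), then profiles the residues flanking every alanine:
relative entropy per offset against the dataset's overall composition,
a 0.001-level shuffle threshold per side, and Tukey-outlier residues.

High totals at the +/-1..4 offsets with A flagged "high" show the
planted self-preference; distant offsets stay at the null level.
"""

import numpy as np

from aacontext import (
    GeneratorConfig,
    annotate_profile,
    background_from_records,
    extract_contexts,
    gen_self_clustering,
    profile,
)

config = GeneratorConfig(n_sequences=400, length_min=150, length_max=300, rng_seed=0)
records, truth = gen_self_clustering(config, run_aa="A", run_rate=0.003, run_length=5)
n_runs = sum(len(r) for r in truth.values())
print(f"{len(records)} sequences, {n_runs} planted A-runs of length 5\n")

background = background_from_records(records)
table = extract_contexts(records, "A", window=8)
prof = profile(table, background)
annotate_profile(table, background, prof, repeats=200, rng_seed=1)

print(f"contexts: n_N={table.n_side['N']}, n_C={table.n_side['C']}")
print(f"thresholds (0.001): N={prof.side_thresholds['N']:.4f} "
      f"C={prof.side_thresholds['C']:.4f}\n")
print("offset  entropy   sd      signif  outliers")
for off in prof.offsets():
    site = prof.sites[off]
    flags = ",".join(f"{aa}:{d}" for aa, d in site.outliers) or "-"
    print(f"{off:+4d}   {site.total:7.4f}  {site.sd:.4f}  "
          f"{'yes' if site.significant else 'no ':4}   {flags}")

print("\nEntropy (bits) measures how far each offset's residue mix departs")
print("from the background; offsets above the shuffle threshold carry a real")
print("positional preference, and the outlier letters name the residues that")
print("drive it (A itself, here, by construction).")
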