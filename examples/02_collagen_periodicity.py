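"""Recovering the 3n-periodic glycine signal of collagen-like repeats.

30% of the synthetic records carry a (G-X-Y)n block — the collagen
triple-helix motif places glycine at every third position — embedded in
i.i.d. flanks. Profiling the sites around glycine at a 6-residue window
should light up exactly the offsets -6, -3, +3, +6, with G itself the
outlier residue at each.
"""

from aacontext import (
    GeneratorConfig,
    annotate_profile,
    background_from_records,
    extract_contexts,
    gen_collagen_mix,
    profile,
)

config = GeneratorConfig(n_sequences=400, rng_seed=0)
records, truth = gen_collagen_mix(config, collagen_fraction=0.3, n_repeats=30)
n_collagen = sum(info["is_collagen"] for info in truth.values())
print(f"{len(records)} sequences, {n_collagen} collagen-like\n")

background = background_from_records(records)
table = extract_contexts(records, "G", window=6)
prof = profile(table, background)
annotate_profile(table, background, prof, repeats=200, rng_seed=1)

print("offset  entropy   signif  G flagged high?")
for off in prof.offsets():
    site = prof.sites[off]
    g_high = ("G", "high") in site.outliers
    print(f"{off:+4d}   {site.total:7.4f}  {'yes' if site.significant else 'no ':4}"
          f"   {'G' if g_high else '-'}")

print(f"\nsignificant offsets: {prof.significant_offsets()} (planted: [-6, -3, 3, 6])")
print("The periodic offsets stand far above the shuffle threshold because")
print("every third site of a repeat is glycine; the intervening offsets are")
print("glycine-free inside the blocks, so their entropies stay near zero.")
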