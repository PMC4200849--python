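"""Structure-stratified recovery of an i,i+4 helix pairing.

All-helix chains are generated with a planted salt-bridge-like pairing:
wherever glutamate (E) occurs, lysine (K) is five times more likely four
residues downstream — the spacing that puts two side chains on the same
helix face. The analysis runs in structure-stratified mode: focal
residues and their 6-site flanks must lie inside one helix segment, and
the background is the helix-residue composition.
"""

from aacontext import (
    GeneratorConfig,
    annotate_profile,
    background_from_records,
    extract_contexts_in_structure,
    gen_helix_pairing,
    profile,
)

config = GeneratorConfig(n_sequences=400, rng_seed=0)
records, truth = gen_helix_pairing(config, ("E", "K"), offset_d=4, enrichment=5.0)
print(f"{len(records)} all-helix chains, planted {truth['pair']} at +{truth['offset_d']} "
      f"(x{truth['enrichment']:.0f})\n")

background = background_from_records(records, scope="structure", structure_class="H")
table = extract_contexts_in_structure(records, "E", "H", window=6)
prof = profile(table, background)
annotate_profile(table, background, prof, repeats=200, rng_seed=1)

print("offset  entropy   signif  outliers")
for off in prof.offsets():
    site = prof.sites[off]
    flags = ",".join(f"{aa}:{d}" for aa, d in site.outliers) or "-"
    print(f"{off:+4d}   {site.total:7.4f}  {'yes' if site.significant else 'no ':4}   {flags}")

print(f"\nsignificant offsets: {prof.significant_offsets()} — only the planted +4,")
print("where K is the flagged outlier; the mirror offset -4 is quiet because")
print("the pairing was planted in one direction only.")
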