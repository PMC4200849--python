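"""Context-dependent substitutions with the bias-correcting background.

Ancestor/descendant pairs are simulated with one planted rule: the
serine-to-proline rate is multiplied by five when a proline already sits
immediately C-terminal (+1) to the site. Events are inferred by
pair-wise comparison of the aligned rows; each substitution type with
enough data is profiled against the per-offset background of its
pre-substituted residue, so the residue's own neighbor preferences
cannot masquerade as substitution context dependence.
"""

from aacontext import (
    GeneratorConfig,
    SubstitutionRule,
    gen_context_substitutions,
    gen_iid,
)
from aacontext.cli import RunConfig, substitution_analysis

config = GeneratorConfig(n_sequences=800, length_min=300, length_max=300, rng_seed=0)
ancestors = gen_iid(config, id_prefix="anc")
rule = SubstitutionRule("S", "P", 1, "P", 5.0)
pairs, events = gen_context_substitutions(ancestors, base_rate=0.02, rule=rule, rng_seed=1)
print(f"{len(pairs)} aligned pairs, {len(events)} substitution events "
      f"(rule: S->P x5 when P at +1)\n")

run_config = RunConfig(window=10, repeats=200, min_events_per_side=100, seed=2)
profiles, summary = substitution_analysis(pairs, ancestors, run_config)

print(summary.to_string(index=False), "\n")
prof = profiles[("S", "P")]
site = prof.sites[1]
print(f"S->P at +1: entropy {site.total:.4f} bits vs threshold "
      f"{site.threshold:.4f}; outliers {site.outliers}")
print("\nOnly the planted S->P type clears the data-size filter and is called")
print("context dependent; its entropy peaks at +1 where P is the flagged")
print("residue — the planted neighborhood rule, recovered from the events.")
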