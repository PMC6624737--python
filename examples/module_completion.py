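"""KEGG-style module completion ratios from a KO inventory.

Shows the boolean step grammar (space = serial steps, comma = alternatives,
plus = complex members, minus = optional) and how a single missing enzyme
caps a pathway's completion.
"""

from thermoprobe import mcr, parse_module_definition

# Entner-Doudoroff-style module: 4 serial steps, step 3 has a single KO
module = parse_module_definition(
    "K00036,K19243 K01057,K07404 K01690 K01625,K17463", module_id="M00008")
print(f"{module.module_id}: {module.n_steps} steps")

present = {"K00036", "K07404", "K01625"}  # phosphogluconate dehydratase absent
res = mcr(module, present)
print(f"KOs present: {sorted(present)}")
print(f"completion: {res.satisfied_steps}/{res.total_steps} steps = {res.mcr}%")
print("Missing K01690 alone holds this pathway at 75% completion - the same")
print("signature that separates metagenomes with and without the ED pathway.\n")

complex_mod = parse_module_definition("(K1,K2)+K3 K4-K5", module_id="demo")
print(f"'{complex_mod.definition_text}' with K2, K3, K4 present:",
      mcr(complex_mod, {"K2", "K3", "K4"}).mcr, "%")
print("(K1,K2)+K3 needs K3 AND one of K1/K2; -K5 is optional and never blocks.")
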