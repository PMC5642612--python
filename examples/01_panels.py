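"""Load the packaged immune gene panels and combine them.

The package ships a 722-gene immune-profiling panel plus synthetic
stand-ins for the type-I/II interferon and cytotoxicity pathway sets;
their union is the 924-gene combined panel the ranking stage uses.
"""

from immunosig import default_registry, membership_table

registry = default_registry()
for name, panel in registry.panels.items():
    print(f"{name:12s} {len(panel):4d} genes  (source: {panel.source.split('/')[-1]})")

combined = registry.combined
print(f"\ncombined union: {len(combined)} genes")

table = membership_table(list(registry.panels.values()))
shared = {g: p for g, p in table.items() if len(p) > 1}
print(f"genes in more than one panel: {len(shared)}")
print("e.g. CXCL9 appears in:", table["CXCL9"])
# The union being smaller than the sum of panel sizes (1134) reflects this
# overlap: interferon-response genes recur across the thematic panels.
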