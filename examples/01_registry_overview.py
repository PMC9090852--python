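"""Load the packaged wheat Rubiscosome registry and summarise its structure.

Prints, per gene, how many loci each subgenome contributes, plus any manual
subgenome assignments (loci on the unassigned chromosome enter the analysis
only through an explicit, recorded override).
"""

import triadbalance as tb

registry = tb.load_packaged_registry()
groups = tb.group_by_gene(registry)

print(f"{tb.count_loci(registry)} loci across {len(groups)} genes\n")
print(f"{'gene':<10} A  B  D")
for gene, by_sg in sorted(groups.items()):
    counts = "  ".join(str(len(by_sg[s])) for s in "ABD")
    print(f"{gene:<10} {counts}")

print("\nManual subgenome overrides:")
for entry in registry.overrides():
    print(f"  {entry.locus.raw_id} -> {entry.effective_subgenome} ({entry.override_note})")

# Counts per subgenome are the number of gene copies that subgenome carries;
# most genes are 1/1/1 triads, while RbcS is a tandem family (9/8/8).
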