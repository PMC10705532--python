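"""Apply the two homologous-recombination deletions and build the diploid
genotype panel used for training-data simulation.

Each deletion collapses a box pair: the haplotype loses exactly the
distance between the two copy starts and keeps a single hybrid box.
"""

from svkg import DEFAULT_SVS, apply_deletion, build_genotype_panel, default_blueprint, generate_haplotype_panel

panel = generate_haplotype_panel(default_blueprint())
template = panel[0]

for sv in DEFAULT_SVS.values():
    mutated = apply_deletion(template, sv)
    print(f"{sv.name}: {len(template)} bp -> {len(mutated)} bp "
          f"(removed {len(template) - len(mutated)} bp; "
          f"surviving box pairs: {sorted(mutated.boxes) or 'none'})")

genomes = build_genotype_panel(panel[:7])
labels = sorted({str(g.label) for g in genomes})
print(f"\n7x7 template pairs x 6 genotypes = {len(genomes)} diploid genomes")
print("genotype classes:", ", ".join(labels))
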