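"""Mendelian trio checking and population allele-frequency estimation.

Works from genotype calls alone, so any caller's output can be audited the
same way: a child is consistent when one of its alleles can come from each
parent, and allele frequencies count het carriers once and homozygotes
twice over the unrelated samples.
"""

import numpy as np

from svkg import Allele, GenotypeLabel, allele_frequencies, mendelian_check, trio_report
from svkg.evaluation import TrioRecord

WT = GenotypeLabel(Allele.WT, Allele.WT)
H37 = GenotypeLabel(Allele.WT, Allele.DEL37)
HOM37 = GenotypeLabel(Allele.DEL37, Allele.DEL37)
C3742 = GenotypeLabel(Allele.DEL37, Allele.DEL42)

trios = [
    TrioRecord("child1", "mum1", "dad1", H37, WT, HOM37),    # forced transmission
    TrioRecord("child2", "mum2", "dad2", C3742, WT, H37),    # impossible
    TrioRecord("child3", "mum3", "dad3", WT, H37, H37),      # both transmit WT
]
report = trio_report(trios)
print(report.to_string(index=False))
n_bad = int((~report.consistent).sum())
print(f"{n_bad} of {len(report)} trios Mendelian-inconsistent "
      f"({n_bad / len(report):.1%})\n")

rng = np.random.default_rng(0)
genotypes, populations = {}, {}
for i in range(400):
    pop = ["AFR", "EUR"][i % 2]
    # emulate a high-frequency deletion in one population only
    p_del = 0.2 if pop == "AFR" else 0.01
    alleles = [Allele.DEL37 if rng.random() < p_del else Allele.WT for _ in range(2)]
    genotypes[f"s{i}"] = GenotypeLabel(*alleles)
    populations[f"s{i}"] = pop

table = allele_frequencies(genotypes, populations)
del37 = table[table.allele == "DEL37"]
print(del37.to_string(index=False, formatters={"frequency": "{:.1%}".format}))
print("\nmendelian_check on child2 alone:",
      mendelian_check(trios[1]))
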