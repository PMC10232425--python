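"""Classify HLA-C alleles into KIR-ligand groups and genotypes into C status.

C1 supertypes: C*01/03/07/08/09/10/12/14/16/17; C2: C*02/04/05/06/15. An
allele group outside both lists raises instead of silently defaulting.
"""

from hedscape import c_group, c_status
from hedscape.hla import HlaGenotype, parse_allele
from hedscape.kir import UnclassifiedAlleleError

for name in ("C*07:01", "C*04:01", "C*12:03"):
    print(f"{name} -> {c_group(parse_allele(name))}")

genotype = HlaGenotype(
    "patient-1",
    {"C": (parse_allele("C*07:01"), parse_allele("C*04:01"))},
)
print(f"genotype C*07:01 / C*04:01 -> {c_status(genotype).status}")

try:
    c_group(parse_allele("C*18:01"))
except UnclassifiedAlleleError as exc:
    print(f"C*18:01 -> unclassified ({exc})")

print()
print("C1 vs C2 carriage shapes natural-killer alloreactivity through the")
print("inhibitory KIR2DL receptors; status feeds the relapse models as a")
print("stratification covariate.")
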