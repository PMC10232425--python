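"""HLA-C KIR-ligand grouping (C1 vs C2).

HLA-C molecules serve as ligands for killer immunoglobulin-like receptors and
partition into two groups by residue 80 of the alpha-1 domain: C1 (Asn77/Asp80,
recognized by KIR2DL2/3) and C2 (Lys80, recognized by KIR2DL1/2DS1). Clinical
assignment works at the level of allele-group supertypes (the first nomenclature
field); genotypes combine into C1/C1, C1/C2 or C2/C2 status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .hla import HlaAllele, HlaGenotype

__all__ = [
    "C1_GROUPS",
    "C2_GROUPS",
    "UnclassifiedAlleleError",
    "CGroupAssignment",
    "CStatus",
    "c_group",
    "c_status",
    "c_status_table",
]

#: Allele-group supertypes carrying the C1 epitope.
C1_GROUPS = frozenset({"01", "03", "07", "08", "09", "10", "12", "14", "16", "17"})
#: Allele-group supertypes carrying the C2 epitope.
C2_GROUPS = frozenset({"02", "04", "05", "06", "15"})


class UnclassifiedAlleleError(ValueError):
    """C-locus allele group outside both supertype lists (e.g. C*18)."""


@dataclass(frozen=True)
class CGroupAssignment:
    allele: HlaAllele
    group: str  # "C1" | "C2"


@dataclass(frozen=True)
class CStatus:
    subject_id: str
    status: str  # "C1/C1" | "C1/C2" | "C2/C2"


def c_group(allele: HlaAllele) -> str:
    """KIR-ligand group of a single HLA-C allele, by allele-group supertype.

    An allele group outside both lists raises, never silently defaults: a
    wrong default would corrupt downstream C1/C2 stratification.
    """
    if allele.locus != "C":
        raise ValueError(f"KIR ligand groups are defined for locus C, got {allele.name}")
    if allele.field1 in C1_GROUPS:
        return "C1"
    if allele.field1 in C2_GROUPS:
        return "C2"
    raise UnclassifiedAlleleError(
        f"allele {allele.name}: group C*{allele.field1} is in neither the C1 "
        f"nor the C2 supertype list"
    )


def c_status(genotype: HlaGenotype) -> CStatus:
    """Genotype-level KIR-ligand status; order of the two alleles is irrelevant."""
    a, b = genotype.pair("C")
    groups = {c_group(a), c_group(b)}
    if groups == {"C1"}:
        status = "C1/C1"
    elif groups == {"C2"}:
        status = "C2/C2"
    else:
        status = "C1/C2"
    return CStatus(subject_id=genotype.subject_id, status=status)


def c_status_table(genotypes: Iterable[HlaGenotype]) -> pd.DataFrame:
    """subject_id -> C status frame for a cohort."""
    records = [c_status(g) for g in genotypes]
    return pd.DataFrame(
        {"subject_id": [r.subject_id for r in records],
         "c_status": [r.status for r in records]}
    ).set_index("subject_id")
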