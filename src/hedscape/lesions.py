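"""Somatic HLA lesion landscape: taxonomy, frequency tabulation, early/late
relapse split, and myeloid co-mutation enrichment.

Inputs are pre-called lesion tables (one row per somatic HLA alteration:
patient, timepoint, allele, category, optional VAF) together with a table of
assayed specimens carrying the grouping covariates. Frequencies collapse to the
patient level — a patient with three lesions counts once — while the
mutation-vs-loss breakdown counts individual lesions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .hla import HlaAllele, parse_allele

__all__ = [
    "TIMEPOINTS",
    "LESION_CATEGORIES",
    "MUTATION_CATEGORIES",
    "LesionTableError",
    "HlaLesion",
    "MyeloidMutation",
    "LesionSummary",
    "read_lesion_table",
    "read_myeloid_table",
    "tabulate",
    "early_late_split",
    "comutation_enrichment",
    "dli_response_crosstab",
]

TIMEPOINTS: tuple[str, ...] = ("diagnosis", "post_chemo_relapse", "post_hct_relapse")
LESION_CATEGORIES: tuple[str, ...] = (
    "missense", "nonsense", "frameshift", "splicing", "UTR", "intronic", "loss",
)
#: Categories counted as mutations (vs allelic losses) in breakdowns.
MUTATION_CATEGORIES: frozenset[str] = frozenset(LESION_CATEGORIES) - {"loss"}


class LesionTableError(ValueError):
    """Malformed lesion/myeloid table or lesion for an unassayed patient."""


@dataclass(frozen=True)
class HlaLesion:
    """One somatic HLA alteration call."""

    patient_id: str
    timepoint: str
    allele: HlaAllele
    category: str
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise LesionTableError(
                f"patient {self.patient_id}: unknown timepoint {self.timepoint!r}"
            )
        if self.category not in LESION_CATEGORIES:
            raise LesionTableError(
                f"patient {self.patient_id}: unknown lesion category {self.category!r}"
            )
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise LesionTableError(
                f"patient {self.patient_id}: VAF {self.vaf} outside [0, 1]"
            )


@dataclass(frozen=True)
class MyeloidMutation:
    """One somatic mutation call in a myeloid driver panel gene."""

    patient_id: str
    timepoint: str
    gene: str
    category: str = "mutation"

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise LesionTableError(
                f"patient {self.patient_id}: unknown timepoint {self.timepoint!r}"
            )


@dataclass(frozen=True)
class LesionSummary:
    """Patient-level lesion frequency for one group."""

    group: str
    numerator: int
    denominator: int
    n_mutation_lesions: int
    n_loss_lesions: int

    @property
    def percent(self) -> int:
        """Nearest-integer percentage, half rounded away from zero."""
        if self.denominator == 0:
            return 0
        return int(math.floor(100.0 * self.numerator / self.denominator + 0.5))

    @property
    def empty(self) -> bool:
        return self.denominator == 0


def read_lesion_table(path: str | Path, *, delimiter: str = "\t") -> list[HlaLesion]:
    """Read a lesion TSV (patient_id, timepoint, allele, category[, vaf])."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = {"patient_id", "timepoint", "allele", "category"}
    missing = required - set(df.columns)
    if missing:
        raise LesionTableError(f"{path}: missing columns {sorted(missing)}")
    lesions = []
    for i, row in df.iterrows():
        try:
            vaf = row.get("vaf")
            lesions.append(
                HlaLesion(
                    patient_id=row["patient_id"],
                    timepoint=row["timepoint"],
                    allele=parse_allele(row["allele"]),
                    category=row["category"],
                    vaf=float(vaf) if vaf not in (None, "") and not pd.isna(vaf) else None,
                )
            )
        except (ValueError, LesionTableError) as exc:
            raise LesionTableError(f"{path} row {i + 2}: {exc}") from exc
    return lesions


def read_myeloid_table(path: str | Path, *, delimiter: str = "\t") -> list[MyeloidMutation]:
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = {"patient_id", "timepoint", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise LesionTableError(f"{path}: missing columns {sorted(missing)}")
    return [
        MyeloidMutation(
            patient_id=r["patient_id"],
            timepoint=r["timepoint"],
            gene=r["gene"],
            category=r.get("category", "mutation") or "mutation",
        )
        for _, r in df.iterrows()
    ]


def _check_assayed(lesions: Iterable[HlaLesion], assayed: pd.DataFrame) -> None:
    have = set(zip(assayed["patient_id"], assayed["timepoint"]))
    for les in lesions:
        if (les.patient_id, les.timepoint) not in have:
            raise LesionTableError(
                f"lesion for patient {les.patient_id} at {les.timepoint} has no "
                f"matching assayed specimen"
            )


def tabulate(
    lesions: Sequence[HlaLesion],
    assayed_patients: pd.DataFrame,
    group_by: str = "timepoint",
) -> list[LesionSummary]:
    """Patient-level lesion frequencies per group.

    ``assayed_patients`` has one row per assayed specimen (patient_id,
    timepoint, grouping covariates). Every lesion must match an assayed
    specimen. Numerators count patients with >= 1 lesion; the mutation/loss
    breakdown counts lesions.
    """
    if group_by not in assayed_patients.columns:
        raise LesionTableError(f"grouping column {group_by!r} not in assayed table")
    _check_assayed(lesions, assayed_patients)
    lesioned: dict[tuple[str, str], list[HlaLesion]] = {}
    for les in lesions:
        lesioned.setdefault((les.patient_id, les.timepoint), []).append(les)

    summaries = []
    for group, sub in assayed_patients.groupby(group_by, sort=True):
        keys = list(zip(sub["patient_id"], sub["timepoint"]))
        hit_keys = [k for k in keys if k in lesioned]
        group_lesions = [l for k in hit_keys for l in lesioned[k]]
        summaries.append(
            LesionSummary(
                group=str(group),
                numerator=len(set(hit_keys)),
                denominator=len(set(keys)),
                n_mutation_lesions=sum(
                    1 for l in group_lesions if l.category in MUTATION_CATEGORIES
                ),
                n_loss_lesions=sum(1 for l in group_lesions if l.category == "loss"),
            )
        )
    return summaries


def early_late_split(
    lesions: Sequence[HlaLesion],
    assayed_patients: pd.DataFrame,
    *,
    time_column: str = "relapse_time_months",
    threshold: float = 6.0,
) -> tuple[LesionSummary, LesionSummary]:
    """Split post-transplant relapse specimens at the relapse-time threshold.

    Late means strictly greater than the threshold (a relapse at exactly 6.0
    months is early). Returns (early, late); a side with no patients is an
    empty summary (denominator 0), flagged via ``LesionSummary.empty``.
    """
    post = assayed_patients[assayed_patients["timepoint"] == "post_hct_relapse"].copy()
    if time_column not in post.columns or post[time_column].isna().any():
        missing = (
            post.loc[post[time_column].isna(), "patient_id"].tolist()
            if time_column in post.columns
            else post["patient_id"].tolist()
        )
        raise LesionTableError(
            f"missing relapse time for post-HCT specimens: {missing}"
        )
    post["__phase"] = [
        "late" if float(t) > threshold else "early" for t in post[time_column]
    ]
    post_lesions = [l for l in lesions if l.timepoint == "post_hct_relapse"]
    by_phase = {s.group: s for s in tabulate(post_lesions, post, group_by="__phase")}
    empty = lambda g: LesionSummary(g, 0, 0, 0, 0)  # noqa: E731
    return by_phase.get("early", empty("early")), by_phase.get("late", empty("late"))


def comutation_enrichment(
    lesions: Sequence[HlaLesion],
    myeloid: Sequence[MyeloidMutation],
    assayed_patients: pd.DataFrame,
    timepoint: str = "post_hct_relapse",
    *,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene enrichment of myeloid driver mutations in HLA-altered patients.

    For each gene, a 2x2 table (HLA-altered vs wild type x gene-mutated vs not)
    is tested with a two-sided Fisher exact test; q-values are
    Benjamini-Hochberg across genes. The displayed odds ratio applies the
    Haldane-Anscombe 0.5 correction; the p-value comes from the uncorrected
    table. Genes with a degenerate margin (mutated in nobody or everybody) are
    kept in the output with OR 1 and p 1 and flagged, with a warning.
    """
    pats = assayed_patients[assayed_patients["timepoint"] == timepoint]
    patients = sorted(set(pats["patient_id"]))
    if not patients:
        raise LesionTableError(f"no assayed patients at timepoint {timepoint!r}")
    altered = {
        l.patient_id for l in lesions
        if l.timepoint == timepoint and l.patient_id in set(patients)
    }
    wild = [p for p in patients if p not in altered]
    if not altered or not wild:
        raise LesionTableError(
            f"need both HLA-altered and wild-type patients at {timepoint!r} "
            f"(altered={len(altered)}, wild type={len(wild)})"
        )
    mut_by_gene: dict[str, set[str]] = {}
    for m in myeloid:
        if m.timepoint == timepoint and m.patient_id in set(patients):
            mut_by_gene.setdefault(m.gene, set()).add(m.patient_id)
    gene_list = list(genes) if genes is not None else sorted(mut_by_gene)

    rows = []
    for gene in gene_list:
        carriers = mut_by_gene.get(gene, set())
        a = len(altered & carriers)                    # altered & mutated
        b = len(altered) - a                           # altered & wild gene
        c = len(carriers) - a                          # HLA-wt & mutated
        d = len(wild) - c                              # HLA-wt & wild gene
        degenerate = (a + c == 0) or (b + d == 0)
        if degenerate:
            warnings.warn(
                f"comutation_enrichment: gene {gene} has a degenerate margin "
                f"({a},{b},{c},{d}); reported with OR 1, p 1",
                stacklevel=2,
            )
            or_display, p = 1.0, 1.0
        else:
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            or_display = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            {"gene": gene, "a_alt_mut": a, "b_alt_wt": b, "c_wt_mut": c,
             "d_wt_wt": d, "odds_ratio": or_display, "p": float(p),
             "degenerate": degenerate}
        )
    out = pd.DataFrame(rows).set_index("gene")
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def dli_response_crosstab(
    lesions: Sequence[HlaLesion],
    dli_patients: pd.DataFrame,
) -> pd.DataFrame:
    """Descriptive cross-tab of lesion class vs response to donor lymphocyte
    infusion (no test: the subgroup is too small for inference).

    ``dli_patients`` has patient_id and a boolean ``dli_response`` column.
    Lesion class per patient: 'exonic_or_loss' if any lesion is exonic
    (missense/nonsense/frameshift/splicing) or a loss, 'utr_or_intronic' if
    lesions are regulatory only, 'none' otherwise.
    """
    exonic = {"missense", "nonsense", "frameshift", "splicing", "loss"}
    by_patient: dict[str, set[str]] = {}
    for l in lesions:
        by_patient.setdefault(l.patient_id, set()).add(l.category)

    def klass(pid: str) -> str:
        cats = by_patient.get(pid, set())
        if cats & exonic:
            return "exonic_or_loss"
        if cats:
            return "utr_or_intronic"
        return "none"

    frame = pd.DataFrame(
        {
            "lesion_class": [klass(p) for p in dli_patients["patient_id"]],
            "response": [
                "complete_response" if bool(r) else "no_response"
                for r in dli_patients["dli_response"]
            ],
        }
    )
    return pd.crosstab(frame["lesion_class"], frame["response"])
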