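"""HLA evolutionary divergence (HED): per-locus, per-class and global scores.

HED at a locus is the mean Grantham distance per aligned position between the
peptide-binding-domain sequences of a subject's two alleles — a proxy for the
breadth of the immunopeptidome the genotype can present. Scores are
dichotomized against the 50th percentile of a healthy-control reference
distribution, slot by slot (each locus, each class mean, and the global mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grantham import GranthamModel, default_model
from .hla import (
    CLASS1_LOCI,
    CLASS2_LOCI,
    HED_LOCI,
    AlleleSequenceDictionary,
    HlaGenotype,
)

__all__ = [
    "SCORE_SLOTS",
    "DivergenceError",
    "HedProfile",
    "ReferenceCutoffs",
    "HedCategoryProfile",
    "sequence_divergence",
    "compute_hed_profile",
    "compute_hed_table",
    "compute_reference_cutoffs",
    "dichotomize",
    "categories_table",
]

#: Score slots carried by every profile: six loci, two class means, global mean.
SCORE_SLOTS: tuple[str, ...] = HED_LOCI + ("class1", "class2", "global")


class DivergenceError(ValueError):
    """Raised for incomparable sequences or missing dictionary entries."""


def sequence_divergence(
    seq_a: str, seq_b: str, model: GranthamModel | None = None
) -> float:
    """Mean per-site Grantham distance between two equal-length domain sequences.

    Positions where either sequence carries an unknown residue ('X') are
    excluded pairwise and the denominator is the number of included positions,
    so unknowns neither inflate nor dilute divergence.
    """
    model = model or default_model()
    if len(seq_a) != len(seq_b):
        raise DivergenceError(
            f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    ia = model.encode(seq_a)
    ib = model.encode(seq_b)
    keep = (ia >= 0) & (ib >= 0)
    n_eff = int(keep.sum())
    if n_eff == 0:
        raise DivergenceError("no comparable positions (all masked or empty)")
    dense = model._dense  # noqa: SLF001 - hot path within the package
    return float(dense[ia[keep], ib[keep]].sum() / n_eff)


@dataclass(frozen=True)
class HedProfile:
    """Divergence scores for one subject: per locus, per class, and global."""

    subject_id: str
    per_locus: Mapping[str, float]
    class1: float
    class2: float
    global_mean: float

    def slot(self, name: str) -> float:
        if name in self.per_locus:
            return self.per_locus[name]
        return {"class1": self.class1, "class2": self.class2,
                "global": self.global_mean}[name]

    def as_dict(self) -> dict[str, float]:
        return {s: self.slot(s) for s in SCORE_SLOTS}


def compute_hed_profile(
    genotype: HlaGenotype,
    dictionary: AlleleSequenceDictionary,
    model: GranthamModel | None = None,
) -> HedProfile:
    """Score one genotype: locus HEDs, class I/II means, and the global mean.

    The class means are unweighted arithmetic means of their three locus
    scores; the global mean averages all six loci. A homozygous locus scores
    exactly 0.
    """
    model = model or default_model()
    per_locus: dict[str, float] = {}
    for locus in HED_LOCI:
        if locus not in genotype.alleles:
            raise DivergenceError(
                f"subject {genotype.subject_id}: locus {locus} missing from genotype"
            )
        a, b = genotype.pair(locus)
        per_locus[locus] = sequence_divergence(
            dictionary.sequence(a), dictionary.sequence(b), model
        )
    class1 = sum(per_locus[l] for l in CLASS1_LOCI) / len(CLASS1_LOCI)
    class2 = sum(per_locus[l] for l in CLASS2_LOCI) / len(CLASS2_LOCI)
    global_mean = sum(per_locus[l] for l in HED_LOCI) / len(HED_LOCI)
    return HedProfile(
        subject_id=genotype.subject_id,
        per_locus=per_locus,
        class1=class1,
        class2=class2,
        global_mean=global_mean,
    )


def compute_hed_table(
    genotypes: Iterable[HlaGenotype],
    dictionary: AlleleSequenceDictionary,
    model: GranthamModel | None = None,
) -> pd.DataFrame:
    """Vector of profiles as a DataFrame indexed by subject_id.

    Pairwise allele divergences are cached per locus, which makes cohort-scale
    scoring (thousands of subjects over a modest allele pool) cheap.
    """
    model = model or default_model()
    cache: dict[tuple[str, str], float] = {}
    rows = []
    for g in genotypes:
        row: dict[str, float | str] = {"subject_id": g.subject_id}
        for locus in HED_LOCI:
            a, b = g.pair(locus)
            key = (a.name, b.name) if a.name <= b.name else (b.name, a.name)
            if key not in cache:
                cache[key] = sequence_divergence(
                    dictionary.sequence(a), dictionary.sequence(b), model
                )
            row[f"HED_{locus}"] = cache[key]
        row["HED_class1"] = np.mean([row[f"HED_{l}"] for l in CLASS1_LOCI])
        row["HED_class2"] = np.mean([row[f"HED_{l}"] for l in CLASS2_LOCI])
        row["HED_global"] = np.mean([row[f"HED_{l}"] for l in HED_LOCI])
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def profiles_from_table(table: pd.DataFrame) -> list[HedProfile]:
    """Rebuild :class:`HedProfile` objects from a :func:`compute_hed_table` frame."""
    return [
        HedProfile(
            subject_id=str(sid),
            per_locus={l: float(row[f"HED_{l}"]) for l in HED_LOCI},
            class1=float(row["HED_class1"]),
            class2=float(row["HED_class2"]),
            global_mean=float(row["HED_global"]),
        )
        for sid, row in table.iterrows()
    ]


@dataclass(frozen=True)
class ReferenceCutoffs:
    """50th-percentile benchmarks per score slot, from a reference cohort."""

    source: str
    cutoffs: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(SCORE_SLOTS) - set(self.cutoffs)
        extra = set(self.cutoffs) - set(SCORE_SLOTS)
        if missing or extra:
            raise ValueError(
                f"cutoff keys must cover exactly {SCORE_SLOTS}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        neg = {k: v for k, v in self.cutoffs.items() if v < 0}
        if neg:
            raise ValueError(f"negative cutoffs: {neg}")


def compute_reference_cutoffs(
    control_profiles: Sequence[HedProfile], *, source: str = "healthy-controls"
) -> ReferenceCutoffs:
    """Median (50th percentile, linear interpolation) of each score slot over
    the control cohort. Requires at least two controls."""
    if len(control_profiles) < 2:
        raise ValueError(
            f"need >= 2 control profiles to define percentile cutoffs, "
            f"got {len(control_profiles)}"
        )
    cutoffs = {
        slot: float(np.percentile([p.slot(slot) for p in control_profiles], 50))
        for slot in SCORE_SLOTS
    }
    return ReferenceCutoffs(source=source, cutoffs=cutoffs)


@dataclass(frozen=True)
class HedCategoryProfile:
    """high/low category per score slot: high iff score strictly above cutoff."""

    subject_id: str
    categories: Mapping[str, str]  # slot -> "high" | "low"


def dichotomize(profile: HedProfile, cutoffs: ReferenceCutoffs) -> HedCategoryProfile:
    """Classify each slot as high iff its score strictly exceeds the reference
    cutoff; a score exactly at the cutoff is low ("high divergence" means
    strictly above the reference median)."""
    cats = {}
    for slot in SCORE_SLOTS:
        if slot not in cutoffs.cutoffs:  # pragma: no cover - guarded by type
            raise KeyError(f"missing cutoff for slot {slot}")
        cats[slot] = "high" if profile.slot(slot) > cutoffs.cutoffs[slot] else "low"
    return HedCategoryProfile(subject_id=profile.subject_id, categories=cats)


def categories_table(hed_table: pd.DataFrame, cutoffs: ReferenceCutoffs) -> pd.DataFrame:
    """Vectorized dichotomization of a :func:`compute_hed_table` frame.

    Returns one ``<slot>_cat`` column per score slot, values 'high'/'low'.
    """
    out = pd.DataFrame(index=hed_table.index)
    for slot in SCORE_SLOTS:
        out[f"{slot}_cat"] = np.where(
            hed_table[f"HED_{slot}"] > cutoffs.cutoffs[slot], "high", "low"
        )
    return out
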