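"""HLA nomenclature parsing, genotype tables, and allele-to-sequence dictionaries.

The analyses in this package work at protein-level (2-field) allele resolution:
``A*02:01:01:01`` and ``A*02:01:01:02`` encode the same mature protein for the
purposes of peptide-binding-domain divergence, so everything downstream keys on
the 2-field name. Expression suffixes (N/L/S/Q/C/A) and 3rd/4th fields are
accepted on input and truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "HlaParseError",
    "UnsupportedLocusError",
    "GenotypeTableError",
    "SequenceDictionaryError",
    "LOCI",
    "CLASS1_LOCI",
    "CLASS2_LOCI",
    "HED_LOCI",
    "HlaAllele",
    "HlaGenotype",
    "AlleleSequenceDictionary",
    "parse_allele",
    "read_genotype_table",
    "write_genotype_table",
    "read_allele_sequences",
]


class HlaParseError(ValueError):
    """Raised when an allele string does not follow HLA nomenclature."""


class UnsupportedLocusError(HlaParseError):
    """Raised when the locus token is not one of the 11 classical loci."""


class GenotypeTableError(ValueError):
    """Raised for malformed genotype tables (duplicates, half-typed loci...)."""


class SequenceDictionaryError(ValueError):
    """Raised for invalid allele sequence collections."""


#: The 11 classical loci typed by clinical HLA assays.
LOCI: tuple[str, ...] = (
    "A", "B", "C",
    "DRB1", "DRB3", "DRB4", "DRB5",
    "DQA1", "DQB1", "DPA1", "DPB1",
)

#: Loci entering divergence scoring, by HLA class.
CLASS1_LOCI: tuple[str, ...] = ("A", "B", "C")
CLASS2_LOCI: tuple[str, ...] = ("DRB1", "DQB1", "DPB1")
HED_LOCI: tuple[str, ...] = CLASS1_LOCI + CLASS2_LOCI

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>[A-Z]+[0-9]*)\*"
    r"(?P<f1>\d{2,4})"
    r":(?P<f2>\d{2,4})"
    r"(?P<rest>(?::\d{2,4}){0,2})"
    r"(?P<suffix>[NLSQCA]?)$"
)


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A protein-level (2-field) HLA allele, e.g. ``C*07:01``."""

    locus: str
    field1: str
    field2: str
    raw: str = field(default="", compare=False)

    @property
    def name(self) -> str:
        return f"{self.locus}*{self.field1}:{self.field2}"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


def parse_allele(text: str) -> HlaAllele:
    """Parse an HLA nomenclature string into a normalized 2-field allele.

    Extra fields (synonymous / intronic) and expression suffixes are truncated;
    legacy no-separator forms (``B07:02``) are rejected.

    Raises
    ------
    HlaParseError
        If the text does not match ``LOCUS*gg:pp[:...][suffix]``.
    UnsupportedLocusError
        If the locus token is not one of the 11 classical loci.
    """
    token = text.strip()
    m = _ALLELE_RE.match(token)
    if m is None:
        raise HlaParseError(
            f"malformed HLA allele string {token!r}: expected LOCUS*gg:pp[...]"
        )
    locus = m.group("locus")
    if locus not in LOCI:
        raise UnsupportedLocusError(
            f"unsupported HLA locus {locus!r} in {token!r}; expected one of {LOCI}"
        )
    return HlaAllele(locus=locus, field1=m.group("f1"), field2=m.group("f2"), raw=token)


@dataclass(frozen=True)
class HlaGenotype:
    """Per-subject mapping locus -> unordered allele tuple.

    The six divergence loci (A, B, C, DRB1, DQB1, DPB1), when present, must hold
    exactly two alleles (identical alleles = homozygous). Other loci may be
    absent or hemizygous (single allele), as DRB3/4/5 commonly are.
    """

    subject_id: str
    alleles: Mapping[str, tuple[HlaAllele, ...]]

    def __post_init__(self) -> None:
        for locus, pair in self.alleles.items():
            if locus not in LOCI:
                raise UnsupportedLocusError(f"unsupported locus {locus!r}")
            if any(a.locus != locus for a in pair):
                raise GenotypeTableError(
                    f"subject {self.subject_id}: allele filed under wrong locus {locus}"
                )
            if locus in HED_LOCI and len(pair) != 2:
                raise GenotypeTableError(
                    f"subject {self.subject_id}: locus {locus} needs exactly 2 alleles, "
                    f"got {len(pair)}"
                )
            if len(pair) not in (1, 2):
                raise GenotypeTableError(
                    f"subject {self.subject_id}: locus {locus} holds {len(pair)} alleles"
                )

    def pair(self, locus: str) -> tuple[HlaAllele, HlaAllele]:
        pair = self.alleles[locus]
        if len(pair) != 2:
            raise GenotypeTableError(
                f"subject {self.subject_id}: locus {locus} is not diploid-typed"
            )
        return pair[0], pair[1]

    def is_homozygous(self, locus: str) -> bool:
        a, b = self.pair(locus)
        return a.name == b.name


def read_genotype_table(path: str | Path, *, delimiter: str = "\t") -> list[HlaGenotype]:
    """Read a wide genotype table (columns ``subject_id`` and ``<LOCUS>_1/_2``).

    Loci with both cells blank are omitted; a single blank cell at a divergence
    locus is an error naming the subject and locus; at other loci the single
    allele is kept (hemizygous call).
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str).fillna("")
    if "subject_id" not in df.columns:
        raise GenotypeTableError(f"{path}: missing required column 'subject_id'")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise GenotypeTableError(f"{path}: duplicate subject id(s): {sorted(set(dupes))}")

    present = [loc for loc in LOCI if f"{loc}_1" in df.columns or f"{loc}_2" in df.columns]
    genotypes: list[HlaGenotype] = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        alleles: dict[str, tuple[HlaAllele, ...]] = {}
        for locus in present:
            cells = [str(row.get(f"{locus}_{i}", "")).strip() for i in (1, 2)]
            filled = [c for c in cells if c]
            if not filled:
                continue
            if len(filled) == 1 and locus in HED_LOCI:
                raise GenotypeTableError(
                    f"subject {sid}: locus {locus} has one of two alleles blank"
                )
            alleles[locus] = tuple(parse_allele(c) for c in filled)
        genotypes.append(HlaGenotype(subject_id=sid, alleles=alleles))
    return genotypes


def write_genotype_table(
    genotypes: Iterable[HlaGenotype], path: str | Path, *, delimiter: str = "\t"
) -> None:
    """Write genotypes in the wide ``<LOCUS>_1/_2`` dialect read back by
    :func:`read_genotype_table`."""
    rows = []
    for g in genotypes:
        row: dict[str, str] = {"subject_id": g.subject_id}
        for locus, pair in g.alleles.items():
            for i, allele in enumerate(pair, start=1):
                row[f"{locus}_{i}"] = allele.name
        rows.append(row)
    cols = ["subject_id"] + [
        f"{loc}_{i}" for loc in LOCI for i in (1, 2)
        if any(f"{loc}_{i}" in r for r in rows)
    ]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, sep=delimiter, index=False)


_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlleleSequenceDictionary:
    """Allele -> peptide-binding-domain amino-acid sequence.

    For class I loci the sequence is the concatenation of the exon 2 and exon 3
    protein products (the alpha-1/alpha-2 domains forming the binding groove);
    for class II beta loci it is the exon 2 product (beta-1 domain). All
    sequences of a locus must have equal length; residues are the 20 standard
    letters plus 'X' for unknown.
    """

    version: str
    entries: Mapping[str, str]  # 2-field allele name -> sequence

    def __post_init__(self) -> None:
        lengths: dict[str, dict[str, int]] = {}
        for name, seq in self.entries.items():
            allele = parse_allele(name)
            bad = set(seq) - _VALID_RESIDUES
            if bad:
                raise SequenceDictionaryError(
                    f"{name}: non-amino-acid characters {sorted(bad)}"
                )
            lengths.setdefault(allele.locus, {})[name] = len(seq)
        for locus, by_allele in lengths.items():
            if len(set(by_allele.values())) > 1:
                raise SequenceDictionaryError(
                    f"locus {locus}: sequence length mismatch: {by_allele}"
                )

    def sequence(self, allele: HlaAllele) -> str:
        try:
            return self.entries[allele.name]
        except KeyError:
            raise SequenceDictionaryError(
                f"allele {allele.name} not present in sequence dictionary "
                f"{self.version!r}"
            ) from None

    def __contains__(self, allele: HlaAllele) -> bool:
        return allele.name in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _header_allele(record_description: str) -> tuple[str, HlaAllele]:
    """Extract the first parseable allele name from a FASTA header.

    IMGT/HLA headers look like ``HLA:HLA00001 A*01:01:01:01 365 bp``; plain
    ``>A*01:01`` headers are accepted too. Returns (full-resolution name, parsed
    2-field allele).
    """
    for token in record_description.split():
        try:
            return token, parse_allele(token)
        except HlaParseError:
            continue
    raise SequenceDictionaryError(
        f"no parseable allele name in FASTA header {record_description!r}"
    )


def read_allele_sequences(path: str | Path, *, version: str | None = None) -> AlleleSequenceDictionary:
    """Read a FASTA of binding-domain protein sequences into a dictionary.

    Entries are keyed at 2-field resolution. When several full-resolution
    alleles reduce to one 2-field key, the sequence of the lexicographically
    smallest full name is kept, so the result does not depend on file order.
    """
    chosen: dict[str, tuple[str, str]] = {}  # 2-field name -> (full name, seq)
    for record in SeqIO.parse(str(path), "fasta"):
        full_name, allele = _header_allele(record.description)
        seq = str(record.seq).upper()
        key = allele.name
        if key not in chosen or full_name < chosen[key][0]:
            chosen[key] = (full_name, seq)
    return AlleleSequenceDictionary(
        version=version if version is not None else Path(path).stem,
        entries={k: v[1] for k, v in chosen.items()},
    )
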