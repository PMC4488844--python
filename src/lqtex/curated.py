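"""Curated mutation and clinical tables from a familial LQTS exome study.

These small transcribed tables serve as worked-example inputs: the
candidate mutations called in the discovery families, the candidate
mutations found in the independent unrelated cases, and the clinical
records of the unrelated RYR2 carriers.  Genomic coordinates are not part
of the published tables, so placeholder coordinates are derived
deterministically from each cDNA change (one synthetic chromosome label
per gene) purely to give every variant a unique join key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .variant_model import (
    Annotation,
    FunctionalClass,
    PolyPhen,
    Sift,
    VariantSite,
)

__all__ = [
    "KNOWN_LQTS_GENES",
    "CALMODULIN_INTERACTING",
    "NOVEL_CANDIDATE_GENES",
    "FAMILY_CANDIDATES",
    "UNRELATED_CANDIDATES",
    "RYR2_CLINICAL",
    "TABLE4_SLC2A5_CARRIERS",
    "CuratedMutation",
    "UnrelatedMutation",
    "ClinicalRecord",
    "to_variant_site",
    "to_annotation",
]

# the 15 known LQTS susceptibility genes (LQT1-LQT15)
KNOWN_LQTS_GENES = frozenset(
    {
        "KCNQ1", "KCNH2", "SCN5A", "ANK2", "KCNE1", "KCNE2", "KCNJ2",
        "CACNA1C", "CAV3", "SCN4B", "AKAP9", "SNTA1", "KCNJ5", "CALM1",
        "CALM2",
    }
)

# novel candidates whose proteins directly bind calmodulin
CALMODULIN_INTERACTING = frozenset({"RYR2", "UBR4", "UBR5", "PI4KA", "KIF21B"})

# the 11 novel candidate pathogenic genes (10 from the PPI network
# analysis plus the gene-based association hit SLC2A5)
NOVEL_CANDIDATE_GENES = (
    "WDR26", "RYR2", "UBR5", "UBR4", "KIF21B", "CIT", "SIRT6", "PIK3CG",
    "PI4KA", "RIMS1", "SLC2A5",
)


@dataclass(frozen=True)
class CuratedMutation:
    family: str
    gene: str
    model: str  # de_novo | recessive_compound_het | dominant
    transcript: str
    cdna: str
    protein: str  # "" for splice variants
    sift: str  # D / T / -
    polyphen: str  # D / P / B / -
    analysis: str  # PPI or GAS


# candidate mutations called in the discovery families and supported by
# the network / association analyses (compound-het pair: the two UBR5
# rows of family T12)
FAMILY_CANDIDATES: tuple[CuratedMutation, ...] = (
    CuratedMutation("T02", "WDR26", "de_novo", "NM_025160.6", "c.612G>T", "p.L204F", "T", "-", "PPI"),
    CuratedMutation("T08", "RYR2", "de_novo", "NM_001035.2", "c.12272C>T", "p.A4091V", "D", "D", "PPI"),
    CuratedMutation("T12", "UBR5", "recessive_compound_het", "NM_015902.5", "c.5837A>G", "p.H1946R", "D", "P", "PPI"),
    CuratedMutation("T12", "UBR5", "recessive_compound_het", "NM_015902.5", "c.3752G>A", "p.R1251H", "D", "B", "PPI"),
    CuratedMutation("T17", "UBR4", "de_novo", "NM_020765.2", "c.6397G>A", "p.A2133T", "T", "D", "PPI"),
    CuratedMutation("T21", "KIF21B", "de_novo", "NM_017596.2", "c.3601C>T", "p.R1201W", "D", "D", "PPI"),
    CuratedMutation("D02", "SLC2A5", "dominant", "NM_003039.2", "c.808C>T", "p.R270W", "D", "D", "GAS"),
    CuratedMutation("D03", "CIT", "dominant", "NM_001206999.1", "c.5786C>A", "p.S1929Y", "D", "D", "PPI"),
    CuratedMutation("D04", "KCNQ1", "dominant", "NM_000218.2", "c.683+2T>G", "", "-", "-", "PPI"),
    CuratedMutation("D07", "CAV3", "dominant", "NM_033337.2", "c.37A>T", "p.I13F", "T", "B", "PPI"),
    CuratedMutation("D08", "KCNQ1", "dominant", "NM_000218.2", "c.1032+1G>A", "", "-", "-", "PPI"),
    CuratedMutation("D09", "KCNE1", "dominant", "NM_000219.3", "c.253G>A", "p.D85N", "D", "P", "PPI"),
    CuratedMutation("D10", "SIRT6", "dominant", "NM_016539.2", "c.742C>T", "p.R248C", "D", "D", "PPI"),
    CuratedMutation("D10", "PIK3CG", "dominant", "NM_002649.2", "c.574G>A", "p.D192N", "T", "D", "PPI"),
    CuratedMutation("D14", "PI4KA", "dominant", "NM_058004.2", "c.247G>A", "p.D83N", "D", "D", "PPI"),
    CuratedMutation("D14", "RIMS1", "dominant", "NM_014989.4", "c.1477G>C", "p.E493Q", "D", "D", "PPI"),
)


@dataclass(frozen=True)
class UnrelatedMutation:
    individual: str
    gene: str
    transcript: str
    cdna: str
    protein: str
    sift: str
    polyphen: str
    conserved: bool


# candidate mutations in the 11 genes found among the independent
# unrelated cases; the WDR26 and RYR2 p.R3673W mutations share one
# carrier (U06), all other mutations have distinct carriers
UNRELATED_CANDIDATES: tuple[UnrelatedMutation, ...] = (
    UnrelatedMutation("U01", "RYR2", "NM_001035.2", "c.497C>G", "p.S166C", "D", "D", True),
    UnrelatedMutation("U02", "RYR2", "NM_001035.2", "c.1259G>A", "p.R420Q", "D", "D", False),
    UnrelatedMutation("U03", "RYR2", "NM_001035.2", "c.1298T>C", "p.L433P", "D", "B", True),
    UnrelatedMutation("U04", "RYR2", "NM_001035.2", "c.5278C>T", "p.R1760W", "D", "D", False),
    UnrelatedMutation("U05", "RYR2", "NM_001035.2", "c.8470C>T", "p.R2824W", "D", "D", False),
    UnrelatedMutation("U06", "RYR2", "NM_001035.2", "c.11017C>T", "p.R3673W", "D", "D", False),
    UnrelatedMutation("U07", "RYR2", "NM_001035.2", "c.12438G>C", "p.E4146D", "D", "D", True),
    UnrelatedMutation("U08", "RYR2", "NM_001035.2", "c.13780A>C", "p.K4594Q", "D", "D", True),
    UnrelatedMutation("U09", "UBR4", "NM_020765.2", "c.1097A>G", "p.K366R", "T", "P", True),
    UnrelatedMutation("U10", "UBR4", "NM_020765.2", "c.1349G>T", "p.R450L", "D", "D", True),
    UnrelatedMutation("U11", "UBR4", "NM_020765.2", "c.1557G>C", "p.Q519H", "D", "D", True),
    UnrelatedMutation("U12", "UBR5", "NM_015902.5", "c.2965C>T", "p.R989W", "-", "-", False),
    UnrelatedMutation("U13", "PI4KA", "NM_058004.2", "c.738C>G", "p.I246M", "T", "P", True),
    UnrelatedMutation("U14", "KIF21B", "NM_017596.2", "c.2224G>A", "p.E742K", "D", "P", True),
    UnrelatedMutation("U15", "CIT", "NM_001206999.1", "c.5783C>T", "p.A1928V", "-", "-", True),
    UnrelatedMutation("U06", "WDR26", "NM_001115113.2", "c.59G>A", "p.G20E", "T", "-", False),
)


@dataclass(frozen=True)
class ClinicalRecord:
    cdna: str
    protein: str
    age: int
    sex: str
    qtc: int  # ms
    event: str
    novel: bool


# clinical background of the unrelated RYR2 mutation carriers
RYR2_CLINICAL: tuple[ClinicalRecord, ...] = (
    ClinicalRecord("c.497C>G", "p.S166C", 11, "F", 416, "Syncope during swim", True),
    ClinicalRecord("c.1259G>A", "p.R420Q", 14, "M", 412, "Syncope during swim (12 y), SD (17 y)", False),
    ClinicalRecord("c.1298T>C", "p.L433P", 18, "F", 452, "VF during exercise (17 y)", False),
    ClinicalRecord("c.5278C>T", "p.R1760W", 16, "M", 425, "Syncope during swim", True),
    ClinicalRecord("c.8470C>T", "p.R2824W", 7, "M", 439, "Asympt", True),
    ClinicalRecord("c.11017C>T", "p.R3673W", 16, "M", 469, "Heart failure", True),
    ClinicalRecord("c.12272C>T", "p.A4091V", 16, "M", 443, "CA during exercise", False),
    ClinicalRecord("c.12438G>C", "p.E4146D", 2, "F", 401, "VF", True),
    ClinicalRecord("c.13780A>C", "p.K4594Q", 12, "F", 496, "Syncope during swim (10 y)", True),
)

# published per-variant het carrier counts (cases, controls) for the
# three rare SLC2A5 variants of the association hit
TABLE4_SLC2A5_CARRIERS: tuple[tuple[int, int], ...] = ((4, 1), (1, 0), (1, 1))


_CDNA_RE = re.compile(r"^c\.(\d+)(?:([+-])(\d+))?([ACGT])>([ACGT])$")

_GENE_CHROM = {g: str(i + 1) for i, g in enumerate(sorted(
    {m.gene for m in FAMILY_CANDIDATES} | {m.gene for m in UNRELATED_CANDIDATES}
))}

_SIFT = {"D": Sift.damaging, "T": Sift.tolerated, "-": Sift.missing}
_POLYPHEN = {
    "D": PolyPhen.probably_damaging,
    "P": PolyPhen.possibly_damaging,
    "B": PolyPhen.benign,
    "-": PolyPhen.missing,
}


def to_variant_site(mut) -> VariantSite:
    """Build a VariantSite with deterministic placeholder coordinates.

    The cDNA coordinate (plus any intronic offset) fixes the position;
    intronic-offset changes are canonical splice-site variants.
    """
    m = _CDNA_RE.match(mut.cdna)
    if not m:
        raise ValueError(f"cannot parse cDNA change {mut.cdna!r}")
    base, sign, offset, ref, alt = m.groups()
    splice = offset is not None
    pos = int(base) * 1000 + (int(offset) if offset else 0)
    return VariantSite(
        chrom=_GENE_CHROM[mut.gene],
        pos=pos,
        ref=ref,
        alt=alt,
        gene=mut.gene,
        transcript=mut.transcript,
        cdna_change=mut.cdna,
        protein_change=mut.protein,
        functional_class=(
            FunctionalClass.canonical_splice if splice else FunctionalClass.missense
        ),
    )


def to_annotation(mut, strand_counts=(20, 20, 10, 10)) -> Annotation:
    """Annotation for a curated mutation: database-absent, balanced strands."""
    return Annotation(
        sift=_SIFT[mut.sift],
        polyphen=_POLYPHEN[mut.polyphen],
        db_flags=frozenset(),
        maf=None,
        strand_counts=strand_counts,
    )
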