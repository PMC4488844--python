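"""Core domain types and file I/O for the LQTS exome pipeline.

Variants are keyed throughout on ``(chrom, pos, ref, alt)`` with 1-based
VCF coordinates.  Multi-allelic VCF records are split into one
:class:`VariantSite` per alternate allele on read.  Genotypes are diploid
and unphased; sex chromosomes are treated as diploid (the candidate
tables this pipeline reproduces are autosomal, and hemizygous handling is
a documented limitation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "FunctionalClass",
    "Sift",
    "PolyPhen",
    "Affection",
    "Genotype",
    "VariantSite",
    "Annotation",
    "PedigreeMember",
    "Pedigree",
    "GenotypeTable",
    "CandidateMutation",
    "FormatError",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_annotations",
    "write_annotations",
    "write_candidate_report",
    "read_candidate_report",
]

DB_NAMES = frozenset({"dbSNP137", "KG1000", "ESP6500", "HGVD", "inhouse"})


class FormatError(ValueError):
    """Raised for malformed input files (message names the offending record)."""


class FunctionalClass(str, enum.Enum):
    missense = "missense"
    nonsense = "nonsense"
    synonymous = "synonymous"
    canonical_splice = "canonical_splice"
    frameshift_indel = "frameshift_indel"
    inframe_indel = "inframe_indel"
    other = "other"


class Sift(str, enum.Enum):
    damaging = "damaging"
    tolerated = "tolerated"
    missing = "missing"


class PolyPhen(str, enum.Enum):
    probably_damaging = "probably_damaging"
    possibly_damaging = "possibly_damaging"
    benign = "benign"
    missing = "missing"


class Affection(str, enum.Enum):
    yes = "yes"
    no = "no"
    unknown = "unknown"


class Genotype(enum.IntEnum):
    """Diploid genotype codes used in :class:`GenotypeTable` matrices."""

    hom_ref = 0
    het = 1
    hom_alt = 2
    missing = -1


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    transcript: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    functional_class: FunctionalClass = FunctionalClass.other

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Annotation:
    sift: Sift = Sift.missing
    polyphen: PolyPhen = PolyPhen.missing
    db_flags: frozenset[str] = frozenset()
    maf: float | None = None
    strand_counts: tuple[int, int, int, int] = (0, 0, 0, 0)  # ref_fwd, ref_rev, alt_fwd, alt_rev

    def __post_init__(self):
        bad = set(self.db_flags) - DB_NAMES
        if bad:
            raise ValueError(f"unknown database flags: {sorted(bad)}")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf outside [0,1]: {self.maf}")
        if any(c < 0 for c in self.strand_counts):
            raise ValueError("negative strand counts")


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    affected: Affection


@dataclass
class Pedigree:
    family_id: str
    members: list[PedigreeMember]
    design: str = ""  # "trio" or "multiplex", set on read

    def __post_init__(self):
        ids = {m.sample_id for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise FormatError(
                        f"family {self.family_id}: dangling parent id {pid!r} "
                        f"referenced by {m.sample_id}"
                    )
        if not self.design:
            self.design = _classify_design(self.members)

    def member(self, sample_id: str) -> PedigreeMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    @property
    def proband(self) -> PedigreeMember:
        """First affected member with both parents in the family, else first affected."""
        affected = [m for m in self.members if m.affected is Affection.yes]
        if not affected:
            raise ValueError(f"family {self.family_id} has no affected member")
        for m in affected:
            if m.father_id is not None and m.mother_id is not None:
                return m
        return affected[0]


def _classify_design(members: list[PedigreeMember]) -> str:
    """A trio is one affected offspring plus its two (unaffected or unknown) parents."""
    if len(members) == 3:
        affected = [m for m in members if m.affected is Affection.yes]
        if len(affected) == 1:
            child = affected[0]
            parent_ids = {child.father_id, child.mother_id}
            others = {m.sample_id for m in members if m.sample_id != child.sample_id}
            if None not in parent_ids and parent_ids == others:
                return "trio"
    return "multiplex"


@dataclass
class GenotypeTable:
    """Per-sample diploid genotype matrix over a list of variant sites.

    ``gt`` is an int8 array of shape (n_samples, n_sites) holding
    :class:`Genotype` codes.
    """

    sample_ids: list[str]
    sites: list[VariantSite]
    gt: np.ndarray

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"genotype matrix shape {self.gt.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        valid = np.isin(self.gt, [-1, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype codes must be in {hom_ref, het, hom_alt, missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def genotype(self, sample_id: str, site_index: int) -> Genotype:
        return Genotype(int(self.gt[self.sample_index(sample_id), site_index]))

    def subset_sites(self, indices) -> "GenotypeTable":
        indices = list(indices)
        return GenotypeTable(
            sample_ids=list(self.sample_ids),
            sites=[self.sites[i] for i in indices],
            gt=self.gt[:, indices].copy(),
        )

    def subset_samples(self, sample_ids) -> "GenotypeTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeTable(
            sample_ids=list(sample_ids),
            sites=list(self.sites),
            gt=self.gt[idx, :].copy(),
        )


@dataclass(frozen=True)
class CandidateMutation:
    site: VariantSite
    model: str  # de_novo | recessive_hom | recessive_compound_het | dominant
    family_id: str
    carriers: tuple[str, ...]
    partner_site: VariantSite | None = None

    def __post_init__(self):
        if self.model == "recessive_compound_het":
            if self.partner_site is None:
                raise ValueError("compound het requires a partner site")
            if self.partner_site.gene != self.site.gene:
                raise ValueError("compound het partner must be in the same gene")
        elif self.partner_site is not None:
            raise ValueError(f"partner_site only valid for compound hets, not {self.model}")


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path, info_fields: dict[str, str] | None = None) -> GenotypeTable:
    """Read a VCF 4.x into a :class:`GenotypeTable`.

    Multi-allelic records are split into one site per alternate allele;
    each sample's genotype for a split site is the count of that specific
    allele (0 -> hom_ref, 1 -> het, 2 -> hom_alt).  Missing genotypes map
    to missing.  Site order is preserved.

    Parameters
    ----------
    path : str
        VCF path (plain or bgzipped).
    info_fields : dict, optional
        Mapping of site attribute name -> INFO key for gene/transcript/
        cDNA/protein/functional-class annotations carried in the VCF.
        Defaults to the keys this package writes (GENE, TRANSCRIPT, CDNA,
        PROT, FCLASS).
    """
    info_fields = info_fields or {
        "gene": "GENE",
        "transcript": "TRANSCRIPT",
        "cdna_change": "CDNA",
        "protein_change": "PROT",
        "functional_class": "FCLASS",
    }
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for rec_no, rec in enumerate(vcf, start=1):
        genos = rec.genotypes  # list of [allele, allele, phased]
        for g in genos:
            if len(g) != 3:
                raise FormatError(
                    f"{path} record {rec_no} ({rec.CHROM}:{rec.POS}): ploidy != 2"
                )
        alleles = np.array([[g[0], g[1]] for g in genos], dtype=int)
        info = {}
        for attr, key in info_fields.items():
            val = rec.INFO.get(key)
            if val is not None:
                info[attr] = str(val)
        fclass = info.pop("functional_class", None)
        for alt_index, alt in enumerate(rec.ALT, start=1):
            per_alt = {k: v for k, v in info.items()}
            if len(rec.ALT) > 1:
                # per-allele INFO values are comma-joined on write
                for k, v in per_alt.items():
                    parts = v.split(",")
                    if len(parts) == len(rec.ALT):
                        per_alt[k] = parts[alt_index - 1]
            site = VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                functional_class=(
                    FunctionalClass(fclass.split(",")[alt_index - 1])
                    if fclass and len(fclass.split(",")) == len(rec.ALT)
                    else FunctionalClass(fclass)
                    if fclass
                    else FunctionalClass.other
                ),
                **per_alt,
            )
            codes = np.where(
                (alleles < 0).any(axis=1), -1, (alleles == alt_index).sum(axis=1)
            ).astype(np.int8)
            sites.append(site)
            columns.append(codes)
    gt = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeTable(sample_ids=sample_ids, sites=sites, gt=gt)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a GenotypeTable as a minimal biallelic VCF 4.2 with GT only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen: list[str] = []
        for site in table.sites:
            if site.chrom not in seen:
                seen.append(site.chrom)
                fh.write(f"##contig=<ID={site.chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript">\n')
        fh.write('##INFO=<ID=CDNA,Number=1,Type=String,Description="cDNA change">\n')
        fh.write('##INFO=<ID=PROT,Number=1,Type=String,Description="Protein change">\n')
        fh.write('##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        for j, site in enumerate(table.sites):
            info_parts = []
            for key, val in (
                ("GENE", site.gene),
                ("TRANSCRIPT", site.transcript),
                ("CDNA", site.cdna_change),
                ("PROT", site.protein_change),
                ("FCLASS", site.functional_class.value),
            ):
                if val:
                    info_parts.append(f"{key}={val}")
            info = ";".join(info_parts) or "."
            gts = "\t".join(_GT_STRINGS[int(c)] for c in table.gt[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PED I/O

_PHENO = {"2": Affection.yes, "1": Affection.no, "0": Affection.unknown, "-9": Affection.unknown}


def read_ped(path) -> list[Pedigree]:
    """Read a 6-column PED file into pedigrees, classifying trio vs multiplex."""
    families: dict[str, list[PedigreeMember]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path} line {line_no}: expected 6 PED columns")
            fam, sid, fid, mid, sex, pheno = fields[:6]
            if pheno not in _PHENO:
                raise FormatError(f"{path} line {line_no}: unknown phenotype code {pheno!r}")
            member = PedigreeMember(
                sample_id=sid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=int(sex),
                affected=_PHENO[pheno],
            )
            if fam not in families:
                families[fam] = []
                order.append(fam)
            families[fam].append(member)
    return [Pedigree(family_id=fam, members=families[fam]) for fam in order]


def write_ped(pedigrees: list[Pedigree], path) -> None:
    rev = {Affection.yes: "2", Affection.no: "1", Affection.unknown: "0"}
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    f"{ped.family_id}\t{m.sample_id}\t{m.father_id or 0}\t"
                    f"{m.mother_id or 0}\t{m.sex}\t{rev[m.affected]}\n"
                )


# ---------------------------------------------------------------------------
# Annotation table I/O

_SIFT_TOKENS = {"D": Sift.damaging, "T": Sift.tolerated, "-": Sift.missing}
_POLYPHEN_TOKENS = {
    "D": PolyPhen.probably_damaging,
    "P": PolyPhen.possibly_damaging,
    "B": PolyPhen.benign,
    "-": PolyPhen.missing,
}

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sift",
    "polyphen",
    "db_flags",
    "maf",
    "ref_fwd",
    "ref_rev",
    "alt_fwd",
    "alt_rev",
]


def read_annotations(path) -> dict[tuple, Annotation]:
    """Read the per-variant annotation TSV into a map keyed on (chrom,pos,ref,alt).

    Predictor verdicts use the single-letter convention D/T for SIFT and
    D/P/B for PolyPhen-2; "-" means no call.  ``db_flags`` is a comma-joined
    list of database names or "-".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing_cols)}")
    out: dict[tuple, Annotation] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.sift not in _SIFT_TOKENS:
            raise FormatError(f"{path} line {row_no}: unknown SIFT token {row.sift!r}")
        if row.polyphen not in _POLYPHEN_TOKENS:
            raise FormatError(
                f"{path} line {row_no}: unknown PolyPhen token {row.polyphen!r}"
            )
        flags = frozenset() if row.db_flags in ("-", "") else frozenset(row.db_flags.split(","))
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        out[key] = Annotation(
            sift=_SIFT_TOKENS[row.sift],
            polyphen=_POLYPHEN_TOKENS[row.polyphen],
            db_flags=flags,
            maf=None if row.maf in ("-", "") else float(row.maf),
            strand_counts=(
                int(row.ref_fwd),
                int(row.ref_rev),
                int(row.alt_fwd),
                int(row.alt_rev),
            ),
        )
    return out


def write_annotations(annotations: dict[tuple, Annotation], path) -> None:
    sift_rev = {v: k for k, v in _SIFT_TOKENS.items()}
    pp_rev = {v: k for k, v in _POLYPHEN_TOKENS.items()}
    rows = []
    for (chrom, pos, ref, alt), ann in annotations.items():
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "sift": sift_rev[ann.sift],
                "polyphen": pp_rev[ann.polyphen],
                "db_flags": ",".join(sorted(ann.db_flags)) or "-",
                "maf": "-" if ann.maf is None else f"{ann.maf:.6g}",
                "ref_fwd": ann.strand_counts[0],
                "ref_rev": ann.strand_counts[1],
                "alt_fwd": ann.strand_counts[2],
                "alt_rev": ann.strand_counts[3],
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Candidate report I/O

_MODEL_LABELS = {
    "de_novo": "De novo",
    "recessive_hom": "AR (HMZ)",
    "recessive_compound_het": "AR (CHTZ)",
    "dominant": "AD",
}
_MODEL_FROM_LABEL = {v: k for k, v in _MODEL_LABELS.items()}

REPORT_COLUMNS = [
    "family",
    "gene",
    "model",
    "chrom",
    "pos",
    "ref",
    "alt",
    "transcript",
    "cdna_change",
    "protein_change",
    "functional_class",
    "carriers",
    "partner_cdna",
]


def _report_row(c: CandidateMutation, site: VariantSite, partner: VariantSite | None) -> dict:
    return {
        "family": c.family_id,
        "gene": site.gene,
        "model": _MODEL_LABELS[c.model],
        "chrom": site.chrom,
        "pos": site.pos,
        "ref": site.ref,
        "alt": site.alt,
        "transcript": site.transcript,
        "cdna_change": site.cdna_change,
        "protein_change": site.protein_change or "-",
        "functional_class": site.functional_class.value,
        "carriers": ",".join(c.carriers),
        "partner_cdna": partner.cdna_change if partner else "-",
    }


def write_candidate_report(candidates: list[CandidateMutation], path) -> None:
    """Write candidates as a TSV ordered by (family, gene, pos).

    A compound-het pair is written as two cross-referencing rows (one per
    member site), matching the two-line convention of published candidate
    tables; each unordered pair appears exactly once.
    """
    rows = []
    seen_pairs: set[tuple] = set()
    for c in candidates:
        if c.model == "recessive_compound_het":
            pair_key = (
                c.family_id,
                c.site.gene,
                frozenset({c.site.key, c.partner_site.key}),
            )
            if pair_key in seen_pairs:
                continue
            seen_pairs.add(pair_key)
            rows.append(_report_row(c, c.site, c.partner_site))
            rows.append(_report_row(c, c.partner_site, c.site))
        else:
            rows.append(_report_row(c, c.site, None))
    rows.sort(key=lambda r: (r["family"], r["gene"], r["pos"]))
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidate_report(path) -> list[CandidateMutation]:
    """Inverse of :func:`write_candidate_report`.

    Compound-het row pairs are re-joined by their cross-referencing cDNA
    columns and returned as one CandidateMutation per pair (the
    lower-coordinate site is the primary).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    by_key: dict[tuple, VariantSite] = {}
    records = []
    for row in df.itertuples(index=False):
        site = VariantSite(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            transcript=row.transcript,
            cdna_change=row.cdna_change,
            protein_change="" if row.protein_change == "-" else row.protein_change,
            functional_class=FunctionalClass(row.functional_class),
        )
        by_key[(row.family, row.gene, row.cdna_change)] = site
        records.append((row, site))
    out = []
    seen_pairs: set[tuple] = set()
    for row, site in records:
        model = _MODEL_FROM_LABEL[row.model]
        carriers = tuple(row.carriers.split(",")) if row.carriers else ()
        if model == "recessive_compound_het":
            partner = by_key.get((row.family, row.gene, row.partner_cdna))
            if partner is None:
                raise FormatError(
                    f"compound-het row {row.family}/{row.gene}/{row.cdna_change} "
                    f"references missing partner {row.partner_cdna!r}"
                )
            pair_key = (row.family, row.gene, frozenset({site.key, partner.key}))
            if pair_key in seen_pairs:
                continue
            seen_pairs.add(pair_key)
            primary, secondary = sorted((site, partner), key=lambda s: s.pos)
            out.append(
                CandidateMutation(
                    site=primary,
                    model=model,
                    family_id=row.family,
                    carriers=carriers,
                    partner_site=secondary,
                )
            )
        else:
            out.append(
                CandidateMutation(
                    site=site,
                    model=model,
                    family_id=row.family,
                    carriers=carriers,
                )
            )
    return out
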