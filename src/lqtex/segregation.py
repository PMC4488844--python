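"""Inheritance-model candidate calling from family genotypes.

Trio families (affected child, two unaffected parents) are screened for
de novo, homozygous-recessive and compound-heterozygous configurations;
multiplex families for dominant co-segregation.  Compound-het phase is
inferred from parental genotypes (one site transmitted only by the
father, the other only by the mother), never from VCF phase separators.

Missing genotypes are disqualifying in the trio models (a de novo call
with an ungenotyped parent is not a de novo call) but are treated as
unknown in the dominant predicate, where pedigrees are typically only
partially sequenced.
"""

from __future__ import annotations

import warnings

from .variant_model import (
    Affection,
    CandidateMutation,
    Genotype,
    GenotypeTable,
    Pedigree,
)

__all__ = [
    "detect_de_novo",
    "detect_recessive_hom",
    "detect_compound_het",
    "detect_dominant",
    "assign_models",
]


def _trio_rows(trio: Pedigree, gt: GenotypeTable) -> tuple[int, int, int, str]:
    if trio.design != "trio":
        raise ValueError(f"family {trio.family_id} is not a trio")
    child = trio.proband
    if child.father_id is None or child.mother_id is None:
        raise ValueError(f"trio {trio.family_id}: proband lacks two genotyped parents")
    return (
        gt.sample_index(child.sample_id),
        gt.sample_index(child.father_id),
        gt.sample_index(child.mother_id),
        child.sample_id,
    )


def detect_de_novo(trio: Pedigree, gt: GenotypeTable) -> list[int]:
    """Indices of sites where the child carries an allele absent from both parents.

    Child het or hom_alt with both parents hom_ref; any missing genotype
    at the site excludes it.  (A hom_alt child with hom_ref parents is
    reported as one de novo candidate; two independent events are not
    distinguished.)
    """
    ci, fi, mi, _ = _trio_rows(trio, gt)
    out = []
    for j in range(gt.n_sites):
        c, f, m = int(gt.gt[ci, j]), int(gt.gt[fi, j]), int(gt.gt[mi, j])
        if Genotype.missing in (c, f, m):
            continue
        if c in (Genotype.het, Genotype.hom_alt) and f == m == Genotype.hom_ref:
            out.append(j)
    return out


def detect_recessive_hom(trio: Pedigree, gt: GenotypeTable) -> list[int]:
    """Indices of sites with child hom_alt and both parents het carriers."""
    ci, fi, mi, _ = _trio_rows(trio, gt)
    out = []
    for j in range(gt.n_sites):
        c, f, m = int(gt.gt[ci, j]), int(gt.gt[fi, j]), int(gt.gt[mi, j])
        if Genotype.missing in (c, f, m):
            continue
        if c == Genotype.hom_alt and f == Genotype.het and m == Genotype.het:
            out.append(j)
    return out


def _uniparental(c: int, f: int, m: int) -> str | None:
    """Which single parent transmitted a het site to the child, if unambiguous."""
    if c != Genotype.het:
        return None
    if f in (Genotype.het, Genotype.hom_alt) and m == Genotype.hom_ref:
        return "father"
    if m in (Genotype.het, Genotype.hom_alt) and f == Genotype.hom_ref:
        return "mother"
    return None


def detect_compound_het(
    trio: Pedigree, gt: GenotypeTable, gene_map: dict[int, str] | None = None
) -> list[tuple[int, int]]:
    """Unordered site-index pairs forming a trans compound heterozygote.

    Both sites lie in the same gene, the child is het at both, one site is
    transmitted only by the father and the other only by the mother.
    ``gene_map`` maps site index -> gene symbol; by default the sites' own
    gene fields are used, and an empty gene symbol is an error.
    """
    ci, fi, mi, _ = _trio_rows(trio, gt)
    if gene_map is None:
        gene_map = {j: s.gene for j, s in enumerate(gt.sites)}
    paternal: dict[str, list[int]] = {}
    maternal: dict[str, list[int]] = {}
    for j in range(gt.n_sites):
        c, f, m = int(gt.gt[ci, j]), int(gt.gt[fi, j]), int(gt.gt[mi, j])
        if Genotype.missing in (c, f, m):
            continue
        origin = _uniparental(c, f, m)
        if origin is None:
            continue
        gene = gene_map.get(j)
        if not gene:
            raise KeyError(f"no gene assignment for site index {j}")
        (paternal if origin == "father" else maternal).setdefault(gene, []).append(j)
    pairs = []
    for gene, pat_sites in paternal.items():
        for jp in pat_sites:
            for jm in maternal.get(gene, []):
                pairs.append((min(jp, jm), max(jp, jm)))
    return sorted(pairs)


def detect_dominant(family: Pedigree, gt: GenotypeTable) -> list[int]:
    """Sites carried by every genotyped affected and no genotyped unaffected.

    Members with unknown affection status, or without genotypes in the
    table, are ignored.  The proband must itself carry the variant.  With
    fewer than two genotyped affecteds the rule degenerates to
    carrier-in-proband and a warning is emitted.
    """
    if family.design != "multiplex":
        raise ValueError(f"family {family.family_id} is not a multiplex pedigree")
    present = {s for s in gt.sample_ids}
    affected = [
        m.sample_id
        for m in family.members
        if m.affected is Affection.yes and m.sample_id in present
    ]
    unaffected = [
        m.sample_id
        for m in family.members
        if m.affected is Affection.no and m.sample_id in present
    ]
    if len(affected) < 2:
        warnings.warn(
            f"family {family.family_id}: fewer than two genotyped affecteds; "
            "dominant rule degenerates to carrier-in-proband",
            stacklevel=2,
        )
    proband_id = family.proband.sample_id
    aff_idx = [gt.sample_index(s) for s in affected]
    unaff_idx = [gt.sample_index(s) for s in unaffected]
    pro_idx = gt.sample_index(proband_id) if proband_id in present else None
    out = []
    for j in range(gt.n_sites):
        col = gt.gt[:, j]
        if pro_idx is not None and int(col[pro_idx]) not in (Genotype.het, Genotype.hom_alt):
            continue
        ok = True
        for i in aff_idx:
            g = int(col[i])
            if g == Genotype.missing:
                continue  # ungenotyped-at-site affected is treated as unknown
            if g not in (Genotype.het, Genotype.hom_alt):
                ok = False
                break
        if not ok:
            continue
        for i in unaff_idx:
            g = int(col[i])
            if g in (Genotype.het, Genotype.hom_alt):
                ok = False
                break
        if ok:
            out.append(j)
    return out


def _affected_carriers(family: Pedigree, gt: GenotypeTable, j: int) -> tuple[str, ...]:
    carriers = []
    for m in family.members:
        if m.affected is not Affection.yes or m.sample_id not in gt.sample_ids:
            continue
        g = int(gt.gt[gt.sample_index(m.sample_id), j])
        if g in (Genotype.het, Genotype.hom_alt):
            carriers.append(m.sample_id)
    return tuple(carriers)


def assign_models(
    families: list[Pedigree],
    tables: dict[str, GenotypeTable],
    cascade_survivors: dict[str, list[int]] | None = None,
) -> list[CandidateMutation]:
    """Dispatch families to the model detectors and aggregate candidates.

    Parameters
    ----------
    families : list of Pedigree
    tables : dict family_id -> GenotypeTable for that family's members
    cascade_survivors : dict family_id -> site indices that passed the
        filter cascade; defaults to all sites.

    Trio families are screened for de novo, homozygous-recessive and
    compound-het configurations (compound-het member sites are reported
    once per pair under the compound-het model, not additionally as
    single-site candidates); multiplex families for dominant
    co-segregation.  Output ordering is deterministic: (family, gene, pos).
    """
    candidates: list[CandidateMutation] = []
    for fam in families:
        gt = tables[fam.family_id]
        keep = (
            set(cascade_survivors[fam.family_id])
            if cascade_survivors is not None
            else set(range(gt.n_sites))
        )
        sub_idx = sorted(keep)
        sub = gt.subset_sites(sub_idx)
        if fam.design == "trio":
            dn = detect_de_novo(fam, sub)
            rh = detect_recessive_hom(fam, sub)
            ch = detect_compound_het(fam, sub)
            ch_members = {j for pair in ch for j in pair}
            for j in dn:
                candidates.append(
                    CandidateMutation(
                        site=sub.sites[j],
                        model="de_novo",
                        family_id=fam.family_id,
                        carriers=_affected_carriers(fam, sub, j),
                    )
                )
            for j in rh:
                candidates.append(
                    CandidateMutation(
                        site=sub.sites[j],
                        model="recessive_hom",
                        family_id=fam.family_id,
                        carriers=_affected_carriers(fam, sub, j),
                    )
                )
            for j1, j2 in ch:
                if j1 in dn or j1 in rh or j2 in dn or j2 in rh:
                    continue  # a site never carries two models in one family
                candidates.append(
                    CandidateMutation(
                        site=sub.sites[j1],
                        model="recessive_compound_het",
                        family_id=fam.family_id,
                        carriers=_affected_carriers(fam, sub, j1),
                        partner_site=sub.sites[j2],
                    )
                )
        else:
            for j in detect_dominant(fam, sub):
                candidates.append(
                    CandidateMutation(
                        site=sub.sites[j],
                        model="dominant",
                        family_id=fam.family_id,
                        carriers=_affected_carriers(fam, sub, j),
                    )
                )
    candidates.sort(key=lambda c: (c.family_id, c.site.gene, c.site.pos))
    return candidates


def model_counts(candidates: list[CandidateMutation]) -> dict[str, int]:
    counts = {"de_novo": 0, "recessive_hom": 0, "recessive_compound_het": 0, "dominant": 0}
    for c in candidates:
        counts[c.model] += 1
    return counts
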