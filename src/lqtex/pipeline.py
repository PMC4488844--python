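"""End-to-end orchestration of the two study arms.

The family arm runs the filter cascade per family and segregation calling
across all families; the association arm runs variant QC, qualifying-
variant selection and per-gene SKAT-O with BH correction; the unrelated
screen reports database-absent non-synonymous variants in a fixed gene
panel for singleton cases (predictor verdicts are reported there but not
filtered on — screening a small prioritized panel keeps even
predictor-benign variants visible for review).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filter_cascade import database_filter, functional_filter, run_cascade
from .rare_assoc import GeneAssocResult, skato_by_gene, variant_qc
from .segregation import assign_models, model_counts
from .variant_model import (
    Annotation,
    CandidateMutation,
    GenotypeTable,
    Genotype,
    Pedigree,
)

logger = logging.getLogger("lqtex")

__all__ = [
    "FamilyArmResult",
    "run_family_arm",
    "run_association_arm",
    "run_unrelated_screen",
    "format_model_counts",
]


@dataclass
class FamilyArmResult:
    candidates: list[CandidateMutation]
    counts: dict[str, int]
    audits: dict[str, pd.DataFrame]  # per-family cascade audit
    failures: dict[str, str]  # family_id -> error message


def run_family_arm(
    families: list[Pedigree],
    tables: dict[str, GenotypeTable],
    annotations: dict[tuple, Annotation],
    strand_alpha: float = 1e-3,
) -> FamilyArmResult:
    """Cascade then segregation per family; per-family failures are logged
    and the run continues."""
    survivors: dict[str, list[int]] = {}
    audits: dict[str, pd.DataFrame] = {}
    failures: dict[str, str] = {}
    ok_families = []
    for fam in families:
        try:
            gt = tables[fam.family_id]
            result = run_cascade(gt.sites, annotations, strand_alpha=strand_alpha)
            surviving_keys = {s.key for s in result.survivors}
            survivors[fam.family_id] = [
                j for j, s in enumerate(gt.sites) if s.key in surviving_keys
            ]
            audits[fam.family_id] = result.audit
            ok_families.append(fam)
            logger.info(
                "family %s: cascade %d -> %d sites",
                fam.family_id,
                gt.n_sites,
                len(survivors[fam.family_id]),
            )
        except Exception as exc:  # keep going on per-family failure
            failures[fam.family_id] = str(exc)
            logger.error("family %s failed: %s", fam.family_id, exc)
    candidates = assign_models(ok_families, tables, survivors)
    return FamilyArmResult(
        candidates=candidates,
        counts=model_counts(candidates),
        audits=audits,
        failures=failures,
    )


def format_model_counts(counts: dict[str, int]) -> str:
    recessive = counts["recessive_hom"] + counts["recessive_compound_het"]
    return (
        f"{counts['de_novo']} de novo / {recessive} recessive / "
        f"{counts['dominant']} dominant"
    )


def run_association_arm(
    gt: GenotypeTable,
    case_labels: np.ndarray,
    annotations: dict[tuple, Annotation] | None = None,
    gene_panel: set[str] | None = None,
    call_rate_min: float = 0.80,
    hwe_min_p: float = 1e-6,
    qc_maf_max: float | None = None,
    test_maf_max: float = 0.01,
    q_threshold: float = 0.05,
) -> tuple[list[GeneAssocResult], pd.DataFrame]:
    """QC -> qualifying variants -> per-gene SKAT-O -> BH q-values.

    Returns the per-gene results (significant when q < ``q_threshold``)
    and a log of skipped genes.  ``qc_maf_max`` defaults to None here
    because the gene test applies its own MAF ceiling (``test_maf_max``).
    """
    labels = np.asarray(case_labels)
    retained, _qc_log = variant_qc(
        gt,
        labels,
        call_rate_min=call_rate_min,
        hwe_min_p=hwe_min_p,
        maf_max=qc_maf_max,
    )
    sub = gt.subset_sites(retained)
    if gene_panel is not None:
        panel_idx = [j for j, s in enumerate(sub.sites) if s.gene in gene_panel]
        sub = sub.subset_sites(panel_idx)
    results, skipped = skato_by_gene(
        sub, labels, annotations, maf_max=test_maf_max
    )
    for r in results:
        if r.q_value < q_threshold:
            logger.info("gene %s significant: p=%.3g q=%.3g", r.gene, r.p_skato, r.q_value)
    return results, skipped


def run_unrelated_screen(
    gt: GenotypeTable,
    annotations: dict[tuple, Annotation],
    gene_list: set[str],
) -> pd.DataFrame:
    """Screen singleton cases for panel-gene candidate mutations.

    Keeps non-synonymous / splice variants absent from all databases in
    the given genes; predictor verdicts are reported, not filtered.
    Output: one row per (individual, variant) carrier pair.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    sites = [s for s in gt.sites if s.gene in gene_list]
    sites = functional_filter(sites)
    sites = database_filter(sites, annotations)
    keep_keys = {s.key for s in sites}
    sift_rev = {"damaging": "D", "tolerated": "T", "missing": "-"}
    pp_rev = {
        "probably_damaging": "D",
        "possibly_damaging": "P",
        "benign": "B",
        "missing": "-",
    }
    rows = []
    for j, site in enumerate(gt.sites):
        if site.key not in keep_keys:
            continue
        ann = annotations[site.key]
        for i, sample in enumerate(gt.sample_ids):
            if int(gt.gt[i, j]) in (Genotype.het, Genotype.hom_alt):
                rows.append(
                    {
                        "individual": sample,
                        "gene": site.gene,
                        "transcript": site.transcript,
                        "cdna_change": site.cdna_change,
                        "protein_change": site.protein_change or "-",
                        "verdicts": f"{sift_rev[ann.sift.value]}/{pp_rev[ann.polyphen.value]}",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["individual", "gene", "transcript", "cdna_change", "protein_change", "verdicts"],
    )
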