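"""Per-proband variant-reduction cascade.

Four successive per-site filters mirror the discovery funnel used in
family-based exome studies of long QT syndrome:

1. functional: drop synonymous and non-coding-impact classes, keeping
   missense, nonsense, canonical splice-site variants and coding indels;
2. database: drop anything present in a population database
   (dbSNP137, 1000 Genomes, ESP6500, HGVD, or the in-house panel) —
   membership is binary, frequency is not consulted here;
3. deleteriousness: drop missense sites called tolerated by SIFT *and*
   benign by PolyPhen-2 (both predictors must agree the site is harmless;
   a missing verdict never triggers removal; non-missense classes pass
   through because the predictors are missense tools);
4. strand bias: drop sites whose alternate-allele reads are skewed to one
   read orientation, by a two-sided Fisher exact test on the 2x2 table of
   (ref fwd/rev vs alt fwd/rev).

Each filter is an idempotent per-site predicate returning a subset of its
input, so the database and deleteriousness stages commute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .variant_model import (
    Annotation,
    FunctionalClass,
    PolyPhen,
    Sift,
    VariantSite,
)

__all__ = [
    "functional_filter",
    "database_filter",
    "deleteriousness_filter",
    "strand_bias_filter",
    "run_cascade",
    "CascadeResult",
]

RETAINED_CLASSES = {
    FunctionalClass.missense,
    FunctionalClass.nonsense,
    FunctionalClass.canonical_splice,
    FunctionalClass.frameshift_indel,
    FunctionalClass.inframe_indel,
}

INDEL_CLASSES = {FunctionalClass.frameshift_indel, FunctionalClass.inframe_indel}


def functional_filter(sites: list[VariantSite]) -> list[VariantSite]:
    """Retain coding-impact classes; synonymous/other sites are removed."""
    for s in sites:
        if s.functional_class is None:
            raise ValueError(f"functional_class missing for {s.chrom}:{s.pos}")
    return [s for s in sites if s.functional_class in RETAINED_CLASSES]


def _ann(site: VariantSite, annotations: dict[tuple, Annotation]) -> Annotation:
    try:
        return annotations[site.key]
    except KeyError:
        raise KeyError(
            f"site {site.chrom}:{site.pos} {site.ref}>{site.alt} absent from annotations"
        ) from None


def database_filter(
    sites: list[VariantSite], annotations: dict[tuple, Annotation]
) -> list[VariantSite]:
    """Remove any site flagged in at least one population database."""
    return [s for s in sites if not _ann(s, annotations).db_flags]


def deleteriousness_filter(
    sites: list[VariantSite], annotations: dict[tuple, Annotation]
) -> list[VariantSite]:
    """Remove missense sites called harmless by *both* predictors.

    possibly_damaging counts as not-benign, and indels/nonsense/splice
    variants are exempt (the predictors do not score them).
    """
    out = []
    for s in sites:
        if s.functional_class is not FunctionalClass.missense:
            out.append(s)
            continue
        ann = _ann(s, annotations)
        if ann.sift is Sift.tolerated and ann.polyphen is PolyPhen.benign:
            continue
        out.append(s)
    return out


def strand_bias_p(strand_counts: tuple[int, int, int, int]) -> float | None:
    """Two-sided Fisher exact p for orientation bias; None if no alt reads."""
    ref_fwd, ref_rev, alt_fwd, alt_rev = strand_counts
    if min(strand_counts) < 0:
        raise ValueError("negative strand counts")
    if alt_fwd + alt_rev == 0:
        return None
    return float(
        stats.fisher_exact([[ref_fwd, ref_rev], [alt_fwd, alt_rev]], alternative="two-sided")[1]
    )


def strand_bias_filter(
    sites: list[VariantSite],
    annotations: dict[tuple, Annotation],
    alpha: float = 1e-3,
) -> list[VariantSite]:
    """Remove sites whose alt allele is orientation-skewed at level ``alpha``.

    Sites with zero alternate reads cannot be tested and are retained with
    a warning.
    """
    out = []
    for s in sites:
        p = strand_bias_p(_ann(s, annotations).strand_counts)
        if p is None:
            warnings.warn(
                f"site {s.chrom}:{s.pos} has no alternate reads; strand-bias "
                "test skipped",
                stacklevel=2,
            )
            out.append(s)
        elif p >= alpha:
            out.append(s)
    return out


@dataclass
class CascadeResult:
    survivors: list[VariantSite]
    audit: pd.DataFrame  # columns: stage, n_in, n_out


def run_cascade(
    sites: list[VariantSite],
    annotations: dict[tuple, Annotation],
    strand_alpha: float = 1e-3,
) -> CascadeResult:
    """Apply the four filters in order, recording per-stage counts."""
    stages = [
        ("functional", lambda s: functional_filter(s)),
        ("database", lambda s: database_filter(s, annotations)),
        ("deleteriousness", lambda s: deleteriousness_filter(s, annotations)),
        ("strand_bias", lambda s: strand_bias_filter(s, annotations, strand_alpha)),
    ]
    audit_rows = []
    current = list(sites)
    for name, fn in stages:
        n_in = len(current)
        current = fn(current)
        audit_rows.append({"stage": name, "n_in": n_in, "n_out": len(current)})
    return CascadeResult(
        survivors=current,
        audit=pd.DataFrame(audit_rows, columns=["stage", "n_in", "n_out"]),
    )
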