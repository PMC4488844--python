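"""Synthetic cohort generation for the LQTS exome pipeline.

Raw exomes from family studies of long QT syndrome are not publicly
distributable, so every downstream stage is exercised on simulated data
with the statistical structure the analysis assumes:

* trio and multiplex pedigrees carrying planted de novo, homozygous
  recessive, compound-heterozygous or dominant co-segregating mutations
  on a background of common, database-annotated variants transmitted
  mendelianly under Hardy-Weinberg founder genotypes;
* a case/control panel in which one designated gene carries an excess of
  rare damaging variants in cases;
* a PPI graph with guaranteed seed-adjacency and hub edges over an
  Erdos-Renyi background; and
* a multi-species protein alignment with a planted conserved-column set.

Every generator is a pure function of (config, seed): the per-family RNG
is spawned from ``(seed, family_index)`` so outputs are reproducible and
independent of call order.  Background sites are a scaled stand-in for a
real exome's per-proband variant load (thousands, not tens of thousands),
drawn with rare-skewed allele frequencies so all filter branches fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ppi_enrichment import InteractionGraph
from .variant_model import (
    Affection,
    Annotation,
    CandidateMutation,
    FunctionalClass,
    Genotype,
    GenotypeTable,
    Pedigree,
    PedigreeMember,
    PolyPhen,
    Sift,
    VariantSite,
)

__all__ = [
    "SimulationConfig",
    "PlantSpec",
    "EnrichedGeneSpec",
    "PPISpec",
    "FamilySim",
    "CohortSim",
    "CaseControlSim",
    "simulate_family",
    "simulate_cohort",
    "simulate_case_control",
    "simulate_ppi",
    "simulate_msa",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class PlantSpec:
    """One mutation (or compound-het pair) to plant in a family."""

    model: str  # de_novo | recessive_hom | recessive_compound_het | dominant
    gene: str = "PLANT"
    sift: Sift = Sift.damaging
    polyphen: PolyPhen = PolyPhen.probably_damaging


@dataclass(frozen=True)
class EnrichedGeneSpec:
    """Rare-damaging-variant enrichment for the association panel.

    Either ``odds_ratio`` (carrier odds multiplier in cases) or explicit
    per-variant het ``carrier_counts`` as (case_carriers, control_carriers)
    pairs; explicit counts override the odds ratio.
    """

    gene: str = "ENRICHED"
    n_variants: int = 3
    odds_ratio: float = 10.0
    carrier_counts: tuple[tuple[int, int], ...] | None = None


@dataclass(frozen=True)
class PPISpec:
    n_genes: int = 200
    edge_density: float = 0.02
    seed_genes: tuple[str, ...] = ("SEED1", "SEED2", "SEED3")
    hub_gene: str = "CALM1"
    candidates: tuple[str, ...] = tuple(f"CAND{i}" for i in range(1, 12))
    hub_degree: int = 5  # candidates guaranteed adjacent to the hub
    direct_candidates: int = 7  # candidates guaranteed adjacent to a seed


@dataclass
class SimulationConfig:
    seed: int = 0
    n_trio_families: int = 4
    n_multiplex_families: int = 3
    n_background_sites: int = 2000
    background_maf_beta: tuple[float, float] = (0.2, 2.0)
    db_flag_maf_threshold: float = 0.001
    n_strand_decoys: int = 2
    plant_spec: list[PlantSpec] | None = None
    # association panel
    n_cases: int = 161
    n_controls: int = 587
    n_genes: int = 44
    variants_per_gene: int = 4
    enriched_gene: EnrichedGeneSpec = field(default_factory=EnrichedGeneSpec)
    ppi: PPISpec = field(default_factory=PPISpec)

    def __post_init__(self):
        for name in (
            "n_trio_families",
            "n_multiplex_families",
            "n_background_sites",
            "n_strand_decoys",
            "n_cases",
            "n_controls",
            "n_genes",
            "variants_per_gene",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FamilySim:
    pedigree: Pedigree
    genotypes: GenotypeTable
    annotations: dict[tuple, Annotation]
    manifest: list[CandidateMutation]  # planted ground truth


@dataclass
class CohortSim:
    families: list[FamilySim]

    @property
    def manifest(self) -> list[CandidateMutation]:
        return [c for f in self.families for c in f.manifest]


@dataclass
class CaseControlSim:
    genotypes: GenotypeTable
    labels: np.ndarray  # 1 = case, 0 = control
    annotations: dict[tuple, Annotation]
    enriched_gene: str


# ---------------------------------------------------------------------------
# families


def _balanced_strand(rng: np.random.Generator, depth: int = 40) -> tuple[int, int, int, int]:
    alt = depth // 2
    ref = depth - alt
    af = int(rng.binomial(alt, 0.5))
    rf = int(rng.binomial(ref, 0.5))
    return (rf, ref - rf, af, alt - af)


def _default_plant(design: str, family_index: int) -> PlantSpec:
    if design == "trio":
        cycle = ["de_novo", "recessive_hom", "recessive_compound_het"]
        return PlantSpec(model=cycle[family_index % 3], gene=f"PLANT_F{family_index}")
    return PlantSpec(model="dominant", gene=f"PLANT_F{family_index}")


def _family_members(design: str, fam: str) -> list[PedigreeMember]:
    if design == "trio":
        return [
            PedigreeMember(f"{fam}_fa", None, None, 1, Affection.no),
            PedigreeMember(f"{fam}_mo", None, None, 2, Affection.no),
            PedigreeMember(f"{fam}_ch", f"{fam}_fa", f"{fam}_mo", 1, Affection.yes),
        ]
    # five-member multiplex: affected parent, affected proband, unaffected
    # sib, unaffected parent, unknown-status sib
    return [
        PedigreeMember(f"{fam}_fa", None, None, 1, Affection.yes),
        PedigreeMember(f"{fam}_mo", None, None, 2, Affection.no),
        PedigreeMember(f"{fam}_c1", f"{fam}_fa", f"{fam}_mo", 2, Affection.yes),
        PedigreeMember(f"{fam}_c2", f"{fam}_fa", f"{fam}_mo", 1, Affection.no),
        PedigreeMember(f"{fam}_c3", f"{fam}_fa", f"{fam}_mo", 2, Affection.unknown),
    ]


def simulate_family(
    config: SimulationConfig, family_index: int, plant: PlantSpec | None = None
) -> FamilySim:
    """Simulate one family: pedigree, genotypes, annotations, truth manifest.

    Background founder genotypes are Hardy-Weinberg draws at rare-skewed
    allele frequencies, transmitted mendelianly to offspring (so no
    background site can mimic a de novo event).  Background missense sites
    absent from the simulated databases are annotated tolerated/benign so
    that, by construction, only planted sites survive the full cascade;
    ``n_strand_decoys`` damaging, database-absent decoy sites with fully
    orientation-skewed alt reads exercise the strand-bias stage.
    """
    design = "trio" if family_index < config.n_trio_families else "multiplex"
    if plant is None:
        if config.plant_spec is not None:
            plant = config.plant_spec[family_index % len(config.plant_spec)]
        else:
            plant = _default_plant(design, family_index)
    if design == "trio" and plant.model == "dominant":
        raise ValueError("dominant plants belong in multiplex families")
    if design == "multiplex" and plant.model != "dominant":
        raise ValueError(f"{plant.model} plants require a trio family")

    rng = np.random.default_rng([config.seed, family_index])
    fam = f"F{family_index:03d}"
    members = _family_members(design, fam)
    ped = Pedigree(family_id=fam, members=members)
    sample_ids = [m.sample_id for m in members]
    founders = [i for i, m in enumerate(members) if m.father_id is None]
    offspring = [i for i, m in enumerate(members) if m.father_id is not None]

    n_bg = config.n_background_sites
    a, b = config.background_maf_beta
    mafs = rng.beta(a, b, size=n_bg)
    class_codes = rng.choice(3, size=n_bg, p=[0.45, 0.45, 0.10])
    class_by_code = [FunctionalClass.synonymous, FunctionalClass.missense, FunctionalClass.other]
    chrom_choices = rng.integers(1, 23, size=n_bg)
    positions = np.cumsum(rng.integers(100, 10_000, size=n_bg)) + 1  # distinct, sorted

    sites: list[VariantSite] = []
    annotations: dict[tuple, Annotation] = {}
    gt = np.zeros((len(members), n_bg), dtype=np.int8)

    # founder genotypes are HWE draws; offspring genotypes are one
    # transmitted allele per parent (so Mendelian errors are impossible)
    for i in founders:
        gt[i, :] = rng.binomial(2, mafs)
    for i in offspring:
        fa = sample_ids.index(members[i].father_id)
        mo = sample_ids.index(members[i].mother_id)
        alleles = np.zeros(n_bg, dtype=np.int8)
        for parent_row in (gt[fa, :], gt[mo, :]):
            coin = rng.integers(0, 2, size=n_bg).astype(np.int8)
            alleles += np.where(parent_row == 2, 1, np.where(parent_row == 0, 0, coin)).astype(
                np.int8
            )
        gt[i, :] = alleles

    alt_fwd = rng.binomial(20, 0.5, size=n_bg)
    ref_fwd = rng.binomial(20, 0.5, size=n_bg)
    flagged_arr = mafs > config.db_flag_maf_threshold
    db_yes, db_no = frozenset({"dbSNP137"}), frozenset()
    for j in range(n_bg):
        fclass = class_by_code[class_codes[j]]
        site = VariantSite(
            chrom=str(chrom_choices[j]),
            pos=int(positions[j]),
            ref="A",
            alt="G",
            gene=f"BG{j:05d}",
            functional_class=fclass,
        )
        sites.append(site)
        flagged = bool(flagged_arr[j])
        if fclass is FunctionalClass.missense:
            sift, polyphen = (
                (Sift.damaging, PolyPhen.benign) if flagged else (Sift.tolerated, PolyPhen.benign)
            )
        else:
            sift, polyphen = Sift.missing, PolyPhen.missing
        annotations[site.key] = Annotation(
            sift=sift,
            polyphen=polyphen,
            db_flags=db_yes if flagged else db_no,
            maf=float(mafs[j]),
            strand_counts=(int(ref_fwd[j]), int(20 - ref_fwd[j]), int(alt_fwd[j]), int(20 - alt_fwd[j])),
        )

    # strand-bias decoys: damaging, database-absent, carried het by one
    # parent and the child, but with all alt reads on one orientation
    next_pos = int(positions[-1]) + 1000 if n_bg else 1_000_000
    for d in range(config.n_strand_decoys):
        site = VariantSite(
            chrom="1",
            pos=next_pos + d * 500,
            ref="C",
            alt="T",
            gene=f"DECOY{d}",
            functional_class=FunctionalClass.missense,
        )
        sites.append(site)
        annotations[site.key] = Annotation(
            sift=Sift.damaging,
            polyphen=PolyPhen.probably_damaging,
            db_flags=frozenset(),
            maf=None,
            strand_counts=(20, 20, 22, 0),
        )
        col = np.zeros(len(members), dtype=np.int8)
        col[founders[0]] = Genotype.het
        for i in offspring:
            if members[i].father_id == members[founders[0]].sample_id:
                col[i] = Genotype.het
        gt = np.column_stack([gt, col])

    plant_sites, plant_cols, manifest = _plant(plant, ped, members, next_pos + 100_000, rng)
    for s, c in zip(plant_sites, plant_cols):
        sites.append(s)
        annotations[s.key] = Annotation(
            sift=plant.sift,
            polyphen=plant.polyphen,
            db_flags=frozenset(),
            maf=None,
            strand_counts=_balanced_strand(rng),
        )
        gt = np.column_stack([gt, c])

    table = GenotypeTable(sample_ids=sample_ids, sites=sites, gt=gt)
    return FamilySim(pedigree=ped, genotypes=table, annotations=annotations, manifest=manifest)


def _plant(
    plant: PlantSpec,
    ped: Pedigree,
    members: list[PedigreeMember],
    base_pos: int,
    rng: np.random.Generator,
) -> tuple[list[VariantSite], list[np.ndarray], list[CandidateMutation]]:
    ids = [m.sample_id for m in members]
    n = len(members)

    def site(offset: int, cdna: str) -> VariantSite:
        return VariantSite(
            chrom="2",
            pos=base_pos + offset,
            ref="G",
            alt="T",
            gene=plant.gene,
            transcript="NM_SIM",
            cdna_change=cdna,
            protein_change="p.SIM",
            functional_class=FunctionalClass.missense,
        )

    if plant.model == "de_novo":
        s = site(0, "c.100G>T")
        col = np.zeros(n, dtype=np.int8)
        ch = ids.index(f"{ped.family_id}_ch")
        col[ch] = Genotype.het
        return [s], [col], [
            CandidateMutation(s, "de_novo", ped.family_id, (ids[ch],))
        ]
    if plant.model == "recessive_hom":
        s = site(0, "c.100G>T")
        col = np.zeros(n, dtype=np.int8)
        fa, mo, ch = (ids.index(f"{ped.family_id}_{r}") for r in ("fa", "mo", "ch"))
        col[fa] = col[mo] = Genotype.het
        col[ch] = Genotype.hom_alt
        return [s], [col], [
            CandidateMutation(s, "recessive_hom", ped.family_id, (ids[ch],))
        ]
    if plant.model == "recessive_compound_het":
        fa, mo, ch = (ids.index(f"{ped.family_id}_{r}") for r in ("fa", "mo", "ch"))
        if members[ch].father_id is None or members[ch].mother_id is None:
            raise ValueError("compound het plant requires both parents")
        s1, s2 = site(0, "c.100G>T"), site(50, "c.200G>T")
        c1 = np.zeros(n, dtype=np.int8)
        c1[fa] = Genotype.het
        c1[ch] = Genotype.het
        c2 = np.zeros(n, dtype=np.int8)
        c2[mo] = Genotype.het
        c2[ch] = Genotype.het
        return [s1, s2], [c1, c2], [
            CandidateMutation(
                s1, "recessive_compound_het", ped.family_id, (ids[ch],), partner_site=s2
            )
        ]
    if plant.model == "dominant":
        s = site(0, "c.100G>T")
        col = np.zeros(n, dtype=np.int8)
        carriers = []
        for i, m in enumerate(members):
            if m.affected is Affection.yes:
                col[i] = Genotype.het
                carriers.append(m.sample_id)
        return [s], [col], [
            CandidateMutation(s, "dominant", ped.family_id, tuple(carriers))
        ]
    raise ValueError(f"unknown inheritance model {plant.model!r}")


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Simulate all configured trio and multiplex families."""
    n = config.n_trio_families + config.n_multiplex_families
    return CohortSim(families=[simulate_family(config, i) for i in range(n)])


# ---------------------------------------------------------------------------
# case/control panel


def simulate_case_control(config: SimulationConfig) -> CaseControlSim:
    """Simulate the rare-variant association panel.

    All genes carry ``variants_per_gene`` rare damaging missense variants
    under Hardy-Weinberg in controls and (for null genes) in cases; the
    designated enriched gene's variants have excess case carriers at the
    configured odds ratio, or exactly the configured het carrier counts.
    """
    if config.n_cases <= 0 or config.n_controls <= 0:
        raise ValueError("need positive case and control counts")
    spec = config.enriched_gene
    rng = np.random.default_rng([config.seed, 10_000])
    n = config.n_cases + config.n_controls
    labels = np.concatenate(
        [np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    )
    sample_ids = [f"case{i:04d}" for i in range(config.n_cases)] + [
        f"ctrl{i:04d}" for i in range(config.n_controls)
    ]
    sites: list[VariantSite] = []
    annotations: dict[tuple, Annotation] = {}
    cols: list[np.ndarray] = []
    pos = 1000
    genes = [spec.gene] + [f"GENE{i:03d}" for i in range(1, config.n_genes)]
    for gi, gene in enumerate(genes):
        enriched = gene == spec.gene
        n_var = spec.n_variants if enriched else config.variants_per_gene
        if enriched and spec.carrier_counts is not None:
            n_var = len(spec.carrier_counts)
            for cc in spec.carrier_counts:
                if cc[0] > config.n_cases or cc[1] > config.n_controls:
                    raise ValueError("enriched-gene carrier count exceeds panel size")
        for v in range(n_var):
            pos += int(rng.integers(50, 500))
            site = VariantSite(
                chrom=str(gi % 22 + 1),
                pos=pos,
                ref="C",
                alt="T",
                gene=gene,
                functional_class=FunctionalClass.missense,
            )
            q = float(rng.uniform(0.0005, 0.008))
            if enriched and spec.carrier_counts is not None:
                case_c, ctrl_c = spec.carrier_counts[v]
                col = np.zeros(n, dtype=np.int8)
                col[rng.choice(config.n_cases, size=case_c, replace=False)] = Genotype.het
                col[
                    config.n_cases
                    + rng.choice(config.n_controls, size=ctrl_c, replace=False)
                ] = Genotype.het
            else:
                ctrl_gt = rng.binomial(1, q, size=config.n_controls) + rng.binomial(
                    1, q, size=config.n_controls
                )
                if enriched:
                    p0 = 2 * q * (1 - q)
                    p1 = spec.odds_ratio * p0 / (1 - p0 + spec.odds_ratio * p0)
                    case_gt = rng.binomial(1, p1, size=config.n_cases)
                else:
                    case_gt = rng.binomial(1, q, size=config.n_cases) + rng.binomial(
                        1, q, size=config.n_cases
                    )
                col = np.concatenate([case_gt, ctrl_gt]).astype(np.int8)
            sites.append(site)
            cols.append(col)
            annotations[site.key] = Annotation(
                sift=Sift.damaging,
                polyphen=PolyPhen.probably_damaging,
                db_flags=frozenset(),
                maf=q,
                strand_counts=_balanced_strand(rng),
            )
    gt = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int8)
    table = GenotypeTable(sample_ids=sample_ids, sites=sites, gt=gt)
    return CaseControlSim(
        genotypes=table, labels=labels, annotations=annotations, enriched_gene=spec.gene
    )


# ---------------------------------------------------------------------------
# PPI graph


def simulate_ppi(config: SimulationConfig) -> InteractionGraph:
    """Erdos-Renyi background plus guaranteed seed/candidate/hub edges."""
    spec = config.ppi
    named = list(spec.seed_genes) + [spec.hub_gene] + list(spec.candidates)
    n_anon = spec.n_genes - len(named)
    if n_anon < 0:
        raise ValueError("n_genes smaller than the number of designated genes")
    if spec.hub_degree > len(spec.candidates):
        raise ValueError("hub_degree exceeds the number of candidates")
    if spec.hub_degree > spec.n_genes - 1:
        raise ValueError("hub_degree exceeds n_genes - 1")
    rng = np.random.default_rng([config.seed, 20_000])
    nodes = named + [f"BGG{i:04d}" for i in range(n_anon)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if spec.edge_density > 0:
        idx = np.triu_indices(len(nodes), k=1)
        mask = rng.random(len(idx[0])) < spec.edge_density
        for i, j in zip(idx[0][mask], idx[1][mask]):
            g.add_edge(nodes[i], nodes[j])
    # guaranteed structure: first `direct_candidates` candidates touch a seed,
    # first `hub_degree` candidates touch the hub
    for k, cand in enumerate(spec.candidates[: spec.direct_candidates]):
        g.add_edge(cand, spec.seed_genes[k % len(spec.seed_genes)])
    for cand in spec.candidates[: spec.hub_degree]:
        g.add_edge(cand, spec.hub_gene)
    # hub must not accidentally touch remaining candidates
    for cand in spec.candidates[spec.hub_degree :]:
        if g.has_edge(cand, spec.hub_gene):
            g.remove_edge(cand, spec.hub_gene)
    return InteractionGraph(
        graph=g,
        seeds=set(spec.seed_genes),
        hub=spec.hub_gene,
        candidates=set(spec.candidates),
    )


# ---------------------------------------------------------------------------
# multi-species alignment


def simulate_msa(
    n_species: int = 7,
    length: int = 100,
    conserved_positions: set[int] | None = None,
    seed: int = 0,
) -> MultipleSeqAlignment:
    """Protein MSA whose columns in ``conserved_positions`` (0-based) are
    invariant across species while every other column varies in >= 1 row."""
    conserved = set(conserved_positions or ())
    bad = {c for c in conserved if not 0 <= c < length}
    if bad:
        raise ValueError(f"conserved positions out of range: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_species, length), dtype="<U1")
    for j in range(length):
        if j in conserved:
            rows[:, j] = rng.choice(AMINO_ACIDS)
        else:
            col = rng.choice(AMINO_ACIDS, size=n_species)
            if len(set(col)) == 1:  # force variability
                i = int(rng.integers(0, n_species))
                col[i] = rng.choice(AMINO_ACIDS[AMINO_ACIDS != col[i]])
            rows[:, j] = col
    species = [
        "Homo_sapiens",
        "Macaca_mulatta",
        "Mus_musculus",
        "Canis_familiaris",
        "Gallus_gallus",
        "Xenopus_tropicalis",
        "Danio_rerio",
    ]
    names = (species + [f"species_{i}" for i in range(7, n_species)])[:n_species]
    return MultipleSeqAlignment(
        [SeqRecord(Seq("".join(rows[i])), id=names[i], description="") for i in range(n_species)]
    )
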