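"""Inheritance-model detectors against exhaustive enumeration oracles."""

import itertools

import numpy as np
import pytest

from lqtex.segregation import (
    assign_models,
    detect_compound_het,
    detect_de_novo,
    detect_dominant,
    detect_recessive_hom,
)
from lqtex.variant_model import (
    Affection,
    FunctionalClass,
    Genotype,
    GenotypeTable,
    Pedigree,
    PedigreeMember,
    VariantSite,
)

GENOS = [Genotype.hom_ref, Genotype.het, Genotype.hom_alt, Genotype.missing]


def _trio():
    return Pedigree(
        "T1",
        [
            PedigreeMember("fa", None, None, 1, Affection.no),
            PedigreeMember("mo", None, None, 2, Affection.no),
            PedigreeMember("ch", "fa", "mo", 1, Affection.yes),
        ],
    )


def _trio_table(columns, genes=None):
    """columns: list of (child, father, mother) genotype triples."""
    sites = [
        VariantSite("1", 100 + j, "A", "G",
                    gene=(genes[j] if genes else f"G{j}"),
                    functional_class=FunctionalClass.missense)
        for j in range(len(columns))
    ]
    gt = np.array(
        [[c[1] for c in columns], [c[2] for c in columns], [c[0] for c in columns]],
        dtype=np.int8,
    )
    return GenotypeTable(["fa", "mo", "ch"], sites, gt)


class TestTrioDetectors:
    def test_defining_de_novo_case(self):
        table = _trio_table([(Genotype.het, Genotype.hom_ref, Genotype.hom_ref)])
        assert detect_de_novo(_trio(), table) == [0]

    def test_carrier_parent_blocks_de_novo(self):
        table = _trio_table([(Genotype.het, Genotype.het, Genotype.hom_ref)])
        assert detect_de_novo(_trio(), table) == []

    def test_de_novo_matches_exhaustive_enumeration(self):
        """All 4^3 ordered (child, father, mother) genotype triples."""
        triples = list(itertools.product(GENOS, repeat=3))
        table = _trio_table(triples)
        got = set(detect_de_novo(_trio(), table))
        oracle = {
            j
            for j, (c, f, m) in enumerate(triples)
            if c in (Genotype.het, Genotype.hom_alt)
            and f == Genotype.hom_ref
            and m == Genotype.hom_ref
        }
        assert got == oracle

    def test_recessive_hom_matches_exhaustive_enumeration(self):
        triples = list(itertools.product(GENOS, repeat=3))
        table = _trio_table(triples)
        got = set(detect_recessive_hom(_trio(), table))
        oracle = {
            j
            for j, (c, f, m) in enumerate(triples)
            if c == Genotype.hom_alt and f == Genotype.het and m == Genotype.het
        }
        assert got == oracle

    def test_mendelian_inconsistency_not_rescued(self):
        table = _trio_table([(Genotype.hom_alt, Genotype.het, Genotype.hom_ref)])
        assert detect_recessive_hom(_trio(), table) == []

    def test_non_trio_family_rejected(self):
        fam = Pedigree(
            "M1",
            [
                PedigreeMember("a", None, None, 1, Affection.yes),
                PedigreeMember("b", None, None, 2, Affection.no),
                PedigreeMember("c", "a", "b", 1, Affection.yes),
                PedigreeMember("d", "a", "b", 2, Affection.no),
            ],
        )
        table = GenotypeTable(
            ["a", "b", "c", "d"],
            [VariantSite("1", 1, "A", "G")],
            np.zeros((4, 1), dtype=np.int8),
        )
        with pytest.raises(ValueError, match="not a trio"):
            detect_de_novo(fam, table)


class TestCompoundHet:
    def test_trans_pair_reported(self):
        table = _trio_table(
            [
                (Genotype.het, Genotype.het, Genotype.hom_ref),
                (Genotype.het, Genotype.hom_ref, Genotype.het),
            ],
            genes=["G", "G"],
        )
        assert detect_compound_het(_trio(), table) == [(0, 1)]

    def test_cis_configuration_rejected(self):
        table = _trio_table(
            [
                (Genotype.het, Genotype.het, Genotype.hom_ref),
                (Genotype.het, Genotype.het, Genotype.hom_ref),
            ],
            genes=["G", "G"],
        )
        assert detect_compound_het(_trio(), table) == []

    def test_cross_product_pairing_matches_oracle(self):
        """3 maternal-only x 2 paternal-only sites in one gene -> 6 pairs."""
        pat = (Genotype.het, Genotype.het, Genotype.hom_ref)
        mat = (Genotype.het, Genotype.hom_ref, Genotype.het)
        cols = [pat, pat, mat, mat, mat]
        table = _trio_table(cols, genes=["G"] * 5)
        got = set(detect_compound_het(_trio(), table))
        oracle = {(min(a, b), max(a, b)) for a in (0, 1) for b in (2, 3, 4)}
        assert got == oracle
        assert len(got) == 6

    def test_different_genes_never_pair(self):
        table = _trio_table(
            [
                (Genotype.het, Genotype.het, Genotype.hom_ref),
                (Genotype.het, Genotype.hom_ref, Genotype.het),
            ],
            genes=["G1", "G2"],
        )
        assert detect_compound_het(_trio(), table) == []


def _multiplex(affections):
    members = [
        PedigreeMember("fa", None, None, 1, affections[0]),
        PedigreeMember("mo", None, None, 2, affections[1]),
    ]
    for i, aff in enumerate(affections[2:]):
        members.append(PedigreeMember(f"c{i}", "fa", "mo", 1 + i % 2, aff))
    return Pedigree("M1", members)


class TestDominant:
    def test_cosegregating_variant_called(self):
        fam = _multiplex([Affection.yes, Affection.no, Affection.yes,
                          Affection.no, Affection.no])
        gt = np.array([[1], [0], [1], [0], [0]], dtype=np.int8)
        table = GenotypeTable([m.sample_id for m in fam.members],
                              [VariantSite("1", 1, "A", "G", gene="G")], gt)
        assert detect_dominant(fam, table) == [0]

    def test_unaffected_carrier_blocks(self):
        fam = _multiplex([Affection.yes, Affection.no, Affection.yes,
                          Affection.no, Affection.no])
        gt = np.array([[1], [0], [1], [1], [0]], dtype=np.int8)
        table = GenotypeTable([m.sample_id for m in fam.members],
                              [VariantSite("1", 1, "A", "G", gene="G")], gt)
        assert detect_dominant(fam, table) == []

    def test_random_families_match_predicate_oracle(self):
        rng = np.random.default_rng(17)
        aff_states = [Affection.yes, Affection.no, Affection.unknown]
        for trial in range(10):
            affs = [Affection.yes, Affection.no] + [
                aff_states[rng.integers(0, 3)] for _ in range(3)
            ]
            fam = _multiplex(affs)
            ids = [m.sample_id for m in fam.members]
            gt = rng.integers(-1, 3, size=(5, 50)).astype(np.int8)
            sites = [VariantSite("1", 1 + j, "A", "G", gene=f"G{j}")
                     for j in range(50)]
            table = GenotypeTable(ids, sites, gt)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = set(detect_dominant(fam, table))
            proband = fam.proband.sample_id
            oracle = set()
            for j in range(50):
                pro_g = gt[ids.index(proband), j]
                if pro_g not in (1, 2):
                    continue
                ok = True
                for m in fam.members:
                    g = gt[ids.index(m.sample_id), j]
                    if m.affected is Affection.yes and g in (0,):
                        ok = False
                    if m.affected is Affection.no and g in (1, 2):
                        ok = False
                if ok:
                    oracle.add(j)
            assert got == oracle

    def test_output_never_contains_unaffected_carrier(self):
        rng = np.random.default_rng(23)
        fam = _multiplex([Affection.yes, Affection.no, Affection.yes,
                          Affection.no, Affection.unknown])
        ids = [m.sample_id for m in fam.members]
        gt = rng.integers(-1, 3, size=(5, 200)).astype(np.int8)
        sites = [VariantSite("1", 1 + j, "A", "G") for j in range(200)]
        table = GenotypeTable(ids, sites, gt)
        unaff = [ids.index(m.sample_id) for m in fam.members
                 if m.affected is Affection.no]
        for j in detect_dominant(fam, table):
            assert not any(gt[i, j] in (1, 2) for i in unaff)


class TestAssignModels:
    def test_manifest_recovery_with_labels(self, small_cohort):
        _, cohort = small_cohort
        fams = [f.pedigree for f in cohort.families]
        tables = {f.pedigree.family_id: f.genotypes for f in cohort.families}
        survivors = {}
        for f in cohort.families:
            truth_keys = {c.site.key for c in f.manifest} | {
                c.partner_site.key for c in f.manifest if c.partner_site
            }
            survivors[f.pedigree.family_id] = [
                j for j, s in enumerate(f.genotypes.sites) if s.key in truth_keys
            ]
        candidates = assign_models(fams, tables, survivors)
        got = {(c.family_id, c.site.key, c.model) for c in candidates}
        want = {(c.family_id, c.site.key, c.model) for c in cohort.manifest}
        assert got == want

    def test_no_site_gets_two_models_within_family(self, small_cohort):
        _, cohort = small_cohort
        fams = [f.pedigree for f in cohort.families]
        tables = {f.pedigree.family_id: f.genotypes for f in cohort.families}
        candidates = assign_models(fams, tables)
        seen = set()
        for c in candidates:
            key = (c.family_id, c.site.key)
            assert key not in seen
            seen.add(key)

    def test_all_flagged_cohort_yields_zero_candidates(self):
        fam = _trio()
        table = _trio_table([(Genotype.het, Genotype.hom_ref, Genotype.hom_ref)])
        # empty survivor set simulates every site failing the cascade
        assert assign_models([fam], {"T1": table}, {"T1": []}) == []
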