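"""Ortholog-group filtering, RBH augmentation, tree validation, audit."""

from __future__ import annotations

import numpy as np
import pytest

from corevert import fixtures
from corevert.config import ConfigurationError
from corevert.io import ProteinCollection, ProteinRecord
from corevert.ortho_core import (
    DUPLICATION,
    CoreGene,
    GeneTree,
    OrthologGroup,
    SpeciesPanel,
    Taxonomy,
    TreeNode,
    ValidationError,
    audit_false_positive,
    count_lineage_duplications,
    derive_core_set,
    filter_has_outgroup,
    filter_one_to_one,
    rbh_augment,
    tree_validates_one_to_one,
)


def make_group(gid, members):
    """members: species -> list of gene ids; one protein per gene."""
    proteins = {}
    representative = {}
    for genes in members.values():
        for g in genes:
            proteins[g] = [f"{g}_p1"]
            representative[g] = f"{g}_p1"
    return OrthologGroup(gid, {sp: list(gs) for sp, gs in members.items()},
                         proteins, representative)


@pytest.fixture()
def panel():
    return SpeciesPanel(
        panel_id="p",
        core_species=frozenset({"a", "b"}),
        extension_species=frozenset({"c"}),
        outgroup_species=frozenset({"og1", "og2"}),
        late_species="late",
        assessment_species=("a", "b", "c", "late"),
    )


class TestPanel:
    def test_roles_must_be_disjoint(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            SpeciesPanel("p", frozenset({"a"}), extension_species=frozenset({"a"}))

    def test_core_nonempty(self):
        with pytest.raises(ConfigurationError):
            SpeciesPanel("p", frozenset())

    def test_assessment_subset_enforced(self):
        with pytest.raises(ConfigurationError, match="assessment"):
            SpeciesPanel("p", frozenset({"a"}), assessment_species=("a", "zzz"))


class TestFilters:
    def test_one_to_one_keeps_exactly_single_copy_groups(self, panel):
        groups = (
            [make_group(f"ok{i}", {"a": [f"ga{i}"], "b": [f"gb{i}"], "c": [f"gc{i}"]})
             for i in range(5)]
            + [make_group(f"dup{i}", {"a": [f"ga{i}x", f"ga{i}y"], "b": [f"gb{i}x"],
                                      "c": [f"gc{i}x"]}) for i in range(3)]
            + [make_group(f"mis{i}", {"a": [f"gz{i}"], "b": [f"gw{i}"]})
               for i in range(2)]
        )
        kept = filter_one_to_one(groups, panel)
        # brute-force check of every group's membership counts
        expected = [
            g for g in groups
            if all(len(g.members.get(sp, [])) == 1 for sp in ("a", "b", "c"))
        ]
        assert kept == expected
        assert len(kept) == 5
        assert filter_one_to_one(kept, panel) == kept  # idempotent

    def test_one_to_one_empty_input(self, panel):
        assert filter_one_to_one([], panel) == []

    def test_outgroup_filter(self, panel):
        with_og = [
            make_group(f"og{i}", {"a": [f"a{i}"], "og1": [f"o{i}"]})
            for i in range(12)
        ]
        both_og = [make_group("both", {"a": ["ab"], "og1": ["o1b"], "og2": ["o2b"]})]
        without = [make_group(f"no{i}", {"a": [f"n{i}"]}) for i in range(8)]
        kept = filter_has_outgroup(with_og + both_og + without,
                                   panel.outgroup_species)
        assert kept == with_og + both_og
        assert filter_has_outgroup(kept, panel.outgroup_species) == kept

    def test_outgroup_filter_requires_species(self):
        with pytest.raises(ConfigurationError):
            filter_has_outgroup([], set())


def _seq_from_rng(rng, length=80):
    return "".join(fixtures.AMINO_ACIDS[i]
                   for i in rng.integers(20, size=length))


class TestRbhAugment:
    def _family_setup(self, n_families=6, seed=0):
        """Families with a reference member and a similar late ortholog."""
        rng = np.random.default_rng(seed)
        groups, ref, late = [], ProteinCollection(), ProteinCollection()
        orthologs = {}
        for i in range(n_families):
            gid = f"f{i}"
            base = _seq_from_rng(rng)
            ref.add(ProteinRecord("a", f"{gid}_a", f"{gid}_a_p1", base))
            groups.append(make_group(gid, {"a": [f"{gid}_a"]}))
            late_seq = fixtures._mutate(base, 0.1, rng)
            late.add(ProteinRecord("late", f"{gid}_late", f"{gid}_late_p1", late_seq))
            orthologs[gid] = f"{gid}_late_p1"
        return groups, ref, late, orthologs, rng

    def test_identity_copies_are_reciprocal(self, scorer):
        groups, ref, late, orthologs, _ = self._family_setup()
        out = rbh_augment(groups, late, scorer, ref)
        assert len(out) == len(groups)
        for g in out:
            assert g.members["late"] == [f"{g.group_id}_late"]

    def test_planted_decoys_never_assigned(self, scorer):
        groups, ref, late, orthologs, rng = self._family_setup()
        # decoys: extra late proteins more diverged from each family than
        # the true ortholog
        for i in range(3):
            gid = f"f{i}"
            decoy = fixtures._mutate(ref.sequence(f"{gid}_a_p1"), 0.4, rng)
            late.add(ProteinRecord("late", f"{gid}_decoy", f"{gid}_decoy_p1", decoy))
        out = rbh_augment(groups, late, scorer, ref)
        # exhaustive all-vs-all check: the decoy always scores below the
        # true ortholog against its family representative
        for i in range(3):
            rep = ref.sequence(f"f{i}_a_p1")
            assert scorer.score(rep, late.sequence(f"f{i}_decoy_p1")) < scorer.score(
                rep, late.sequence(f"f{i}_late_p1")
            )
        assert len(out) == len(groups)
        for g in out:
            assert g.members["late"] == [f"{g.group_id}_late"]

    def test_family_without_late_ortholog_is_dropped(self, scorer):
        groups, ref, late, orthologs, _ = self._family_setup()
        trimmed = ProteinCollection(
            r for r in late if r.protein_id != "f0_late_p1"
        )
        out = rbh_augment(groups, trimmed, scorer, ref)
        assert {g.group_id for g in out} == {f"f{i}" for i in range(1, 6)}

    def test_empty_proteome_drops_everything(self, scorer):
        groups, ref, _, _, _ = self._family_setup(2)
        assert rbh_augment(groups, ProteinCollection(), scorer, ref) == []


def leaf(gene, species):
    return TreeNode(label=gene, species=species)


def internal(event, taxon, children):
    node = TreeNode(event=event, taxon=taxon)
    for c in children:
        node.add_child(c)
    return node


@pytest.fixture(scope="module")
def taxonomy():
    return fixtures.default_taxonomy()


def spanning_oracle(tree: GeneTree, gene_ids):
    """Brute force: union of internal nodes on paths between leaf pairs."""
    leaves = [tree.leaf_for_gene(g) for g in gene_ids]
    nodes = set()
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            anc_a = list(a.ancestors(include_self=True))
            anc_b = list(b.ancestors(include_self=True))
            common = set(anc_a) & set(anc_b)
            mrca = next(n for n in anc_a if n in common)
            for path in (anc_a, anc_b):
                for n in path:
                    if not n.is_leaf:
                        nodes.add(n)
                    if n is mrca:
                        break
            nodes.add(mrca)
    return nodes


def validates_oracle(group, tree, taxonomy, clade="Vertebrata"):
    lineage = taxonomy.species_in(clade)
    genes = [g for sp, g in group.genes() if sp in lineage]
    for node in spanning_oracle(tree, genes):
        if node.event == DUPLICATION and node.taxon in taxonomy:
            if taxonomy.descends_from(node.taxon, clade):
                return False
    return True


class TestTreeValidation:
    def test_vertebrate_duplication_invalidates(self, taxonomy):
        tree = GeneTree(
            internal("duplication", "Vertebrata", [
                internal("speciation", "Amniota", [
                    leaf("g_h", "human"), leaf("g_c", "chicken")]),
                leaf("g_z", "zebrafish"),
            ])
        )
        group = make_group("g", {"human": ["g_h"], "chicken": ["g_c"],
                                 "zebrafish": ["g_z"]})
        assert tree_validates_one_to_one(group, tree, taxonomy) is False

    def test_outgroup_side_duplication_ignored(self, taxonomy):
        # duplication produced a second tunicate copy only; the vertebrate
        # spanning subtree does not contain the duplication node
        tree = GeneTree(
            internal("speciation", "Chordata", [
                internal("speciation", "Amniota", [
                    leaf("g_h", "human"), leaf("g_c", "chicken")]),
                internal("duplication", "Tunicata", [
                    leaf("g_t1", "ciona_i"), leaf("g_t2", "ciona_i")]),
            ])
        )
        group = make_group("g", {"human": ["g_h"], "chicken": ["g_c"],
                                 "ciona_i": ["g_t1", "g_t2"]})
        assert tree_validates_one_to_one(group, tree, taxonomy) is True

    def test_missing_member_raises(self, taxonomy):
        tree = GeneTree(internal("speciation", "Amniota",
                                 [leaf("g_h", "human"), leaf("g_c", "chicken")]))
        group = make_group("g", {"human": ["g_h"], "zebrafish": ["g_z"]})
        with pytest.raises(ValidationError):
            tree_validates_one_to_one(group, tree, taxonomy)

    def test_matches_exhaustive_oracle_on_simulated_trees(self, taxonomy):
        scenarios = fixtures.standard_scenarios(
            50, n_duplication=20, n_pre_vertebrate=10, seed=7
        )
        sim = fixtures.simulate_gene_families(50, scenarios=scenarios, seed=7)
        checked = 0
        for group in sim.groups:
            tree = sim.trees[group.group_id]
            assert tree_validates_one_to_one(
                group, tree, sim.taxonomy
            ) == validates_oracle(group, tree, sim.taxonomy)
            checked += 1
        assert checked == 50

    def test_spanning_nodes_match_pairwise_path_oracle(self):
        sim = fixtures.simulate_gene_families(
            10,
            scenarios=fixtures.standard_scenarios(10, n_duplication=5, seed=3),
            seed=3,
        )
        for group in sim.groups:
            tree = sim.trees[group.group_id]
            genes = [g for _, g in group.genes()
                     if not g.endswith(("ciona_i", "ciona_s"))]
            assert tree.spanning_internal_nodes(genes) == spanning_oracle(tree, genes)


class TestCountLineageDuplications:
    def test_no_duplications_empty_table(self, taxonomy):
        tree = GeneTree(internal("speciation", "Amniota",
                                 [leaf("a", "human"), leaf("b", "chicken")]))
        table = count_lineage_duplications({"g1": tree}, taxonomy, "Vertebrata")
        assert table.empty

    def test_planted_events_recovered_exactly(self, taxonomy):
        rng = np.random.default_rng(5)
        trees = {}
        expected = []
        vertebrate_clades = ["Vertebrata", "Gnathostomata", "Euteleostomi",
                             "Amniota", "Tetrapoda"]
        for i in range(20):
            gid = f"g{i}"
            taxon = vertebrate_clades[rng.integers(len(vertebrate_clades))]
            n_dups = int(rng.integers(0, 3))
            node = internal("speciation", "Mammalia",
                            [leaf(f"{gid}_h", "human"), leaf(f"{gid}_p", "platypus")])
            for d in range(n_dups):
                node = internal("duplication", taxon,
                                [node, leaf(f"{gid}_x{d}", "zebrafish")])
                expected.append((gid, taxon))
            # plus one event outside the lineage, never counted
            node = internal("duplication", "Chordata",
                            [node, leaf(f"{gid}_t", "ciona_i")])
            trees[gid] = GeneTree(node)
        table = count_lineage_duplications(trees, taxonomy, "Vertebrata")
        got = sorted(map(tuple, table.values))
        assert got == sorted(expected)
        assert table.gene_id.nunique() <= len(table)


class TestDeriveCoreSet:
    def test_planted_defects_recovered_exactly(self, sim_families, core_set):
        truth = sim_families.truth
        expected = set(truth[truth.survives].family_id)
        assert set(core_set.gene_ids()) == expected
        counts = [n for _, n in core_set.derivation_log]
        assert counts == sorted(counts, reverse=True)
        # stage counts match the planted defect counts
        n = len(truth)
        assert counts[0] == n - (truth.defect == "missing_species").sum()
        assert counts[1] == counts[0] - (truth.defect == "no_outgroup").sum()
        assert counts[2] == counts[1] - (truth.defect == "rbh_decoy").sum()
        assert counts[3] == counts[2] - (truth.defect == "lineage_duplication").sum()

    def test_all_pass_identity(self, sim_families, scorer):
        sim = fixtures.simulate_gene_families(
            5, scenarios=fixtures.standard_scenarios(5, seed=2), seed=2
        )
        out = derive_core_set(
            sim.groups, sim.trees, sim.late_proteome, sim.taxonomy, sim.panel,
            scorer, sim.reference_proteins,
        )
        assert len(out.genes) == len(sim.groups)

    def test_assessment_species_materialized(self, core_set):
        for gene in core_set.genes:
            assert set(gene.representatives) >= set(
                core_set.panel.assessment_species
            )
            for sp in core_set.panel.assessment_species:
                assert gene.transcripts[sp]


@pytest.fixture(scope="module")
def family():
    rng = np.random.default_rng(17)
    ortholog = _seq_from_rng(rng, 120)
    # ancient paralog: heavily diverged copy from a pre-amniote duplication
    paralog = fixtures._mutate(ortholog, 0.35, rng)
    unrelated = _seq_from_rng(rng, 120)
    proteome = ProteinCollection([
        ProteinRecord("human", "G6PD", "G6PD_h", ortholog),
        ProteinRecord("human", "H6PD", "H6PD_h", paralog),
        ProteinRecord("human", "OTHER", "OTHER_h", unrelated),
    ])
    gene = CoreGene("fam_g6pd", {"human": "G6PD_h"}, {"human": ["G6PD_h"]})
    annotations = {"G6PD_h": {"H6PD_h": "Vertebrata"}}
    return gene, proteome, annotations, ortholog, paralog, rng


class TestAuditFalsePositive:
    def test_paralog_query_flagged(self, family, taxonomy, scorer):
        gene, proteome, annot, _, paralog, rng = family
        # a query derived from the paralog (e.g. chicken H6PD)
        query = fixtures._mutate(paralog, 0.05, rng)
        assert audit_false_positive(
            query, gene, proteome, annot, taxonomy, scorer, "human"
        ) is True

    def test_self_hit_never_flagged(self, family, taxonomy, scorer):
        gene, proteome, annot, ortholog, _, _ = family
        assert audit_false_positive(
            ortholog, gene, proteome, annot, taxonomy, scorer, "human"
        ) is False

    def test_post_split_duplication_not_flagged(self, family, taxonomy, scorer):
        gene, proteome, _, _, paralog, rng = family
        annot = {"G6PD_h": {"H6PD_h": "Mammalia"}}  # duplicated after the split
        query = fixtures._mutate(paralog, 0.05, rng)
        assert audit_false_positive(
            query, gene, proteome, annot, taxonomy, scorer, "human"
        ) is False

    def test_missing_reference_member_raises(self, family, taxonomy, scorer):
        gene, proteome, annot, ortholog, _, _ = family
        bad_gene = CoreGene("x", {"human": "NOPE"}, {"human": ["NOPE"]})
        with pytest.raises(ValueError):
            audit_false_positive(
                ortholog, bad_gene, proteome, annot, taxonomy, scorer, "human"
            )
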