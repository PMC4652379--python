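"""Derivation of core sets of strictly one-to-one orthologous genes.

A core set is built from precomputed ortholog groups by a cascade of
filters: (1) keep groups in which every required species has exactly one
gene; (2) keep groups with at least one outgroup ortholog, which anchors
the family outside the lineage of interest; (3) add a late-released
species by reciprocal best hit and keep groups that gain exactly one
ortholog; (4) keep groups whose annotated gene tree shows no duplication
node inside the lineage's crown clade on the paths among the family's
members. Families surviving all four stages behaved as single-copy genes
throughout the lineage's evolution and are safe references for
completeness assessment.

The module also audits predicted orthologs for the classic failure mode of
core-gene pipelines: a query whose best hit in a reference proteome is an
ancient paralog of the family (duplicated before the mammal-sauropsid
split), e.g. H6PD picked up as a G6PD ortholog.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from corevert.align import PairwiseScorer, best_hit
from corevert.config import ConfigurationError
from corevert.io import ProteinCollection, ProteinRecord

logger = logging.getLogger(__name__)

SPECIATION = "speciation"
DUPLICATION = "duplication"


class ValidationError(ValueError):
    """A group member could not be resolved against its gene tree."""


class StageError(RuntimeError):
    """A derivation stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SpeciesPanel:
    """Species roles in the derivation.

    ``core_species`` and ``extension_species`` are held to the one-to-one
    requirement; ``outgroup_species`` only need one ortholog in at least
    one of them; ``late_species`` is added post hoc by reciprocal best hit;
    ``assessment_species`` is the ordered subset materialized into the
    final set (used for alignment/profile construction).
    """

    panel_id: str
    core_species: frozenset[str]
    extension_species: frozenset[str] = frozenset()
    outgroup_species: frozenset[str] = frozenset()
    late_species: str | None = None
    assessment_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.core_species:
            raise ConfigurationError("core_species must be nonempty")
        roles = [self.core_species, self.extension_species, self.outgroup_species]
        if self.late_species is not None:
            roles.append(frozenset({self.late_species}))
        seen: set[str] = set()
        for role in roles:
            if seen & role:
                raise ConfigurationError(
                    f"species roles overlap: {sorted(seen & role)}"
                )
            seen |= role
        allowed = self.core_species | self.extension_species
        if self.late_species is not None:
            allowed = allowed | {self.late_species}
        extra = set(self.assessment_species) - allowed
        if extra:
            raise ConfigurationError(
                f"assessment species outside core/extension/late: {sorted(extra)}"
            )

    @property
    def one_to_one_species(self) -> frozenset[str]:
        return self.core_species | self.extension_species


@dataclass
class OrthologGroup:
    """One ortholog group: genes per species, proteins per gene."""

    group_id: str
    members: dict[str, list[str]]  # species -> gene ids
    proteins: dict[str, list[str]]  # gene id -> protein ids
    representative: dict[str, str]  # gene id -> flagged protein id

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id}: no species")
        for species, genes in self.members.items():
            if not genes:
                raise ValueError(f"group {self.group_id}: species {species} empty")
            for gene in genes:
                prots = self.proteins.get(gene, [])
                if not prots:
                    raise ValueError(f"group {self.group_id}: gene {gene} has no protein")
                rep = self.representative.get(gene)
                if rep is None or rep not in prots:
                    raise ValueError(
                        f"group {self.group_id}: gene {gene} lacks a representative"
                    )

    def gene_count(self, species: str) -> int:
        return len(self.members.get(species, []))

    def genes(self) -> list[tuple[str, str]]:
        """(species, gene_id) over all members."""
        return [(sp, g) for sp, genes in self.members.items() for g in genes]

    def representative_proteins(self) -> list[str]:
        return [self.representative[g] for _, g in self.genes()]

    def with_member(
        self, species: str, gene_id: str, protein_id: str
    ) -> "OrthologGroup":
        new = copy.deepcopy(self)
        new.members.setdefault(species, [])
        new.members[species].append(gene_id)
        new.proteins[gene_id] = [protein_id]
        new.representative[gene_id] = protein_id
        return new


class TreeNode:
    """Node of a gene tree or taxonomy (simple rooted, labelled)."""

    __slots__ = ("label", "children", "parent", "species", "event", "taxon")

    def __init__(
        self,
        label: str | None = None,
        species: str | None = None,
        event: str | None = None,
        taxon: str | None = None,
    ) -> None:
        self.label = label
        self.species = species
        self.event = event
        self.taxon = taxon
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def ancestors(self, include_self: bool = False) -> Iterable["TreeNode"]:
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent


@dataclass
class GeneTree:
    """Rooted gene tree with speciation/duplication annotations.

    Leaves carry ``(species, gene_id)``; internal nodes carry an event
    (speciation or duplication) and the taxon (clade) at which the event
    occurred.
    """

    root: TreeNode

    def __post_init__(self) -> None:
        self._leaf_by_gene: dict[str, TreeNode] = {}
        for leaf in self.root.leaves():
            if leaf.label is not None:
                self._leaf_by_gene[leaf.label] = leaf

    def leaf_for_gene(self, gene_id: str) -> TreeNode:
        try:
            return self._leaf_by_gene[gene_id]
        except KeyError:
            raise ValidationError(f"gene {gene_id!r} absent from tree") from None

    def duplication_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.event == DUPLICATION]

    def spanning_internal_nodes(self, gene_ids: Sequence[str]) -> set[TreeNode]:
        """Internal nodes of the minimal subtree connecting the given leaves.

        These are exactly the nodes lying on a path between two of the
        leaves: every ancestor of a target leaf at or below the MRCA.
        """
        leaves = [self.leaf_for_gene(g) for g in gene_ids]
        if len(leaves) < 2:
            return set()
        # MRCA via ancestor-path intersection
        paths = []
        for leaf in leaves:
            paths.append(list(leaf.ancestors(include_self=True)))
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common ancestor = first element of any path that is common
        mrca = next(n for n in paths[0] if n in common)
        spanning: set[TreeNode] = set()
        for p in paths:
            for node in p:
                if node is mrca:
                    break
                if not node.is_leaf:
                    spanning.add(node)
        spanning.add(mrca)
        return spanning

    # -- NHX serialization -------------------------------------------------

    def to_nhx(self) -> str:
        def fmt(node: TreeNode) -> str:
            attrs = []
            if node.is_leaf:
                name = node.label or ""
                if node.species:
                    attrs.append(f"S={node.species}")
            else:
                name = ""
                if node.event:
                    attrs.append("D=" + ("Y" if node.event == DUPLICATION else "N"))
                if node.taxon:
                    attrs.append(f"T={node.taxon}")
            nhx = f"[&&NHX:{':'.join(attrs)}]" if attrs else ""
            if node.is_leaf:
                return f"{name}{nhx}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){nhx}"

        return fmt(self.root) + ";"

    @classmethod
    def from_dendropy(cls, tree, comment_parser: Callable[[str], dict]) -> "GeneTree":
        def convert(dnode) -> TreeNode:
            attrs: dict[str, str] = {}
            for comment in dnode.comments or []:
                attrs.update(comment_parser(comment))
            if dnode.is_leaf():
                label = None
                if dnode.taxon is not None:
                    label = dnode.taxon.label
                elif dnode.label:
                    label = dnode.label
                node = TreeNode(label=label, species=attrs.get("S"))
            else:
                event = None
                if "D" in attrs:
                    event = DUPLICATION if attrs["D"] == "Y" else SPECIATION
                node = TreeNode(event=event, taxon=attrs.get("T"))
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(root=convert(tree.seed_node))


class Taxonomy:
    """Rooted tree over clade labels with species at the leaves."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._by_label: dict[str, TreeNode] = {}
        for node in root.walk():
            if node.label:
                if node.label in self._by_label:
                    raise ValueError(f"duplicate taxonomy label {node.label!r}")
                self._by_label[node.label] = node

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def node(self, label: str) -> TreeNode:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"unknown taxonomy label {label!r}") from None

    def descends_from(self, label: str, ancestor_label: str) -> bool:
        """True iff ``ancestor_label`` is on the root path of ``label`` (inclusive)."""
        anc = self.node(ancestor_label)
        node = self.node(label)
        return any(n is anc for n in node.ancestors(include_self=True))

    def species_in(self, clade_label: str) -> set[str]:
        return {
            leaf.label for leaf in self.node(clade_label).leaves() if leaf.label
        }

    @classmethod
    def from_dendropy(cls, tree) -> "Taxonomy":
        def convert(dnode) -> TreeNode:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = TreeNode(label=label)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(tree.seed_node))

    @classmethod
    def from_newick(cls, newick: str) -> "Taxonomy":
        import dendropy

        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
        return cls.from_dendropy(tree)


@dataclass
class CoreGene:
    """One family of the core set, materialized over the assessment species."""

    group_id: str
    representatives: dict[str, str]  # species -> representative protein id
    transcripts: dict[str, list[str]]  # species -> all transcript protein ids
    alignment_ref: str | None = None
    profile_ref: str | None = None

    def validate(self, assessment_species: Sequence[str]) -> None:
        for sp in assessment_species:
            if sp not in self.representatives:
                raise ValueError(
                    f"core gene {self.group_id}: assessment species {sp} absent"
                )


@dataclass
class CoreGeneSet:
    set_id: str
    panel: SpeciesPanel
    genes: list[CoreGene]
    derivation_log: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.group_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate group ids in core set")
        counts = [n for _, n in self.derivation_log]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("derivation log must be non-increasing")

    def gene_ids(self) -> list[str]:
        return [g.group_id for g in self.genes]


# ---------------------------------------------------------------------------
# Filters


def filter_one_to_one(
    groups: Sequence[OrthologGroup], panel: SpeciesPanel
) -> list[OrthologGroup]:
    """Keep groups in which every core/extension species has exactly one gene."""
    required = panel.one_to_one_species
    if not required:
        raise ConfigurationError("one-to-one filter requires a nonempty species set")
    return [g for g in groups if all(g.gene_count(sp) == 1 for sp in required)]


def filter_has_outgroup(
    groups: Sequence[OrthologGroup], outgroup: Iterable[str]
) -> list[OrthologGroup]:
    """Keep groups with at least one ortholog in at least one outgroup species."""
    outgroup = set(outgroup)
    if not outgroup:
        raise ConfigurationError("outgroup filter requires a nonempty species set")
    return [g for g in groups if any(g.gene_count(sp) >= 1 for sp in outgroup)]


# ---------------------------------------------------------------------------
# Reciprocal best hit


def rbh_augment(
    groups: Sequence[OrthologGroup],
    new_proteome: ProteinCollection,
    scorer: PairwiseScorer,
    reference_proteins: ProteinCollection,
) -> list[OrthologGroup]:
    """Add a late species to each group by reciprocal best hit.

    A new-species protein ``c`` is assigned to group ``g`` iff its best hit
    across the representatives of *all* groups is a representative of ``g``
    and that representative's best hit across the new proteome is ``c``.
    Groups gaining exactly one protein are returned (augmented); the rest
    are dropped. A best-hit tie spanning *different* groups makes the
    group identity ambiguous and assigns nothing; a tie between
    representatives of the same group is harmless (any tied representative
    may carry the reciprocal relation).
    """
    if not groups:
        return []
    rep_to_group: dict[str, str] = {}
    rep_seqs: list[tuple[str, str]] = []
    for g in groups:
        for pid in g.representative_proteins():
            rep_to_group[pid] = g.group_id
            rep_seqs.append((pid, reference_proteins.sequence(pid)))

    new_seqs = list(new_proteome.items())
    assigned: dict[str, list[ProteinRecord]] = {}
    for rec in new_proteome:
        scores = {pid: scorer.score(rec.sequence, seq) for pid, seq in rep_seqs}
        top = max(scores.values())
        top_reps = [pid for pid, s in scores.items() if s == top]
        top_groups = {rep_to_group[pid] for pid in top_reps}
        if len(top_groups) > 1:
            logger.warning(
                "rbh: best hit of %s tied across groups %s; assigned to none",
                rec.protein_id,
                sorted(top_groups),
            )
            continue
        reciprocal = False
        for pid in top_reps:
            back_id, _, back_tied = best_hit(
                reference_proteins.sequence(pid), new_seqs, scorer
            )
            if not back_tied and back_id == rec.protein_id:
                reciprocal = True
                break
        if not reciprocal:
            continue
        assigned.setdefault(top_groups.pop(), []).append(rec)

    out: list[OrthologGroup] = []
    for g in groups:
        hits = assigned.get(g.group_id, [])
        if len(hits) == 1:
            rec = hits[0]
            out.append(g.with_member(rec.species, rec.gene_id, rec.protein_id))
        elif len(hits) > 1:
            logger.info(
                "rbh: group %s gained %d proteins; dropped", g.group_id, len(hits)
            )
    return out


# ---------------------------------------------------------------------------
# Gene-tree validation and duplication dating


def tree_validates_one_to_one(
    group: OrthologGroup,
    tree: GeneTree,
    taxonomy: Taxonomy,
    lineage_clade: str = "Vertebrata",
) -> bool:
    """True iff the family shows no duplication inside the lineage crown clade.

    Only duplication nodes on paths among the group's lineage members count
    (the minimal spanning subtree); duplications wholly outside the
    family's own subtree do not disqualify it.
    """
    lineage_species = taxonomy.species_in(lineage_clade)
    member_genes = [
        g for sp, g in group.genes() if sp in lineage_species
    ]
    if not member_genes:
        raise ValidationError(
            f"group {group.group_id}: no members within {lineage_clade}"
        )
    spanning = tree.spanning_internal_nodes(member_genes)
    for node in spanning:
        if node.event == DUPLICATION:
            if node.taxon is None:
                return False  # undated duplication inside the family: not safe
            if node.taxon in taxonomy and taxonomy.descends_from(
                node.taxon, lineage_clade
            ):
                return False
    return True


def count_lineage_duplications(
    trees: Mapping[str, GeneTree],
    taxonomy: Taxonomy,
    lineage_clade: str,
) -> pd.DataFrame:
    """One row per duplication node dated within the lineage, over all trees."""
    if lineage_clade not in taxonomy:
        raise KeyError(f"{lineage_clade!r} is not a clade of the taxonomy")
    rows = []
    for gene_id, tree in trees.items():
        for node in tree.duplication_nodes():
            if node.taxon and node.taxon in taxonomy and taxonomy.descends_from(
                node.taxon, lineage_clade
            ):
                rows.append((gene_id, node.taxon))
    return pd.DataFrame(rows, columns=["gene_id", "duplication_taxon"])


# ---------------------------------------------------------------------------
# Full derivation


def derive_core_set(
    groups: Sequence[OrthologGroup],
    trees: Mapping[str, GeneTree],
    new_proteome: ProteinCollection,
    taxonomy: Taxonomy,
    panel: SpeciesPanel,
    scorer: PairwiseScorer,
    reference_proteins: ProteinCollection,
    lineage_clade: str = "Vertebrata",
    set_id: str = "core-set",
) -> CoreGeneSet:
    """Run the full filter cascade and materialize the core set.

    Stages: one-to-one filter, outgroup filter, reciprocal-best-hit
    augmentation, gene-tree validation. The derivation log records the
    group count surviving each stage. Groups without a gene tree are
    excluded with a warning (they cannot be validated).
    """
    try:
        stage1 = filter_one_to_one(groups, panel)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage identity
        raise StageError("one_to_one", str(exc)) from exc
    try:
        stage2 = filter_has_outgroup(stage1, panel.outgroup_species)
    except Exception as exc:  # noqa: BLE001
        raise StageError("outgroup", str(exc)) from exc
    try:
        stage3 = rbh_augment(stage2, new_proteome, scorer, reference_proteins)
    except Exception as exc:  # noqa: BLE001
        raise StageError("rbh", str(exc)) from exc

    stage4: list[OrthologGroup] = []
    for g in stage3:
        tree = trees.get(g.group_id)
        if tree is None:
            logger.warning(
                "no gene tree for group %s; excluded from the validated set",
                g.group_id,
            )
            continue
        try:
            ok = tree_validates_one_to_one(g, tree, taxonomy, lineage_clade)
        except ValidationError as exc:
            logger.warning("group %s: %s; excluded", g.group_id, exc)
            continue
        if ok:
            stage4.append(g)

    genes = []
    for g in stage4:
        reps: dict[str, str] = {}
        transcripts: dict[str, list[str]] = {}
        for sp in panel.assessment_species:
            sp_genes = g.members.get(sp, [])
            if len(sp_genes) != 1:
                raise StageError(
                    "materialize",
                    f"group {g.group_id}: assessment species {sp} has "
                    f"{len(sp_genes)} genes",
                )
            gene = sp_genes[0]
            reps[sp] = g.representative[gene]
            transcripts[sp] = list(g.proteins[gene])
        core_gene = CoreGene(group_id=g.group_id, representatives=reps,
                             transcripts=transcripts)
        core_gene.validate(panel.assessment_species)
        genes.append(core_gene)

    log = [
        ("one_to_one", len(stage1)),
        ("outgroup", len(stage2)),
        ("rbh", len(stage3)),
        ("tree_validated", len(stage4)),
    ]
    return CoreGeneSet(set_id=set_id, panel=panel, genes=genes, derivation_log=log)


# ---------------------------------------------------------------------------
# False-positive audit


def audit_false_positive(
    predicted_protein: str,
    gene: CoreGene,
    reference_proteome: ProteinCollection,
    reference_tree_annotations: Mapping[str, Mapping[str, str]],
    taxonomy: Taxonomy,
    scorer: PairwiseScorer,
    reference_species: str,
    split_clade: str = "Amniota",
) -> bool | None:
    """Flag a predicted ortholog as an ancient-paralog false positive.

    The query's best hit is sought in the reference-species proteome. The
    prediction is a false positive iff that best hit is a paralog of the
    gene's reference member *and* the pair's duplication taxon is at or
    above the mammal-sauropsid split (``split_clade``). Returns ``None``
    when the best hit is tied (unresolved).

    ``reference_tree_annotations`` maps a protein id to
    ``{paralog protein id: duplication taxon}``.
    """
    ref_member = gene.representatives.get(reference_species)
    if ref_member is None or ref_member not in reference_proteome:
        raise ValueError(
            f"reference proteome lacks the {reference_species} member of "
            f"{gene.group_id}"
        )
    hit_id, _, tied = best_hit(
        predicted_protein, list(reference_proteome.items()), scorer
    )
    if tied or hit_id is None:
        return None
    if hit_id == ref_member:
        return False
    hit_gene = reference_proteome.get(hit_id).gene_id
    member_gene = reference_proteome.get(ref_member).gene_id
    if hit_gene == member_gene:
        return False  # alternative transcript of the ortholog itself
    partners = reference_tree_annotations.get(ref_member, {})
    taxon = partners.get(hit_id)
    if taxon is None:
        return False  # best hit is not an annotated paralog of the family
    return taxon in taxonomy and taxonomy.descends_from(split_clade, taxon)
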