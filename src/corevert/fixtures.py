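"""Deterministic synthetic inputs with ground truth for the whole pipeline.

The generator emulates the situation the derivation pipeline is built for:
a chordate taxonomy with a vertebrate crown clade, gene families evolved
from an ancestral protein by point substitution (no indels, so alignments
and profile lengths are analytically known), tunicate outgroups, a
late-released species (shark) added by reciprocal best hit, and defect
classes that each trip exactly one derivation filter:

* ``missing_species`` — one required species absent (one-to-one filter);
* ``no_outgroup`` — no tunicate ortholog (outgroup filter);
* ``rbh_decoy`` — the late species lacks a true ortholog, so reciprocal
  best hit finds none (RBH stage);
* ``lineage_duplication`` — the family's members descend from two copies
  of a duplication dated inside the vertebrate crown clade (tree stage);
* ``pre_vertebrate_duplication`` — a duplication on the family's spanning
  subtree but dated before vertebrates; the family must survive.

Branch lengths follow the real panel's asymmetry: the cyclostome and
tunicate members are far more divergent than the tetrapods, which is what
makes real detection cutoffs permissive relative to the best members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from corevert.io import PairMapping, ProteinCollection, ProteinRecord
from corevert.ortho_core import (
    DUPLICATION,
    SPECIATION,
    CoreGeneSet,
    GeneTree,
    OrthologGroup,
    SpeciesPanel,
    Taxonomy,
    TreeNode,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Most-frequent codon of the standard code per amino acid (back-translation).
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

DEFAULT_TAXONOMY_NEWICK = (
    "((((((("
    "human,platypus)Mammalia,chicken)Amniota,xenopus)Tetrapoda,"
    "(zebrafish,stickleback)Teleostei)Euteleostomi,shark)Gnathostomata,"
    "lamprey)Vertebrata,(ciona_i,ciona_s)Tunicata)Chordata;"
)

#: Relative divergence of each species from the family ancestor, scaled by
#: the scenario's substitution rate. Cyclostomes/tunicates are deep.
RELATIVE_DEPTH = {
    "human": 0.05,
    "platypus": 0.15,
    "chicken": 0.15,
    "xenopus": 0.25,
    "zebrafish": 0.35,
    "stickleback": 0.35,
    "shark": 0.45,
    "lamprey": 1.00,
    "ciona_i": 1.10,
    "ciona_s": 1.10,
}

DEFECTS = (
    "none",
    "missing_species",
    "no_outgroup",
    "rbh_decoy",
    "lineage_duplication",
    "pre_vertebrate_duplication",
)

#: Defect classes whose families must survive the full derivation.
SURVIVING_DEFECTS = {"none", "pre_vertebrate_duplication"}


def default_taxonomy() -> Taxonomy:
    return Taxonomy.from_newick(DEFAULT_TAXONOMY_NEWICK)


def default_panel() -> SpeciesPanel:
    return SpeciesPanel(
        panel_id="vertebrate-8",
        core_species=frozenset(
            {"human", "platypus", "chicken", "xenopus", "stickleback"}
        ),
        extension_species=frozenset({"zebrafish", "lamprey"}),
        outgroup_species=frozenset({"ciona_i", "ciona_s"}),
        late_species="shark",
        assessment_species=(
            "human",
            "platypus",
            "chicken",
            "xenopus",
            "zebrafish",
            "stickleback",
            "shark",
            "lamprey",
        ),
    )


@dataclass(frozen=True)
class FamilyScenario:
    family_id: str
    defect: str = "none"
    rate: float = 0.40  # substitution probability per site on the deepest branch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.defect not in DEFECTS:
            raise ValueError(f"unknown defect {self.defect!r}")
        if not (0.0 <= self.rate < 0.5):
            raise ValueError("rate must be in [0, 0.5)")


def standard_scenarios(
    n: int,
    n_missing: int = 0,
    n_no_outgroup: int = 0,
    n_rbh: int = 0,
    n_duplication: int = 0,
    n_pre_vertebrate: int = 0,
    rate: float = 0.40,
    seed: int = 0,
) -> list[FamilyScenario]:
    """Scenario list with the given disjoint defect counts, rest defect-free."""
    defects = (
        ["missing_species"] * n_missing
        + ["no_outgroup"] * n_no_outgroup
        + ["rbh_decoy"] * n_rbh
        + ["lineage_duplication"] * n_duplication
        + ["pre_vertebrate_duplication"] * n_pre_vertebrate
    )
    if len(defects) > n:
        raise ValueError("more defects than families")
    defects += ["none"] * (n - len(defects))
    rng = np.random.default_rng(seed)
    rng.shuffle(defects)
    return [
        FamilyScenario(family_id=f"fam{i:04d}", defect=d, rate=rate, seed=seed + i)
        for i, d in enumerate(defects)
    ]


@dataclass
class SimulatedFamilies:
    groups: list[OrthologGroup]
    trees: dict[str, GeneTree]
    taxonomy: Taxonomy
    panel: SpeciesPanel
    reference_proteins: ProteinCollection  # members of all groups (no late species)
    late_proteome: ProteinCollection  # late-species proteins only
    truth: pd.DataFrame  # family_id, defect, survives


def _mutate(seq: str, prob: float, rng: np.random.Generator) -> str:
    if prob <= 0:
        return seq
    chars = list(seq)
    n_mut = int(round(prob * len(chars)))
    positions = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for pos in positions:
        current = chars[pos]
        choices = AMINO_ACIDS.replace(current, "")
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _pruned_species_tree(tax_node: TreeNode, species: set[str],
                         gene_of: Mapping[str, str]) -> TreeNode | None:
    """Prune the taxonomy to the given species; speciation nodes keep labels."""
    if tax_node.is_leaf:
        if tax_node.label in species:
            return TreeNode(label=gene_of[tax_node.label], species=tax_node.label)
        return None
    kids = [
        sub
        for child in tax_node.children
        if (sub := _pruned_species_tree(child, species, gene_of)) is not None
    ]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    node = TreeNode(event=SPECIATION, taxon=tax_node.label)
    for k in kids:
        node.add_child(k)
    return node


def _family_tree(
    scenario: FamilyScenario,
    member_species: set[str],
    gene_of: Mapping[str, str],
    taxonomy: Taxonomy,
    rng: np.random.Generator,
) -> GeneTree:
    if scenario.defect not in ("lineage_duplication", "pre_vertebrate_duplication"):
        root = _pruned_species_tree(taxonomy.root, member_species, gene_of)
        return GeneTree(root=root)

    if scenario.defect == "lineage_duplication":
        dup_taxon = ["Vertebrata", "Gnathostomata", "Euteleostomi"][
            rng.integers(3)
        ]
        inside = sorted(member_species & taxonomy.species_in(dup_taxon))
        outside = member_species - set(inside)
    else:  # pre-vertebrate duplication: the two copies split at Chordata
        dup_taxon = "Chordata"
        inside = sorted(member_species & taxonomy.species_in("Chordata"))
        outside = member_species - set(inside)
    # split the clade's members across the two duplicate copies
    k = int(rng.integers(1, len(inside)))
    perm = list(rng.permutation(inside))
    copy_a, copy_b = set(perm[:k]), set(perm[k:])
    dup = TreeNode(event=DUPLICATION, taxon=dup_taxon)
    for side in (copy_a, copy_b):
        sub = _pruned_species_tree(taxonomy.root, side, gene_of)
        dup.add_child(sub)
    if outside:
        root = TreeNode(event=SPECIATION, taxon="Chordata")
        root.add_child(dup)
        root.add_child(_pruned_species_tree(taxonomy.root, outside, gene_of))
    else:
        root = dup
    return GeneTree(root=root)


def simulate_gene_families(
    n: int,
    panel: SpeciesPanel | None = None,
    scenarios: Sequence[FamilyScenario] | None = None,
    seed: int = 0,
    min_length: int = 150,
    max_length: int = 300,
    isoform_prob: float = 0.5,
) -> SimulatedFamilies:
    """Evolve ``n`` gene families down the taxonomy with planted defects.

    Each family starts from a random ancestral protein and acquires
    species-specific point substitutions proportional to the species'
    depth. Every species contributes one representative protein and,
    with probability ``isoform_prob``, one extra (slightly more diverged)
    transcript isoform. The truth table marks which families must survive
    the full derivation.
    """
    panel = panel or default_panel()
    taxonomy = default_taxonomy()
    if scenarios is None:
        scenarios = standard_scenarios(n, seed=seed)
    if len(scenarios) != n:
        raise ValueError("scenarios must cover all n families")

    groups: list[OrthologGroup] = []
    trees: dict[str, GeneTree] = {}
    reference = ProteinCollection()
    late = ProteinCollection()
    truth_rows = []
    master = np.random.default_rng(seed)

    for scenario in scenarios:
        rng = np.random.default_rng(
            [seed, scenario.seed, master.integers(2**31)]
        )
        fam = scenario.family_id
        length = int(rng.integers(min_length, max_length + 1))
        ancestor = "".join(
            AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)
        )

        member_species = set(panel.one_to_one_species)
        outgroups = {"ciona_i"} | (
            {"ciona_s"} if rng.random() < 0.5 else set()
        )
        member_species |= outgroups
        # defects are disjoint by design: families failing an early filter
        # contribute no late-species ortholog, so they cannot interact with
        # the reciprocal-best-hit stage they never reach
        has_shark = scenario.defect not in (
            "missing_species", "no_outgroup", "rbh_decoy"
        )
        if scenario.defect == "missing_species":
            drop = sorted(panel.one_to_one_species)[
                rng.integers(len(panel.one_to_one_species))
            ]
            member_species.discard(drop)
        elif scenario.defect == "no_outgroup":
            member_species -= {"ciona_i", "ciona_s"}

        members: dict[str, list[str]] = {}
        proteins: dict[str, list[str]] = {}
        representative: dict[str, str] = {}
        gene_of: dict[str, str] = {}
        paralog_extra = 0.08 if "duplication" in scenario.defect else 0.0
        # pre-assign a duplicate-copy side per species for sequence divergence
        for sp in sorted(member_species) + (["shark"] if has_shark else []):
            gene = f"{fam}_{sp}"
            gene_of[sp] = gene
            depth = RELATIVE_DEPTH[sp]
            prob = min(0.49, scenario.rate * depth)
            rep_seq = _mutate(ancestor, prob, rng)
            if paralog_extra and rng.random() < 0.5:
                rep_seq = _mutate(rep_seq, paralog_extra, rng)
            rep_pid = f"{gene}_p1"
            rec = ProteinRecord(sp, gene, rep_pid, rep_seq)
            pids = [rep_pid]
            if sp == "shark":
                late.add(rec)
            else:
                reference.add(rec)
                if rng.random() < isoform_prob:
                    iso_pid = f"{gene}_p2"
                    iso_seq = _mutate(rep_seq, 0.05, rng)
                    reference.add(ProteinRecord(sp, gene, iso_pid, iso_seq))
                    pids.append(iso_pid)
            if sp != "shark":
                members.setdefault(sp, []).append(gene)
            proteins[gene] = pids
            representative[gene] = rep_pid

        groups.append(
            OrthologGroup(
                group_id=fam,
                members=members,
                proteins={g: p for g, p in proteins.items() if not g.endswith("_shark")},
                representative={
                    g: r for g, r in representative.items() if not g.endswith("_shark")
                },
            )
        )
        tree_species = set(member_species)
        if has_shark:
            tree_species.add("shark")
        trees[fam] = _family_tree(scenario, tree_species, gene_of, taxonomy, rng)
        truth_rows.append(
            (fam, scenario.defect, scenario.defect in SURVIVING_DEFECTS)
        )

    truth = pd.DataFrame(truth_rows, columns=["family_id", "defect", "survives"])
    return SimulatedFamilies(
        groups=groups,
        trees=trees,
        taxonomy=taxonomy,
        panel=panel,
        reference_proteins=reference,
        late_proteome=late,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Assemblies


@dataclass(frozen=True)
class AssemblyScenario:
    """Planted per-gene statuses for a synthetic assembly.

    ``planted`` maps gene id to ``("complete", None)``,
    ``("partial", coverage_fraction)`` with fraction in (0, 0.7), or
    ``("missing", None)``.
    """

    planted: Mapping[str, tuple[str, float | None]]
    n_decoys: int = 10
    decoy_length: int = 500
    gene_read_count: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for gid, (status, frac) in self.planted.items():
            if status not in ("complete", "partial", "missing"):
                raise ValueError(f"{gid}: unknown planted status {status!r}")
            if status == "partial":
                if frac is None or not (0.0 < frac < 0.7):
                    raise ValueError(
                        f"{gid}: partial coverage fraction must be in (0, 0.7)"
                    )


def back_translate(protein: str) -> str:
    return "".join(PREFERRED_CODON[aa] for aa in protein)


@dataclass
class SimulatedAssembly:
    contigs: list[tuple[str, str, str | None]]  # (contig_id, seq, locus)
    locus_map: dict[str, str]
    counts: dict[str, int]
    truth: pd.DataFrame  # gene_id, expected_status


def uniform_scenario(
    gene_ids: Sequence[str],
    fractions: tuple[float, float, float] = (1.0, 0.0, 0.0),
    partial_coverage: float = 0.5,
    n_decoys: int = 10,
    seed: int = 0,
) -> AssemblyScenario:
    """Scenario with given (complete, partial, missing) gene proportions."""
    fc, fp, fm = fractions
    if abs(fc + fp + fm - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(gene_ids)
    n_complete = int(round(fc * n))
    n_partial = int(round(fp * n))
    planted: dict[str, tuple[str, float | None]] = {}
    for i, gid in enumerate(gene_ids):
        if i < n_complete:
            planted[gid] = ("complete", None)
        elif i < n_complete + n_partial:
            planted[gid] = ("partial", partial_coverage)
        else:
            planted[gid] = ("missing", None)
    return AssemblyScenario(planted=planted, n_decoys=n_decoys, seed=seed)


def simulate_assembly(
    core_set: CoreGeneSet,
    scenario: AssemblyScenario,
    proteins: ProteinCollection,
    seed: int = 0,
) -> SimulatedAssembly:
    """Back-translate planted genes into contigs with decoys and counts.

    Complete genes get a contig carrying the full coding sequence of the
    least-diverged member (the first assessment species); partial genes a
    5' truncation at the stated coverage fraction. Decoys are random
    sequence with GC content matched (within 2 %) to the gene contigs.
    Gene contigs receive a high mapped-read count, decoys counts of 0-4.
    """
    rng = np.random.default_rng([seed, scenario.seed])
    species = core_set.panel.assessment_species[0]
    contigs: list[tuple[str, str, str | None]] = []
    locus_map: dict[str, str] = {}
    counts: dict[str, int] = {}
    truth_rows = []
    nt = "ACGT"

    def random_utr(lo: int = 30, hi: int = 60) -> str:
        k = int(rng.integers(lo, hi + 1))
        return "".join(nt[i] for i in rng.integers(4, size=k))

    for gene in core_set.genes:
        status, frac = scenario.planted.get(gene.group_id, ("missing", None))
        truth_rows.append((gene.group_id, status))
        if status == "missing":
            continue
        member = proteins.sequence(gene.representatives[species])
        if status == "partial":
            member = member[: max(1, int(len(member) * frac))]
        cds = back_translate(member)
        cid = f"contig_{gene.group_id}"
        seq = random_utr() + cds + "TAA" + random_utr()
        locus = f"locus_{gene.group_id}"
        contigs.append((cid, seq, locus))
        locus_map[cid] = locus
        counts[cid] = scenario.gene_read_count

    gc = 0.5
    if contigs:
        joined = "".join(seq for _, seq, _ in contigs)
        gc = (joined.count("G") + joined.count("C")) / len(joined)
    for i in range(scenario.n_decoys):
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = "".join(
            nt[j]
            for j in rng.choice(4, size=scenario.decoy_length, p=probs)
        )
        cid = f"decoy_{i:03d}"
        contigs.append((cid, seq, None))
        locus_map[cid] = cid
        counts[cid] = int(rng.integers(0, 5))

    truth = pd.DataFrame(truth_rows, columns=["gene_id", "expected_status"])
    return SimulatedAssembly(
        contigs=contigs, locus_map=locus_map, counts=counts, truth=truth
    )


# ---------------------------------------------------------------------------
# Read-pair mappings


def simulate_pair_mappings(
    contigs: Sequence[tuple[str, str]] | Sequence[tuple[str, int]],
    fragment_mean: float = 360.0,
    fragment_sd: float = 80.0,
    n_pairs: int = 10_000,
    mate_len: int = 50,
    seed: int = 0,
    second_mean: float | None = None,
) -> tuple[list[PairMapping], dict]:
    """Draw properly-paired mappings with truncated-normal fragment spans.

    ``contigs`` is a list of ``(contig_id, sequence)`` or
    ``(contig_id, length)``. Fragment spans are drawn from a normal
    truncated to [2 * mate_len, contig length]; with ``second_mean`` set,
    an equal mixture of two such normals (a bimodal library). Returns the
    mappings plus the true parameters used.
    """
    lengths = {
        cid: (len(x) if isinstance(x, str) else int(x)) for cid, x in contigs
    }
    lo = 2 * mate_len
    eligible = [cid for cid, ln in lengths.items() if ln >= max(lo, 1)]
    if not eligible:
        raise ValueError("no contig long enough for the requested geometry")
    if fragment_mean >= min(lengths[c] for c in eligible):
        raise ValueError("fragment_mean must be below the shortest usable contig")
    rng = np.random.default_rng(seed)
    means = [fragment_mean] if second_mean is None else [fragment_mean, second_mean]
    out: list[PairMapping] = []
    for i in range(n_pairs):
        cid = eligible[int(rng.integers(len(eligible)))]
        hi = lengths[cid]
        mu = means[int(rng.integers(len(means)))]
        if fragment_sd == 0:
            span = mu
        else:
            span = rng.normal(mu, fragment_sd)
            while not (lo <= span <= hi):
                span = rng.normal(mu, fragment_sd)
        span = int(round(span))
        span = min(max(span, lo), hi)
        pos1 = int(rng.integers(0, hi - span + 1))
        pos2 = pos1 + span - mate_len
        out.append(
            PairMapping(
                fragment_id=f"frag{i:06d}",
                contig_id=cid,
                pos1=pos1,
                pos2=pos2,
                mate_len=mate_len,
                properly_paired=True,
            )
        )
    params = {
        "fragment_mean": fragment_mean,
        "fragment_sd": fragment_sd,
        "second_mean": second_mean,
        "n_pairs": n_pairs,
        "mate_len": mate_len,
    }
    return out, params
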