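"""File formats consumed and produced by the toolkit.

* Proteomes: FASTA with headers ``species|gene_id|protein_id``.
* Ortholog groups: TSV with columns
  ``group_id, species, gene_id, protein_id, is_representative``.
* Gene trees: NHX-annotated Newick — node comments carry ``S=<species>``
  on leaves and ``D=Y/N`` plus ``T=<taxon>`` on internal nodes.
* Taxonomy: plain Newick with named internal nodes (clade labels).
* Read-pair mappings: SAM/BAM via pysam (flag 0x2 = properly paired) or a
  TSV fallback with columns
  ``fragment_id, contig_id, pos1, pos2, mate_len, proper``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# Proteins


@dataclass(frozen=True)
class ProteinRecord:
    species: str
    gene_id: str
    protein_id: str
    sequence: str


class ProteinCollection:
    """Proteins indexed by protein id, with species/gene lookups."""

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._by_protein: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: ProteinRecord) -> None:
        if rec.protein_id in self._by_protein:
            raise ValueError(f"duplicate protein id {rec.protein_id!r}")
        self._by_protein[rec.protein_id] = rec

    def __len__(self) -> int:
        return len(self._by_protein)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._by_protein.values())

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_protein

    def get(self, protein_id: str) -> ProteinRecord:
        try:
            return self._by_protein[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def sequence(self, protein_id: str) -> str:
        return self.get(protein_id).sequence

    def by_species(self, species: str) -> list[ProteinRecord]:
        return [r for r in self if r.species == species]

    def species(self) -> set[str]:
        return {r.species for r in self}

    def items(self) -> Iterable[tuple[str, str]]:
        """(protein_id, sequence) pairs — the shape best-hit search wants."""
        return ((r.protein_id, r.sequence) for r in self)

    def merged(self, other: "ProteinCollection") -> "ProteinCollection":
        out = ProteinCollection(self)
        for rec in other:
            out.add(rec)
        return out


def read_proteome(path: str | Path) -> ProteinCollection:
    coll = ProteinCollection()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"proteome header {rec.id!r} is not 'species|gene_id|protein_id'"
            )
        coll.add(ProteinRecord(parts[0], parts[1], parts[2], str(rec.seq).upper()))
    return coll


def write_proteome(coll: ProteinCollection, path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.species}|{r.gene_id}|{r.protein_id}",
            description="",
        )
        for r in coll
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Contig FASTA (optional "locus=" header token)


def read_contigs(path: str | Path) -> list[tuple[str, str, str | None]]:
    """(contig_id, sequence, locus_or_None) triples from nucleotide FASTA."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        locus = None
        m = re.search(r"\blocus=(\S+)", rec.description)
        if m:
            locus = m.group(1)
        out.append((rec.id, str(rec.seq).upper(), locus))
    return out


def write_contigs(
    contigs: Iterable[tuple[str, str, str | None]], path: str | Path
) -> None:
    records = []
    for cid, seq, locus in contigs:
        rec = SeqRecord(Seq(seq), id=cid, description=f"locus={locus}" if locus else "")
        records.append(rec)
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Ortholog-group TSV

GROUP_COLUMNS = ["group_id", "species", "gene_id", "protein_id", "is_representative"]


def read_group_table(path: str | Path):
    """Parse the group membership TSV into OrthologGroup objects."""
    from corevert.ortho_core import OrthologGroup

    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GROUP_COLUMNS:
            raise ValueError(f"unexpected group-table header: {header}")
        for line in fh:
            gid, species, gene, protein, is_rep = line.rstrip("\n").split("\t")
            if gid not in rows:
                rows[gid] = {"members": {}, "proteins": {}, "representative": {}}
                order.append(gid)
            g = rows[gid]
            g["members"].setdefault(species, [])
            if gene not in g["members"][species]:
                g["members"][species].append(gene)
            g["proteins"].setdefault(gene, []).append(protein)
            if is_rep == "1":
                g["representative"][gene] = protein
    return [
        OrthologGroup(
            group_id=gid,
            members=rows[gid]["members"],
            proteins=rows[gid]["proteins"],
            representative=rows[gid]["representative"],
        )
        for gid in order
    ]


def write_group_table(groups, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GROUP_COLUMNS) + "\n")
        for g in groups:
            for species, genes in g.members.items():
                for gene in genes:
                    for protein in g.proteins[gene]:
                        rep = "1" if g.representative.get(gene) == protein else "0"
                        fh.write(f"{g.group_id}\t{species}\t{gene}\t{protein}\t{rep}\n")


# ---------------------------------------------------------------------------
# NHX gene trees

_NHX_RE = re.compile(r"&&NHX:?(.*)", re.DOTALL)


def _parse_nhx_comment(comment: str) -> dict[str, str]:
    m = _NHX_RE.search(comment)
    if not m:
        return {}
    out = {}
    for item in m.group(1).split(":"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gene_tree(path: str | Path):
    """Read one NHX gene tree file into a GeneTree."""
    from corevert.ortho_core import GeneTree

    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        extract_comment_metadata=False,
    )
    return GeneTree.from_dendropy(tree, _parse_nhx_comment)


def write_gene_tree(gene_tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(gene_tree.to_nhx() + "\n")


# ---------------------------------------------------------------------------
# Taxonomy


def read_taxonomy(path: str | Path):
    from corevert.ortho_core import Taxonomy

    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
    )
    return Taxonomy.from_dendropy(tree)


# ---------------------------------------------------------------------------
# Species panels and core sets (JSON)


def read_panel(path: str | Path):
    import json

    from corevert.ortho_core import SpeciesPanel

    with open(path) as fh:
        d = json.load(fh)
    return SpeciesPanel(
        panel_id=d["panel_id"],
        core_species=frozenset(d["core_species"]),
        extension_species=frozenset(d.get("extension_species", [])),
        outgroup_species=frozenset(d.get("outgroup_species", [])),
        late_species=d.get("late_species"),
        assessment_species=tuple(d.get("assessment_species", [])),
    )


def write_panel(panel, path: str | Path) -> None:
    import json

    d = {
        "panel_id": panel.panel_id,
        "core_species": sorted(panel.core_species),
        "extension_species": sorted(panel.extension_species),
        "outgroup_species": sorted(panel.outgroup_species),
        "late_species": panel.late_species,
        "assessment_species": list(panel.assessment_species),
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def write_core_set(core_set, path: str | Path) -> None:
    import json

    d = {
        "set_id": core_set.set_id,
        "panel": {
            "panel_id": core_set.panel.panel_id,
            "core_species": sorted(core_set.panel.core_species),
            "extension_species": sorted(core_set.panel.extension_species),
            "outgroup_species": sorted(core_set.panel.outgroup_species),
            "late_species": core_set.panel.late_species,
            "assessment_species": list(core_set.panel.assessment_species),
        },
        "derivation_log": core_set.derivation_log,
        "genes": [
            {
                "group_id": g.group_id,
                "representatives": g.representatives,
                "transcripts": g.transcripts,
            }
            for g in core_set.genes
        ],
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def read_core_set(path: str | Path):
    import json

    from corevert.ortho_core import CoreGene, CoreGeneSet, SpeciesPanel

    with open(path) as fh:
        d = json.load(fh)
    p = d["panel"]
    panel = SpeciesPanel(
        panel_id=p["panel_id"],
        core_species=frozenset(p["core_species"]),
        extension_species=frozenset(p.get("extension_species", [])),
        outgroup_species=frozenset(p.get("outgroup_species", [])),
        late_species=p.get("late_species"),
        assessment_species=tuple(p.get("assessment_species", [])),
    )
    genes = [
        CoreGene(
            group_id=g["group_id"],
            representatives=g["representatives"],
            transcripts=g["transcripts"],
        )
        for g in d["genes"]
    ]
    return CoreGeneSet(
        set_id=d["set_id"],
        panel=panel,
        genes=genes,
        derivation_log=[tuple(x) for x in d["derivation_log"]],
    )


# ---------------------------------------------------------------------------
# Tabular helpers


def read_counts_tsv(path: str | Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig_id\t"):
                continue
            cid, n = line.split("\t")
            counts[cid] = int(n)
    return counts


def write_counts_tsv(counts: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tcount\n")
        for cid, n in counts.items():
            fh.write(f"{cid}\t{n}\n")


def read_locus_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("contig_id\t"):
                continue
            cid, locus = line.split("\t")
            out[cid] = locus
    return out


def write_locus_map(locus_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tsubcomponent_id\n")
        for cid, locus in locus_map.items():
            fh.write(f"{cid}\t{locus}\n")


# ---------------------------------------------------------------------------
# Pair mappings


@dataclass(frozen=True)
class PairMapping:
    """A mapped read pair on one contig (0-based leftmost positions)."""

    fragment_id: str
    contig_id: str
    pos1: int
    pos2: int
    mate_len: int
    properly_paired: bool
    orientation: str = "FR"


def read_pair_mappings_tsv(path: str | Path) -> list[PairMapping]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("fragment_id\t"):
                continue
            fid, cid, p1, p2, mlen, proper = line.split("\t")[:6]
            out.append(
                PairMapping(fid, cid, int(p1), int(p2), int(mlen), proper in ("1", "True"))
            )
    return out


def write_pair_mappings_tsv(mappings: Iterable[PairMapping], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_id\tcontig_id\tpos1\tpos2\tmate_len\tproper\n")
        for m in mappings:
            fh.write(
                f"{m.fragment_id}\t{m.contig_id}\t{m.pos1}\t{m.pos2}\t"
                f"{m.mate_len}\t{1 if m.properly_paired else 0}\n"
            )


def read_pair_mappings_sam(path: str | Path) -> list[PairMapping]:
    """Collect mapped pairs from SAM/BAM; flag 0x2 marks properly paired."""
    import pysam

    first_mates: dict[str, "pysam.AlignedSegment"] = {}
    out: list[PairMapping] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired:
                continue
            if read.query_name in first_mates:
                mate = first_mates.pop(read.query_name)
                if mate.reference_name != read.reference_name:
                    continue
                out.append(
                    PairMapping(
                        fragment_id=read.query_name,
                        contig_id=read.reference_name,
                        pos1=mate.reference_start,
                        pos2=read.reference_start,
                        mate_len=read.query_length or mate.query_length or 0,
                        properly_paired=read.is_proper_pair,
                    )
                )
            else:
                first_mates[read.query_name] = read
    return out


def read_pair_mappings(path: str | Path) -> list[PairMapping]:
    p = str(path)
    if p.endswith((".sam", ".bam", ".cram")):
        return read_pair_mappings_sam(p)
    return read_pair_mappings_tsv(p)
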