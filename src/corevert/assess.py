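"""Completeness assessment of an assembly against a core gene set.

Candidate proteins are taken from all six reading frames of the contigs as
maximal stop-to-stop open reading frames (transcriptome mode; spliced gene
prediction on genomes is out of scope). Each family's profile HMM is
searched against the candidates, and the family is classified:

* *complete* — some hit reaches the family's completeness bit-score cutoff
  and covers more than ``coverage_threshold`` (default 70 %) of the
  profile's match states;
* *partial* — otherwise, some hit reaches the detection cutoff;
* *missing* — neither.

The completeness score of an assembly is the percentage of families
classified complete; the partial-inclusive score additionally counts
partial families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from corevert.io import read_contigs
from corevert.profiles import (
    AssessmentDataset,
    CutoffEntry,
    HmmerEngine,
    ProfileModel,
    SearchHit,
)

COMPLETE = "complete"
PARTIAL = "partial"
MISSING = "missing"


class ClassificationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Candidate proteins


@dataclass(frozen=True)
class CandidateProtein:
    """A stop-free translation of one maximal ORF, with source coordinates.

    ``nt_start``/``nt_end`` are 0-based half-open on the forward strand of
    the source contig, so the encoded nucleotides can be reconstructed
    exactly regardless of frame sign.
    """

    candidate_id: str
    contig_id: str
    frame: int  # +1, +2, +3, -1, -2, -3
    nt_start: int
    nt_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.nt_end - self.nt_start != 3 * len(self.sequence):
            raise ValueError("ORF coordinates inconsistent with protein length")
        if "*" in self.sequence:
            raise ValueError("candidate protein contains a stop")


def _orfs_in_frame(translation: str, min_len: int) -> list[tuple[int, int, str]]:
    """(aa_start, aa_end, peptide) of stop-free segments of a translation."""
    out = []
    start = 0
    for i, aa in enumerate(translation + "*"):
        if aa == "*":
            if i - start >= min_len:
                out.append((start, i, translation[start:i]))
            start = i + 1
    return out


def extract_candidate_proteins(
    contigs: Sequence[tuple[str, str]] | str | Path,
    min_len: int = 30,
) -> list[CandidateProtein]:
    """Six-frame stop-to-stop ORFs of length >= ``min_len`` aa.

    ``contigs`` is a list of ``(contig_id, sequence)`` or a nucleotide
    FASTA path. Ambiguity codes translate to X and do not break an ORF.
    """
    if isinstance(contigs, (str, Path)):
        contigs = [(cid, seq) for cid, seq, _ in read_contigs(contigs)]
    out: list[CandidateProtein] = []
    for contig_id, seq in contigs:
        seq = seq.upper()
        n = len(seq)
        rc = str(Seq(seq).reverse_complement())
        for strand, src in ((1, seq), (-1, rc)):
            for offset in range(3):
                usable = (len(src) - offset) // 3 * 3
                if usable < 3:
                    continue
                translation = str(Seq(src[offset : offset + usable]).translate())
                frame = strand * (offset + 1)
                for aa_start, aa_end, pep in _orfs_in_frame(translation, min_len):
                    if strand == 1:
                        nt_start = offset + 3 * aa_start
                        nt_end = offset + 3 * aa_end
                    else:
                        # coordinates on the forward strand
                        nt_end = n - (offset + 3 * aa_start)
                        nt_start = n - (offset + 3 * aa_end)
                    out.append(
                        CandidateProtein(
                            candidate_id=f"{contig_id}|f{frame:+d}|{nt_start}",
                            contig_id=contig_id,
                            frame=frame,
                            nt_start=nt_start,
                            nt_end=nt_end,
                            sequence=pep,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# Search and classification

#: A ProfileHit is a SearchHit whose target is a CandidateProtein id.
ProfileHit = SearchHit


def search_profiles(
    profiles: Mapping[str, ProfileModel],
    candidates: Sequence[CandidateProtein],
    engine: HmmerEngine | None = None,
) -> list[ProfileHit]:
    """Search every family profile against the candidate proteins."""
    engine = engine or HmmerEngine()
    targets = [(c.candidate_id, c.sequence) for c in candidates]
    hits: list[ProfileHit] = []
    for profile in profiles.values():
        hits.extend(engine.search(profile, targets))
    return hits


@dataclass(frozen=True)
class GeneStatus:
    gene_id: str
    status: str  # complete | partial | missing
    n_complete_copies: int = 0
    best_score: float | None = None
    best_coverage: float | None = None

    def __post_init__(self) -> None:
        if (self.status == COMPLETE) != (self.n_complete_copies >= 1):
            raise ValueError("status/complete-copy count inconsistent")


def classify_gene(
    gene_id: str,
    hits: Sequence[ProfileHit],
    cutoffs: CutoffEntry,
    coverage_threshold: float = 0.70,
    locus_of: Mapping[str, str] | None = None,
) -> GeneStatus:
    """Classify one family from its profile hits.

    A hit qualifies as complete when its bit score is at or above the
    completeness cutoff *and* its merged match-state coverage is strictly
    greater than ``coverage_threshold``. ``locus_of`` maps a candidate id
    to its locus (subcomponent); distinct loci among complete-qualifying
    hits give the copy count. Default locus is the candidate id itself.
    """
    if not (0.0 < coverage_threshold < 1.0):
        raise ClassificationError("coverage_threshold must be in (0, 1)")
    if cutoffs is None:
        raise ClassificationError(f"no cutoff entry for gene {gene_id}")
    best_score: float | None = None
    best_cov: float | None = None
    complete_loci: set[str] = set()
    any_detected = False
    for hit in hits:
        if best_score is None or hit.score > best_score:
            best_score, best_cov = hit.score, hit.coverage
        if hit.score >= cutoffs.detection_cutoff:
            any_detected = True
        if (
            hit.score >= cutoffs.completeness_cutoff
            and hit.coverage > coverage_threshold
        ):
            locus = (locus_of or {}).get(hit.target_id, hit.target_id)
            complete_loci.add(locus)
    if complete_loci:
        status = COMPLETE
    elif any_detected:
        status = PARTIAL
    else:
        status = MISSING
    return GeneStatus(
        gene_id=gene_id,
        status=status,
        n_complete_copies=len(complete_loci),
        best_score=best_score,
        best_coverage=best_cov,
    )


@dataclass
class CompletenessReport:
    set_id: str
    statuses: dict[str, GeneStatus]

    @property
    def n_genes(self) -> int:
        return len(self.statuses)

    def count(self, status: str) -> int:
        return sum(1 for s in self.statuses.values() if s.status == status)

    @property
    def completeness_score(self) -> float:
        return 100.0 * self.count(COMPLETE) / self.n_genes if self.n_genes else 0.0

    @property
    def partial_inclusive_score(self) -> float:
        if not self.n_genes:
            return 0.0
        return 100.0 * (self.count(COMPLETE) + self.count(PARTIAL)) / self.n_genes

    def to_dict(self) -> dict:
        return {
            "set_id": self.set_id,
            "n_genes": self.n_genes,
            "complete": self.count(COMPLETE),
            "partial": self.count(PARTIAL),
            "missing": self.count(MISSING),
            "completeness_score": self.completeness_score,
            "partial_inclusive_score": self.partial_inclusive_score,
            "genes": {
                gid: {
                    "status": s.status,
                    "n_complete_copies": s.n_complete_copies,
                    "best_score": s.best_score,
                    "best_coverage": s.best_coverage,
                }
                for gid, s in self.statuses.items()
            },
        }

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tstatus\tbest_score\tbest_coverage\tcopies\n")
            for gid, s in self.statuses.items():
                score = "" if s.best_score is None else f"{s.best_score:.2f}"
                cov = "" if s.best_coverage is None else f"{s.best_coverage:.4f}"
                fh.write(f"{gid}\t{s.status}\t{score}\t{cov}\t{s.n_complete_copies}\n")


def assess_assembly(
    contigs: Sequence[tuple[str, str]] | str | Path,
    dataset: AssessmentDataset,
    coverage_threshold: float = 0.70,
    min_orf: int = 30,
    locus_map: Mapping[str, str] | None = None,
    engine: HmmerEngine | None = None,
) -> CompletenessReport:
    """Extract candidates, search all profiles, classify every family."""
    engine = engine or HmmerEngine()
    candidates = extract_candidate_proteins(contigs, min_len=min_orf)
    hits = search_profiles(dataset.profiles, candidates, engine)
    by_gene: dict[str, list[ProfileHit]] = {gid: [] for gid in dataset.profiles}
    for hit in hits:
        by_gene[hit.gene_id].append(hit)
    # locus defaults to the contig id when no subcomponent map is given
    candidate_locus = {
        c.candidate_id: (locus_map or {}).get(c.contig_id, c.contig_id)
        for c in candidates
    }
    statuses = {
        gid: classify_gene(
            gid,
            by_gene[gid],
            dataset.cutoffs.get(gid),
            coverage_threshold=coverage_threshold,
            locus_of=candidate_locus,
        )
        for gid in dataset.profiles
    }
    return CompletenessReport(set_id=dataset.set_id, statuses=statuses)
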