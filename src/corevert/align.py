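"""Pairwise scoring contracts used for best-hit searches and clustering.

The reciprocal-best-hit and false-positive audits rank candidate pairs by a
pluggable protein scorer; the built-in default is Smith-Waterman local
alignment under BLOSUM62 with gap open 11 / extend 1, ranked by raw score.
Nucleotide identity for assembly deduplication/clustering is computed by
local alignment over the shared region, on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Protocol, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import reverse_complement


class PairwiseScorer(Protocol):
    """Scoring contract: higher is better; symmetric in the roles of a, b."""

    def score(self, a: str, b: str) -> float: ...


@lru_cache(maxsize=1)
def _blosum62() -> substitution_matrices.Array:
    return substitution_matrices.load("BLOSUM62")


class Blosum62LocalScorer:
    """Smith-Waterman local protein alignment, BLOSUM62, gap 11/1."""

    def __init__(self, open_gap: float = -11.0, extend_gap: float = -1.0) -> None:
        self._aligner = PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = _blosum62()
        self._aligner.open_gap_score = open_gap
        self._aligner.extend_gap_score = extend_gap

    def score(self, a: str, b: str) -> float:
        if not a or not b:
            return float("-inf")
        return float(self._aligner.score(a.upper(), b.upper()))


def best_hit(
    query: str,
    candidates: Iterable[tuple[str, str]],
    scorer: PairwiseScorer,
) -> tuple[str | None, float, bool]:
    """Best-scoring candidate for ``query``.

    Returns ``(candidate_id, score, tied)``. On an exact score tie for the
    top rank the id is ``None`` and ``tied`` is True (the conservative
    drop-on-tie rule: an ambiguous best hit assigns nothing).
    """
    best_id: str | None = None
    best_score = float("-inf")
    tied = False
    for cid, seq in candidates:
        s = scorer.score(query, seq)
        if s > best_score:
            best_id, best_score, tied = cid, s, False
        elif s == best_score and best_id is not None and cid != best_id:
            tied = True
    if tied:
        return None, best_score, True
    return best_id, best_score, False


@dataclass(frozen=True)
class OverlapIdentity:
    """Identity of the best local alignment between two nucleotide sequences."""

    identity: float  # matches / alignment columns within the aligned region
    overlap: int  # alignment columns of the aligned region
    strand: int  # +1 or -1 (second sequence reverse-complemented)


@lru_cache(maxsize=1)
def _nt_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _local_identity(a: str, b: str) -> tuple[float, int]:
    aligner = _nt_aligner()
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return 0.0, 0
    counts = aln.counts()
    columns = counts.aligned + counts.internal_gaps
    if columns == 0:
        return 0.0, 0
    return counts.identities / columns, columns


def overlap_identity(a: str, b: str, both_strands: bool = True) -> OverlapIdentity:
    """Best-strand local-alignment identity between two contigs.

    Identity is matches / alignment columns restricted to the locally
    aligned region (terminal overhangs do not count against identity);
    ``overlap`` is the column count of that region.
    """
    a, b = a.upper(), b.upper()
    ident, cols = _local_identity(a, b)
    strand = 1
    if both_strands:
        ident_rc, cols_rc = _local_identity(a, reverse_complement(b))
        if (ident_rc * cols_rc) > (ident * cols):
            ident, cols, strand = ident_rc, cols_rc, -1
    return OverlapIdentity(identity=ident, overlap=cols, strand=strand)


def shares_kmer(a: str, b: str, k: int) -> bool:
    """Cheap k-mer prefilter used before computing full overlap identity."""
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    rc = reverse_complement(b)
    return any(
        b[i : i + k] in kmers or rc[i : i + k] in kmers
        for i in range(len(b) - k + 1)
    )


def containment_identity(shorter: str, longer: str, both_strands: bool = True) -> float:
    """Identity of ``shorter`` against its best match inside ``longer``.

    Used by the deduplication stage, where a sequence is redundant when
    nearly all of it is contained in a longer retained sequence (matches
    over the length of the shorter sequence).
    """
    import edlib

    shorter, longer = shorter.upper(), longer.upper()
    if not shorter or not longer:
        return 0.0
    res = edlib.align(shorter, longer, mode="HW", task="distance")
    dist = res["editDistance"]
    if both_strands:
        res_rc = edlib.align(
            reverse_complement(shorter), longer, mode="HW", task="distance"
        )
        if res_rc["editDistance"] >= 0 and (
            dist < 0 or res_rc["editDistance"] < dist
        ):
            dist = res_rc["editDistance"]
    if dist < 0:
        return 0.0
    return max(0.0, 1.0 - dist / len(shorter))
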