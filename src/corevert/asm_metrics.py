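"""Assembly post-processing and evaluation metrics.

Covers the statistics used to compare de novo transcriptome assemblies:
N50 (including the per-locus variant computed over one representative
contig per subcomponent), exclusion of contigs with too few mapped reads,
the properly-paired mapping rate, insert/fragment-size inference from
truncated mates, and the two-stage integration of multiple assemblies
(near-identity deduplication followed by overlap clustering) with
single-linkage reassignment of locus labels.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from corevert.align import containment_identity, overlap_identity, shares_kmer
from corevert.io import PairMapping


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    subcomponent_id: str | None = None
    mapped_read_count: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id}: empty sequence")
        if self.mapped_read_count is not None and self.mapped_read_count < 0:
            raise ValueError(f"contig {self.contig_id}: negative read count")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    contigs: list[Contig]
    label: str = "assembly"

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.label}: duplicate contig ids")

    def __len__(self) -> int:
        return len(self.contigs)

    def lengths(self) -> list[int]:
        return [c.length for c in self.contigs]

    def subcomponents(self) -> dict[str, list[Contig]]:
        out: dict[str, list[Contig]] = {}
        for c in self.contigs:
            out.setdefault(c.subcomponent_id or c.contig_id, []).append(c)
        return out


@dataclass
class SizeDistribution:
    """Histogram of fragment/insert lengths with its count-weighted mean."""

    histogram: Counter  # length (bp) -> count
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return sum(self.histogram.values())

    @property
    def mean(self) -> float:
        if not self.n:
            return float("nan")
        return sum(k * v for k, v in self.histogram.items()) / self.n

    @property
    def sd(self) -> float:
        if self.n < 2:
            return float("nan")
        mu = self.mean
        var = sum(v * (k - mu) ** 2 for k, v in self.histogram.items()) / (self.n - 1)
        return math.sqrt(var)

    def shifted(self, delta: int) -> "SizeDistribution":
        return SizeDistribution(
            Counter({k + delta: v for k, v in self.histogram.items()}),
            n_skipped=self.n_skipped,
        )


# ---------------------------------------------------------------------------
# N50


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that sequences of length >= L hold half the bases."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")


def subcomponent_n50(assembly: Assembly) -> int:
    """N50 over the longest contig of each subcomponent (one per locus)."""
    reps = [max(cs, key=lambda c: c.length) for cs in assembly.subcomponents().values()]
    return n50([c.length for c in reps])


# ---------------------------------------------------------------------------
# Read-count filtering


def filter_by_mapping_count(assembly: Assembly, min_count: int = 5) -> Assembly:
    """Drop contigs with fewer than ``min_count`` mapped reads.

    Subcomponents whose contigs are all dropped disappear with them.
    """
    kept = []
    for c in assembly.contigs:
        if c.mapped_read_count is None:
            raise ValueError(f"contig {c.contig_id} has no mapped read count")
        if c.mapped_read_count >= min_count:
            kept.append(c)
    return Assembly(contigs=kept, label=assembly.label)


# ---------------------------------------------------------------------------
# Pair mappings


def properly_paired_rate(mappings: Sequence[PairMapping]) -> float:
    if not mappings:
        raise ValueError("properly-paired rate of zero pairs is undefined")
    return sum(1 for m in mappings if m.properly_paired) / len(mappings)


def truncate_mates(
    pairs: Iterable[tuple[str, str]], n: int = 50
) -> list[tuple[str, str]]:
    """Keep only the first ``n`` bases of each mate (shorter mates unchanged).

    Truncation before mapping prevents long mates of short-insert pairs
    from overlapping each other, which would bias the inferred span.
    """
    if n < 1:
        raise ValueError("truncation length must be >= 1")
    return [(m1[:n], m2[:n]) for m1, m2 in pairs]


def estimate_insert_sizes(
    mappings: Sequence[PairMapping],
    adapter_total: int = 0,
) -> tuple[SizeDistribution, SizeDistribution]:
    """Infer insert and fragment size distributions from mapped pairs.

    The insert length of a pair is the outer span: from the leftmost base
    of the leftmost mate to the rightmost base of the rightmost mate, the
    mate length being the (truncated) length used in mapping. Pairs not
    properly paired are skipped and counted in ``n_skipped``. The fragment
    distribution is the insert distribution shifted by ``adapter_total``
    (fragment size = insert size + ligated adapter lengths).
    """
    hist: Counter = Counter()
    skipped = 0
    for m in mappings:
        if not m.properly_paired:
            skipped += 1
            continue
        left = min(m.pos1, m.pos2)
        right = max(m.pos1, m.pos2)
        hist[right + m.mate_len - left] += 1
    insert = SizeDistribution(hist, n_skipped=skipped)
    return insert, insert.shifted(adapter_total)


# ---------------------------------------------------------------------------
# Merge and cluster


@dataclass
class ClusterMap:
    """Origin contig id -> cluster id, plus dedup survivorship."""

    cluster_of: dict[str, str] = field(default_factory=dict)
    survivor_of: dict[str, str] = field(default_factory=dict)  # dropped -> retained

    def n_clusters(self) -> int:
        return len(set(self.cluster_of.values()))

    def members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cid, cluster in self.cluster_of.items():
            out.setdefault(cluster, set()).add(cid)
        return out


def merge_and_cluster(
    assemblies: Sequence[Assembly],
    dedup_identity: float = 0.99,
    dedup_word: int = 8,
    cluster_identity: float = 0.95,
    min_overlap: int = 50,
    label: str = "merged",
) -> tuple[Assembly, ClusterMap]:
    """Integrate assemblies: near-identity dedup, then overlap clustering.

    Stage 1 (cd-hit-est-like): scanning contigs longest-first, a contig is
    dropped when at least ``dedup_identity`` of it matches a longer
    retained contig (``dedup_word`` is the k-mer prefilter word size).
    Stage 2 (gicl-like): surviving contigs sharing an alignment of at
    least ``cluster_identity`` identity over at least ``min_overlap``
    columns join the same cluster (connected components, either strand).
    Contig ids are prefixed with their assembly label when labels collide.
    """
    for name, v in (("dedup_identity", dedup_identity),
                    ("cluster_identity", cluster_identity)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {v}")

    pool: list[Contig] = []
    seen_ids: set[str] = set()
    for asm in assemblies:
        for c in asm.contigs:
            cid = c.contig_id
            if cid in seen_ids:
                cid = f"{asm.label}.{cid}"
            if cid in seen_ids:
                raise ValueError(f"cannot disambiguate contig id {c.contig_id!r}")
            seen_ids.add(cid)
            pool.append(replace(c, contig_id=cid))

    # stage 1: greedy longest-first dedup
    cmap = ClusterMap()
    retained: list[Contig] = []
    for c in sorted(pool, key=lambda x: (-x.length, x.contig_id)):
        survivor = None
        for r in retained:
            if not shares_kmer(r.sequence, c.sequence, dedup_word):
                continue
            if containment_identity(c.sequence, r.sequence) >= dedup_identity:
                survivor = r
                break
        if survivor is None:
            retained.append(c)
        else:
            cmap.survivor_of[c.contig_id] = survivor.contig_id

    # stage 2: overlap clustering of survivors (union-find)
    parent = {c.contig_id: c.contig_id for c in retained}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i, a in enumerate(retained):
        for b in retained[i + 1 :]:
            if find(a.contig_id) == find(b.contig_id):
                continue
            if not shares_kmer(a.sequence, b.sequence, dedup_word):
                continue
            ov = overlap_identity(a.sequence, b.sequence)
            if ov.overlap >= min_overlap and ov.identity >= cluster_identity:
                union(a.contig_id, b.contig_id)

    roots = sorted({find(c.contig_id) for c in retained})
    cluster_name = {root: f"cluster{idx}" for idx, root in enumerate(roots)}
    for c in retained:
        cmap.cluster_of[c.contig_id] = cluster_name[find(c.contig_id)]
    for dropped, survivor in cmap.survivor_of.items():
        cmap.cluster_of[dropped] = cmap.cluster_of[survivor]

    merged = Assembly(contigs=retained, label=label)
    return merged, cmap


def reassign_loci(assembly: Assembly, cmap: ClusterMap) -> Assembly:
    """Single-linkage reassignment of subcomponent (locus) labels.

    Contigs sharing a cluster OR an original locus end up in the same
    subcomponent (transitive closure over both relations).
    """
    ids = [c.contig_id for c in assembly.contigs]
    parent = {cid: cid for cid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_key: dict[tuple[str, str], list[str]] = {}
    for c in assembly.contigs:
        if c.contig_id in cmap.cluster_of:
            by_key.setdefault(("cluster", cmap.cluster_of[c.contig_id]), []).append(
                c.contig_id
            )
        if c.subcomponent_id is not None:
            by_key.setdefault(("locus", c.subcomponent_id), []).append(c.contig_id)
    for members in by_key.values():
        for other in members[1:]:
            union(members[0], other)

    groups: dict[str, list[str]] = {}
    for cid in ids:
        groups.setdefault(find(cid), []).append(cid)
    new_locus: dict[str, str] = {}
    for idx, root in enumerate(sorted(groups)):
        for cid in groups[root]:
            new_locus[cid] = f"locus{idx}"
    return Assembly(
        contigs=[replace(c, subcomponent_id=new_locus[c.contig_id])
                 for c in assembly.contigs],
        label=assembly.label,
    )
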