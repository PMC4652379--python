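"""Per-family alignments, profile HMMs, and detection/completeness cutoffs.

Each core gene gets a multiple protein alignment of its assessment-species
members, a profile HMM built from that alignment, and two bit-score
cutoffs:

* the *detection* cutoff — the minimum full-sequence bit score among the
  species' representative proteins, below which a hit is not considered an
  ortholog candidate at all;
* the *completeness* cutoff — per species, the maximum bit score over
  *all* of that species' transcript isoforms (not just the representative),
  aggregated across species by the minimum of those per-species maxima.
  The within-species maximum acknowledges that any isoform of a true
  ortholog is a legitimate full-length match; the cross-species minimum
  guarantees that every known ortholog clears its own family's cutoff.

A length criterion (mean +/- k standard deviations of member lengths)
accompanies the scores for BUSCO-style assessment. Alignment, profile
building, searching, and consensus emission are pluggable engine
contracts; the built-in engines wrap MAFFT and HMMER (via pyhmmer).
"""

from __future__ import annotations

import json
import shutil
import statistics
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import pyhmmer
from pyhmmer.easel import Alphabet, DigitalSequenceBlock, TextMSA, TextSequence

from corevert.io import ProteinCollection
from corevert.ortho_core import CoreGene, CoreGeneSet


class ProfileBuildError(RuntimeError):
    pass


class CutoffError(RuntimeError):
    """A species contributed no scoring sequence; the cutoff is undefined."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class MultipleAlignment:
    gene_id: str
    rows: list[tuple[str, str, str]]  # (species, protein_id, aligned sequence)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"{self.gene_id}: alignment needs >= 2 rows")
        lengths = {len(seq) for _, _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: ragged alignment rows {lengths}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][2])


@dataclass
class ProfileModel:
    """A profile HMM with its match-state length L."""

    gene_id: str
    L: int
    hmm: pyhmmer.plan7.HMM

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"{self.gene_id}: profile has no match states")

    def write(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            self.hmm.write(fh)

    @classmethod
    def read(cls, path: str | Path) -> "ProfileModel":
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            hmm = fh.read()
        name = hmm.name if isinstance(hmm.name, str) else hmm.name.decode()
        return cls(gene_id=name, L=hmm.M, hmm=hmm)


@dataclass(frozen=True)
class ConsensusSequence:
    gene_id: str
    sequence: str


@dataclass(frozen=True)
class CutoffEntry:
    detection_cutoff: float
    completeness_cutoff: float
    length_mean: float
    length_sd: float

    def __post_init__(self) -> None:
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")


class CutoffTable:
    """Per-gene bit-score and length cutoffs."""

    def __init__(self, entries: Mapping[str, CutoffEntry] | None = None) -> None:
        self._entries: dict[str, CutoffEntry] = dict(entries or {})

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._entries

    def __iter__(self):
        return iter(self._entries.items())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CutoffTable) and self._entries == other._entries

    def add(self, gene_id: str, entry: CutoffEntry) -> None:
        if gene_id in self._entries:
            raise ValueError(f"duplicate cutoff entry for {gene_id}")
        self._entries[gene_id] = entry

    def get(self, gene_id: str) -> CutoffEntry:
        try:
            return self._entries[gene_id]
        except KeyError:
            raise KeyError(f"no cutoffs for gene {gene_id!r}") from None

    def gene_ids(self) -> list[str]:
        return list(self._entries)


# ---------------------------------------------------------------------------
# Engine contracts and built-ins

_AMINO = Alphabet.amino()


class AlignmentEngine(Protocol):
    def align(self, sequences: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
        """(id, sequence) -> (id, aligned sequence), preserving order."""
        ...


class StackAligner:
    """Trivial engine for equal-length inputs: stacks them gaplessly.

    Suitable for families evolved without indels (the synthetic fixtures);
    refuses ragged inputs rather than aligning them.
    """

    def align(self, sequences: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
        lengths = {len(s) for _, s in sequences}
        if len(lengths) != 1:
            raise ProfileBuildError(
                "StackAligner requires equal-length sequences; use MafftAligner"
            )
        return list(sequences)


class MafftAligner:
    """MAFFT subprocess engine (deterministic for given inputs)."""

    def __init__(self, binary: str = "mafft", args: tuple[str, ...] = ("--auto",)) -> None:
        self.binary = binary
        self.args = args

    def align(self, sequences: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
        if shutil.which(self.binary) is None:
            raise ProfileBuildError(f"alignment engine {self.binary!r} not on PATH")
        with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
            for sid, seq in sequences:
                fh.write(f">{sid}\n{seq}\n")
            tmp = fh.name
        try:
            result = subprocess.run(
                [self.binary, *self.args, tmp],
                capture_output=True,
                text=True,
                check=True,
            )
        except subprocess.CalledProcessError as exc:
            raise ProfileBuildError(f"mafft failed: {exc.stderr[-500:]}") from exc
        finally:
            Path(tmp).unlink(missing_ok=True)
        aligned: dict[str, str] = {}
        current = None
        for line in result.stdout.splitlines():
            if line.startswith(">"):
                current = line[1:].split()[0]
                aligned[current] = ""
            elif current is not None:
                aligned[current] += line.strip()
        return [(sid, aligned[sid].upper()) for sid, _ in sequences]


@dataclass(frozen=True)
class SearchHit:
    """One profile-vs-sequence hit with merged match-state span(s)."""

    gene_id: str
    target_id: str
    score: float  # full-sequence bit score
    spans: tuple[tuple[int, int], ...]  # merged [from, to) over match states
    profile_length: int

    @property
    def coverage(self) -> float:
        covered = sum(b - a for a, b in self.spans)
        return covered / self.profile_length


def _merge_spans(spans: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    spans = sorted(spans)
    merged: list[list[int]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


class HmmerEngine:
    """Profile build / search / consensus engine backed by pyhmmer (HMMER3).

    Profiles are built *without* entropy-based effective-sequence-number
    reweighting (HMMER's ``--enone``). Entropy weighting deliberately
    flattens emission probabilities toward a target information content,
    which compresses the score gap between conserved and divergent family
    members; the cutoff criteria used here (minimum member score for
    detection, minimum per-species maximum for completeness) rely on that
    gap being informative, as it was under the HMMER 2-era tools this
    assessment scheme was designed around. Pass
    ``effective_number="entropy"`` to restore the HMMER3 default.
    """

    def __init__(self, seed: int = 42, effective_number: str | float = "none") -> None:
        self.seed = seed
        self.effective_number = effective_number
        self._background = pyhmmer.plan7.Background(_AMINO)

    # -- build -------------------------------------------------------------

    def build(self, msa: MultipleAlignment) -> ProfileModel:
        seqs = [
            TextSequence(name=pid.encode(), sequence=aligned)
            for _, pid, aligned in msa.rows
        ]
        try:
            text_msa = TextMSA(name=msa.gene_id.encode(), sequences=seqs)
            digital = text_msa.digitize(_AMINO)
            builder = pyhmmer.plan7.Builder(
                _AMINO, seed=self.seed, effective_number=self.effective_number
            )
            hmm, _, _ = builder.build_msa(digital, self._background)
        except Exception as exc:  # noqa: BLE001 - engine errors carry gene id
            raise ProfileBuildError(f"{msa.gene_id}: {exc}") from exc
        return ProfileModel(gene_id=msa.gene_id, L=hmm.M, hmm=hmm)

    # -- search ------------------------------------------------------------

    def search(
        self,
        profile: ProfileModel,
        targets: Sequence[tuple[str, str]],
    ) -> list[SearchHit]:
        """All reported hits of the profile against the target sequences."""
        if not targets:
            return []
        block = DigitalSequenceBlock(
            _AMINO,
            [
                TextSequence(name=tid.encode(), sequence=seq).digitize(_AMINO)
                for tid, seq in targets
            ],
        )
        pipeline = pyhmmer.plan7.Pipeline(_AMINO, background=self._background,
                                          seed=self.seed)
        hits = pipeline.search_hmm(profile.hmm, block)
        out = []
        for hit in hits:
            spans = [
                (d.alignment.hmm_from - 1, d.alignment.hmm_to)
                for d in hit.domains
            ]
            out.append(
                SearchHit(
                    gene_id=profile.gene_id,
                    target_id=(
                        hit.name if isinstance(hit.name, str) else hit.name.decode()
                    ),
                    score=float(hit.score),
                    spans=_merge_spans(spans),
                    profile_length=profile.L,
                )
            )
        return out

    def scores(
        self, profile: ProfileModel, targets: Sequence[tuple[str, str]]
    ) -> dict[str, float]:
        return {h.target_id: h.score for h in self.search(profile, targets)}

    # -- consensus ---------------------------------------------------------

    def consensus(self, profile: ProfileModel) -> ConsensusSequence:
        seq = profile.hmm.consensus
        if seq is None:
            raise ProfileBuildError(f"{profile.gene_id}: profile has no consensus")
        return ConsensusSequence(gene_id=profile.gene_id, sequence=seq.upper())


# ---------------------------------------------------------------------------
# Operations


def build_alignment(
    gene: CoreGene,
    proteins: ProteinCollection,
    engine: AlignmentEngine | None = None,
) -> MultipleAlignment:
    """Align the representative member proteins of one core gene."""
    engine = engine or MafftAligner()
    inputs = []
    for species, pid in gene.representatives.items():
        inputs.append((pid, proteins.sequence(pid)))
    if len(inputs) < 2:
        raise ProfileBuildError(f"{gene.group_id}: needs >= 2 member proteins")
    try:
        aligned = engine.align(inputs)
    except ProfileBuildError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ProfileBuildError(f"{gene.group_id}: {exc}") from exc
    species_by_pid = {pid: sp for sp, pid in gene.representatives.items()}
    rows = [(species_by_pid[pid], pid, seq) for pid, seq in aligned]
    return MultipleAlignment(gene_id=gene.group_id, rows=rows)


def build_profile(msa: MultipleAlignment, engine: HmmerEngine | None = None) -> ProfileModel:
    return (engine or HmmerEngine()).build(msa)


def compute_completeness_cutoff(
    profile: ProfileModel,
    all_transcript_proteins: Mapping[str, Sequence[tuple[str, str]]],
    engine: HmmerEngine | None = None,
    aggregate: str = "min",
) -> float:
    """Per-species maximum over all transcript isoforms, then aggregate.

    ``aggregate`` is ``min`` (default: cross-species minimum of the
    per-species maxima), ``median``, or ``min_all`` (minimum over every
    (species, transcript) score).
    """
    engine = engine or HmmerEngine()
    per_species_max: dict[str, float] = {}
    all_scores: list[float] = []
    for species, transcripts in all_transcript_proteins.items():
        if not transcripts:
            raise CutoffError(
                f"{profile.gene_id}: species {species} contributed no transcripts"
            )
        scores = engine.scores(profile, list(transcripts))
        if not scores:
            raise CutoffError(
                f"{profile.gene_id}: no transcript of {species} scores "
                "against the profile"
            )
        per_species_max[species] = max(scores.values())
        all_scores.extend(scores.values())
    if aggregate == "min":
        return min(per_species_max.values())
    if aggregate == "median":
        return float(statistics.median(per_species_max.values()))
    if aggregate == "min_all":
        return min(all_scores)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def compute_detection_cutoff(
    profile: ProfileModel,
    representative_proteins: Mapping[str, tuple[str, str]],
    engine: HmmerEngine | None = None,
) -> float:
    """Minimum bit score over the species' representative proteins."""
    engine = engine or HmmerEngine()
    targets = list(representative_proteins.values())
    scores = engine.scores(profile, targets)
    missing = [
        sp for sp, (pid, _) in representative_proteins.items() if pid not in scores
    ]
    if missing:
        raise CutoffError(
            f"{profile.gene_id}: representatives of {missing} do not score"
        )
    return min(scores.values())


def compute_detection_cutoff_loo(
    msa: MultipleAlignment,
    engine: HmmerEngine | None = None,
) -> float:
    """Cross-validated detection cutoff: minimum leave-one-out member score.

    Each member is scored against a profile built from the alignment with
    that member's row removed, and the minimum over members is taken.
    Because the held-out member contributed nothing to the profile, a
    divergent member scores realistically low, which is what keeps the
    detection cutoff permissive enough to pick up truncated or diverged
    orthologs while the family's own members all clear it against the
    full profile.
    """
    engine = engine or HmmerEngine()
    if len(msa.rows) < 3:
        raise CutoffError(f"{msa.gene_id}: leave-one-out needs >= 3 members")
    worst: float | None = None
    for i, (_, pid, aligned) in enumerate(msa.rows):
        rest = MultipleAlignment(
            gene_id=msa.gene_id, rows=[r for j, r in enumerate(msa.rows) if j != i]
        )
        loo_profile = engine.build(rest)
        held_out = aligned.replace("-", "").replace(".", "")
        scores = engine.scores(loo_profile, [(pid, held_out)])
        score = scores.get(pid)
        if score is None:
            raise CutoffError(
                f"{msa.gene_id}: member {pid} does not score against the "
                "leave-one-out profile"
            )
        worst = score if worst is None else min(worst, score)
    return worst


def compute_length_cutoffs(member_lengths: Sequence[int]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation of member lengths."""
    if len(member_lengths) < 2:
        raise ValueError("length cutoffs need >= 2 member lengths")
    mean = statistics.fmean(member_lengths)
    sd = statistics.stdev(member_lengths)
    return mean, sd


def emit_consensus(
    profile: ProfileModel, engine: HmmerEngine | None = None
) -> ConsensusSequence:
    return (engine or HmmerEngine()).consensus(profile)


def build_gene_cutoffs(
    gene: CoreGene,
    profile: ProfileModel,
    proteins: ProteinCollection,
    engine: HmmerEngine | None = None,
    aggregate: str = "min",
    detection_mode: str = "leave_one_out",
    msa: MultipleAlignment | None = None,
) -> CutoffEntry:
    """All cutoffs for one gene from its member proteins.

    ``detection_mode`` is ``"leave_one_out"`` (cross-validated minimum
    member score; needs ``msa``) or ``"profile"`` (minimum member score
    against the full profile).
    """
    engine = engine or HmmerEngine()
    reps = {
        sp: (pid, proteins.sequence(pid)) for sp, pid in gene.representatives.items()
    }
    transcripts = {
        sp: [(pid, proteins.sequence(pid)) for pid in pids]
        for sp, pids in gene.transcripts.items()
    }
    if detection_mode == "leave_one_out":
        if msa is None:
            raise ValueError("leave_one_out detection mode requires the alignment")
        detection = compute_detection_cutoff_loo(msa, engine)
    elif detection_mode == "profile":
        detection = compute_detection_cutoff(profile, reps, engine)
    else:
        raise ValueError(f"unknown detection_mode {detection_mode!r}")
    completeness = compute_completeness_cutoff(profile, transcripts, engine, aggregate)
    lengths = [len(seq) for _, (_, seq) in reps.items()]
    mean, sd = compute_length_cutoffs(lengths)
    return CutoffEntry(
        detection_cutoff=detection,
        completeness_cutoff=completeness,
        length_mean=mean,
        length_sd=sd,
    )


# ---------------------------------------------------------------------------
# Dataset container and export

PROFILES_CUTOFF_TBL = "profiles_cutoff.tbl"
COMPLETENESS_CUTOFF_TBL = "completeness_cutoff.tbl"
LENGTHS_CUTOFF_TBL = "lengths_cutoff.tbl"


@dataclass
class AssessmentDataset:
    """Profiles + cutoffs (+ consensus) ready for completeness assessment."""

    set_id: str
    profiles: dict[str, ProfileModel]
    cutoffs: CutoffTable
    consensus: dict[str, ConsensusSequence] = field(default_factory=dict)
    flavor: str = "cegma-like"

    def gene_ids(self) -> list[str]:
        return list(self.profiles)


def build_dataset(
    core_set: CoreGeneSet,
    proteins: ProteinCollection,
    aligner: AlignmentEngine | None = None,
    engine: HmmerEngine | None = None,
    aggregate: str = "min",
    flavor: str = "cegma-like",
) -> AssessmentDataset:
    """Alignment -> profile -> cutoffs (-> consensus) for every core gene."""
    engine = engine or HmmerEngine()
    profiles: dict[str, ProfileModel] = {}
    cutoffs = CutoffTable()
    consensus: dict[str, ConsensusSequence] = {}
    for gene in core_set.genes:
        msa = build_alignment(gene, proteins, aligner)
        profile = build_profile(msa, engine)
        profiles[gene.group_id] = profile
        cutoffs.add(
            gene.group_id,
            build_gene_cutoffs(gene, profile, proteins, engine, aggregate, msa=msa),
        )
        if flavor == "busco-like":
            consensus[gene.group_id] = emit_consensus(profile, engine)
    return AssessmentDataset(
        set_id=core_set.set_id,
        profiles=profiles,
        cutoffs=cutoffs,
        consensus=consensus,
        flavor=flavor,
    )


def _write_cutoff_tbl(path: Path, values: Iterable[tuple[str, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gid, v in values:
            fh.write(f"{gid}\t{v!r}\n")


def _read_cutoff_tbl(path: Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            gid, v = line.rstrip("\n").split("\t")
            out[gid] = float(v)
    return out


def export_dataset(dataset: AssessmentDataset, out_dir: str | Path) -> None:
    """Write a CEGMA-like or BUSCO-like dataset directory.

    CEGMA-like: one HMMER3 profile per gene plus the two score cutoff
    tables (``profiles_cutoff.tbl`` for detection,
    ``completeness_cutoff.tbl``) and the length-cutoff table. BUSCO-like
    additionally writes consensus sequences (``ancestral`` FASTA) and
    per-gene gene-structure profile placeholders.
    """
    missing = [
        gid
        for gid in dataset.profiles
        if gid not in dataset.cutoffs
    ] + [gid for gid in dataset.cutoffs.gene_ids() if gid not in dataset.profiles]
    if missing:
        raise ValueError(f"export aborted; genes lacking profile or cutoffs: {missing}")
    out = Path(out_dir)
    (out / "hmms").mkdir(parents=True, exist_ok=True)
    for gid, profile in dataset.profiles.items():
        profile.write(out / "hmms" / f"{gid}.hmm")
    _write_cutoff_tbl(
        out / PROFILES_CUTOFF_TBL,
        ((gid, e.detection_cutoff) for gid, e in dataset.cutoffs),
    )
    _write_cutoff_tbl(
        out / COMPLETENESS_CUTOFF_TBL,
        ((gid, e.completeness_cutoff) for gid, e in dataset.cutoffs),
    )
    with open(out / LENGTHS_CUTOFF_TBL, "w") as fh:
        fh.write("gene_id\tlength_mean\tlength_sd\n")
        for gid, e in dataset.cutoffs:
            fh.write(f"{gid}\t{e.length_mean!r}\t{e.length_sd!r}\n")
    if dataset.flavor == "busco-like":
        with open(out / "ancestral", "w") as fh:
            for gid, cons in dataset.consensus.items():
                fh.write(f">{gid}\n{cons.sequence}\n")
        prfl = out / "prfl"
        prfl.mkdir(exist_ok=True)
        for gid in dataset.profiles:
            (prfl / f"{gid}.prfl").write_text(
                f"# gene-structure profile placeholder for {gid}\n"
            )
    manifest = {
        "set_id": dataset.set_id,
        "flavor": dataset.flavor,
        "genes": sorted(dataset.profiles),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_dataset(out_dir: str | Path) -> AssessmentDataset:
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    profiles = {
        gid: ProfileModel.read(out / "hmms" / f"{gid}.hmm")
        for gid in manifest["genes"]
    }
    detection = _read_cutoff_tbl(out / PROFILES_CUTOFF_TBL)
    completeness = _read_cutoff_tbl(out / COMPLETENESS_CUTOFF_TBL)
    lengths: dict[str, tuple[float, float]] = {}
    if (out / LENGTHS_CUTOFF_TBL).exists():
        with open(out / LENGTHS_CUTOFF_TBL) as fh:
            next(fh)
            for line in fh:
                gid, mean, sd = line.rstrip("\n").split("\t")
                lengths[gid] = (float(mean), float(sd))
    cutoffs = CutoffTable()
    for gid in manifest["genes"]:
        mean, sd = lengths.get(gid, (0.0, 0.0))
        cutoffs.add(
            gid,
            CutoffEntry(
                detection_cutoff=detection[gid],
                completeness_cutoff=completeness[gid],
                length_mean=mean,
                length_sd=sd,
            ),
        )
    consensus: dict[str, ConsensusSequence] = {}
    if (out / "ancestral").exists():
        from Bio import SeqIO

        for rec in SeqIO.parse(str(out / "ancestral"), "fasta"):
            consensus[rec.id] = ConsensusSequence(rec.id, str(rec.seq))
    return AssessmentDataset(
        set_id=manifest["set_id"],
        profiles=profiles,
        cutoffs=cutoffs,
        consensus=consensus,
        flavor=manifest["flavor"],
    )
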