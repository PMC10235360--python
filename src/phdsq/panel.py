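"""Hybridization-ligation probe panel design.

A probe pair is two 27-nt DNA arms that hybridize to adjacent windows of a
transcript; when both arms anneal, a ligase seals the nick between them and
the ligated 54-mer becomes the countable unit of the assay.  Design rules:

1. arms are exactly 27 nt and junctions preferentially span an exon-exon
   boundary (so genomic DNA cannot template a ligation product);
2. per-arm GC fraction lies within [0.40, 0.60];
3. the candidate 54-mer must have no (or limited) exact k-mer sharing with
   off-target transcripts;
4. the ligation junction must not overlap a known SNP — a mismatch at the
   nick blocks ligation and silences the probe in a genotype-dependent way.

Coordinates are 0-based half-open throughout; the junction position is the
transcript coordinate at which the right arm begins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ARM_LENGTH = 27
GC_MIN = 0.40
GC_MAX = 0.60

_VALID_BASES = frozenset("ACGT")


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or characters outside A/C/G/T."""


class NoCandidateError(ValueError):
    """Raised when a transcript is too short to host any probe pair."""


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases in an uppercase ACGT string.

    Raises
    ------
    InvalidSequenceError
        If the sequence is empty or contains non-ACGT characters.
    """
    if not seq:
        raise InvalidSequenceError("empty sequence")
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise InvalidSequenceError(f"non-ACGT characters: {bad}")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with exon structure and known polymorphic positions.

    ``exon_boundaries`` are internal exon-exon junction positions in
    transcript coordinates (0-based): position ``b`` means one exon ends at
    ``b`` (exclusive) and the next begins at ``b``.
    """

    gene_id: str
    transcript_id: str
    seq: str
    exon_boundaries: tuple[int, ...] = ()
    snp_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.seq or not _VALID_BASES.issuperset(self.seq):
            raise InvalidSequenceError(
                f"{self.transcript_id}: sequence must be non-empty uppercase ACGT"
            )
        n = len(self.seq)
        bounds = tuple(self.exon_boundaries)
        if list(bounds) != sorted(set(bounds)):
            raise ValueError(f"{self.transcript_id}: exon boundaries must be strictly increasing")
        if bounds and (bounds[0] <= 0 or bounds[-1] >= n):
            raise ValueError(f"{self.transcript_id}: exon boundaries must lie inside the sequence")
        if any(p < 0 or p >= n for p in self.snp_positions):
            raise ValueError(f"{self.transcript_id}: SNP positions must lie inside the sequence")
        object.__setattr__(self, "exon_boundaries", bounds)
        object.__setattr__(self, "snp_positions", frozenset(self.snp_positions))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProbeArm:
    """One 27-nt arm of a probe pair, anchored at ``target_start``."""

    arm_seq: str
    side: str  # "left" | "right"
    target_start: int

    def __post_init__(self) -> None:
        if len(self.arm_seq) != ARM_LENGTH:
            raise ValueError(f"arm must be {ARM_LENGTH} nt, got {len(self.arm_seq)}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass(frozen=True)
class ProbePair:
    """A gene-targeting left/right arm pair with a defined ligation junction."""

    probe_id: str
    gene_id: str
    left: ProbeArm
    right: ProbeArm
    junction_pos: int
    exon_spanning: bool = False

    def __post_init__(self) -> None:
        if self.left.target_start + ARM_LENGTH != self.right.target_start:
            raise ValueError(f"{self.probe_id}: arms are not contiguous")
        if self.right.target_start != self.junction_pos:
            raise ValueError(f"{self.probe_id}: junction must equal right-arm start")

    @property
    def reference(self) -> str:
        """The ligated 54-nt product; the mapping reference for counting."""
        return self.left.arm_seq + self.right.arm_seq


@dataclass
class ProbePanel:
    """An ordered collection of probe pairs; a gene may carry >1 pair."""

    pairs: list[ProbePair]
    gene_to_probes: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("probe_ids must be unique within a panel")
        refs = [p.reference for p in self.pairs]
        if len(set(refs)) != len(refs):
            raise ValueError("54-nt probe references must be unique within a panel")
        self.gene_to_probes = {}
        for p in self.pairs:
            self.gene_to_probes.setdefault(p.gene_id, []).append(p.probe_id)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.pairs]

    @property
    def genes(self) -> list[str]:
        return list(self.gene_to_probes)

    def by_id(self, probe_id: str) -> ProbePair:
        for p in self.pairs:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def gene_of(self, probe_id: str) -> str:
        return self.by_id(probe_id).gene_id


@dataclass(frozen=True)
class CandidateSite:
    """A feasible junction position on a transcript."""

    junction: int
    exon_spanning: bool


def enumerate_candidate_sites(t: TranscriptRecord) -> list[CandidateSite]:
    """Every junction j whose 27-nt flanking windows fit inside the transcript.

    Junctions sitting on a known SNP are excluded (ligation would fail on the
    alternate allele).  A site is flagged exon-spanning when an exon boundary
    lies within the 54-nt window [j-27, j+27).

    Raises
    ------
    NoCandidateError
        If the transcript is shorter than 54 nt.
    """
    n = len(t.seq)
    if n < 2 * ARM_LENGTH:
        raise NoCandidateError(
            f"{t.transcript_id}: transcript of {n} nt cannot host a {2 * ARM_LENGTH}-nt probe pair"
        )
    sites = []
    for j in range(ARM_LENGTH, n - ARM_LENGTH + 1):
        if j in t.snp_positions:
            continue
        spanning = any(j - ARM_LENGTH <= b < j + ARM_LENGTH for b in t.exon_boundaries)
        sites.append(CandidateSite(junction=j, exon_spanning=spanning))
    return sites


def make_pair(t: TranscriptRecord, junction: int, probe_id: str,
              exon_spanning: bool | None = None) -> ProbePair:
    """Build the probe pair whose ligation junction sits at ``junction``."""
    if junction < ARM_LENGTH or junction + ARM_LENGTH > len(t.seq):
        raise ValueError(f"junction {junction} out of range for {t.transcript_id}")
    if exon_spanning is None:
        exon_spanning = any(
            junction - ARM_LENGTH <= b < junction + ARM_LENGTH for b in t.exon_boundaries
        )
    left = ProbeArm(t.seq[junction - ARM_LENGTH:junction], "left", junction - ARM_LENGTH)
    right = ProbeArm(t.seq[junction:junction + ARM_LENGTH], "right", junction)
    return ProbePair(probe_id, t.gene_id, left, right, junction, exon_spanning)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def homology_screen(pair: ProbePair, background: list[TranscriptRecord],
                    k: int = ARM_LENGTH, max_shared: int = 1) -> tuple[bool, int]:
    """Exact k-mer cross-hybridization screen against off-target transcripts.

    Transcripts of the pair's own gene are excluded (self-matches are
    expected).  Fails when any single off-target transcript shares
    ``max_shared`` or more exact k-mers with the pair's 54-nt reference.

    Returns ``(passed, max_shared_kmer_count)``.
    """
    if k > 2 * ARM_LENGTH:
        raise ValueError("k cannot exceed the 54-nt reference length")
    off_target = [t for t in background if t.gene_id != pair.gene_id]
    if not off_target:
        warnings.warn("homology screen ran against an empty background", stacklevel=2)
        return True, 0
    ref_kmers = _kmers(pair.reference, k)
    worst = 0
    for t in off_target:
        shared = len(ref_kmers & _kmers(t.seq, k))
        worst = max(worst, shared)
    return worst < max_shared, worst


@dataclass
class DesignFailure:
    gene_id: str
    reason: str


@dataclass
class DesignResult:
    panel: ProbePanel
    failures: list[DesignFailure]


def _rank_key(pair: ProbePair, junction: int) -> tuple:
    # exon-spanning preferred; then arms closest to 50% GC; then leftmost junction
    dev_l = abs(gc_fraction(pair.left.arm_seq) - 0.5)
    dev_r = abs(gc_fraction(pair.right.arm_seq) - 0.5)
    return (0 if pair.exon_spanning else 1,
            round(max(dev_l, dev_r), 12),
            round((dev_l + dev_r) / 2, 12),
            junction)


def design_panel(transcripts: list[TranscriptRecord], genes: list[str],
                 pairs_per_gene: int = 1,
                 background: list[TranscriptRecord] | None = None,
                 homology_k: int = ARM_LENGTH,
                 homology_max_shared: int = 1) -> DesignResult:
    """Design up to ``pairs_per_gene`` probe pairs per requested gene.

    Candidates are enumerated exhaustively per transcript, filtered on the
    hard rules (arm GC in [0.40, 0.60], no SNP at the junction, homology
    screen), then ranked: exon-spanning first, arms closest to 50% GC next,
    leftmost junction as the deterministic tie-break.  Genes with no passing
    candidate are returned in the failure list rather than raising.

    The result is a pure function of its inputs: identical inputs yield a
    byte-identical panel.
    """
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    if background is None:
        background = transcripts

    # one shared k-mer index over the background: kmer -> transcripts carrying it
    kmer_index: dict[str, list[int]] = {}
    bg_gene = [t.gene_id for t in background]
    for ti, t in enumerate(background):
        for kmer in _kmers(t.seq, homology_k):
            kmer_index.setdefault(kmer, []).append(ti)

    def _passes_homology(pair: ProbePair) -> bool:
        shared: dict[int, int] = {}
        for kmer in _kmers(pair.reference, homology_k):
            for ti in kmer_index.get(kmer, ()):
                if bg_gene[ti] != pair.gene_id:
                    shared[ti] = shared.get(ti, 0) + 1
                    if shared[ti] >= homology_max_shared:
                        return False
        return True

    chosen: list[ProbePair] = []
    failures: list[DesignFailure] = []
    for gene in genes:
        gene_transcripts = by_gene.get(gene, [])
        if not gene_transcripts:
            failures.append(DesignFailure(gene, "no transcript provided"))
            continue
        ranked: list[tuple[tuple, ProbePair]] = []
        for t in sorted(gene_transcripts, key=lambda t: t.transcript_id):
            try:
                sites = enumerate_candidate_sites(t)
            except NoCandidateError:
                continue
            for site in sites:
                pair = make_pair(t, site.junction, f"{gene}_tmp", site.exon_spanning)
                gl = gc_fraction(pair.left.arm_seq)
                gr = gc_fraction(pair.right.arm_seq)
                if not (GC_MIN <= gl <= GC_MAX and GC_MIN <= gr <= GC_MAX):
                    continue
                if not _passes_homology(pair):
                    continue
                ranked.append((_rank_key(pair, site.junction), pair))
        ranked.sort(key=lambda x: x[0])
        picked: list[ProbePair] = []
        used_junctions: set[int] = set()
        for _, pair in ranked:
            if pair.junction_pos in used_junctions:
                continue
            picked.append(pair)
            used_junctions.add(pair.junction_pos)
            if len(picked) == pairs_per_gene:
                break
        if not picked:
            failures.append(DesignFailure(gene, "no candidate passed all design rules"))
            continue
        for i, pair in enumerate(picked, start=1):
            chosen.append(ProbePair(f"{gene}_p{i}", pair.gene_id, pair.left, pair.right,
                                    pair.junction_pos, pair.exon_spanning))
    return DesignResult(panel=ProbePanel(chosen), failures=failures)


# ---------------------------------------------------------------------------
# serialization


def read_transcripts(fasta_path: str | Path, annot_path: str | Path) -> list[TranscriptRecord]:
    """Load transcripts from FASTA plus a tab-separated annotation.

    The annotation columns are gene_id, transcript_id, exon_boundaries and
    snp_positions; the latter two are comma-separated integer lists and may
    be empty.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    annot = pd.read_csv(annot_path, sep="\t", dtype=str).fillna("")
    out = []
    for row in annot.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise KeyError(f"transcript {row.transcript_id} absent from FASTA")
        bounds = tuple(int(x) for x in str(row.exon_boundaries).split(",") if x != "")
        snps = frozenset(int(x) for x in str(row.snp_positions).split(",") if x != "")
        out.append(TranscriptRecord(row.gene_id, row.transcript_id,
                                    seqs[row.transcript_id], bounds, snps))
    return out


def panel_to_frame(panel: ProbePanel) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in panel],
            "gene_id": [p.gene_id for p in panel],
            "left_seq": [p.left.arm_seq for p in panel],
            "right_seq": [p.right.arm_seq for p in panel],
            "junction_pos": [p.junction_pos for p in panel],
            "exon_spanning": [p.exon_spanning for p in panel],
        }
    )


def write_panel_tsv(panel: ProbePanel, path: str | Path) -> None:
    panel_to_frame(panel).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> ProbePanel:
    df = pd.read_csv(path, sep="\t", dtype={"junction_pos": int})
    pairs = []
    for row in df.itertuples(index=False):
        j = int(row.junction_pos)
        left = ProbeArm(row.left_seq, "left", j - ARM_LENGTH)
        right = ProbeArm(row.right_seq, "right", j)
        pairs.append(ProbePair(row.probe_id, row.gene_id, left, right, j,
                               bool(row.exon_spanning)))
    return ProbePanel(pairs)


def write_panel_fasta(panel: ProbePanel, path: str | Path) -> None:
    """One 54-nt reference record per probe pair; the mapping reference."""
    records = [SeqRecord(Seq(p.reference), id=p.probe_id, description="") for p in panel]
    SeqIO.write(records, str(path), "fasta")
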