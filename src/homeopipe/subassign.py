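"""Assign read fragments to subgenome and gene via shared canonical k-mers.

A read pair from an allopolyploid maps to both homoeologs of a gene wherever
their sequence is conserved; only k-mers overlapping diverged sites are
diagnostic.  At ~17% transcript divergence a 21-mer is conserved between
homoeologs with probability ~(0.83)^21 ≈ 2%, so a 2x150 bp fragment carries
dozens of diagnostic k-mers and subgenome assignment by k-mer counting is
near-deterministic.  Canonical k-mers (lexicographic minimum of a k-mer and
its reverse complement) make the score strand-agnostic without alignment.

``separate_alignments`` preserves the semantics of routing externally mapped
records by the subgenome of their reference sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .core import AnnotatedTranscriptome, revcomp

MIN_K = 11
DEFAULT_K = 21
DEFAULT_MIN_MARGIN = 2


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    """Canonical k-mer -> list of (gene ID, 0-based position, is_forward).

    ``is_forward`` is True when the canonical form equals the k-mer as read
    from the transcript's forward strand; it lets a hit vote for an ungapped
    read placement with orientation.
    Duplicated k-mers are retained with every location.
    """

    label: str
    k: int
    entries: dict[str, list[tuple[str, int, bool]]]
    genes: frozenset[str]
    gene_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_sets:
            self.gene_sets = {
                canon: tuple(dict.fromkeys(g for g, _, _ in hits))
                for canon, hits in self.entries.items()
            }

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.entries

    def lookup(self, canon: str) -> list[tuple[str, int, bool]]:
        return self.entries.get(canon, [])


def build_index(transcriptome: AnnotatedTranscriptome, k: int = DEFAULT_K) -> KmerIndex:
    """Index every canonical k-mer of every transcript.

    Raises ``ValueError`` when ``k`` is below the minimum informative size or
    exceeds the shortest transcript.
    """
    if k < MIN_K:
        raise ValueError(f"k={k} below minimum {MIN_K}")
    min_len = min((len(s) for s in transcriptome.records.values()), default=0)
    if len(transcriptome.records) and k > min_len:
        raise ValueError(f"k={k} exceeds shortest transcript length {min_len}")
    entries: dict[str, list[tuple[str, int, bool]]] = {}
    for gid, seq in transcriptome.records.items():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            canon = canonical(km)
            entries.setdefault(canon, []).append((gid, i, canon == km))
    return KmerIndex(label=transcriptome.label, k=k, entries=entries, genes=frozenset(transcriptome.records))


@dataclass
class ReadAssignment:
    read_id: str
    subgenome: str  # "AT" | "AA" | "ambiguous" | "unmapped"
    gene: str | None
    score: int
    margin: int

    def __post_init__(self) -> None:
        if self.subgenome in ("AT", "AA") and self.gene is None:
            raise ValueError("assigned fragment must carry a gene ID")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


def _read_canonical_kmers(seq: str, k: int) -> list[str]:
    return [canonical(seq[i : i + k]) for i in range(len(seq) - k + 1)]


def _best_gene_score(mates: Sequence[str], index: KmerIndex) -> tuple[str | None, int]:
    """Best gene and its shared-canonical-k-mer score, summed across mates.

    Each read k-mer counts once per gene it occurs in (multiplicity within a
    gene does not inflate the score).
    """
    scores: Counter[str] = Counter()
    gene_sets = index.gene_sets
    for seq in mates:
        for canon in _read_canonical_kmers(seq, index.k):
            hits = gene_sets.get(canon)
            if hits:
                scores.update(hits)
    if not scores:
        return None, 0
    # deterministic tie-break: highest score, then lexicographic gene ID
    gene = min(scores, key=lambda g: (-scores[g], g))
    return gene, scores[gene]


def assign_fragment(
    mate1: str,
    mate2: str,
    index_at: KmerIndex,
    index_aa: KmerIndex,
    min_margin: int = DEFAULT_MIN_MARGIN,
    read_id: str = "",
) -> ReadAssignment:
    """Score a fragment against both subgenome indices and call the winner.

    The fragment is assigned to the subgenome whose best gene shares the most
    canonical k-mers with the two mates, provided the lead over the other
    subgenome reaches ``min_margin``; otherwise it is ambiguous.  Zero score
    on both sides means unmapped.
    """
    if index_at.k != index_aa.k:
        raise ValueError("indices must be built with the same k")
    mates = [m.upper() for m in (mate1, mate2) if m]
    gene_at, score_at = _best_gene_score(mates, index_at)
    gene_aa, score_aa = _best_gene_score(mates, index_aa)
    if score_at == 0 and score_aa == 0:
        return ReadAssignment(read_id, "unmapped", None, 0, 0)
    margin = abs(score_at - score_aa)
    if margin < min_margin:
        return ReadAssignment(read_id, "ambiguous", None, max(score_at, score_aa), margin)
    if score_at > score_aa:
        return ReadAssignment(read_id, "AT", gene_at, score_at, margin)
    return ReadAssignment(read_id, "AA", gene_aa, score_aa, margin)


def locate_ungapped(seq: str, index: KmerIndex, gene: str) -> tuple[int, str] | None:
    """Ungapped placement of a mate on its assigned transcript.

    Matching k-mers vote for (orientation, offset); the modal vote wins.
    Returns ``(offset, oriented_sequence)`` where ``oriented_sequence`` is the
    mate as it reads along the transcript's forward strand, or ``None`` when
    no k-mer anchors the mate to the gene.
    """
    seq = seq.upper()
    k = index.k
    n = len(seq)
    votes: Counter[tuple[bool, int]] = Counter()
    for i in range(n - k + 1):
        km = seq[i : i + k]
        canon = canonical(km)
        read_fwd = canon == km
        for g, pos, gene_fwd in index.entries.get(canon, ()):
            if g != gene:
                continue
            if gene_fwd == read_fwd:
                votes[(True, pos - i)] += 1
            else:
                votes[(False, pos - (n - k - i))] += 1
    if not votes:
        return None
    (fwd, offset), _ = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    oriented = seq if fwd else revcomp(seq)
    return offset, oriented


@dataclass
class GeneCounts:
    """Per-sample fragment counts after subgenome assignment.

    Ambiguous fragments are excluded from per-gene counts but included in the
    library-wide mapped total (they were mapped, just not attributable),
    mirroring a mapper that reports multi-mapped reads.  Unmapped fragments
    count in neither.
    """

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    subgenome_of: dict[str, str] = field(default_factory=dict)
    ambiguous: int = 0
    unmapped: int = 0

    @property
    def subgenome_totals(self) -> dict[str, int]:
        tot = {"AT": 0, "AA": 0}
        for g, c in self.counts.items():
            tot[self.subgenome_of[g]] += c
        return tot

    @property
    def mapped_total(self) -> int:
        """Library-wide mapped fragments: assigned plus ambiguous."""
        return sum(self.counts.values()) + self.ambiguous

    @property
    def input_total(self) -> int:
        return sum(self.counts.values()) + self.ambiguous + self.unmapped


def count_fragments(assignments: Iterable[ReadAssignment], sample_id: str) -> GeneCounts:
    """Aggregate fragment assignments of one sample into gene counts."""
    gc = GeneCounts(sample_id=sample_id)
    seen: set[str] = set()
    for a in assignments:
        if a.read_id:
            if a.read_id in seen:
                raise ValueError(f"duplicate read ID {a.read_id}")
            seen.add(a.read_id)
        if a.subgenome == "ambiguous":
            gc.ambiguous += 1
        elif a.subgenome == "unmapped":
            gc.unmapped += 1
        else:
            assert a.gene is not None
            gc.counts[a.gene] = gc.counts.get(a.gene, 0) + 1
            gc.subgenome_of[a.gene] = a.subgenome
    return gc


def assign_sample(
    fragments: Iterable[tuple[str, str, str]],
    index_at: KmerIndex,
    index_aa: KmerIndex,
    min_margin: int = DEFAULT_MIN_MARGIN,
) -> list[ReadAssignment]:
    """Assign every (read_id, mate1, mate2) fragment of a sample."""
    return [
        assign_fragment(m1, m2, index_at, index_aa, min_margin=min_margin, read_id=rid)
        for rid, m1, m2 in fragments
    ]


def separate_alignments(
    sam_in: str | Path,
    subgenome_of_ref: dict[str, str],
    out_at: str | Path,
    out_aa: str | Path,
) -> dict[str, int]:
    """Route mapped SAM records into per-subgenome files by reference name.

    Unmapped records (FLAG 0x4 or '*' reference) are dropped and counted.
    Record order is preserved within each output stream.  A mapped record
    whose reference is absent from ``subgenome_of_ref`` is an error.
    """
    summary = {"AT": 0, "AA": 0, "unmapped_dropped": 0}
    with pysam.AlignmentFile(str(sam_in), "r", check_sq=False) as fin:
        with pysam.AlignmentFile(str(out_at), "w", template=fin) as fat, pysam.AlignmentFile(
            str(out_aa), "w", template=fin
        ) as faa:
            for rec in fin:
                if rec.is_unmapped or rec.reference_name is None:
                    summary["unmapped_dropped"] += 1
                    continue
                ref = rec.reference_name
                if ref not in subgenome_of_ref:
                    raise KeyError(f"reference {ref!r} has no subgenome in the provided map")
                sub = subgenome_of_ref[ref]
                (fat if sub == "AT" else faa).write(rec)
                summary[sub] += 1
    return summary
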