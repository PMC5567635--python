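"""Shared containers: per-subgenome transcriptomes and the homoeolog map."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUBGENOMES = ("AT", "AA")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AnnotatedTranscriptome:
    """Transcript sequences of one subgenome, keyed by gene ID.

    ``label`` tags the subgenome ("AT" or "AA"); gene IDs carry the label
    as a prefix so they stay unique across the concatenated reference.
    """

    label: str
    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in SUBGENOMES:
            raise ValueError(f"subgenome label must be one of {SUBGENOMES}, got {self.label!r}")
        for gid, seq in self.records.items():
            if len(seq) == 0:
                raise ValueError(f"zero-length transcript {gid}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def length(self, gene: str) -> int:
        return len(self.records[gene])

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.records.values())

    def lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.records.items()}

    def to_fasta(self, path: str | Path) -> None:
        recs = (
            SeqRecord(Seq(seq), id=gid, description="")
            for gid, seq in self.records.items()
        )
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, label: str) -> "AnnotatedTranscriptome":
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(label=label, records=records)


@dataclass
class HomoeologMap:
    """Pairing between AT-subgenome and AA-subgenome gene IDs.

    Each gene belongs to at most one pair; unpaired genes simply do not
    appear here.
    """

    rows: list[tuple[str, str, str]] = field(default_factory=list)  # (pair, at, aa)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pair_id, at_gene, aa_gene in self.rows:
            for g in (at_gene, aa_gene):
                if g in seen:
                    raise ValueError(f"gene {g} appears in more than one homoeolog pair")
                seen.add(g)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(self.rows)

    @property
    def pair_of(self) -> dict[str, str]:
        """gene ID -> pair ID for every paired gene."""
        out: dict[str, str] = {}
        for pair_id, at_gene, aa_gene in self.rows:
            out[at_gene] = pair_id
            out[aa_gene] = pair_id
        return out

    @property
    def partner_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for _, at_gene, aa_gene in self.rows:
            out[at_gene] = aa_gene
            out[aa_gene] = at_gene
        return out

    def members(self, pair_id: str) -> tuple[str, str]:
        for pid, at_gene, aa_gene in self.rows:
            if pid == pair_id:
                return at_gene, aa_gene
        raise KeyError(pair_id)

    def validate_against(
        self, at: AnnotatedTranscriptome, aa: AnnotatedTranscriptome
    ) -> None:
        for pair_id, at_gene, aa_gene in self.rows:
            if at_gene not in at:
                raise ValueError(f"pair {pair_id}: {at_gene} missing from AT transcriptome")
            if aa_gene not in aa:
                raise ValueError(f"pair {pair_id}: {aa_gene} missing from AA transcriptome")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pair_id\tat_gene\taa_gene\n")
            for pair_id, at_gene, aa_gene in self.rows:
                fh.write(f"{pair_id}\t{at_gene}\t{aa_gene}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomoeologMap":
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("pair_id"):
                raise ValueError("homoeolog map TSV must have a pair_id/at_gene/aa_gene header")
            for line in fh:
                pair_id, at_gene, aa_gene = line.rstrip("\n").split("\t")
                rows.append((pair_id, at_gene, aa_gene))
        return cls(rows=rows)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, str]]) -> "HomoeologMap":
        return cls(rows=list(pairs))
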