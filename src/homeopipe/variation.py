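"""Transcript-space SNP calling, set partitioning, and enrichment tests.

Variants live in transcript coordinates (CHROM = transcript ID, POS 1-based).
The accessions are treated as homozygous inbred lines, so calling reduces to
a consensus threshold over an ungapped pileup: a site is a SNP when enough
reads cover it and nearly all of them agree on a non-reference base.

Set algebra operates on (transcript, position, alt) keys — the semantics of
merging per-sample VCFs for comparison.  The partition against a reference
panel reproduces the shared / accession-only x in-panel / not-in-panel cells
used to classify private and lineage-specific variants.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotatedTranscriptome
from .subassign import KmerIndex, ReadAssignment, locate_ungapped

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

SnpKey = tuple[str, int, str]


@dataclass(frozen=True)
class SnpRecord:
    """One substitution (or small indel) against the reference transcript."""

    transcript: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float = 0.0
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if not self.is_indel and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("substitution records must have single-base alleles")

    @property
    def key(self) -> SnpKey:
        return (self.transcript, self.pos, self.alt)


class SnpSet:
    """Keyed collection of SNP records for one accession or panel member."""

    def __init__(self, label: str, records: Iterable[SnpRecord] = ()) -> None:
        self.label = label
        self._records: dict[SnpKey, SnpRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SnpRecord) -> None:
        if rec.key in self._records:
            raise ValueError(f"duplicate SNP key {rec.key}")
        self._records[rec.key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: SnpKey) -> bool:
        return key in self._records

    def __iter__(self):
        return iter(self._records.values())

    @property
    def keys(self) -> frozenset[SnpKey]:
        return frozenset(self._records)

    def get(self, key: SnpKey) -> SnpRecord:
        return self._records[key]

    def union(self, other: "SnpSet", label: str | None = None) -> "SnpSet":
        out = SnpSet(label or f"{self.label}|{other.label}")
        out._records = dict(self._records)
        for k, v in other._records.items():
            out._records.setdefault(k, v)
        return out

    def to_vcf(self, path: str | Path, reference_name: str = "transcripts") -> None:
        """Write a minimal VCF 4.2 text file (CHROM = transcript, POS 1-based)."""
        recs = sorted(self._records.values(), key=lambda r: (r.transcript, r.pos, r.alt))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=homeopipe\n##reference={reference_name}\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in recs:
                fh.write(
                    f"{r.transcript}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:.1f}\t.\t.\n"
                )

    @classmethod
    def from_vcf(cls, path: str | Path, label: str) -> "SnpSet":
        from cyvcf2 import VCF

        out = cls(label)
        for v in VCF(str(path)):
            for alt in v.ALT:
                is_indel = len(v.REF) != 1 or len(alt) != 1
                out.add(
                    SnpRecord(
                        transcript=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                        is_indel=is_indel,
                    )
                )
        return out


# ---------------------------------------------------------------------------
# Pileup construction and consensus calling


def build_pileups(
    read_pairs: Sequence[tuple[str, str, str]],
    assignments: Sequence[ReadAssignment],
    indices: dict[str, KmerIndex],
    transcriptomes: dict[str, AnnotatedTranscriptome],
) -> dict[str, np.ndarray]:
    """Ungapped base-count pileups per assigned transcript.

    Each assigned mate is anchored to its transcript by modal k-mer offset
    voting and contributes one base count per covered position.  Returns
    gene ID -> (length x 4) array of A/C/G/T counts.
    """
    by_id = {rid: (m1, m2) for rid, m1, m2 in read_pairs}
    pileups: dict[str, np.ndarray] = {}
    for a in assignments:
        if a.subgenome not in ("AT", "AA"):
            continue
        gene = a.gene
        assert gene is not None
        index = indices[a.subgenome]
        tlen = transcriptomes[a.subgenome].length(gene)
        if gene not in pileups:
            pileups[gene] = np.zeros((tlen, 4), dtype=np.int32)
        pile = pileups[gene]
        for mate in by_id[a.read_id]:
            placed = locate_ungapped(mate, index, gene)
            if placed is None:
                continue
            offset, oriented = placed
            for j, base in enumerate(oriented):
                pos = offset + j
                if 0 <= pos < tlen and base in _BASE_IDX:
                    pile[pos, _BASE_IDX[base]] += 1
    return pileups


def _phred_quality(alt_count: int, depth: int, err: float = 0.01) -> float:
    """Phred-scaled confidence that the alt pile is not sequencing error.

    Upper binomial tail of observing >= alt_count error bases among depth
    reads at per-base error rate ``err``, capped at 60.
    """
    p = stats.binom.sf(alt_count - 1, depth, err)
    if p <= 0:
        return 60.0
    return float(min(60.0, -10.0 * math.log10(p)))


def call_snps(
    pileups: dict[str, np.ndarray],
    reference: AnnotatedTranscriptome | dict[str, str],
    min_depth: int = 4,
    min_alt_frac: float = 0.9,
    label: str = "called",
) -> SnpSet:
    """Homozygous-consensus SNP calling from base-count pileups.

    A site is called when total depth >= ``min_depth`` and the most frequent
    non-reference base reaches fraction ``min_alt_frac`` of the depth.
    """
    refseqs = reference.records if isinstance(reference, AnnotatedTranscriptome) else reference
    out = SnpSet(label)
    for gene, pile in pileups.items():
        if gene not in refseqs:
            raise KeyError(f"reference transcript {gene!r} not found")
        seq = refseqs[gene]
        depth = pile.sum(axis=1)
        covered = np.nonzero(depth >= min_depth)[0]
        for pos in covered:
            ref_base = seq[pos]
            if ref_base not in _BASE_IDX:
                continue
            counts = pile[pos]
            alt_idx = int(np.argmax([c if i != _BASE_IDX[ref_base] else -1 for i, c in enumerate(counts)]))
            alt_count = int(counts[alt_idx])
            d = int(depth[pos])
            if alt_count / d >= min_alt_frac:
                out.add(
                    SnpRecord(
                        transcript=gene,
                        pos=int(pos) + 1,
                        ref=ref_base,
                        alt=_BASES[alt_idx],
                        qual=_phred_quality(alt_count, d),
                    )
                )
    return out


def filter_snps(snps: SnpSet, remove_indels: bool = True, min_quality: float = 30.0) -> SnpSet:
    """Drop indels and low-quality records (strictly greater-than retained)."""
    out = SnpSet(snps.label)
    for rec in snps:
        if remove_indels and rec.is_indel:
            continue
        if rec.qual <= min_quality:
            continue
        out.add(rec)
    return out


# ---------------------------------------------------------------------------
# Set partitioning


@dataclass
class PairwisePartition:
    shared: int
    a_only: int
    b_only: int

    @property
    def a_total(self) -> int:
        return self.shared + self.a_only

    @property
    def b_total(self) -> int:
        return self.shared + self.b_only


def partition_pairwise(a: SnpSet, b: SnpSet) -> PairwisePartition:
    """Disjoint shared / A-only / B-only partition by SNP key."""
    ka, kb = a.keys, b.keys
    return PairwisePartition(
        shared=len(ka & kb), a_only=len(ka - kb), b_only=len(kb - ka)
    )


@dataclass
class PanelPartition:
    """Six-cell partition of two accession SNP sets against a panel union.

    "In panel" means present in at least one panel member.  Private SNPs are
    the accession-only, not-in-panel cells.
    """

    shared_in_panel: int
    shared_not_panel: int
    a_only_in_panel: int
    a_only_not_panel: int  # private A
    b_only_in_panel: int
    b_only_not_panel: int  # private B

    @property
    def a_total(self) -> int:
        return (
            self.shared_in_panel + self.shared_not_panel
            + self.a_only_in_panel + self.a_only_not_panel
        )

    @property
    def b_total(self) -> int:
        return (
            self.shared_in_panel + self.shared_not_panel
            + self.b_only_in_panel + self.b_only_not_panel
        )

    @property
    def a_not_in_panel(self) -> int:
        return self.shared_not_panel + self.a_only_not_panel

    @property
    def b_not_in_panel(self) -> int:
        return self.shared_not_panel + self.b_only_not_panel

    def as_dict(self) -> dict[str, int]:
        return {
            "shared_in_panel": self.shared_in_panel,
            "shared_not_panel": self.shared_not_panel,
            "a_only_in_panel": self.a_only_in_panel,
            "a_only_not_panel": self.a_only_not_panel,
            "b_only_in_panel": self.b_only_in_panel,
            "b_only_not_panel": self.b_only_not_panel,
            "a_total": self.a_total,
            "b_total": self.b_total,
            "a_not_in_panel": self.a_not_in_panel,
            "b_not_in_panel": self.b_not_in_panel,
        }


def partition_with_panel(a: SnpSet, b: SnpSet, panel: SnpSet) -> PanelPartition:
    ka, kb, kp = a.keys, b.keys, panel.keys
    shared = ka & kb
    a_only = ka - kb
    b_only = kb - ka
    return PanelPartition(
        shared_in_panel=len(shared & kp),
        shared_not_panel=len(shared - kp),
        a_only_in_panel=len(a_only & kp),
        a_only_not_panel=len(a_only - kp),
        b_only_in_panel=len(b_only & kp),
        b_only_not_panel=len(b_only - kp),
    )


# ---------------------------------------------------------------------------
# Enrichment of SNPs in DEGs, and panel matching


def snp_deg_enrichment(
    total_snps: int,
    snps_in_degs: int,
    deg_bp: int,
    total_bp: int,
    method: str = "goodness_of_fit",
) -> tuple[float, int, float]:
    """Chi-square test of SNPs falling in DEG base pairs at the random rate.

    Default is the two-cell bp-weighted goodness-of-fit: expected in-DEG SNPs
    = total_snps * deg_bp / total_bp, expected outside = the remainder.
    ``method="contingency"`` instead tests a 2x2 SNP-vs-bp table (without
    continuity correction).  Returns (statistic, df, p).
    """
    if deg_bp > total_bp:
        raise ValueError("deg_bp cannot exceed total_bp")
    if snps_in_degs > total_snps:
        raise ValueError("snps_in_degs cannot exceed total_snps")
    if method == "goodness_of_fit":
        exp_in = total_snps * deg_bp / total_bp
        exp_out = total_snps - exp_in
        if exp_in == 0 or exp_out == 0:
            raise ValueError("zero expected cell; test undefined")
        obs_out = total_snps - snps_in_degs
        chi2 = (snps_in_degs - exp_in) ** 2 / exp_in + (obs_out - exp_out) ** 2 / exp_out
        df = 1
    elif method == "contingency":
        table = np.array(
            [
                [snps_in_degs, total_snps - snps_in_degs],
                [deg_bp - snps_in_degs, (total_bp - total_snps) - (deg_bp - snps_in_degs)],
            ]
        )
        chi2, _, df, _ = stats.chi2_contingency(table, correction=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


def match_accessions(query: SnpSet, members: Sequence[SnpSet]) -> pd.DataFrame:
    """Rank panel members by Jaccard similarity of SNP keys to the query.

    Ties are broken lexicographically by member label and flagged.
    """
    kq = query.keys
    rows = []
    for m in members:
        km = m.keys
        union = len(kq | km)
        score = len(kq & km) / union if union else 0.0
        rows.append((m.label, score))
    rows.sort(key=lambda r: (-r[1], r[0]))
    scores = Counter(s for _, s in rows)
    df = pd.DataFrame(rows, columns=["member", "score"])
    df["tied"] = [scores[s] > 1 for s in df["score"]]
    df["rank"] = range(1, len(df) + 1)
    return df
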