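"""Synthetic allopolyploid study generator with complete ground truth.

The simulator emulates the structure of a two-accession allopolyploid
RNA-seq experiment: two subgenomes whose homoeologous transcripts have
diverged to a configurable pairwise identity (~83% for the
*A. thaliana* / *A. arenosa*-proxy system), three biological replicates per
accession of 2x150 bp paired-end fragments, per-accession SNPs on the AT
subgenome with a shared core and private remainders (optionally planted into
a reference panel so every cell of the shared/private x in-panel/not-in-panel
partition has a known count), a heavy-tailed expression baseline with an
optional subgenome-wide dominance offset, and a small set of truly
differentially expressed genes enriched for coordinated homoeologous pairs.

Every stochastic choice flows from one seed; identical configuration and
seed give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .core import AnnotatedTranscriptome, HomoeologMap, revcomp
from .variation import SnpRecord, SnpSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe the full-scale study conditions (13,394 homoeolog
    pairs, three replicates of tens of millions of 150 PE fragments, ~83%
    homoeolog identity, ~2x subgenome dominance).  ``desk_scale`` returns a
    configuration small enough for interactive runs and tests.
    """

    n_pairs: int = 13394
    n_unpaired_per_subgenome: int = 0
    transcript_len_range: tuple[int, int] = (500, 2000)
    subgenome_divergence: float = 0.17
    accession_snp_rate: float = 0.005
    shared_snp_fraction: float = 0.724
    panel_size: int = 1135
    panel_shared_in_fraction: float = 0.75
    panel_private_in_fraction: float = 0.5
    panel_background_rate: float = 0.0005
    n_de_genes: int = 148
    n_coordinated_pairs: int = 21
    de_log2fc: float = 3.0
    dominance_log2: float = 1.0
    expr_log_mean: float = 3.0  # ln-scale location of the log-normal baseline
    expr_log_sigma: float = 1.2
    pair_log_sd: float = 0.3  # ln-scale deviation between homoeolog partners
    replicate_log_sd: float = 0.1  # ln-scale biological noise per replicate
    read_len: int = 150
    fragment_len_mean: float = 515.0
    fragment_len_sd: float = 50.0
    seq_error_rate: float = 0.001
    n_replicates: int = 3
    reads_per_sample: int = 34_000_000
    quality_range: tuple[float, float] = (20.0, 60.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.subgenome_divergence < 1.0):
            raise ValueError("subgenome_divergence must be in [0, 1)")
        if not (0.0 <= self.shared_snp_fraction <= 1.0):
            raise ValueError("shared_snp_fraction must be in [0, 1]")
        for name in (
            "n_pairs", "n_unpaired_per_subgenome", "panel_size", "n_de_genes",
            "n_coordinated_pairs", "n_replicates", "reads_per_sample",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_coordinated_pairs > self.n_de_genes / 2:
            raise ValueError("n_coordinated_pairs cannot exceed n_de_genes/2")
        if self.n_coordinated_pairs > self.n_pairs:
            raise ValueError("n_coordinated_pairs cannot exceed n_pairs")
        if self.transcript_len_range[0] > self.transcript_len_range[1]:
            raise ValueError("transcript_len_range must be (lo, hi) with lo <= hi")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """A small configuration preserving the study's structure.

        200 homoeolog pairs plus 20 unpaired genes per subgenome, 2x10^4
        fragments per sample: large enough for every downstream stage to
        have signal, small enough to run in seconds.
        """
        cfg = cls(
            n_pairs=200,
            n_unpaired_per_subgenome=20,
            transcript_len_range=(300, 900),
            panel_size=5,
            n_de_genes=30,
            n_coordinated_pairs=8,
            fragment_len_mean=300.0,
            fragment_len_sd=30.0,
            reads_per_sample=20_000,
            seed=seed,
        )
        return replace(cfg, **overrides)


ACCESSIONS = ("acc1", "acc2")


@dataclass
class TruthSet:
    """Everything the generator decided, for downstream truth comparison."""

    config: SimulationConfig
    at: AnnotatedTranscriptome
    aa: AnnotatedTranscriptome
    homoeolog_map: HomoeologMap
    accession_snps: dict[str, SnpSet]
    panel_snps: dict[str, SnpSet]
    expression: pd.DataFrame  # per-gene truth table
    accession_seqs: dict[str, dict[str, str]]  # accession -> gene -> sequence

    @property
    def de_truth(self) -> pd.DataFrame:
        return self.expression[self.expression["is_de"]]

    def validate(self) -> None:
        for gene in self.de_truth.index:
            if gene not in self.at and gene not in self.aa:
                raise AssertionError(f"DE-truth gene {gene} missing from transcriptomes")
        lengths = {**self.at.lengths(), **self.aa.lengths()}
        for acc_set in list(self.accession_snps.values()) + list(self.panel_snps.values()):
            for rec in acc_set:
                if rec.pos > lengths[rec.transcript]:
                    raise AssertionError(f"SNP beyond transcript end: {rec}")


# ---------------------------------------------------------------------------
# Subgenomes


def _per_copy_mutation_rate(divergence: float) -> float:
    """Per-site, per-copy substitution rate giving expected pairwise
    difference ``divergence`` when both homoeolog copies mutate independently.

    With rate m per copy and uniform choice among the three non-ancestral
    bases, two copies differ with probability 2m - (4/3)m^2; solving the
    quadratic for m accounts for coincident double hits.
    """
    if divergence == 0:
        return 0.0
    return (3.0 / 8.0) * (2.0 - math.sqrt(4.0 - 16.0 * divergence / 3.0))


def _random_seq_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate == 0:
        return codes.copy()
    mask = rng.random(codes.shape[0]) < rate
    out = codes.copy()
    # shift by 1..3 mod 4: uniform over the three other bases
    out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()), dtype=np.int8)) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def generate_subgenomes(
    config: SimulationConfig, rng: np.random.Generator | None = None, min_transcript_len: int = 21
) -> tuple[AnnotatedTranscriptome, AnnotatedTranscriptome, HomoeologMap]:
    """Two diverged subgenome transcript sets plus their homoeolog map.

    Each pair descends from a random ancestor sequence mutated independently
    in both copies (substitutions only) so expected pairwise identity is
    1 - subgenome_divergence.  Unpaired genes get novel sequences.
    """
    config.validate()
    lo, hi = config.transcript_len_range
    if lo < min_transcript_len:
        raise ValueError(
            f"transcript_len_range lower bound {lo} is below the downstream "
            f"k-mer size {min_transcript_len}; reads could not be indexed"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m = _per_copy_mutation_rate(config.subgenome_divergence)

    at_records: dict[str, str] = {}
    aa_records: dict[str, str] = {}
    rows: list[tuple[str, str, str]] = []
    for i in range(config.n_pairs):
        length = int(rng.integers(lo, hi + 1))
        anc = _random_seq_codes(rng, length)
        at_gene = f"AT_g{i:05d}"
        aa_gene = f"AA_g{i:05d}"
        at_records[at_gene] = _codes_to_str(_mutate_codes(anc, m, rng))
        aa_records[aa_gene] = _codes_to_str(_mutate_codes(anc, m, rng))
        rows.append((f"p{i:05d}", at_gene, aa_gene))
    for i in range(config.n_unpaired_per_subgenome):
        length = int(rng.integers(lo, hi + 1))
        at_records[f"AT_u{i:05d}"] = _codes_to_str(_random_seq_codes(rng, length))
        length = int(rng.integers(lo, hi + 1))
        aa_records[f"AA_u{i:05d}"] = _codes_to_str(_random_seq_codes(rng, length))

    at = AnnotatedTranscriptome(label="AT", records=at_records)
    aa = AnnotatedTranscriptome(label="AA", records=aa_records)
    return at, aa, HomoeologMap(rows=rows)


# ---------------------------------------------------------------------------
# Accession and panel variants


def _sample_distinct_sites(
    transcriptome: AnnotatedTranscriptome, n: int, rng: np.random.Generator,
    exclude: set[tuple[str, int]] | None = None,
) -> list[tuple[str, int]]:
    """n distinct (transcript, 1-based position) sites, length-weighted."""
    genes = list(transcriptome.records)
    lengths = np.array([transcriptome.length(g) for g in genes], dtype=np.int64)
    cum = np.cumsum(lengths)
    total = int(cum[-1]) if len(cum) else 0
    if n > total:
        raise ValueError("more SNP sites requested than transcriptome base pairs")
    chosen: set[tuple[str, int]] = set()
    banned = exclude or set()
    while len(chosen) < n:
        offsets = rng.integers(0, total, size=(n - len(chosen)) * 2 + 8)
        idx = np.searchsorted(cum, offsets, side="right")
        for o, gi in zip(offsets, idx):
            pos_in_gene = int(o - (cum[gi - 1] if gi > 0 else 0)) + 1
            site = (genes[int(gi)], pos_in_gene)
            if site not in banned and site not in chosen:
                chosen.add(site)
                if len(chosen) == n:
                    break
    out = sorted(chosen)
    rng.shuffle(out)
    return out


def _snp_at(
    transcriptome: AnnotatedTranscriptome,
    site: tuple[str, int],
    rng: np.random.Generator,
    qual_range: tuple[float, float],
) -> SnpRecord:
    gene, pos = site
    ref = transcriptome.records[gene][pos - 1]
    alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
    qual = float(rng.uniform(*qual_range))
    return SnpRecord(transcript=gene, pos=pos, ref=ref, alt=alt, qual=qual)


def plant_snp_partition(
    at: AnnotatedTranscriptome,
    cells: dict[str, int],
    panel_size: int,
    rng: np.random.Generator,
    qual_range: tuple[float, float] = (20.0, 60.0),
) -> tuple[SnpSet, SnpSet, list[SnpSet]]:
    """Construct accession SNP sets realizing exact partition cell counts.

    ``cells`` keys: shared_in_panel, shared_not_panel, a_only_in_panel,
    a_only_not_panel, b_only_in_panel, b_only_not_panel.  Each in-panel SNP is
    planted into one uniformly chosen panel member.
    """
    order = [
        "shared_in_panel", "shared_not_panel",
        "a_only_in_panel", "a_only_not_panel",
        "b_only_in_panel", "b_only_not_panel",
    ]
    counts = {k: int(cells.get(k, 0)) for k in order}
    total = sum(counts.values())
    sites = _sample_distinct_sites(at, total, rng)
    snp_a, snp_b = SnpSet("acc1"), SnpSet("acc2")
    panel = [SnpSet(f"panel{j:04d}") for j in range(panel_size)]
    it = iter(sites)
    for cell in order:
        for _ in range(counts[cell]):
            rec = _snp_at(at, next(it), rng, qual_range)
            if cell.startswith("shared"):
                snp_a.add(rec)
                snp_b.add(SnpRecord(rec.transcript, rec.pos, rec.ref, rec.alt,
                                    float(rng.uniform(*qual_range))))
            elif cell.startswith("a_only"):
                snp_a.add(rec)
            else:
                snp_b.add(rec)
            if cell.endswith("in_panel"):
                if panel_size == 0:
                    raise ValueError("in-panel cells require panel_size > 0")
                panel[int(rng.integers(0, panel_size))].add(
                    SnpRecord(rec.transcript, rec.pos, rec.ref, rec.alt,
                              float(rng.uniform(*qual_range)))
                )
    return snp_a, snp_b, panel


def generate_accession_variants(
    at: AnnotatedTranscriptome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, SnpSet], dict[str, SnpSet]]:
    """Per-accession SNP sets on the AT subgenome plus a reference panel.

    Each accession carries ``accession_snp_rate * total_bp`` substitutions:
    a core shared between the accessions (identical position and allele) and
    a private remainder.  Configured fractions of the shared and private
    categories are also planted into panel members, populating every cell of
    the shared/private x in-panel/not-in-panel partition with known counts.
    Panel members additionally carry background SNPs of their own at
    ``panel_background_rate`` (at sites disjoint from the accession SNPs).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n_per_acc = int(round(config.accession_snp_rate * at.total_bp))
    n_shared = int(round(config.shared_snp_fraction * n_per_acc))
    n_private = n_per_acc - n_shared
    cells = {
        "shared_in_panel": int(round(config.panel_shared_in_fraction * n_shared)),
        "a_only_in_panel": int(round(config.panel_private_in_fraction * n_private)),
        "b_only_in_panel": int(round(config.panel_private_in_fraction * n_private)),
    }
    cells["shared_not_panel"] = n_shared - cells["shared_in_panel"]
    cells["a_only_not_panel"] = n_private - cells["a_only_in_panel"]
    cells["b_only_not_panel"] = n_private - cells["b_only_in_panel"]
    if n_per_acc == 0:
        snp_a, snp_b = SnpSet("acc1"), SnpSet("acc2")
        panel = [SnpSet(f"panel{j:04d}") for j in range(config.panel_size)]
    else:
        snp_a, snp_b, panel = plant_snp_partition(
            at, cells, config.panel_size, rng, config.quality_range
        )
    # independent panel background, away from accession SNP sites
    occupied = {(r.transcript, r.pos) for r in snp_a} | {(r.transcript, r.pos) for r in snp_b}
    n_bg = int(round(config.panel_background_rate * at.total_bp))
    for member in panel:
        if n_bg == 0:
            break
        for site in _sample_distinct_sites(at, n_bg, rng, exclude=occupied):
            rec = _snp_at(at, site, rng, config.quality_range)
            if rec.key not in member:
                member.add(rec)
    return {"acc1": snp_a, "acc2": snp_b}, {m.label: m for m in panel}


# ---------------------------------------------------------------------------
# Expression truth


def generate_expression_truth(
    hmap: HomoeologMap,
    at: AnnotatedTranscriptome,
    aa: AnnotatedTranscriptome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene true mean expression for both accessions.

    Baselines are log-normal (heavy-tailed, FPKM-like) and correlated within
    a homoeologous pair: partners share a per-pair level and deviate from it
    by a smaller log-normal factor (``pair_log_sd``), as real homoeologs do.
    The AT subgenome is offset by ``dominance_log2`` doublings;
    ``n_de_genes`` genes receive a +/- ``de_log2fc`` accession effect,
    ``n_coordinated_pairs`` of the DE slots applied to both members of a
    homoeologous pair in the same direction.  Direction +1 means up in acc2.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    genes = list(at.records) + list(aa.records)
    n_genes = len(genes)
    if config.n_de_genes > n_genes:
        raise ValueError("n_de_genes exceeds gene count")
    sub = ["AT"] * len(at.records) + ["AA"] * len(aa.records)
    lengths = [at.length(g) for g in at.records] + [aa.length(g) for g in aa.records]
    pair_level = {
        pid: rng.lognormal(config.expr_log_mean, config.expr_log_sigma)
        for pid, _, _ in hmap
    }
    pair_of = hmap.pair_of
    base = np.empty(n_genes)
    for i, g in enumerate(genes):
        if g in pair_of:
            base[i] = pair_level[pair_of[g]] * rng.lognormal(0.0, config.pair_log_sd)
        else:
            base[i] = rng.lognormal(config.expr_log_mean, config.expr_log_sigma)
    dom = np.where(np.array(sub) == "AT", 2.0 ** config.dominance_log2, 1.0)
    baseline = base * dom

    pair_of = hmap.pair_of
    df = pd.DataFrame(
        {
            "subgenome": sub,
            "length": lengths,
            "pair_id": [pair_of.get(g, "") for g in genes],
            "baseline": baseline,
        },
        index=pd.Index(genes, name="gene"),
    )
    direction = pd.Series(0, index=df.index, dtype=int)
    coordinated = pd.Series(False, index=df.index)

    effective_fc = config.de_log2fc != 0
    if effective_fc and config.n_de_genes > 0:
        pair_rows = list(hmap.rows)
        chosen_pair_idx = rng.choice(len(pair_rows), size=config.n_coordinated_pairs, replace=False) \
            if config.n_coordinated_pairs else np.array([], dtype=int)
        used: set[str] = set()
        for pi in chosen_pair_idx:
            _, at_gene, aa_gene = pair_rows[int(pi)]
            d = 1 if rng.random() < 0.5 else -1
            direction[at_gene] = d
            direction[aa_gene] = d
            coordinated[at_gene] = True
            coordinated[aa_gene] = True
            used.update((at_gene, aa_gene))
        n_singles = config.n_de_genes - 2 * config.n_coordinated_pairs
        partner = hmap.partner_of
        pool = [g for g in genes if g not in used]
        rng.shuffle(pool)
        picked = 0
        blocked: set[str] = set()
        for g in pool:
            if picked == n_singles:
                break
            if g in blocked:
                continue
            direction[g] = 1 if rng.random() < 0.5 else -1
            if g in partner:
                blocked.add(partner[g])  # keep singleton DEGs true singletons
            picked += 1
        if picked < n_singles:
            raise ValueError("not enough eligible genes for requested singleton DEGs")

    fc = 2.0 ** (direction.to_numpy() * config.de_log2fc)
    df["expr_acc1"] = df["baseline"]
    df["expr_acc2"] = df["baseline"] * fc
    df["direction"] = direction
    df["is_de"] = direction != 0
    df["coordinated"] = coordinated
    return df


# ---------------------------------------------------------------------------
# Reads


def _apply_snps(seq: str, snps: list[SnpRecord]) -> str:
    arr = list(seq)
    for rec in snps:
        if arr[rec.pos - 1] != rec.ref:
            raise AssertionError("SNP ref does not match reference sequence")
        arr[rec.pos - 1] = rec.alt
    return "".join(arr)


def accession_sequences(
    at: AnnotatedTranscriptome,
    aa: AnnotatedTranscriptome,
    accession_snps: dict[str, SnpSet],
) -> dict[str, dict[str, str]]:
    """Accession transcript sequences: AT reference with SNPs applied, AA as is."""
    out: dict[str, dict[str, str]] = {}
    for acc, snpset in accession_snps.items():
        by_gene: dict[str, list[SnpRecord]] = {}
        for rec in snpset:
            by_gene.setdefault(rec.transcript, []).append(rec)
        seqs = dict(aa.records)
        for gene, seq in at.records.items():
            seqs[gene] = _apply_snps(seq, by_gene.get(gene, []))
        out[acc] = seqs
    return out


def simulate_fragment_counts(
    expression: pd.DataFrame,
    accession: str,
    n_fragments: int,
    rng: np.random.Generator,
    replicate_log_sd: float = 0.0,
) -> pd.Series:
    """Multinomial fragment counts with probabilities ∝ expression x length.

    ``replicate_log_sd`` adds per-gene log-normal jitter to the expression
    means before sampling — the biological variability that distinguishes
    replicates of the same accession.
    """
    expr = expression[f"expr_{accession}"].to_numpy()
    if replicate_log_sd > 0:
        expr = expr * rng.lognormal(0.0, replicate_log_sd, size=expr.shape)
    w = expr * expression["length"].to_numpy()
    p = w / w.sum()
    counts = rng.multinomial(n_fragments, p)
    return pd.Series(counts, index=expression.index, name=accession)


def simulate_reads(
    truth: TruthSet,
    accession: str,
    replicate: int,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Paired reads for one sample plus the read-origin truth table.

    Fragment counts per gene are multinomial ∝ expression x length, fragment
    lengths Gaussian (clipped to [read_len, transcript length]); when a
    transcript is shorter than the read length both mates are the whole
    fragment (overlapping-mates policy).  Read names carry only a serial;
    truth lives in the origin table.  Deterministic given config seed,
    accession and replicate.
    """
    cfg = truth.config
    acc_idx = ACCESSIONS.index(accession)
    rng = np.random.default_rng([cfg.seed, 7, acc_idx, replicate])
    counts = simulate_fragment_counts(
        truth.expression, accession, cfg.reads_per_sample, rng, cfg.replicate_log_sd
    )
    seqs = truth.accession_seqs[accession]
    sub_of = truth.expression["subgenome"]
    sample = f"{accession}_r{replicate}"
    fragments: list[tuple[str, str, str]] = []
    origin: list[tuple[str, str, str]] = []
    serial = 0
    err = cfg.seq_error_rate

    def _errorify(s: str) -> str:
        if err == 0 or not s:
            return s
        n_err = rng.binomial(len(s), err)
        if n_err == 0:
            return s
        arr = list(s)
        for i in rng.choice(len(s), size=n_err, replace=False):
            arr[i] = "ACGT"[("ACGT".index(arr[i]) + int(rng.integers(1, 4))) % 4]
        return "".join(arr)

    for gene, c in counts.items():
        if c == 0:
            continue
        seq = seqs[gene]
        L = len(seq)
        flens = np.clip(
            np.rint(rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd, size=c)).astype(int),
            min(cfg.read_len, L),
            L,
        )
        starts = (rng.random(c) * (L - flens + 1)).astype(int)
        for flen, start in zip(flens, starts):
            frag = seq[start : start + flen]
            if flen < cfg.read_len:
                m1, m2 = frag, revcomp(frag)
            else:
                m1 = frag[: cfg.read_len]
                m2 = revcomp(frag[-cfg.read_len :])
            if rng.random() < 0.5:
                m1, m2 = m2, m1
            rid = f"{sample}:{serial:08d}"
            serial += 1
            fragments.append((rid, _errorify(m1), _errorify(m2)))
            origin.append((rid, sub_of[gene], gene))
    origin_df = pd.DataFrame(origin, columns=["read_id", "subgenome", "gene"])
    return fragments, origin_df


def iter_samples(config: SimulationConfig) -> Iterator[tuple[str, int, str]]:
    """(accession, replicate, sample_id) for every sample of the study."""
    for acc in ACCESSIONS:
        for rep in range(1, config.n_replicates + 1):
            yield acc, rep, f"{acc}_r{rep}"


def simulate_study(config: SimulationConfig) -> TruthSet:
    """Generate the full study truth (reads are produced per sample on demand)."""
    config.validate()
    at, aa, hmap = generate_subgenomes(config, np.random.default_rng(config.seed))
    acc_snps, panel_snps = generate_accession_variants(
        at, config, np.random.default_rng([config.seed, 1])
    )
    expression = generate_expression_truth(
        hmap, at, aa, config, np.random.default_rng([config.seed, 2])
    )
    truth = TruthSet(
        config=config,
        at=at,
        aa=aa,
        homoeolog_map=hmap,
        accession_snps=acc_snps,
        panel_snps=panel_snps,
        expression=expression,
        accession_seqs=accession_sequences(at, aa, acc_snps),
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# File output


def write_fastq(fragments: list[tuple[str, str, str]], path1: str | Path, path2: str | Path) -> None:
    """4-line FASTQ records, Phred+33, constant quality (assigner ignores it)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, m1, m2 in fragments:
            f1.write(f"@{rid}/1\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{rid}/2\n{m2}\n+\n{'I' * len(m2)}\n")


def write_study(truth: TruthSet, outdir: str | Path, with_reads: bool = True) -> None:
    """Materialize the study as FASTA/FASTQ/TSV/VCF under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.at.to_fasta(out / "subgenome_AT.fasta")
    truth.aa.to_fasta(out / "subgenome_AA.fasta")
    truth.homoeolog_map.to_tsv(out / "homoeolog_map.tsv")
    truth.expression.to_csv(out / "expression_truth.tsv", sep="\t")
    for acc, snpset in truth.accession_snps.items():
        snpset.to_vcf(out / f"snps_{acc}.vcf")
    for label, snpset in truth.panel_snps.items():
        snpset.to_vcf(out / f"panel_{label}.vcf")
    if with_reads:
        for acc, rep, sample in iter_samples(truth.config):
            fragments, origin = simulate_reads(truth, acc, rep)
            write_fastq(fragments, out / f"{sample}_1.fastq", out / f"{sample}_2.fastq")
            origin.to_csv(out / f"{sample}_origin.tsv", sep="\t", index=False)
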