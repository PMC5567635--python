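"""End-to-end orchestration: simulate -> assign -> quantify -> statistics.

``run_pipeline`` executes every stage in order and assembles a
machine-readable ``StudyReport`` whose sections mirror the study's summary
figures as tables: the DEG pair decomposition and its arithmetic identities,
direction percentages, the pair-enrichment permutation result, direction
concordance, subgenome dominance ratios, the SNP pairwise and panel
partitions, the SNP-in-DEG chi-square, and a term-enrichment table.
Config plus seed fully determine the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, enrichment, expression, homeostats, synthsim, variation
from .core import AnnotatedTranscriptome, HomoeologMap
from .subassign import (
    DEFAULT_K,
    DEFAULT_MIN_MARGIN,
    assign_sample,
    build_index,
    count_fragments,
)

logger = logging.getLogger(__name__)

MODES = ("simulate", "from-fastq", "from-alignments")


@dataclass
class PipelineConfig:
    mode: str = "simulate"
    sim: synthsim.SimulationConfig = field(default_factory=synthsim.SimulationConfig.desk_scale)
    k: int = DEFAULT_K
    min_margin: int = DEFAULT_MIN_MARGIN
    de_alpha: float = 0.05
    permutation_replicates: int = 100_000
    snp_min_depth: int = 4
    snp_min_alt_frac: float = 0.9
    snp_min_quality: float = 30.0
    n_terms: int = 40
    genes_per_term: int = 15
    n_deg_biased_terms: int = 10
    seed: int = 0
    outdir: str | None = None
    # from-fastq / from-alignments inputs
    inputs: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.sim.validate()

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Serializable summary of one pipeline run."""

    pair_join: dict[str, int]
    direction: dict[str, float]
    permutation: dict[str, Any] | None
    concordance: dict[str, Any] | None
    ratios: dict[str, dict[str, Any]]
    snp_pairwise: dict[str, int] | None
    snp_partition: dict[str, int] | None
    snp_chi2: dict[str, Any] | None
    enrichment_table: list[dict[str, Any]]
    provenance: dict[str, Any]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyReport":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _synthetic_annotations(
    universe: list[str], degs: list[str], config: PipelineConfig
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Random term->gene annotations with a few DEG-biased terms.

    Stand-in for a curated ontology: terms annotate random universe genes;
    ``n_deg_biased_terms`` draw half their genes from the DEG set so the
    enrichment stage has true positives to find.  Categories cycle through
    the four stress classes.
    """
    rng = np.random.default_rng([config.seed, 11])
    ann: dict[str, set[str]] = {}
    cats: dict[str, str] = {}
    cat_cycle = list(enrichment.CATEGORIES)
    for i in range(config.n_terms):
        term = f"TERM:{i:04d}"
        gpt = min(config.genes_per_term, len(universe))
        if i < config.n_deg_biased_terms and degs:
            n_deg_part = min(gpt // 2, len(degs))
            picked = set(rng.choice(degs, size=n_deg_part, replace=False))
            rest = [g for g in universe if g not in picked]
            picked |= set(rng.choice(rest, size=gpt - n_deg_part, replace=False))
        else:
            picked = set(rng.choice(universe, size=gpt, replace=False))
        ann[term] = picked
        cats[term] = cat_cycle[i % len(cat_cycle)]
    return ann, cats


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str) -> None:
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute all stages for the configured mode and assemble the report."""
    config.validate()
    t0 = time.time()
    if config.mode != "simulate":
        return _run_external(config)

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name: str):
        logger.info("stage %-12s t=%.1fs", name, time.time() - t0)

    try:
        _stage("simulate")
        truth = synthsim.simulate_study(config.sim)
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("simulate", str(e)) from e

    _stage("assign")
    idx_at = build_index(truth.at, config.k)
    idx_aa = build_index(truth.aa, config.k)
    per_sample = []
    groups = {}
    snp_reads: dict[str, tuple] = {}
    for acc, rep, sample in synthsim.iter_samples(config.sim):
        fragments, _ = synthsim.simulate_reads(truth, acc, rep)
        assignments = assign_sample(fragments, idx_at, idx_aa, config.min_margin)
        per_sample.append(count_fragments(assignments, sample))
        groups[sample] = acc
        if rep == 1:  # one replicate per accession feeds SNP calling
            snp_reads[acc] = (fragments, assignments)

    _stage("quantify")
    matrix = expression.matrix_from_counts(
        per_sample, {"AT": truth.at, "AA": truth.aa}, groups
    )
    de = expression.differential_expression(matrix, "acc1", "acc2", alpha=config.de_alpha)
    degs = expression.significant_degs(de)
    direction = expression.direction_summary(degs)

    _stage("pair-stats")
    pj = homeostats.join_pairs(degs, truth.homoeolog_map)
    universe = list(de.index)  # quantified universe: every tested gene
    permutation = None
    if pj.n_pairs <= len(degs) // 2 and len(degs) <= len(universe) and len(degs) > 0:
        perm = homeostats.pair_enrichment_permutation(
            universe,
            truth.homoeolog_map,
            n_draw=len(degs),
            observed_pairs=pj.n_pairs,
            replicates=config.permutation_replicates,
            seed=config.seed,
        )
        permutation = {
            "observed": perm.observed,
            "replicates": perm.replicates,
            "p": perm.p,
            "null_max": perm.null_max,
            "histogram_mass": sum(perm.histogram.values()),
        }
    conc = homeostats.direction_concordance(pj)

    _stage("dominance")
    ratios = {}
    for acc in synthsim.ACCESSIONS:
        rs = expression.subgenome_ratio(matrix, truth.homoeolog_map, acc)
        ratios[acc] = {
            "n_pairs": rs.n_pairs,
            "n_analyzed": rs.n_analyzed,
            "n_excluded": rs.n_excluded,
            "mean_log2_at_over_aa": rs.mean,
            "median_log2_at_over_aa": rs.median,
        }

    _stage("snp-call")
    called: dict[str, variation.SnpSet] = {}
    indices = {"AT": idx_at, "AA": idx_aa}
    transcriptomes = {"AT": truth.at, "AA": truth.aa}
    for acc, (fragments, assignments) in snp_reads.items():
        at_assign = [a for a in assignments if a.subgenome == "AT"]
        piles = variation.build_pileups(fragments, at_assign, indices, transcriptomes)
        raw = variation.call_snps(
            piles, truth.at, config.snp_min_depth, config.snp_min_alt_frac, label=acc
        )
        called[acc] = variation.filter_snps(
            raw, remove_indels=True, min_quality=config.snp_min_quality
        )
    pairwise = variation.partition_pairwise(called["acc1"], called["acc2"])
    panel_union = variation.SnpSet("panel")
    for member in truth.panel_snps.values():
        panel_union = panel_union.union(member, label="panel")
    panel_part = variation.partition_with_panel(called["acc1"], called["acc2"], panel_union)

    # chi-square: SNPs differing between accessions vs DEG base-pair share
    between = (called["acc1"].keys | called["acc2"].keys) - (
        called["acc1"].keys & called["acc2"].keys
    )
    at_deg_genes = set(degs.index[degs["subgenome"] == "AT"])
    deg_bp = int(sum(truth.at.length(g) for g in at_deg_genes))
    total_bp = truth.at.total_bp
    in_deg = sum(1 for (t, _, _) in between if t in at_deg_genes)
    chi2_result = None
    if between and 0 < deg_bp < total_bp:
        chi2, df, p = variation.snp_deg_enrichment(len(between), in_deg, deg_bp, total_bp)
        chi2_result = {
            "total_snps": len(between), "snps_in_degs": in_deg,
            "deg_bp": deg_bp, "total_bp": total_bp,
            "chi2": chi2, "df": df, "p": p,
        }

    _stage("enrichment")
    ann, cats = _synthetic_annotations(universe, list(degs.index), config)
    rows = enrichment.fisher_enrichment(degs.index, universe, ann)
    reported = enrichment.filter_terms(rows)
    reported = reported.assign(category=[cats[t] for t in reported["term"]])

    report = StudyReport(
        pair_join={
            "at_only": pj.at_only, "aa_only": pj.aa_only, "pairs": pj.n_pairs,
            "total": pj.total, "at_total": pj.at_total, "aa_total": pj.aa_total,
        },
        direction=direction,
        permutation=permutation,
        concordance={"concordant": conc.concordant, "discordant": conc.discordant, "p": conc.p},
        ratios=ratios,
        snp_pairwise={
            "shared": pairwise.shared, "a_only": pairwise.a_only, "b_only": pairwise.b_only,
            "a_total": pairwise.a_total, "b_total": pairwise.b_total,
        },
        snp_partition=panel_part.as_dict(),
        snp_chi2=chi2_result,
        enrichment_table=reported.to_dict("records"),
        provenance={
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "mode": config.mode,
        },
    )
    if outdir:
        report.to_json(outdir / "study_report.json")
        de.to_csv(outdir / "differential_expression.tsv", sep="\t")
        matrix.fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
        matrix.counts.to_csv(outdir / "counts.tsv", sep="\t")
        pj.pair_rows.to_csv(outdir / "deg_pairs.tsv", sep="\t", index=False)
        reported.to_csv(outdir / "enriched_terms.tsv", sep="\t", index=False)
    _stage("done")
    return report


def _run_external(config: PipelineConfig) -> StudyReport:
    """from-fastq / from-alignments modes: expression and pair stages only.

    Inputs (config.inputs): "ref_at"/"ref_aa" FASTA paths, "map" homoeolog
    map TSV, and either "fastq" = {sample: (fq1, fq2)} with "groups" =
    {sample: group}, or "counts" = {sample: {gene: count}}.  Variant and
    enrichment sections require user-called VCFs and annotations and are left
    empty here.
    """
    from Bio import SeqIO

    inp = config.inputs
    try:
        at = AnnotatedTranscriptome.from_fasta(inp["ref_at"], "AT")
        aa = AnnotatedTranscriptome.from_fasta(inp["ref_aa"], "AA")
        hmap = HomoeologMap.from_tsv(inp["map"])
    except KeyError as e:
        raise StageError("inputs", f"missing input {e}") from e
    hmap.validate_against(at, aa)
    idx_at = build_index(at, config.k)
    idx_aa = build_index(aa, config.k)
    groups = dict(inp["groups"])
    per_sample = []
    if config.mode == "from-fastq":
        for sample, (fq1, fq2) in inp["fastq"].items():
            r1 = list(SeqIO.parse(str(fq1), "fastq"))
            r2 = list(SeqIO.parse(str(fq2), "fastq"))
            fragments = [
                (a.id.rsplit("/", 1)[0], str(a.seq), str(b.seq)) for a, b in zip(r1, r2)
            ]
            assignments = assign_sample(fragments, idx_at, idx_aa, config.min_margin)
            per_sample.append(count_fragments(assignments, sample))
    else:
        from .subassign import GeneCounts

        sub_of = {g: "AT" for g in at.records} | {g: "AA" for g in aa.records}
        for sample, counts in inp["counts"].items():
            gc = GeneCounts(sample_id=sample, counts=dict(counts),
                            subgenome_of={g: sub_of[g] for g in counts})
            per_sample.append(gc)
    matrix = expression.matrix_from_counts(per_sample, {"AT": at, "AA": aa}, groups)
    g1, g2 = sorted(set(groups.values()))
    de = expression.differential_expression(matrix, g1, g2, alpha=config.de_alpha)
    degs = expression.significant_degs(de)
    pj = homeostats.join_pairs(degs, hmap)
    conc = homeostats.direction_concordance(pj)
    ratios = {}
    for grp in (g1, g2):
        rs = expression.subgenome_ratio(matrix, hmap, grp)
        ratios[grp] = {
            "n_pairs": rs.n_pairs, "n_analyzed": rs.n_analyzed,
            "n_excluded": rs.n_excluded, "mean_log2_at_over_aa": rs.mean,
            "median_log2_at_over_aa": rs.median,
        }
    return StudyReport(
        pair_join={
            "at_only": pj.at_only, "aa_only": pj.aa_only, "pairs": pj.n_pairs,
            "total": pj.total, "at_total": pj.at_total, "aa_total": pj.aa_total,
        },
        direction=expression.direction_summary(degs),
        permutation=None,
        concordance={"concordant": conc.concordant, "discordant": conc.discordant, "p": conc.p},
        ratios=ratios,
        snp_pairwise=None,
        snp_partition=None,
        snp_chi2=None,
        enrichment_table=[],
        provenance={
            "config_digest": config.digest(), "seed": config.seed,
            "version": __version__, "mode": config.mode,
        },
    )


def verify_report(report: StudyReport) -> list[tuple[str, bool, str]]:
    """Arithmetic identity checks over a report; empty sections pass vacuously."""
    checks: list[tuple[str, bool, str]] = []
    pj = report.pair_join
    checks.append((
        "deg_total_identity",
        pj["total"] == pj["at_only"] + pj["aa_only"] + 2 * pj["pairs"],
        f"{pj['total']} vs {pj['at_only']}+{pj['aa_only']}+2*{pj['pairs']}",
    ))
    checks.append((
        "subgenome_totals",
        pj["at_total"] == pj["at_only"] + pj["pairs"]
        and pj["aa_total"] == pj["aa_only"] + pj["pairs"],
        "per-subgenome DEG totals = only + pairs",
    ))
    d = report.direction
    if d.get("n", 0) > 0:
        ok = abs(d["pct_up_in_1"] + d["pct_up_in_2"] - 100) <= 1  # integer rounding
        checks.append(("direction_percentages", ok, f"{d['pct_up_in_1']}+{d['pct_up_in_2']}"))
    else:
        checks.append(("direction_percentages", True, "warning: no DEGs"))
    if report.permutation is not None:
        perm = report.permutation
        checks.append((
            "permutation_mass",
            perm["histogram_mass"] == perm["replicates"],
            f"{perm['histogram_mass']} vs {perm['replicates']}",
        ))
    else:
        checks.append(("permutation_mass", True, "warning: section absent"))
    for grp, r in report.ratios.items():
        checks.append((
            f"ratio_accounting_{grp}",
            r["n_analyzed"] + r["n_excluded"] == r["n_pairs"],
            f"{r['n_analyzed']}+{r['n_excluded']} vs {r['n_pairs']}",
        ))
    if report.snp_partition is not None:
        sp = report.snp_partition
        ok = (
            sp["a_total"] == sp["shared_in_panel"] + sp["shared_not_panel"]
            + sp["a_only_in_panel"] + sp["a_only_not_panel"]
            and sp["b_total"] == sp["shared_in_panel"] + sp["shared_not_panel"]
            + sp["b_only_in_panel"] + sp["b_only_not_panel"]
            and sp["a_not_in_panel"] == sp["shared_not_panel"] + sp["a_only_not_panel"]
            and sp["b_not_in_panel"] == sp["shared_not_panel"] + sp["b_only_not_panel"]
        )
        checks.append(("partition_marginals", ok, "six cells vs derived totals"))
    else:
        checks.append(("partition_marginals", True, "warning: section absent"))
    return checks
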