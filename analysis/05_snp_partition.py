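"""Call SNPs from subgenome-assigned reads and partition them.

For one replicate per accession: assign reads, anchor the AT-assigned mates
to their transcripts, call SNPs by homozygous consensus, filter
(quality > 30, no indels), then compute the pairwise accession partition,
the six-cell partition against the panel union, the chi-square test for SNP
enrichment in DEG base pairs, and the panel similarity ranking.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_truth  # noqa: E402

from homeopipe import subassign, synthsim, variation  # noqa: E402


def main() -> None:
    truth = load_truth()
    idx = {
        "AT": subassign.build_index(truth.at, 21),
        "AA": subassign.build_index(truth.aa, 21),
    }
    tr = {"AT": truth.at, "AA": truth.aa}

    called = {}
    for acc in synthsim.ACCESSIONS:
        fragments, _ = synthsim.simulate_reads(truth, acc, 1)
        assignments = subassign.assign_sample(fragments, idx["AT"], idx["AA"])
        piles = variation.build_pileups(
            fragments, [a for a in assignments if a.subgenome == "AT"], idx, tr
        )
        raw = variation.call_snps(piles, truth.at, label=acc)
        called[acc] = variation.filter_snps(raw, remove_indels=True, min_quality=30.0)
        planted = truth.accession_snps[acc]
        tp = len(called[acc].keys & planted.keys)
        print(f"{acc}: called {len(called[acc])} SNPs "
              f"({tp} of {len(planted)} planted recovered, "
              f"{len(called[acc]) - tp} spurious)")

    pw = variation.partition_pairwise(called["acc1"], called["acc2"])
    print(f"pairwise: shared {pw.shared}, acc1-only {pw.a_only}, acc2-only {pw.b_only} "
          f"(totals {pw.a_total} / {pw.b_total})")

    panel = variation.SnpSet("panel")
    for member in truth.panel_snps.values():
        panel = panel.union(member, label="panel")
    part = variation.partition_with_panel(called["acc1"], called["acc2"], panel)
    cells = part.as_dict()
    pd.Series(cells).to_csv(RESULTS / "snp_partition.tsv", sep="\t", header=False)
    print("panel partition cells:", cells)

    de = pd.read_csv(RESULTS / "differential_expression.tsv", sep="\t", index_col=0)
    deg_at = set(de.index[(de["significant"]) & (de["subgenome"] == "AT")])
    between = (called["acc1"].keys | called["acc2"].keys) - (
        called["acc1"].keys & called["acc2"].keys
    )
    deg_bp = sum(truth.at.length(g) for g in deg_at)
    in_deg = sum(1 for t, _, _ in between if t in deg_at)
    if between and 0 < deg_bp < truth.at.total_bp:
        chi2, df, p = variation.snp_deg_enrichment(
            len(between), in_deg, deg_bp, truth.at.total_bp
        )
        print(f"SNPs in DEGs: {in_deg}/{len(between)} over {deg_bp}/{truth.at.total_bp} bp "
              f"-> chi2({df}) = {chi2:.3f}, p = {p:.3f}")

    ranking = variation.match_accessions(called["acc1"], list(truth.panel_snps.values()))
    ranking.to_csv(RESULTS / "panel_matching.tsv", sep="\t", index=False)
    print("closest panel members to acc1:")
    print(ranking.head(3).to_string(index=False))


if __name__ == "__main__":
    main()
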