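"""Differential expression between the two accessions, plus dominance ratios.

Reads the FPKM/count matrices written by 02, runs the per-gene t-test with
BH correction, summarizes DEG directions, recovers the subgenome dominance
ratio per accession, and writes the DEG table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_truth  # noqa: E402

from homeopipe import expression, synthsim  # noqa: E402


def main() -> None:
    truth = load_truth()
    counts = pd.read_csv(RESULTS / "counts.tsv", sep="\t", index_col=0)
    fpkm = pd.read_csv(RESULTS / "fpkm.tsv", sep="\t", index_col=0)
    groups = {s: s.split("_")[0] for s in counts.columns}
    meta = truth.expression[["subgenome", "length"]]
    matrix = expression.ExpressionMatrix(
        counts=counts, fpkm=fpkm, groups=groups, gene_meta=meta
    )

    de = expression.differential_expression(matrix, "acc1", "acc2", alpha=0.05)
    degs = expression.significant_degs(de)
    summary = expression.direction_summary(degs)
    true_de = set(truth.expression.index[truth.expression["is_de"]])
    found = set(degs.index)

    de.to_csv(RESULTS / "differential_expression.tsv", sep="\t", float_format="%.6g")
    print(f"tested {len(de)} genes; {len(degs)} significant at q<=0.05")
    print(f"  up in acc2: {summary['up_in_2']} ({summary['pct_up_in_2']}%), "
          f"up in acc1: {summary['up_in_1']} ({summary['pct_up_in_1']}%)")
    print(f"  vs planted truth ({len(true_de)} DE genes): "
          f"TP={len(found & true_de)} FP={len(found - true_de)} FN={len(true_de - found)}")
    for acc in synthsim.ACCESSIONS:
        rs = expression.subgenome_ratio(matrix, truth.homoeolog_map, acc)
        print(f"  {acc} dominance: mean log2(AT/AA) = {rs.mean:+.3f} "
              f"(median {rs.median:+.3f}; {rs.n_excluded} zero-FPKM pairs excluded; "
              f"truth {truth.config.dominance_log2:+.1f})")


if __name__ == "__main__":
    main()
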