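"""Fisher term enrichment of the DEG set with stress categorization.

Builds a synthetic term->gene annotation (some terms deliberately biased
toward the DEG set), runs one-sided Fisher tests against the quantified
universe, applies the p < .05 / >= 2 genes reporting filter, and assigns
stress categories to the annotated DEGs.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, STUDY_SEED  # noqa: E402

from homeopipe import enrichment  # noqa: E402


def main() -> None:
    de = pd.read_csv(RESULTS / "differential_expression.tsv", sep="\t", index_col=0)
    universe = list(de.index)
    degs = list(de.index[de["significant"]])

    rng = np.random.default_rng(STUDY_SEED)
    categories = {}
    ann = {}
    cat_cycle = list(enrichment.CATEGORIES)
    for i in range(40):
        term = f"TERM:{i:04d}"
        if i < 10 and degs:  # DEG-biased terms: true enrichment to find
            half = min(7, len(degs))
            genes = set(rng.choice(degs, size=half, replace=False))
            genes |= set(rng.choice(universe, size=15 - half, replace=False))
        else:
            genes = set(rng.choice(universe, size=15, replace=False))
        ann[term] = genes
        categories[term] = cat_cycle[i % len(cat_cycle)]

    rows = enrichment.fisher_enrichment(degs, universe, ann)
    reported = enrichment.filter_terms(rows)
    reported = reported.assign(category=[categories[t] for t in reported["term"]])
    reported.to_csv(RESULTS / "enriched_terms.tsv", sep="\t", index=False)

    gene_cats = enrichment.categorize_genes(reported, ann, categories, degs)
    counts = pd.Series(gene_cats).value_counts()

    print(f"tested {len(rows)} terms against {len(degs)} DEGs in a "
          f"{len(universe)}-gene universe")
    print(f"reported (p<.05, >=2 DEG genes): {len(reported)} terms")
    if len(reported):
        print(reported.head(10).to_string(index=False))
    print("DEG stress categories:", counts.to_dict())
    print(f"written: {RESULTS/'enriched_terms.tsv'}")


if __name__ == "__main__":
    main()
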