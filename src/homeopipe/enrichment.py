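"""Term over-representation in DEG sets by one-sided Fisher's exact test.

Per term, the p-value is the upper hypergeometric tail of drawing at least
the observed number of term-annotated genes into a DEG set of the observed
size from the universe.  P-values are reported uncorrected; the reporting
filter keeps terms with p < 0.05 and at least two annotated genes in the DEG
set.  Significant terms can carry a stress category (not-stress, abiotic,
biotic, general); a gene annotated with a mixture of distinct stress
categories collapses to "general".
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ("not-stress", "abiotic", "biotic", "general")
STRESS_CATEGORIES = ("abiotic", "biotic", "general")


def fisher_enrichment(
    deg: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher test per term.

    ``annotations`` maps term ID -> annotated gene IDs; genes outside the
    universe are ignored.  Terms with zero universe annotation are skipped
    with a log entry.  Returns term, in-DEG count, DEG size, universe
    annotated count, universe size, p.
    """
    uni = set(universe)
    degset = set(deg)
    if not degset <= uni:
        raise ValueError("DEG set must be a subset of the universe")
    N, n = len(uni), len(degset)
    rows = []
    for term, genes in annotations.items():
        ann = genes & uni
        K = len(ann)
        if K == 0:
            logger.info("term %s has no universe annotation; skipped", term)
            continue
        k = len(ann & degset)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, p))
    return pd.DataFrame(
        rows, columns=["term", "in_deg", "deg_size", "annotated", "universe", "p"]
    )


def filter_terms(rows: pd.DataFrame, alpha: float = 0.05, min_genes: int = 2) -> pd.DataFrame:
    """Reporting filter: p strictly below alpha AND >= min_genes in the DEG set."""
    return rows[(rows["p"] < alpha) & (rows["in_deg"] >= min_genes)].reset_index(drop=True)


def categorize_genes(
    reported: pd.DataFrame,
    annotations: Mapping[str, set[str]],
    term_category: Mapping[str, str],
    deg: Iterable[str],
) -> dict[str, str]:
    """Stress category per DEG annotated with a reported term.

    A gene's category is that of its reported terms; any combination of
    distinct stress categories (abiotic, biotic, general) collapses to
    "general"; genes with only not-stress terms stay "not-stress".  Genes
    with no reported term are absent from the output.
    """
    degset = set(deg)
    cats_of: dict[str, set[str]] = {}
    for term in reported["term"]:
        cat = term_category.get(term, "not-stress")
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r} for term {term}")
        for g in annotations.get(term, set()) & degset:
            cats_of.setdefault(g, set()).add(cat)
    out: dict[str, str] = {}
    for g, cats in cats_of.items():
        stress = cats & set(STRESS_CATEGORIES)
        if len(stress) > 1:
            out[g] = "general"
        elif len(stress) == 1:
            out[g] = next(iter(stress))
        else:
            out[g] = "not-stress"
    return out


# ---------------------------------------------------------------------------
# TSV interfaces


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) -> term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=0)
    term_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for term, gene in zip(df[term_col], df[gene_col]):
        out.setdefault(str(term), set()).add(str(gene))
    return out


def read_category_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0)
    term_col, cat_col = df.columns[:2]
    return {str(t): str(c) for t, c in zip(df[term_col], df[cat_col])}
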