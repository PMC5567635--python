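"""Enrichment of homoeologous pairs among DEGs, and direction concordance.

The central question: among the differentially expressed genes, do complete
homoeologous pairs (both members DE) occur more often than random draws of
the same number of genes from the quantified universe would produce?  The
permutation test draws ``n_draw`` genes without replacement from the universe
(paired and unpaired genes alike), counts complete pairs, repeats, and
records the null maximum; the empirical p uses the add-one permutation
estimator, so "p < 1/replicates" is reportable exactly when no null draw
reaches the observed count.  An exact dynamic-programming oracle over the
(pairs, singletons) composition provides the same tail probability in closed
form for verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import HomoeologMap


@dataclass
class PairJoin:
    """Decomposition of a DEG list into pair-complete and single homoeologs."""

    at_only: int
    aa_only: int
    n_pairs: int  # complete pairs: both members DE
    pair_rows: pd.DataFrame  # pair_id, at_gene, aa_gene, dir_at, dir_aa

    @property
    def total(self) -> int:
        return self.at_only + self.aa_only + 2 * self.n_pairs

    @property
    def at_total(self) -> int:
        return self.at_only + self.n_pairs

    @property
    def aa_total(self) -> int:
        return self.aa_only + self.n_pairs


def join_pairs(degs: pd.DataFrame, hmap: HomoeologMap) -> PairJoin:
    """Join a DEG table (index gene; columns subgenome, direction) to pairs."""
    deg_genes = set(degs.index)
    rows = []
    paired_genes: set[str] = set()
    for pair_id, at_gene, aa_gene in hmap:
        if at_gene in deg_genes and aa_gene in deg_genes:
            rows.append(
                (
                    pair_id,
                    at_gene,
                    aa_gene,
                    degs.loc[at_gene, "direction"],
                    degs.loc[aa_gene, "direction"],
                )
            )
            paired_genes.update((at_gene, aa_gene))
    singles = degs.loc[[g for g in degs.index if g not in paired_genes]]
    at_only = int((singles["subgenome"] == "AT").sum())
    aa_only = int((singles["subgenome"] == "AA").sum())
    pair_rows = pd.DataFrame(
        rows, columns=["pair_id", "at_gene", "aa_gene", "dir_at", "dir_aa"]
    )
    return PairJoin(at_only=at_only, aa_only=aa_only, n_pairs=len(rows), pair_rows=pair_rows)


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class PermutationResult:
    observed: int
    replicates: int
    histogram: dict[int, int]
    null_max: int
    p: float
    seed: int

    def __post_init__(self) -> None:
        if sum(self.histogram.values()) != self.replicates:
            raise ValueError("histogram mass must equal replicate count")
        if self.histogram and self.null_max != max(self.histogram):
            raise ValueError("null_max must be the largest histogram key")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("empirical p must be in (0, 1]")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "observed": self.observed,
            "replicates": self.replicates,
            "p": self.p,
            "null_max": self.null_max,
            "seed": self.seed,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _pair_codes(universe: Sequence[str], hmap: HomoeologMap) -> np.ndarray:
    """Integer pair code per universe gene; -1 for unpaired.

    Only pairs with *both* members inside the universe keep a code — a pair
    with one member absent can never be completed by a draw.
    """
    uset = set(universe)
    code_of: dict[str, int] = {}
    nxt = 0
    for _, at_gene, aa_gene in hmap:
        if at_gene in uset and aa_gene in uset:
            code_of[at_gene] = nxt
            code_of[aa_gene] = nxt
            nxt += 1
    return np.array([code_of.get(g, -1) for g in universe], dtype=np.int64)


def _count_pairs_rows(pair_codes_drawn: np.ndarray) -> np.ndarray:
    """Complete pairs per row: drawn genes sharing a non-negative pair code.

    Each code occurs at most twice in the universe, so after sorting a row,
    adjacent equal non-negative codes mark exactly one complete pair.
    """
    s = np.sort(pair_codes_drawn, axis=1)
    return ((s[:, 1:] == s[:, :-1]) & (s[:, 1:] >= 0)).sum(axis=1)


def pair_enrichment_permutation(
    universe: Sequence[str],
    hmap: HomoeologMap,
    n_draw: int,
    observed_pairs: int,
    replicates: int = 10**6,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null for the number of complete homoeologous pairs.

    Each replicate draws ``n_draw`` genes uniformly without replacement from
    the universe and counts complete pairs.  Empirical p is
    (1 + #{null >= observed}) / (1 + replicates); the null maximum is the
    largest pair count seen in any replicate.
    """
    U = len(universe)
    if n_draw > U:
        raise ValueError("cannot draw more genes than the universe holds")
    if observed_pairs > n_draw // 2:
        raise ValueError("observed pair count impossible for this draw size")
    codes = _pair_codes(universe, hmap)
    rng = np.random.default_rng(seed)
    hist: dict[int, int] = {}
    done = 0
    ge_observed = 0
    # small or dense draws: rank random keys; sparse draws: rejection sampling
    use_keys = U <= 64 or n_draw > 0.3 * U
    while done < replicates:
        if use_keys:
            b = min(replicates - done, max(1, 5_000_000 // max(U, 1)))
            keys = rng.random((b, U))
            drawn = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw] if n_draw else np.empty((b, 0), dtype=int)
        else:
            b = min(replicates - done, max(1, 5_000_000 // max(n_draw, 1)))
            drawn = rng.integers(0, U, size=(b, n_draw))
            while True:
                s = np.sort(drawn, axis=1)
                bad = (s[:, 1:] == s[:, :-1]).any(axis=1)
                if not bad.any():
                    break
                drawn[bad] = rng.integers(0, U, size=(int(bad.sum()), n_draw))
        counts = _count_pairs_rows(codes[drawn]) if n_draw else np.zeros(b, dtype=int)
        binc = np.bincount(counts)
        for k, v in enumerate(binc):
            if v:
                hist[k] = hist.get(k, 0) + int(v)
        ge_observed += int((counts >= observed_pairs).sum())
        done += b
    p = (1 + ge_observed) / (1 + replicates)
    return PermutationResult(
        observed=observed_pairs,
        replicates=replicates,
        histogram=hist,
        null_max=max(hist) if hist else 0,
        p=p,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Exact oracle


def pair_enrichment_exact(
    universe: Sequence[str],
    hmap: HomoeologMap,
    n_draw: int,
    observed_pairs: int,
) -> float:
    """Exact P(complete pairs >= observed) for a uniform draw w/o replacement.

    Dynamic count over compositions: with P pairs and S singletons in the
    universe, a draw of n genes realizing exactly j complete pairs chooses
    j pairs fully, m further pairs half (2 ways each) and the remaining
    n - 2j - m genes among singletons:

        #ways(j) = C(P, j) * sum_m C(P-j, m) 2^m C(S, n-2j-m)

    Exact integer arithmetic; returns the tail as a float.
    """
    U = len(universe)
    if n_draw > U:
        raise ValueError("cannot draw more genes than the universe holds")
    codes = _pair_codes(universe, hmap)
    P = int((codes >= 0).sum()) // 2
    S = U - 2 * P
    if observed_pairs <= 0:
        return 1.0
    num = 0
    for j in range(observed_pairs, min(P, n_draw // 2) + 1):
        ways_j = 0
        for m in range(0, min(P - j, n_draw - 2 * j) + 1):
            rest = n_draw - 2 * j - m
            if rest > S:
                continue
            ways_j += comb(P - j, m) * (2**m) * comb(S, rest)
        num += comb(P, j) * ways_j
    return float(Fraction(num, comb(U, n_draw)))


def expected_pairs(universe_size: int, pairs_in_universe: int, n_draw: int) -> float:
    """Closed-form E[complete pairs] for a uniform draw without replacement."""
    if universe_size < 2 or n_draw < 2:
        return 0.0
    return pairs_in_universe * n_draw * (n_draw - 1) / (universe_size * (universe_size - 1))


# ---------------------------------------------------------------------------
# Direction concordance


@dataclass
class ConcordanceResult:
    concordant: int
    discordant: int
    p: float  # two-sided exact sign test

    @property
    def n(self) -> int:
        return self.concordant + self.discordant


def direction_concordance(pairjoin: PairJoin) -> ConcordanceResult:
    """Sign test for same-direction regulation of complete pair members.

    Two-sided exact binomial: p = min(1, 2 * P(X >= max(c, n-c))) with
    X ~ Binomial(n, 1/2).
    """
    rows = pairjoin.pair_rows
    if len(rows) == 0:
        return ConcordanceResult(0, 0, 1.0)
    conc = int((rows["dir_at"] == rows["dir_aa"]).sum())
    n = len(rows)
    k = max(conc, n - conc)
    p = min(1.0, 2.0 * float(stats.binom.sf(k - 1, n, 0.5)))
    return ConcordanceResult(concordant=conc, discordant=n - conc, p=p)
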