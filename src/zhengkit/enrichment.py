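"""Hypergeometric over-representation ranking of pathways.

For a relevant-gene list of size n drawn from a universe of N genes, a
pathway with K member genes and k of them in the list is scored by the
upper-tail hypergeometric probability

    P = P(X >= k),   X ~ Hypergeometric(N, K, n)

and pathways are ranked by -log10 P. This is a generic, reproducible
over-representation test in the spirit of platform "pathway map" enrichment
reports; it does not replicate any proprietary scoring. No multiple-testing
correction is applied by default (the ranking statistic is the raw
-log10 P); Benjamini-Hochberg q-values are available by flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["EnrichmentResult", "hypergeometric_pvalue", "rank_enriched_pathways"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Rows of (pathway, K, n, k, p, -log10 p[, q]) sorted by descending
    -log10 p, ties by pathway id."""

    rows: tuple  # of dicts

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(list(self.rows))


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), exact."""
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or K < 0 or n < 0:
        raise ValidationError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy computes it in a
    # numerically stable way
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def rank_enriched_pathways(
    gene_list,
    gene_sets: dict,
    universe=None,
    include_zero_overlap: bool = False,
    fdr: bool = False,
) -> EnrichmentResult:
    """Score every pathway's overlap with the gene list.

    ``gene_sets`` maps pathway id -> gene set; the universe defaults to all
    genes appearing in any pathway. Pathway gene sets are intersected with
    the universe, and the gene list must be a subset of it. Pathways with
    zero overlap are excluded unless requested. With ``fdr=True`` a
    Benjamini-Hochberg q-value column is added (ranking stays by raw p).
    """
    if universe is None:
        universe = set().union(*gene_sets.values()) if gene_sets else set()
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    gene_list = set(gene_list)
    stray = gene_list - universe
    if stray:
        raise ValidationError(
            f"{len(stray)} genes of the list are outside the universe"
        )
    N, n = len(universe), len(gene_list)
    rows = []
    for pathway in sorted(gene_sets):
        members = set(gene_sets[pathway]) & universe
        overlap = members & gene_list
        k, K = len(overlap), len(members)
        if k == 0 and not include_zero_overlap:
            continue
        p = hypergeometric_pvalue(k, K, n, N) if K else 1.0
        rows.append(
            {
                "pathway": pathway,
                "K": K,
                "n": n,
                "k": k,
                "p_value": p,
                "neg_log10_p": -math.log10(p) if p > 0 else math.inf,
            }
        )
    if not rows:
        warnings.warn("gene list overlaps no pathway")
    if fdr and rows:
        ps = np.array([r["p_value"] for r in rows])
        order = np.argsort(ps)
        m = len(ps)
        q = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, ps[i] * m / (rank_pos + 1))
            q[i] = running
        for r, qv in zip(rows, q):
            r["q_value"] = float(qv)
    rows.sort(key=lambda r: (-r["neg_log10_p"], r["pathway"]))
    return EnrichmentResult(rows=tuple(rows))
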