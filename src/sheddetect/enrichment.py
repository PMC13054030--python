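"""Gene-set enrichment against an expressed background, and two-list overlap.

Enrichment uses a one-sided Fisher exact test per gene set on the 2x2 table
(in-set/not x in-query/not) restricted to a user-defined background of
expressed genes, with BH q-values across sets.  The background defaults to
genes whose summed raw counts over control samples reach a minimum total
(10, matching common practice for "expressed in this cell line").

Two-list overlap significance is a hypergeometric upper tail P[X >= k]
drawing |list1| genes from a genome-sized universe containing |list2|
successes, with the representation factor k * genome / (|list1| * |list2|)
as the observed/expected ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import ExpressionMatrix, GeneSetLibrary, SampleDesign

__all__ = ["build_background", "fisher_enrichment", "overlap_stats", "OverlapResult"]


def build_background(
    counts: ExpressionMatrix,
    design: SampleDesign,
    min_total: int = 10,
) -> set[str]:
    """Genes with summed raw counts over control samples >= ``min_total``."""
    ctrl = design.samples("control")
    missing = [s for s in ctrl if s not in counts.sample_ids]
    if len(ctrl) - len(missing) == 0:
        raise ValueError("no control samples present in the count matrix")
    idx = [counts.sample_ids.index(s) for s in ctrl if s not in missing]
    totals = counts.values[idx, :].sum(axis=0)
    return {g for g, t in zip(counts.feature_ids, totals) if t >= min_total}


def fisher_enrichment(
    query,
    library: GeneSetLibrary,
    background,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``query`` in each library set.

    Query and sets are intersected with the background first (dropped query
    ids are simply outside the expressed universe); sets with no background
    overlap are skipped.  Returns one row per tested set with the 2x2
    counts, odds ratio, hypergeometric p, and BH q.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query) & background
    N = len(background)
    n = len(query)

    rows = []
    for name, genes in library:
        in_set = set(genes) & background
        K = len(in_set)
        if K == 0:
            continue
        k = len(in_set & query)
        # one-sided enrichment p = P[X >= k], X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c > 0 else np.nan
        )
        rows.append(
            {
                "set_name": name,
                "overlap_count": k,
                "set_size_in_background": K,
                "query_size_in_background": n,
                "background_size": N,
                "odds_ratio": odds,
                "pvalue": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "overlap_count", "set_size_in_background",
                 "query_size_in_background", "background_size", "odds_ratio", "pvalue"],
    )
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out


@dataclass
class OverlapResult:
    """Overlap of two gene lists against a genome-sized universe."""

    n1: int
    n2: int
    overlap: int
    genome_size: int
    representation_factor: float
    pvalue: float


def overlap_stats(list1, list2, genome_size: int = 20000) -> OverlapResult:
    """Representation factor and hypergeometric upper-tail p for two gene lists.

    The genome size defaults to 20,000 protein-coding genes.  Lists are
    deduplicated; the overlap is their intersection.
    """
    s1, s2 = set(list1), set(list2)
    n1, n2 = len(s1), len(s2)
    if max(n1, n2) > genome_size:
        raise ValueError("list larger than the genome universe")
    k = len(s1 & s2)
    if k > min(n1, n2):  # unreachable from sets; guards count-style misuse
        raise ValueError("overlap exceeds the smaller list")
    rf = k * genome_size / (n1 * n2) if n1 and n2 else 0.0
    p = float(stats.hypergeom.sf(k - 1, genome_size, n2, n1))
    return OverlapResult(n1, n2, k, genome_size, rf, min(p, 1.0))
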