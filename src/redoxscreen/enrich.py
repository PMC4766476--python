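"""Hypergeometric term enrichment of a gene set against a background.

For a term annotating K of N background genes, of which k appear in the
n-gene query set, the enrichment p-value is the hypergeometric upper tail
``P(X >= k)``.  The output mirrors the familiar GO-term-finder summary:
cluster frequency (100*k/n), genome frequency (100*K/N), and a corrected
p-value (Bonferroni over the tested terms by default, BH optionally).
The annotation table is taken as-is with no ontology-graph propagation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .destats import bh_adjust


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k hits among the n drawn genes, K annotated among the N background genes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_set,
    background,
    annotation: pd.DataFrame,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Test every annotation term for over-representation in ``gene_set``.

    ``annotation`` is a long table with ``term_id``, ``term_name`` and
    ``gene_id`` columns (one association per row).  Annotations are
    intersected with the background before counting; only terms with at
    least one hit in the set are reported, and the correction multiplicity
    counts exactly the tested (k >= 1) terms.  Rows are sorted by corrected,
    then raw, p-value.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set or not background:
        raise ValueError("gene set and background must be non-empty")
    stray = gene_set - background
    if stray:
        raise ValueError(f"gene set not contained in background, e.g. {sorted(stray)[:5]}")
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")

    N, n = len(background), len(gene_set)
    rows = []
    for (term_id, term_name), sub in annotation.groupby(["term_id", "term_name"], sort=True):
        annotated = set(sub["gene_id"]) & background
        K = len(annotated)
        k = len(annotated & gene_set)
        if K == 0 or k == 0:
            continue
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "cluster_frequency": 100.0 * k / n,
                "genome_frequency": 100.0 * K / N,
                "p_raw": hypergeom_upper_tail(k, K, n, N),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "K", "n", "N",
            "cluster_frequency", "genome_frequency", "p_raw",
        ],
    )
    if out.empty:
        out["p_corrected"] = []
        return out
    if correction == "bonferroni":
        out["p_corrected"] = np.minimum(1.0, out["p_raw"] * len(out))
    else:
        out["p_corrected"] = bh_adjust(out["p_raw"].to_numpy())
    return out.sort_values(
        ["p_corrected", "p_raw", "term_id"], kind="mergesort"
    ).reset_index(drop=True)


def write_enrichment(table: pd.DataFrame, path) -> None:
    """TSV with the three summary columns first, then the count audit."""
    cols = [
        "term_name", "cluster_frequency", "genome_frequency", "p_corrected",
        "term_id", "p_raw", "k", "K", "n", "N",
    ]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
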