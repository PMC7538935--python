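"""Pathway membership tabulation and hypergeometric over-representation.

Two complementary views of a result set against user-supplied gene sets:

* :func:`tabulate_membership` — the report-table view: one row per
  (pathway, result transcript whose gene symbol belongs to the pathway),
  carrying the transcript's enrichment and DE statistics. A transcript in
  k pathways contributes k rows; transcripts mapping to no pathway are
  omitted.
* :func:`hypergeometric_ora` — the statistical view: one-sided
  hypergeometric (Fisher exact upper tail) over-representation of a hit
  list within a universe, BH-adjusted across the tested sets. ORA is
  universe-sensitive; callers choose the universe (the default used by
  the pipeline is every analysed transcript with a mapped symbol).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .countmodel import bh_adjust
from .errors import ValidationError
from .io import GeneSetCollection


def tabulate_membership(
    results: pd.DataFrame,
    genesets: GeneSetCollection,
    alpha_de: float = 0.05,
) -> pd.DataFrame:
    """Cross a result table with gene sets into a per-pathway report.

    ``results`` needs columns transcript_id, gene_symbol, enrichment,
    de_log2fc, de_padj (one row per transcript; the caller selects which
    transcripts — typically the oxidation-enriched set). Output columns:
    pathway, transcript_id, gene_symbol, enrichment, de_log2fc, de_padj,
    de_significant (de_padj < alpha_de).
    """
    if len(genesets) == 0:
        raise ValidationError("no gene sets supplied")
    required = {"transcript_id", "gene_symbol", "enrichment", "de_log2fc", "de_padj"}
    missing = required - set(results.columns)
    if missing:
        raise ValidationError(f"results table missing columns: {sorted(missing)}")
    rows = []
    for gs in genesets:
        member = results["gene_symbol"].isin(gs.members)
        for _, r in results.loc[member].iterrows():
            padj = r["de_padj"]
            rows.append(
                {
                    "pathway": gs.name,
                    "transcript_id": r["transcript_id"],
                    "gene_symbol": r["gene_symbol"],
                    "enrichment": r["enrichment"],
                    "de_log2fc": r["de_log2fc"],
                    "de_padj": padj,
                    "de_significant": bool(padj < alpha_de) if pd.notna(padj) else False,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "transcript_id",
            "gene_symbol",
            "enrichment",
            "de_log2fc",
            "de_padj",
            "de_significant",
        ],
    )


def hypergeometric_ora(
    hit_symbols: set[str],
    genesets: GeneSetCollection,
    universe_symbols: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of hits in each set.

    With a universe of M symbols, K of which belong to the (universe-
    intersected) gene set, and N hits drawn, the p-value is
    P(X >= overlap) for X ~ Hypergeometric(M, K, N); BH adjustment runs
    across all tested sets. Hits must be a subset of the universe.
    """
    hit_symbols = set(hit_symbols)
    universe_symbols = set(universe_symbols)
    stray = hit_symbols - universe_symbols
    if stray:
        raise ValidationError(f"hit symbols outside the universe: {sorted(stray)[:10]}")
    m = len(universe_symbols)
    n_hits = len(hit_symbols)
    rows = []
    for gs in genesets:
        members = gs.members & universe_symbols
        k = len(members)
        overlap = len(members & hit_symbols)
        # P(X >= overlap); sf(k-1) is the exact upper tail
        p = float(stats.hypergeom.sf(overlap - 1, m, k, n_hits)) if m else 1.0
        p = min(p, 1.0)
        rows.append(
            {
                "pathway": gs.name,
                "overlap": overlap,
                "set_size": k,
                "hits": n_hits,
                "universe": m,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("pathway")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
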