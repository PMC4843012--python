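"""Hypergeometric gene-set enrichment, run separately per direction.

With *n* background genes analysed in a dataset, *k* of them flagged
interesting (e.g. up-regulated DEGs) and *m* members of a pathway present
in the background, the chance of seeing at least the observed *x*
interesting genes inside the pathway is the upper-tail cumulative
hypergeometric probability. Up- and down-regulated lists are analysed
independently, each with its own BH correction, because mixed lists
dilute direction-specific pathway signals.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection
from .differential import DOWN, TIED, UP, DifferentialTable, bh_adjust

__all__ = ["hypergeom_upper_tail", "hypergeom_enrich", "enrich_updown"]


def hypergeom_upper_tail(x: int, n: int, m: int, k: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(population n, successes m, draws k)."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, n, m, k))


def hypergeom_enrich(
    interesting: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    fdr_threshold: float = 0.2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``interesting`` in each set.

    Set members are intersected with the background before counting; sets
    with no background member are skipped. Interesting genes must be a
    subset of the background (hard error listing offenders). Results are
    BH-corrected across tested sets and sorted by raw p.
    """
    bg = set(background)
    interest = set(interesting)
    orphans = sorted(interest - bg)
    if orphans:
        raise ValueError(
            f"{len(orphans)} interesting gene(s) absent from background, "
            f"e.g. {orphans[:5]}"
        )
    n, k = len(bg), len(interest)
    rows = []
    empty_cols = [
        "set_id",
        "n_background",
        "k_interesting",
        "m_set",
        "x_hits",
        "p_hyper",
        "q_bh",
        "hit_genes",
    ]
    if k == 0:
        return pd.DataFrame(columns=empty_cols)
    for gs in sets:
        members = set(gs.members) & bg
        m = len(members)
        if m == 0:
            continue
        hits = sorted(interest & members)
        x = len(hits)
        rows.append(
            {
                "set_id": gs.set_id,
                "n_background": n,
                "k_interesting": k,
                "m_set": m,
                "x_hits": x,
                "p_hyper": hypergeom_upper_tail(x, n, m, k),
                "hit_genes": ",".join(hits),
            }
        )
    if not rows:
        return pd.DataFrame(columns=empty_cols)
    df = pd.DataFrame(rows)
    df["q_bh"] = bh_adjust(df["p_hyper"].to_numpy())
    df = df.sort_values(["p_hyper", "set_id"], kind="mergesort").reset_index(
        drop=True
    )
    return df[
        [
            "set_id",
            "n_background",
            "k_interesting",
            "m_set",
            "x_hits",
            "p_hyper",
            "q_bh",
            "hit_genes",
        ]
    ]


def enrich_updown(
    de: DifferentialTable,
    sets: GeneSetCollection,
    background: Iterable[str],
    fdr_threshold: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enrichment run separately on up- and down-regulated significant genes.

    Returns (up table, down table); an empty direction yields an empty
    table, not an error. Tied features belong to neither list.
    """
    sig = de.significant(fdr_threshold)
    up = [str(g) for g in sig.loc[sig["direction"] == UP, "feature_id"]]
    down = [str(g) for g in sig.loc[sig["direction"] == DOWN, "feature_id"]]
    bg = list(background)
    return (
        hypergeom_enrich(up, bg, sets, fdr_threshold),
        hypergeom_enrich(down, bg, sets, fdr_threshold),
    )
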