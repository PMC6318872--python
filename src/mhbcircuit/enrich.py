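"""Cumulative hypergeometric annotation enrichment of gene clusters.

Each (cluster, term) pair with at least one annotated member is tested
against the background of all annotated host genes: p = P(X >= k) for
X ~ Hypergeometric(N, K, n), where N is the background size, K the number
of background genes carrying the term, n the cluster size (restricted to
the background) and k the number of cluster members carrying the term.
The tail is exact, not normal-approximated.  Following common practice for
small per-cluster vocabularies, the raw p < 0.05 threshold is used by
default; a Benjamini-Hochberg option exists but is off by default.  Terms
are tested exactly as annotated -- no ontology-graph ancestor propagation.

A term is *uniquely* enriched when it is enriched in exactly one cluster;
uniqueness feeds the sensor-candidate screen in :mod:`mhbcircuit.circuit`.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AnnotationMap
from .stats import bh_fdr


def hypergeometric_tail(k: int, n: int, K_bg: int, N_bg: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N_bg, K_bg, n)."""
    if not (0 <= k <= n <= N_bg and 0 <= K_bg <= N_bg and k <= K_bg):
        raise ValueError(
            f"inconsistent hypergeometric arguments k={k}, n={n}, "
            f"K_bg={K_bg}, N_bg={N_bg}"
        )
    return float(sps.hypergeom.sf(k - 1, N_bg, K_bg, n))


def enrich_clusters(
    assignment: pd.Series,
    annotations: AnnotationMap,
    background: Iterable[str],
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Test every (cluster, term) pair with k >= 1 member annotations.

    Parameters
    ----------
    assignment : gene id -> cluster index (e.g. ``ClusterModel.assignment``).
    annotations : gene id -> set of terms.
    background : the background gene universe (all annotated host genes);
        cluster genes outside it are ignored for testing.
    alpha : enrichment threshold on the (possibly adjusted) p-value.
    correction : None for the raw threshold (default) or ``"fdr"`` for BH
        across all tests.

    Returns a frame with columns cluster, term, k, n, K_bg, N_bg, p,
    (q when corrected), enriched_flag, unique_flag.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    bg_annotated = {g for g in background if annotations.get(g)}
    N_bg = len(bg_annotated)
    if N_bg == 0:
        raise ValueError("no annotated genes in the background")
    term_bg_count: dict[str, int] = {}
    for g in bg_annotated:
        for t in annotations[g]:
            term_bg_count[t] = term_bg_count.get(t, 0) + 1

    rows = []
    for cluster in sorted(pd.unique(assignment)):
        members = [g for g in assignment.index[assignment == cluster] if g in bg_annotated]
        n = len(members)
        if n == 0:
            continue
        counts: dict[str, int] = {}
        for g in members:
            for t in annotations[g]:
                counts[t] = counts.get(t, 0) + 1
        for term in sorted(counts):
            k = counts[term]
            K_bg = term_bg_count[term]
            p = hypergeometric_tail(k, n, K_bg, N_bg)
            rows.append((cluster, term, k, n, K_bg, N_bg, p))

    table = pd.DataFrame(
        rows, columns=["cluster", "term", "k", "n", "K_bg", "N_bg", "p"]
    )
    if table.empty:
        table["enriched_flag"] = pd.Series(dtype=bool)
        table["unique_flag"] = pd.Series(dtype=bool)
        return table
    if correction == "fdr":
        table["q"] = bh_fdr(table["p"].to_numpy())
        table["enriched_flag"] = table["q"] < alpha
    elif correction is None:
        table["enriched_flag"] = table["p"] < alpha
    else:
        raise ValueError("correction must be None or 'fdr'")
    return unique_enrichment(table)


def unique_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Flag terms enriched in exactly one cluster (``unique_flag``)."""
    out = table.copy()
    enriched = out[out["enriched_flag"]]
    per_term = enriched.groupby("term")["cluster"].nunique()
    unique_terms = set(per_term.index[per_term == 1])
    out["unique_flag"] = out["enriched_flag"] & out["term"].isin(unique_terms)
    return out


def enriched_terms(table: pd.DataFrame, cluster: int) -> Set[str]:
    """Terms enriched in one cluster."""
    mask = (table["cluster"] == cluster) & table["enriched_flag"]
    return set(table.loc[mask, "term"])


def write_enrichment_tsv(table: pd.DataFrame, path) -> None:
    """Cluster-grouped enrichment export."""
    table.sort_values(["cluster", "p"]).to_csv(path, sep="\t", index=False)
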