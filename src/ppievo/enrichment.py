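"""Hypergeometric over-representation analysis (ORA) of node sets.

Given a query set of proteins (e.g. one consensus cluster intersection), an
annotation collection and a background universe, each term is scored with
the exact hypergeometric upper-tail probability of the observed overlap,
and p-values are adjusted across the emitted terms by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from ppievo.graph_model import AnnotationCollection


def hypergeom_upper_tail(k: int, m: int, n_term: int, n_query: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population m, successes n_term,
    draws n_query): the ORA p-value for an overlap of k."""
    return float(stats.hypergeom.sf(k - 1, m, n_term, n_query))


def ora(
    query: set[str],
    annotations: AnnotationCollection,
    background: set[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each annotation term.

    Only terms with overlap >= 1 are reported.  Columns: ``term``,
    ``description``, ``term_size``, ``query_size``, ``overlap``,
    ``p_value`` (hypergeometric upper tail), ``q_value``
    (Benjamini-Hochberg), ``members``; rows sorted by ascending p-value.
    Query identifiers outside the background are dropped with a warning;
    term members are likewise restricted to the background.
    """
    if not query:
        raise ValueError("empty query set")
    if not background:
        raise ValueError("empty background set")
    stray = query - background
    if stray:
        warnings.warn(
            f"{len(stray)} query identifier(s) outside the background dropped",
            stacklevel=2,
        )
        query = query & background
        if not query:
            raise ValueError("no query identifiers left inside the background")
    m = len(background)
    n_query = len(query)
    rows = []
    for term, (desc, raw_members) in annotations.terms.items():
        members = raw_members & background
        overlap = query & members
        if not overlap:
            continue
        k = len(overlap)
        p = hypergeom_upper_tail(k, m, len(members), n_query)
        rows.append(
            {
                "term": term,
                "description": desc,
                "term_size": len(members),
                "query_size": n_query,
                "overlap": k,
                "p_value": min(max(p, 0.0), 1.0),
                "members": ";".join(sorted(overlap)),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term",
                "description",
                "term_size",
                "query_size",
                "overlap",
                "p_value",
                "q_value",
                "members",
            ]
        )
    df = pd.DataFrame(rows).sort_values(
        ["p_value", "term"], ignore_index=True
    )
    df["q_value"] = benjamini_hochberg(df["p_value"].tolist())
    return df[
        [
            "term",
            "description",
            "term_size",
            "query_size",
            "overlap",
            "p_value",
            "q_value",
            "members",
        ]
    ]


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Step-up BH adjustment; monotone non-decreasing in p-rank."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, p_values[i] * m / rank)
        q[i] = running
    return q
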