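"""Two-list overrepresentation analysis of annotation terms.

Given a target protein set (e.g. differentially connected proteins) and a
background set (all identified proteins), each annotation term is scored
with the upper-tail hypergeometric probability of observing at least the
target's overlap with the term, then BH-corrected across terms.  Terms are
flat labels supplied by the annotation table; no ontology hierarchy is
expanded.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import benjamini_hochberg


def _term_sets(
    annotations: Mapping[str, set[str]] | pd.DataFrame,
) -> dict[str, set[str]]:
    """Normalise annotations to protein_id -> set of terms."""
    if isinstance(annotations, pd.DataFrame):
        if not {"protein_id", "keyword"} <= set(annotations.columns):
            raise ValueError("annotation frame needs protein_id and keyword columns")
        grouped = annotations.groupby("protein_id")["keyword"].agg(set)
        return {str(k): {str(t) for t in v} for k, v in grouped.items()}
    return {str(k): set(v) for k, v in annotations.items()}


def overrepresentation_test(
    target: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, set[str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each term in the target set.

    For a term annotating K of the N background proteins, with n target
    proteins of which k carry the term, the p-value is P(X >= k) for
    X ~ Hypergeometric(N, K, n).  Rows are sorted by BH-adjusted p.
    """
    target = {str(t) for t in target}
    background = {str(b) for b in background}
    if not background:
        raise ValueError("background set is empty")
    stray = target - background
    if stray:
        raise ValueError(f"target proteins outside background: {sorted(stray)[:5]}")
    protein_terms = _term_sets(annotations)

    term_members: dict[str, set[str]] = {}
    for protein, terms in protein_terms.items():
        if protein in background:
            for term in terms:
                term_members.setdefault(term, set()).add(protein)

    n_bg, n_target = len(background), len(target)
    rows = []
    for term, members in sorted(term_members.items()):
        big_k = len(members)
        k = len(members & target)
        # survival function at k-1 gives P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_target))
        rows.append((term, n_bg, big_k, n_target, k, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["term", "background_size", "term_size", "target_size",
                 "overlap", "p_value"],
    )
    if out.empty:
        out["p_adjusted"] = pd.Series(dtype=float)
        return out
    out["p_adjusted"] = benjamini_hochberg(out["p_value"])
    return out.sort_values(
        ["p_adjusted", "p_value", "term"], kind="stable"
    ).reset_index(drop=True)
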