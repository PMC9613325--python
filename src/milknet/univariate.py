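"""Per-protein nonparametric group screening and abundance-trend summaries.

Screening follows the classic rank-based chain for a four-group design:
Kruskal-Wallis across all groups with Benjamini-Hochberg correction over
proteins, then Dunn's pairwise post-hoc tests for proteins passing an
uncorrected Kruskal-Wallis gate, with a second BH correction over the
pooled family of (protein, pair) tests.  Trend direction is taken from
the difference of group means of log10 abundance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable, StudyDesign, split_by_group


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class UnivariateResult:
    protein_id: str
    h_statistic: float
    p_value: float
    p_adjusted: float = np.nan


@dataclass
class PosthocComparison:
    protein_id: str
    group_a: str
    group_b: str
    z: float
    p_value: float
    p_adjusted: float = np.nan
    trend: str = "none"  # group with the higher mean log10 abundance


def _kruskal_one(groups: list[np.ndarray]) -> tuple[float, float]:
    # scipy raises on all-identical input; convention there is H=0, p=1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kruskal_wallis_screen(
    table: AbundanceTable, design: StudyDesign
) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis per protein; BH across proteins.

    Returns a DataFrame indexed by protein with columns
    ``h_statistic``, ``p_value``, ``p_adjusted``.
    """
    per_group = split_by_group(table, design)
    if len(per_group) < 2:
        raise ValueError("need at least two groups")
    small = [g for g, f in per_group.items() if f.shape[0] < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    rows = []
    for protein in table.protein_ids:
        groups = [f[protein].to_numpy(dtype=float) for f in per_group.values()]
        h, p = _kruskal_one(groups)
        rows.append((protein, h, p))
    out = pd.DataFrame(rows, columns=["protein_id", "h_statistic", "p_value"])
    out["p_adjusted"] = benjamini_hochberg(out["p_value"])
    return out.set_index("protein_id")


def _dunn_z(
    values: np.ndarray, labels: np.ndarray, a: str, b: str
) -> float:
    """Dunn's z for one pair, ranks over ALL groups, tie-corrected variance."""
    n = values.size
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    in_a, in_b = labels == a, labels == b
    na, nb = int(in_a.sum()), int(in_b.sum())
    se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
    if se == 0:
        return 0.0
    return float((ranks[in_a].mean() - ranks[in_b].mean()) / se)


def dunn_posthoc(
    table: AbundanceTable,
    design: StudyDesign,
    kw_results: pd.DataFrame | None = None,
    candidate_alpha: float = 0.05,
    bh_family: str = "pooled",
) -> pd.DataFrame:
    """Dunn's pairwise tests for proteins passing the uncorrected
    Kruskal-Wallis gate (raw p < ``candidate_alpha``).

    ``bh_family`` chooses the BH correction family: ``"pooled"`` corrects
    over all (protein, pair) tests together; ``"per-protein"`` corrects the
    six pairs within each protein separately.  The ``trend`` column names
    the group of the pair with the higher mean log10 abundance.
    """
    if bh_family not in ("pooled", "per-protein"):
        raise ValueError(f"unknown bh_family {bh_family!r}")
    if kw_results is None:
        kw_results = kruskal_wallis_screen(table, design)
    candidates = kw_results.index[kw_results["p_value"] < candidate_alpha]
    pairs = list(itertools.combinations(design.group_labels, 2))
    labels = design.groups.reindex(table.sample_ids).to_numpy()
    rows = []
    for protein in candidates:
        values = table.data[protein].to_numpy(dtype=float)
        for a, b in pairs:
            z = _dunn_z(values, labels, a, b)
            p = float(2.0 * stats.norm.sf(abs(z)))
            mean_a = values[labels == a].mean()
            mean_b = values[labels == b].mean()
            trend = a if mean_a > mean_b else (b if mean_b > mean_a else "none")
            rows.append((protein, a, b, z, p, trend))
    out = pd.DataFrame(
        rows, columns=["protein_id", "group_a", "group_b", "z", "p_value", "trend"]
    )
    if out.empty:
        out["p_adjusted"] = pd.Series(dtype=float)
        return out
    if bh_family == "pooled":
        out["p_adjusted"] = benjamini_hochberg(out["p_value"])
    else:
        out["p_adjusted"] = out.groupby("protein_id")["p_value"].transform(
            lambda p: benjamini_hochberg(p.to_numpy())
        )
    return out


def screening_table(
    kw: pd.DataFrame, dunn: pd.DataFrame, annotation: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combined screening report: one row per significant (protein, pair)
    Dunn result (adjusted p < alpha), with the protein's KW p-values and
    keyword, trend as 'up'/'down' for the first group of the pair."""
    hits = dunn[dunn["p_adjusted"] < alpha].copy()
    hits["kw_p_value"] = kw["p_value"].reindex(hits["protein_id"]).to_numpy()
    hits["kw_p_adjusted"] = kw["p_adjusted"].reindex(hits["protein_id"]).to_numpy()
    hits["trend_arrow"] = np.where(hits["trend"] == hits["group_a"], "up", "down")
    if annotation is not None:
        kw_map = annotation.set_index("protein_id")["keyword"]
        hits["keyword"] = (
            kw_map.reindex(hits["protein_id"]).fillna("unannotated").to_numpy()
        )
    order = ["group_a", "group_b", "p_adjusted"]
    return hits.sort_values(order).reset_index(drop=True)


def abundance_trend_summary(
    table: AbundanceTable,
    design: StudyDesign,
    annotation: pd.DataFrame,
    group_pair: tuple[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein log10-mean ratios for one group pair, plus per-keyword
    counts of proteins with higher mean in either group (volcano-ready).

    Returns ``(per_protein, per_keyword)``.  ``ratio`` is
    mean_log10(group_a) / mean_log10(group_b); ``higher_in`` names the
    group with the larger mean (``"none"`` on exact ties).  Proteins
    absent from the annotation are counted under ``"unannotated"``.
    """
    a, b = group_pair
    for g in group_pair:
        if g not in design.group_labels:
            raise ValueError(f"unknown group {g!r}")
    data_a = table.data.loc[design.samples_in(a)]
    data_b = table.data.loc[design.samples_in(b)]
    mean_a = data_a.mean(axis=0)
    mean_b = data_b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_a / mean_b
    higher = pd.Series(
        np.where(mean_a > mean_b, a, np.where(mean_b > mean_a, b, "none")),
        index=mean_a.index,
    )
    keyword_map = annotation.set_index("protein_id")["keyword"]
    per_protein = pd.DataFrame(
        {
            "mean_log10_a": mean_a,
            "mean_log10_b": mean_b,
            "ratio": ratio,
            "higher_in": higher,
            "keyword": keyword_map.reindex(mean_a.index).fillna("unannotated"),
        }
    )
    per_protein.index.name = "protein_id"
    per_keyword = (
        per_protein.groupby("keyword")["higher_in"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[a, b, "none"], fill_value=0)
    )
    per_keyword.columns = [f"higher_in_{c}" for c in per_keyword.columns]
    per_keyword["total"] = per_keyword.sum(axis=1)
    return per_protein, per_keyword
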