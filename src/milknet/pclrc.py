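"""Probabilistic correlation networks (PCLRC), connectivity, and
differential-connectivity inference.

PCLRC scores each protein pair by the frequency with which its Spearman
correlation survives background filtering by a Context Likelihood of
Relatedness (CLR) transform across many random subsamples of the data.
Pairs retained in a fraction >= tau of iterations form the group network;
edge weights are the full-data Spearman correlations.  A protein's
connectivity chi_i is its weighted node strength,

    chi_i = (sum_j |r_ij|) - 1,

where the unit diagonal cancels the -1; differential connectivity between
two group networks is Delta_i = chi_i(a) - chi_i(b).  Because no analytic
null for Delta exists, significance comes from a group-label permutation
test with a reduced resampling budget per permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import benjamini_hochberg


def spearman_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix (average-rank ties) of a group's
    samples x proteins block.  Constant proteins get correlation 0 with
    everything (rank-degenerate), with a warning."""
    if data.shape[0] < 3:
        raise ValueError("need at least 3 samples for Spearman correlation")
    if data.isna().any().any():
        raise ValueError("missing cells; impute before correlation")
    values = data.to_numpy(dtype=float)
    corr, constant = _spearman(values)
    if constant.any():
        names = [data.columns[j] for j in np.nonzero(constant)[0]]
        warnings.warn(
            f"constant proteins, correlations set to 0: {names[:5]}", stacklevel=2
        )
    return pd.DataFrame(corr, index=data.columns, columns=data.columns)


def _spearman(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank-then-Pearson Spearman with guard for constant columns."""
    ranks = stats.rankdata(values, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr, constant


def clr_transform(similarity: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Context-likelihood-of-relatedness scores of a similarity matrix.

    Works on M = |similarity| with the diagonal excluded from row
    statistics: ``z_ij^(i) = max(0, (M_ij - mu_i) / sigma_i)`` and
    ``CLR_ij = sqrt(z_ij^(i)^2 + z_ij^(j)^2)``; rows with sigma_i = 0
    contribute z = 0.  Output is symmetric, non-negative, zero diagonal.
    """
    m = np.asarray(similarity, dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    m = np.abs(m.copy())
    np.fill_diagonal(m, np.nan)  # exclude self-similarity from row stats
    mu = np.nanmean(m, axis=1)
    sigma = np.nanstd(m, axis=1)  # population sd over off-diagonal entries
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m - mu[:, None]) / sigma[:, None]
    z[sigma == 0] = 0.0
    z = np.nan_to_num(np.maximum(z, 0.0))
    clr = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(clr, 0.0)
    return clr


@dataclass
class EdgeProbabilityMatrix:
    """Per-pair edge retention probabilities from the resampling loop."""

    probabilities: pd.DataFrame
    n_iterations: int
    subsample_fraction: float
    keep_fraction: float


def _top_edges_mask(clr: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Boolean J x J mask retaining the top keep_fraction of upper-triangle
    edges by CLR score; ties broken deterministically by (score, i, j)."""
    j = clr.shape[0]
    iu = np.triu_indices(j, k=1)
    scores = clr[iu]
    m = int(round(keep_fraction * scores.size))
    # stable sort on -score keeps canonical (i, j) order among ties
    order = np.argsort(-scores, kind="stable")[:m]
    mask = np.zeros((j, j), dtype=bool)
    mask[iu[0][order], iu[1][order]] = True
    return mask | mask.T


def estimate_edge_probabilities(
    data: pd.DataFrame,
    n_iterations: int = 1000,
    subsample_fraction: float = 0.75,
    keep_fraction: float = 0.30,
    seed: int = 0,
) -> EdgeProbabilityMatrix:
    """PCLRC resampling: per iteration draw ``subsample_fraction`` of the
    samples without replacement, compute Spearman + CLR, and mark the top
    ``keep_fraction`` of upper-triangle edges as retained; the probability
    p_ij is the retention frequency over iterations.  Diagonal is 1."""
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in (0, 1]")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must lie in (0, 1]")
    n = data.shape[0]
    n_sub = int(np.ceil(subsample_fraction * n))
    if n_sub < 4:
        raise ValueError(f"subsample of {n_sub} samples is too small (need >= 4)")
    values = data.to_numpy(dtype=float)
    j = values.shape[1]
    rng = np.random.default_rng(seed)
    counts = np.zeros((j, j), dtype=np.int64)
    for _ in range(n_iterations):
        idx = rng.choice(n, size=n_sub, replace=False)
        corr, _ = _spearman(values[idx])
        clr = clr_transform(corr)
        counts += _top_edges_mask(clr, keep_fraction)
    probs = counts / float(n_iterations)
    np.fill_diagonal(probs, 1.0)
    return EdgeProbabilityMatrix(
        probabilities=pd.DataFrame(probs, index=data.columns, columns=data.columns),
        n_iterations=n_iterations,
        subsample_fraction=subsample_fraction,
        keep_fraction=keep_fraction,
    )


@dataclass
class AssociationNetwork:
    """Thresholded group network: weights are full-data Spearman values
    where p_ij >= tau, else 0; diagonal 1."""

    group: str
    weights: pd.DataFrame
    probabilities: pd.DataFrame | None = None
    tau: float = 0.99

    @property
    def protein_ids(self) -> list[str]:
        return list(self.weights.columns)

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle nonzero edges as (protein_i, protein_j, weight[, probability])."""
        w = self.weights.to_numpy()
        iu = np.triu_indices(w.shape[0], k=1)
        keep = w[iu] != 0
        cols = {
            "protein_i": np.asarray(self.weights.index)[iu[0][keep]],
            "protein_j": np.asarray(self.weights.columns)[iu[1][keep]],
            "weight": w[iu][keep],
        }
        if self.probabilities is not None:
            cols["probability"] = self.probabilities.to_numpy()[iu][keep]
        return pd.DataFrame(cols)


def build_network(
    similarity: pd.DataFrame,
    probabilities: EdgeProbabilityMatrix | pd.DataFrame,
    tau: float = 0.99,
    group: str = "",
) -> AssociationNetwork:
    """Threshold: keep r_ij where p_ij >= tau, else 0; diagonal set to 1.
    Signed correlations are preserved in the retained weights."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    probs = (
        probabilities.probabilities
        if isinstance(probabilities, EdgeProbabilityMatrix)
        else probabilities
    )
    if similarity.shape != probs.shape:
        raise ValueError("similarity and probability matrices differ in shape")
    weights = similarity.to_numpy(dtype=float).copy()
    weights[probs.to_numpy(dtype=float) < tau] = 0.0
    np.fill_diagonal(weights, 1.0)
    return AssociationNetwork(
        group=group,
        weights=pd.DataFrame(weights, index=similarity.index, columns=similarity.columns),
        probabilities=probs,
        tau=tau,
    )


def connectivity(network: AssociationNetwork | pd.DataFrame) -> pd.Series:
    """Weighted node strength chi_i = (sum_j |r_ij|) - 1; the unit diagonal
    cancels the -1, so an isolated protein has chi = 0."""
    weights = network.weights if isinstance(network, AssociationNetwork) else network
    w = weights.to_numpy(dtype=float)
    if not np.allclose(np.diag(w), 1.0):
        raise ValueError("network diagonal must be 1 (convention for the -1 term)")
    chi = np.abs(w).sum(axis=1) - 1.0
    return pd.Series(chi, index=weights.index, name="connectivity")


def differential_connectivity(chi_a: pd.Series, chi_b: pd.Series) -> pd.Series:
    """Delta_i = chi_i(a) - chi_i(b), elementwise over a shared protein set."""
    if set(chi_a.index) != set(chi_b.index):
        raise ValueError("connectivity profiles cover different protein sets")
    delta = chi_a - chi_b.reindex(chi_a.index)
    delta.name = "delta_connectivity"
    return delta


def infer_group_network(
    data: pd.DataFrame,
    n_iterations: int = 1000,
    subsample_fraction: float = 0.75,
    keep_fraction: float = 0.30,
    tau: float = 0.99,
    seed: int = 0,
    group: str = "",
) -> AssociationNetwork:
    """Full PCLRC chain for one group: Spearman -> resampled CLR edge
    probabilities -> thresholded signed network."""
    sim = spearman_matrix(data)
    probs = estimate_edge_probabilities(
        data, n_iterations=n_iterations,
        subsample_fraction=subsample_fraction,
        keep_fraction=keep_fraction, seed=seed,
    )
    return build_network(sim, probs, tau=tau, group=group)


@dataclass
class DifferentialConnectivityTable:
    table: pd.DataFrame  # delta, p_value, p_adjusted, selected
    n_permutations: int
    n_iterations: int
    delta_observed: pd.Series = field(repr=False, default=None)


def dc_permutation_pvalues(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    n_permutations: int = 99,
    n_iterations: int = 100,
    subsample_fraction: float = 0.75,
    keep_fraction: float = 0.30,
    tau: float = 0.99,
    seed: int = 0,
    alpha: float = 0.05,
) -> DifferentialConnectivityTable:
    """Permutation p-values for differential connectivity.

    Samples of the two groups are pooled; each permutation reassigns group
    labels (preserving sizes), rebuilds both networks with a reduced
    ``n_iterations`` resampling budget, and recomputes Delta.  Two-sided
    raw p = (1 + #{|Delta_perm| >= |Delta_obs|}) / (n_permutations + 1),
    BH-corrected across proteins.  The observed Delta uses the same budget
    so observed and null statistics are exchangeable.
    """
    if n_permutations < 19:
        raise ValueError("n_permutations must be >= 19 to reach p < 0.05")
    if set(data_a.columns) != set(data_b.columns):
        raise ValueError("groups cover different protein sets")
    if set(data_a.index) & set(data_b.index):
        raise ValueError("groups share samples; they must be disjoint")
    data_b = data_b[data_a.columns]

    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(2 * (n_permutations + 1))

    def _delta(block_a: np.ndarray, block_b: np.ndarray, s_a, s_b) -> np.ndarray:
        chis = []
        for block, s in ((block_a, s_a), (block_b, s_b)):
            frame = pd.DataFrame(block, columns=data_a.columns)
            net = infer_group_network(
                frame, n_iterations=n_iterations,
                subsample_fraction=subsample_fraction,
                keep_fraction=keep_fraction, tau=tau,
                seed=int(s.generate_state(1)[0] % 2**31),
            )
            chis.append(connectivity(net).to_numpy())
        return chis[0] - chis[1]

    obs = _delta(
        data_a.to_numpy(dtype=float), data_b.to_numpy(dtype=float),
        seeds[0], seeds[1],
    )

    pooled = np.vstack([data_a.to_numpy(dtype=float), data_b.to_numpy(dtype=float)])
    n_a = data_a.shape[0]
    exceed = np.zeros(pooled.shape[1], dtype=np.int64)
    for p in range(n_permutations):
        rng = np.random.default_rng(seeds[2 + 2 * p])
        order = rng.permutation(pooled.shape[0])
        perm = _delta(
            pooled[order[:n_a]], pooled[order[n_a:]],
            seeds[2 + 2 * p], seeds[3 + 2 * p],
        )
        exceed += np.abs(perm) >= np.abs(obs)
    raw_p = (1.0 + exceed) / (n_permutations + 1.0)
    adj_p = benjamini_hochberg(raw_p)
    table = pd.DataFrame(
        {
            "delta": obs,
            "p_value": raw_p,
            "p_adjusted": adj_p,
            "selected": adj_p < alpha,
        },
        index=data_a.columns,
    )
    table.index.name = "protein_id"
    return DifferentialConnectivityTable(
        table=table,
        n_permutations=n_permutations,
        n_iterations=n_iterations,
        delta_observed=pd.Series(obs, index=data_a.columns),
    )


def select_candidates(
    delta_tables: dict[str, pd.Series],
    delta_threshold: float = 50.0,
    signed: bool = False,
) -> tuple[dict[str, list[str]], list[str]]:
    """Per-comparison candidate sets |Delta| > threshold (or signed
    Delta > threshold with ``signed=True``) and their intersection.

    ``delta_tables`` maps a comparison name to its per-protein Delta series
    (typically the three contrasts of each group against the double-negative
    group).  Returns ``(per_comparison_sets, shared)``; ``shared`` preserves
    the protein order of the first comparison.
    """
    selections: dict[str, list[str]] = {}
    for name, delta in delta_tables.items():
        stat = delta if signed else delta.abs()
        selections[name] = list(delta.index[stat > delta_threshold])
    sets = [set(v) for v in selections.values()]
    common = set.intersection(*sets) if sets else set()
    first = next(iter(delta_tables.values()), pd.Series(dtype=float))
    shared = [p for p in first.index if p in common]
    return selections, shared


def to_graphml(network: AssociationNetwork, path) -> None:
    """Optional GraphML export (requires networkx)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(network.protein_ids)
    for row in network.edge_list().itertuples(index=False):
        g.add_edge(row.protein_i, row.protein_j, weight=float(row.weight))
    nx.write_graphml(g, path)
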