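"""Synthetic label-free proteomics datasets with planted ground truth.

The generator emulates the statistical structure a 2x2 mother/child allergy
milk-proteome analysis assumes: four equal groups of samples, log-normal LFQ
intensities, left-censored missing-not-at-random (MNAR) detection, group
specific correlation blocks, differential hub proteins, and a keyword-tagged
protein set with shifted abundance in one group.  Every planted effect is
returned in a :class:`SyntheticTruth` so downstream stages can be tested
against known answers.

Randomness is organised as one master seed with fixed derived streams
(protein baselines, one stream per group's correlated draws, one stream for
censoring), so a configuration plus seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceTable, StudyDesign

DEFAULT_GROUPS = ("M-C-", "M+C-", "M-C+", "M+C+")


class ConfigurationError(ValueError):
    """Inconsistent synthetic configuration (overlapping or out-of-range indices)."""


@dataclass(frozen=True)
class BlockSpec:
    """A correlated protein block: ``size`` consecutive proteins starting at
    ``start``, pairwise correlation ``rho`` in the groups listed in
    ``active_groups`` (independent elsewhere)."""

    start: int
    size: int
    rho: float
    active_groups: tuple[str, ...]

    @property
    def indices(self) -> range:
        return range(self.start, self.start + self.size)


@dataclass(frozen=True)
class HubSpec:
    """A star-shaped differential hub.

    The hub protein at ``index`` is correlated (at ``rho``) with its first
    ``neighbors[g]`` pool proteins in group ``g``; the pool is the run of
    indices directly after the hub.  Neighbors share a single latent factor,
    so neighbor-neighbor correlation is ``rho**2``.
    """

    index: int
    neighbors: dict[str, int] = field(default_factory=dict)
    rho: float = 0.9

    def pool(self) -> range:
        width = max(self.neighbors.values(), default=0)
        return range(self.index + 1, self.index + 1 + width)


@dataclass(frozen=True)
class ShiftSpec:
    """Keyword-tagged proteins whose log10 mean is shifted in one group."""

    indices: tuple[int, ...]
    keyword: str
    group: str
    log10_shift: float


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 4 groups x 75 samples, 687 proteins, log10 LFQ
    intensities around mean 6.0 (sd 0.8), left-censored logistic missingness."""

    n_per_group: int = 75
    n_proteins: int = 687
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    base_log10_mean: float = 6.0
    base_log10_sd: float = 0.8
    protein_mean_sd: float = 0.5
    block_spec: tuple[BlockSpec, ...] = ()
    hub_spec: tuple[HubSpec, ...] = ()
    shifted_set: ShiftSpec | None = None
    censor_quantile: float = 0.0
    censor_softness: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if not (0.0 <= self.censor_quantile < 1.0):
            raise ConfigurationError("censor_quantile must lie in [0, 1)")
        if self.censor_softness <= 0:
            raise ConfigurationError("censor_softness must be positive")
        if len(set(self.group_labels)) != len(self.group_labels):
            raise ConfigurationError("duplicate group labels")
        used: set[int] = set()
        total_block = 0
        for b in self.block_spec:
            idx = set(b.indices)
            total_block += b.size
            if b.start < 0 or b.start + b.size > self.n_proteins:
                raise ConfigurationError(f"block {b} out of protein range")
            if idx & used:
                raise ConfigurationError(f"block {b} overlaps another block/hub")
            if not set(b.active_groups) <= set(self.group_labels):
                raise ConfigurationError(f"block {b} names unknown groups")
            used |= idx
        if total_block > self.n_proteins:
            raise ConfigurationError("block sizes sum beyond n_proteins")
        for h in self.hub_spec:
            if any(n >= self.n_proteins for n in h.neighbors.values()):
                raise ConfigurationError("hub neighbor count must be < n_proteins")
            if not set(h.neighbors) <= set(self.group_labels):
                raise ConfigurationError(f"hub {h} names unknown groups")
            idx = {h.index, *h.pool()}
            if h.index < 0 or (h.pool().stop) > self.n_proteins:
                raise ConfigurationError(f"hub {h} out of protein range")
            if idx & used:
                raise ConfigurationError(f"hub {h} overlaps a block or another hub")
            used |= idx
        if self.shifted_set is not None:
            s = self.shifted_set
            if not set(s.indices) <= set(range(self.n_proteins)):
                raise ConfigurationError("shifted_set indices out of range")
            if s.group not in self.group_labels:
                raise ConfigurationError(f"shifted_set group {s.group!r} unknown")

    def protein_ids(self) -> list[str]:
        width = max(4, len(str(self.n_proteins)))
        return [f"P{i:0{width}d}" for i in range(self.n_proteins)]

    def sample_ids(self) -> list[str]:
        n = self.n_per_group * len(self.group_labels)
        width = max(4, len(str(n)))
        return [f"S{i:0{width}d}" for i in range(n)]


@dataclass
class SyntheticTruth:
    """Planted effects: uncensored log10 matrix, per-group correlation targets,
    shifted protein ids, and the per-protein censoring bound (log10 units;
    -inf means no censoring)."""

    true_log10: pd.DataFrame
    group_correlation_targets: dict[str, pd.DataFrame]
    differential_proteins: list[str]
    censoring_bound: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "true_log10": {
                "index": list(self.true_log10.index),
                "columns": list(self.true_log10.columns),
                "values": self.true_log10.to_numpy().tolist(),
            },
            "differential_proteins": list(self.differential_proteins),
            "censoring_bound": {
                k: (None if np.isneginf(v) else float(v))
                for k, v in self.censoring_bound.items()
            },
        }


def _group_correlation(config: SyntheticConfig, group: str) -> np.ndarray:
    """Target correlation matrix for one group (identity + blocks + hub stars)."""
    corr = np.eye(config.n_proteins)
    for b in config.block_spec:
        if group in b.active_groups:
            idx = np.fromiter(b.indices, dtype=int)
            corr[np.ix_(idx, idx)] = b.rho
            corr[idx, idx] = 1.0
    for h in config.hub_spec:
        m = h.neighbors.get(group, 0)
        if m == 0:
            continue
        nbrs = np.arange(h.index + 1, h.index + 1 + m)
        corr[h.index, nbrs] = corr[nbrs, h.index] = h.rho
        # one shared latent factor => neighbor-neighbor correlation rho^2
        corr[np.ix_(nbrs, nbrs)] = h.rho**2
        corr[nbrs, nbrs] = 1.0
    return corr


def _correlated_normal(corr: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # clip tiny negative eigenvalues from accumulated float error
        w, v = np.linalg.eigh(corr)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, corr.shape[0]))
    return z @ chol.T


def generate_lfq_dataset(
    config: SyntheticConfig,
) -> tuple[AbundanceTable, StudyDesign, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic LFQ dataset with planted ground truth.

    Returns ``(abundance, design, annotation, truth)``.  Abundances are
    ``10**log10`` draws; cells are censored to missing with probability
    following a decreasing logistic in the true log10 value, centred at the
    per-protein ``censor_quantile`` of the pooled true values.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    # fixed stream layout: [means, censor, group 0, group 1, ...]
    streams = master.spawn(2 + len(config.group_labels))
    rng_means = np.random.default_rng(streams[0])
    rng_censor = np.random.default_rng(streams[1])

    J = config.n_proteins
    protein_ids = config.protein_ids()
    sample_ids = config.sample_ids()

    mu = config.base_log10_mean + config.protein_mean_sd * rng_means.standard_normal(J)

    blocks: list[np.ndarray] = []
    corr_targets: dict[str, pd.DataFrame] = {}
    for gi, group in enumerate(config.group_labels):
        corr = _group_correlation(config, group)
        corr_targets[group] = pd.DataFrame(corr, index=protein_ids, columns=protein_ids)
        rng_g = np.random.default_rng(streams[2 + gi])
        latent = _correlated_normal(corr, config.n_per_group, rng_g)
        log10 = mu + config.base_log10_sd * latent
        if config.shifted_set is not None and group == config.shifted_set.group:
            idx = np.fromiter(config.shifted_set.indices, dtype=int)
            log10[:, idx] += config.shifted_set.log10_shift
        blocks.append(log10)

    true_log10 = pd.DataFrame(np.vstack(blocks), index=sample_ids, columns=protein_ids)

    if config.censor_quantile > 0:
        bound = np.quantile(true_log10.to_numpy(), config.censor_quantile, axis=0)
        p_miss = 1.0 / (1.0 + np.exp((true_log10.to_numpy() - bound) / config.censor_softness))
    else:
        bound = np.full(J, -np.inf)
        p_miss = np.zeros_like(true_log10.to_numpy())
    uniforms = rng_censor.uniform(size=true_log10.shape)
    missing = uniforms < p_miss

    raw = np.power(10.0, true_log10.to_numpy())
    raw[missing] = np.nan
    abundance = AbundanceTable(
        pd.DataFrame(raw, index=sample_ids, columns=protein_ids), state="raw"
    )

    design_rows = []
    for group in config.group_labels:
        mother = "+" if "M+" in group else "-"
        child = "+" if "C+" in group else "-"
        design_rows += [(mother, child)] * config.n_per_group
    design = StudyDesign(
        pd.DataFrame(
            design_rows,
            index=pd.Index(sample_ids, name="sample_id"),
            columns=["mother_allergy", "child_allergy"],
        )
    )

    annotation = annotation_table(config)

    shifted_ids = (
        [protein_ids[i] for i in config.shifted_set.indices]
        if config.shifted_set is not None
        else []
    )
    truth = SyntheticTruth(
        true_log10=true_log10,
        group_correlation_targets=corr_targets,
        differential_proteins=shifted_ids,
        censoring_bound=pd.Series(bound, index=protein_ids),
    )
    return abundance, design, annotation, truth


def annotation_table(config: SyntheticConfig) -> pd.DataFrame:
    """Protein -> keyword table; the shifted set carries its configured tag."""
    protein_ids = config.protein_ids()
    keywords = ["other"] * config.n_proteins
    if config.shifted_set is not None:
        for i in config.shifted_set.indices:
            keywords[i] = config.shifted_set.keyword
    return pd.DataFrame({"protein_id": protein_ids, "keyword": keywords})


def generate_group_networks(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Planted per-group reference adjacency (binary, symmetric, unit diagonal).

    Blocks active in a group contribute complete subgraphs; hubs contribute
    star edges from the hub to its first ``neighbors[g]`` pool proteins.
    """
    config.validate()
    protein_ids = config.protein_ids()
    networks: dict[str, pd.DataFrame] = {}
    for group in config.group_labels:
        adj = np.eye(config.n_proteins)
        for b in config.block_spec:
            if group in b.active_groups:
                idx = np.fromiter(b.indices, dtype=int)
                adj[np.ix_(idx, idx)] = 1.0
        for h in config.hub_spec:
            m = h.neighbors.get(group, 0)
            if m:
                nbrs = np.arange(h.index + 1, h.index + 1 + m)
                adj[h.index, nbrs] = adj[nbrs, h.index] = 1.0
        networks[group] = pd.DataFrame(adj, index=protein_ids, columns=protein_ids)
    return networks


def generate_covariance_set(
    n_matrices: int,
    prototypes: list[np.ndarray],
    weights: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Build symmetric matrices S_k = sum_l c_kl z_l z_l' + symmetric noise.

    Inverts the simultaneous-component model so its fitter can be tested
    against known weights and prototypes.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n_matrices, len(prototypes)):
        raise ValueError(
            f"weights shape {weights.shape} != ({n_matrices}, {len(prototypes)})"
        )
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    protos = [np.asarray(z, dtype=float).ravel() for z in prototypes]
    sizes = {z.size for z in protos}
    if len(sizes) != 1:
        raise ValueError("prototypes must share one dimension")
    j = sizes.pop()
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_matrices):
        s = np.zeros((j, j))
        for c, z in zip(weights[k], protos):
            s += c * np.outer(z, z)
        if noise_sd > 0:
            noise = rng.standard_normal((j, j)) * noise_sd
            s += (noise + noise.T) / 2.0
        out.append(s)
    return out
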