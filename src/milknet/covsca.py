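"""Simultaneous low-rank modeling of several symmetric matrices (COVSCA).

A set of K symmetric matrices (group covariance or network adjacency
matrices over the same J proteins) is modeled as non-negative combinations
of L shared low-rank prototypes:

    S_k ~= sum_l c_kl Z_l Z_l',     c_kl >= 0,  ||columns of Z_l|| = 1.

The weights c_k place each matrix as a point in an L-dimensional component
space (the score plot); the prototype loadings say which proteins shape the
differences between the matrices.  Fitting alternates an exactly optimal
non-negative least-squares weights step with an exactly optimal
dominant-eigenvector loadings step, so the Frobenius objective is
monotonically non-increasing; multiple random starts plus one spectral
start guard against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .pclrc import AssociationNetwork


@dataclass
class NetworkCollection:
    """K symmetric J x J matrices over a shared protein set."""

    matrices: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.matrices.values()}
        if len(shapes) != 1:
            raise ValueError(f"matrices differ in shape: {shapes}")
        for name, m in self.matrices.items():
            v = m.to_numpy(dtype=float)
            if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-10):
                raise ValueError(f"matrix {name!r} is not symmetric")

    @property
    def names(self) -> list[str]:
        return list(self.matrices)

    @property
    def protein_ids(self) -> list[str]:
        return list(next(iter(self.matrices.values())).columns)

    @property
    def n_matrices(self) -> int:
        return len(self.matrices)

    @property
    def n_proteins(self) -> int:
        return next(iter(self.matrices.values())).shape[0]

    def arrays(self) -> list[np.ndarray]:
        return [m.to_numpy(dtype=float) for m in self.matrices.values()]

    @classmethod
    def from_networks(
        cls,
        networks: dict[str, AssociationNetwork],
        mode: str = "absolute",
        diagonal: str = "zero",
    ) -> "NetworkCollection":
        """Assemble PCLRC networks into a COVSCA input.

        ``mode``: ``"absolute"`` (default, |weights| keep matrices near PSD)
        or ``"signed"``.  ``diagonal``: ``"zero"`` (default, self-edges do
        not load the Frobenius objective) or ``"unit"``.
        """
        if mode not in ("absolute", "signed"):
            raise ValueError(f"unknown mode {mode!r}")
        if diagonal not in ("zero", "unit"):
            raise ValueError(f"unknown diagonal {diagonal!r}")
        matrices = {}
        for name, net in networks.items():
            w = net.weights.to_numpy(dtype=float).copy()
            if mode == "absolute":
                w = np.abs(w)
            np.fill_diagonal(w, 0.0 if diagonal == "zero" else 1.0)
            matrices[name] = pd.DataFrame(
                w, index=net.weights.index, columns=net.weights.columns
            )
        return cls(matrices)


@dataclass
class CovscaModel:
    """Fitted model: weights (K x L, >= 0), unit-norm loadings per prototype,
    goodness of fit (percent), and convergence metadata."""

    weights: pd.DataFrame              # K x L, non-negative
    loadings: list[pd.DataFrame]       # per prototype: J x R_l, unit-norm cols
    ranks: tuple[int, ...]
    gof_pct: float
    objective_trace: list[float] = field(default_factory=list)
    n_starts: int = 1
    converged: bool = True

    @property
    def n_components(self) -> int:
        return len(self.loadings)

    def prototype(self, l: int) -> np.ndarray:
        z = self.loadings[l].to_numpy(dtype=float)
        return z @ z.T

    def reconstruct(self, k: int) -> np.ndarray:
        c = self.weights.to_numpy(dtype=float)[k]
        j = self.loadings[0].shape[0]
        s = np.zeros((j, j))
        for l in range(self.n_components):
            s += c[l] * self.prototype(l)
        return s


def _nnls_weights(matrices: list[np.ndarray], protos: list[np.ndarray]) -> np.ndarray:
    """Exactly optimal c_k >= 0 per matrix via NNLS on the prototype Gram."""
    L = len(protos)
    gram = np.array([[np.sum(p * q) for q in protos] for p in protos])
    # factor the Gram so ||R c - R^-T b||^2 reproduces the quadratic form
    jitter = 1e-12 * max(np.trace(gram), 1.0)
    chol = np.linalg.cholesky(gram + jitter * np.eye(L))
    weights = np.zeros((len(matrices), L))
    for k, s in enumerate(matrices):
        b = np.array([np.sum(s * p) for p in protos])
        rhs = np.linalg.solve(chol, b)
        weights[k], _ = nnls(chol.T, rhs)
    return weights


def _loading_update(
    matrices: list[np.ndarray], weights: np.ndarray,
    loadings: list[np.ndarray], l: int,
) -> np.ndarray:
    """Optimal unit-norm Z_l given everything else: top eigenvectors of the
    weighted residual sum (largest algebraic eigenvalues)."""
    j = matrices[0].shape[0]
    target = np.zeros((j, j))
    for k, s in enumerate(matrices):
        resid = s.copy()
        for m, z in enumerate(loadings):
            if m != l:
                resid -= weights[k, m] * (z @ z.T)
        target += weights[k, l] * resid
    r = loadings[l].shape[1]
    vals, vecs = np.linalg.eigh((target + target.T) / 2.0)
    top = np.argsort(vals)[::-1][:r]
    return vecs[:, top]


def _objective(matrices, weights, loadings) -> float:
    total = 0.0
    for k, s in enumerate(matrices):
        recon = np.zeros_like(s)
        for l, z in enumerate(loadings):
            recon += weights[k, l] * (z @ z.T)
        total += float(np.sum((s - recon) ** 2))
    return total


def _random_loadings(j, ranks, rng) -> list[np.ndarray]:
    out = []
    for r in ranks:
        z, _ = np.linalg.qr(rng.standard_normal((j, r)))
        out.append(z[:, :r])
    return out


def _spectral_loadings(matrices, ranks) -> list[np.ndarray]:
    mean = np.mean(matrices, axis=0)
    _, vecs = np.linalg.eigh(mean)
    vecs = vecs[:, ::-1]
    out, offset = [], 0
    for r in ranks:
        out.append(vecs[:, offset : offset + r])
        offset += r
    return out


def fit_covsca(
    collection: NetworkCollection | list[np.ndarray],
    n_components: int = 2,
    ranks: tuple[int, ...] | None = None,
    n_starts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int = 0,
) -> CovscaModel:
    """Fit S_k = sum_l c_kl Z_l Z_l' by alternating minimisation.

    Defaults follow the two rank-1 prototype configuration.  The best of
    ``n_starts`` random starts plus one spectral start (top eigenvectors of
    the mean matrix) is returned; convergence is a relative objective
    decrease below ``tol``.
    """
    if isinstance(collection, NetworkCollection):
        matrices = collection.arrays()
        names = collection.names
        protein_ids = collection.protein_ids
    else:
        matrices = [np.asarray(m, dtype=float) for m in collection]
        for i, m in enumerate(matrices):
            if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"matrix {i} is not symmetric")
        names = [f"S{k}" for k in range(len(matrices))]
        protein_ids = [f"P{j}" for j in range(matrices[0].shape[0])]
    k_mats = len(matrices)
    if k_mats < 2:
        raise ValueError("need at least 2 matrices")
    j = matrices[0].shape[0]
    if ranks is None:
        ranks = (1,) * n_components
    if len(ranks) != n_components:
        raise ValueError("one rank per component required")
    if n_components > k_mats * j:
        raise ValueError("more components than the collection can support")

    ss = np.random.SeedSequence(seed)
    starts: list[list[np.ndarray]] = [_spectral_loadings(matrices, ranks)]
    for child in ss.spawn(n_starts):
        starts.append(_random_loadings(j, ranks, np.random.default_rng(child)))

    best = None
    for loadings in starts:
        loadings = [z.copy() for z in loadings]
        trace: list[float] = []
        converged = False
        weights = _nnls_weights(matrices, [z @ z.T for z in loadings])
        obj = _objective(matrices, weights, loadings)
        trace.append(obj)
        for _ in range(max_iter):
            for l in range(n_components):
                loadings[l] = _loading_update(matrices, weights, loadings, l)
            weights = _nnls_weights(matrices, [z @ z.T for z in loadings])
            new_obj = _objective(matrices, weights, loadings)
            trace.append(new_obj)
            if obj - new_obj <= tol * max(obj, 1e-30):
                converged = True
                obj = new_obj
                break
            obj = new_obj
        if best is None or obj < best[0]:
            best = (obj, weights, loadings, trace, converged)

    obj, weights, loadings, trace, converged = best
    # canonical sign: largest-|loading| entry of each column positive
    for z in loadings:
        for c in range(z.shape[1]):
            anchor = np.argmax(np.abs(z[:, c]))
            if z[anchor, c] < 0:
                z[:, c] *= -1.0

    total = sum(float(np.sum(s**2)) for s in matrices)
    gof = 100.0 * (1.0 - obj / total) if total > 0 else np.nan
    weight_frame = pd.DataFrame(
        weights, index=names,
        columns=[f"component_{l + 1}" for l in range(n_components)],
    )
    loading_frames = [
        pd.DataFrame(
            z, index=protein_ids,
            columns=[f"component_{l + 1}_r{c + 1}" for c in range(z.shape[1])],
        )
        for l, z in enumerate(loadings)
    ]
    return CovscaModel(
        weights=weight_frame,
        loadings=loading_frames,
        ranks=tuple(ranks),
        gof_pct=gof,
        objective_trace=trace,
        n_starts=len(starts),
        converged=converged,
    )


def goodness_of_fit(
    model: CovscaModel, collection: NetworkCollection | list[np.ndarray]
) -> float:
    """Percent of total squared Frobenius norm explained:
    100 * (1 - sum_k ||S_k - S_k_hat||_F^2 / sum_k ||S_k||_F^2)."""
    matrices = (
        collection.arrays()
        if isinstance(collection, NetworkCollection)
        else [np.asarray(m, dtype=float) for m in collection]
    )
    total = sum(float(np.sum(s**2)) for s in matrices)
    if total == 0:
        raise ValueError("all-zero collection has no norm to explain")
    resid = sum(
        float(np.sum((s - model.reconstruct(k)) ** 2))
        for k, s in enumerate(matrices)
    )
    return 100.0 * (1.0 - resid / total)


def loading_selection(
    model: CovscaModel, z_threshold: float = 2.0
) -> pd.DataFrame:
    """Standardise each component's loadings to z-scores and flag proteins
    with |z| above the threshold (the proteins driving network differences).

    Only rank-1 components have a single loading vector to standardise;
    higher ranks are standardised column-wise and flagged if any column
    exceeds the threshold.
    """
    pieces = []
    for l, frame in enumerate(model.loadings):
        values = frame.to_numpy(dtype=float)
        sd = values.std(axis=0, ddof=0)
        if (sd <= 1e-12 * (np.abs(values).max() + 1.0)).any():
            raise ValueError(f"component {l + 1} has a zero-variance loading vector")
        z = (values - values.mean(axis=0)) / sd
        selected = (np.abs(z) > z_threshold).any(axis=1)
        pieces.append(
            pd.DataFrame(
                {
                    "component": l + 1,
                    "loading": values[:, 0] if values.shape[1] == 1 else np.nan,
                    "z_score": z[:, 0] if z.shape[1] == 1 else np.abs(z).max(axis=1),
                    "selected": selected,
                },
                index=frame.index,
            )
        )
    out = pd.concat(pieces)
    out.index.name = "protein_id"
    return out.reset_index()


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two loading vectors (sign-sensitive)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
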