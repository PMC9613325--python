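"""Preprocessing: group-validity filtering, log transform, left-censored
imputation, and unit-variance scaling.

The imputer targets the detection-limit missingness of label-free
proteomics: values are missing because they fell below the instrument's
effective limit, so missingness is informative (MNAR) and left-censored.
It runs Gibbs-style sweeps in which each incomplete protein is regressed
on its most correlated peers (ridge-regularised) and its missing cells are
redrawn from a normal centred at the prediction, truncated above at that
protein's observed minimum — the left-censoring constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, StudyDesign, split_by_group


def filter_by_group_validity(
    table: AbundanceTable, design: StudyDesign, min_valid: int = 25
) -> AbundanceTable:
    """Retain proteins with >= ``min_valid`` observed values in at least one
    design group; proteins quantified in only one group are thereby kept.
    Column order is preserved."""
    if table.state not in ("raw", "log10"):
        raise ValueError(f"filter expects raw or log10 state, got {table.state!r}")
    sizes = design.group_sizes()
    if min_valid > sizes.max():
        raise ValueError(
            f"min_valid={min_valid} exceeds the largest group size {sizes.max()}"
        )
    per_group = split_by_group(table, design)
    valid_counts = pd.DataFrame(
        {g: frame.notna().sum(axis=0) for g, frame in per_group.items()}
    )
    keep = valid_counts.max(axis=1) >= min_valid
    kept_cols = [p for p in table.protein_ids if keep[p]]
    return table.with_data(table.data[kept_cols], state=table.state)


def log10_transform(table: AbundanceTable) -> AbundanceTable:
    """log10 of observed cells; missing cells untouched."""
    if table.state != "raw":
        raise ValueError(f"log transform expects raw state, got {table.state!r}")
    values = table.data.to_numpy(dtype=float)
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [
            (table.sample_ids[r], table.protein_ids[c])
            for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValueError(f"non-positive observed values at cells {cells}")
    with np.errstate(invalid="ignore"):
        logged = np.log10(values)
    return table.with_data(
        pd.DataFrame(logged, index=table.data.index, columns=table.data.columns),
        state="log10",
    )


@dataclass
class ImputationResult:
    """Completed log10 matrix plus diagnostics of the Gibbs sweeps."""

    table: AbundanceTable
    truncation_bounds: pd.Series
    n_sweeps: int
    convergence_trace: list[float] = field(default_factory=list)


def impute_left_censored(
    table: AbundanceTable,
    design: StudyDesign | None = None,
    sweeps: int = 20,
    predictor_regularization: float = 1.0,
    n_predictors: int = 40,
    init_fraction: float = 0.9,
    tol: float = 1e-3,
    average_last: int = 5,
    seed: int = 0,
    per_group: bool = False,
) -> ImputationResult:
    """Impute left-censored missing values with truncated-normal Gibbs sweeps.

    Each missing cell is initialised at ``init_fraction`` times the protein's
    observed minimum.  Per sweep, every incomplete protein is regressed
    (ridge, alpha=``predictor_regularization``) on its ``n_predictors`` most
    correlated peers over the current completed matrix, and its missing cells
    are redrawn from a normal at the prediction with the residual sd,
    truncated above at the protein's observed minimum.  Sweeping stops at
    ``sweeps`` or when the mean relative change drops below ``tol``; the
    final matrix averages the last ``average_last`` sweeps.  Observed cells
    are never altered.

    With ``per_group=True`` the procedure runs independently inside each
    design group (requires ``design``); the default imputes the pooled matrix.
    """
    if table.state != "log10":
        raise ValueError(f"imputation expects log10 state, got {table.state!r}")
    if per_group:
        if design is None:
            raise ValueError("per_group imputation requires a design")
        return _impute_per_group(
            table, design, sweeps, predictor_regularization, n_predictors,
            init_fraction, tol, average_last, seed,
        )

    data = table.data.to_numpy(dtype=float).copy()
    missing = np.isnan(data)
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        names = [table.protein_ids[j] for j in np.nonzero(fully_missing)[0]]
        raise ValueError(f"fully missing proteins (filter violated): {names[:5]}")

    obs_min = np.nanmin(np.where(missing, np.nan, data), axis=0)
    bounds = pd.Series(obs_min, index=table.protein_ids)

    if not missing.any():
        return ImputationResult(
            table=table.with_data(table.data.copy(), state="log10-imputed"),
            truncation_bounds=bounds,
            n_sweeps=0,
        )

    completed = data.copy()
    completed[missing] = np.broadcast_to(init_fraction * obs_min, data.shape)[missing]

    rng = np.random.default_rng(seed)
    incomplete_cols = np.nonzero(missing.any(axis=0))[0]
    trace: list[float] = []
    history: list[np.ndarray] = []
    n_sweeps = 0
    for sweep in range(sweeps):
        previous = completed[missing].copy()
        corr = _safe_corr(completed)
        for j in incomplete_cols:
            rows = missing[:, j]
            others = np.delete(np.arange(data.shape[1]), j)
            strength = np.abs(corr[j, others])
            strength[np.isnan(strength)] = 0.0
            k = min(n_predictors, others.size)
            predictors = others[np.argsort(-strength, kind="stable")[:k]]
            x = completed[:, predictors]
            y = completed[:, j]
            coef, intercept = _ridge_fit(
                x[~rows], y[~rows], predictor_regularization
            )
            pred = x[rows] @ coef + intercept
            resid = y[~rows] - (x[~rows] @ coef + intercept)
            sigma = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
            completed[rows, j] = _draw_truncated(pred, sigma, obs_min[j], rng)
        n_sweeps = sweep + 1
        history.append(completed[missing].copy())
        denom = np.maximum(np.abs(previous), 1e-12)
        change = float(np.mean(np.abs(completed[missing] - previous) / denom))
        trace.append(change)
        if change < tol:
            break

    k = min(average_last, len(history))
    final = data.copy()
    final[missing] = np.mean(history[-k:], axis=0)
    # averaging respects each truncation bound because every draw does
    final[missing] = np.minimum(
        final[missing], np.broadcast_to(obs_min, data.shape)[missing]
    )
    out = table.with_data(
        pd.DataFrame(final, index=table.data.index, columns=table.data.columns),
        state="log10-imputed",
    )
    return ImputationResult(out, bounds, n_sweeps, trace)


def _impute_per_group(
    table, design, sweeps, alpha, n_predictors, init_fraction, tol, average_last, seed
) -> ImputationResult:
    pieces = []
    bounds = {}
    traces: list[float] = []
    total_sweeps = 0
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(design.group_labels))
    for child, group in zip(children, design.group_labels):
        sub = table.with_data(
            table.data.loc[design.samples_in(group)], state="log10"
        )
        res = impute_left_censored(
            sub, sweeps=sweeps, predictor_regularization=alpha,
            n_predictors=n_predictors, init_fraction=init_fraction, tol=tol,
            average_last=average_last, seed=int(child.generate_state(1)[0] % 2**31),
        )
        pieces.append(res.table.data)
        bounds[group] = res.truncation_bounds
        traces.extend(res.convergence_trace)
        total_sweeps = max(total_sweeps, res.n_sweeps)
    completed = pd.concat(pieces).reindex(table.data.index)
    out = table.with_data(completed, state="log10-imputed")
    pooled_bounds = pd.DataFrame(bounds).min(axis=1)
    return ImputationResult(out, pooled_bounds, total_sweeps, traces)


def _safe_corr(matrix: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.corrcoef(matrix, rowvar=False)


def _ridge_fit(x: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Closed-form centred ridge; intercept unpenalised."""
    x_mean = x.mean(axis=0)
    y_mean = y.mean()
    xc = x - x_mean
    yc = y - y_mean
    gram = xc.T @ xc + alpha * np.eye(x.shape[1])
    coef = np.linalg.solve(gram, xc.T @ yc)
    return coef, float(y_mean - x_mean @ coef)


def _draw_truncated(
    mean: np.ndarray, sigma: float, upper: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw N(mean, sigma^2) truncated above at ``upper`` (left-censoring)."""
    if sigma <= 0:
        return np.minimum(mean, upper)
    b = (upper - mean) / sigma
    return stats.truncnorm.rvs(
        a=-np.inf, b=b, loc=mean, scale=sigma, random_state=rng
    )


def scale_unit_variance(table: AbundanceTable) -> AbundanceTable:
    """Centre each protein to mean 0 and scale to unit (sample) variance."""
    if table.state not in ("log10-imputed", "scaled"):
        raise ValueError(f"scaling expects an imputed matrix, got {table.state!r}")
    values = table.data.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        names = [table.protein_ids[j] for j in np.nonzero(zero)[0]]
        raise ValueError(f"zero-variance proteins cannot be scaled: {names[:5]}")
    scaled = (values - values.mean(axis=0)) / sd
    return table.with_data(
        pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns),
        state="scaled",
    )


def constant_minimum_impute(table: AbundanceTable) -> AbundanceTable:
    """Baseline imputer: every missing cell set to its protein's observed
    minimum.  Used as the reference the Gibbs imputer must beat."""
    if table.state != "log10":
        raise ValueError(f"expects log10 state, got {table.state!r}")
    data = table.data.to_numpy(dtype=float).copy()
    missing = np.isnan(data)
    obs_min = np.nanmin(np.where(missing, np.nan, data), axis=0)
    data[missing] = np.broadcast_to(obs_min, data.shape)[missing]
    return table.with_data(
        pd.DataFrame(data, index=table.data.index, columns=table.data.columns),
        state="log10-imputed",
    )
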