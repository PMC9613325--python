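"""Unsupervised (PCA) and supervised (Random Forest) structure checks.

These reproduce the negative-control arms of the analysis: PCA asks
whether group structure dominates overall variance; pairwise Random
Forest models with a label-permutation test ask whether any two allergy
groups are separable at all.  Classifier metrics come from out-of-bag
(OOB) votes, the forest's internal validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .containers import AbundanceTable, StudyDesign


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components, with 'group' column
    loadings: pd.DataFrame        # proteins x components
    variance_explained_pct: np.ndarray


def pca_explore(
    table: AbundanceTable,
    design: StudyDesign | None = None,
    n_components: int = 2,
) -> PcaResult:
    """Centered PCA on the scaled matrix with canonical component signs
    (largest-|loading| entry positive), so results are reproducible."""
    if table.state != "scaled":
        raise ValueError(f"PCA expects a scaled table, got state {table.state!r}")
    max_rank = min(table.n_samples, table.n_proteins)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_rank}")
    x = table.data.to_numpy(dtype=float)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # proteins x components
    for c in range(n_components):
        anchor = np.argmax(np.abs(loadings[:, c]))
        if loadings[anchor, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    comp_names = [f"PC{c + 1}" for c in range(n_components)]
    score_frame = pd.DataFrame(scores, index=table.data.index, columns=comp_names)
    if design is not None:
        score_frame["group"] = design.groups.reindex(table.sample_ids).to_numpy()
    return PcaResult(
        scores=score_frame,
        loadings=pd.DataFrame(loadings, index=table.data.columns, columns=comp_names),
        variance_explained_pct=100.0 * model.explained_variance_ratio_,
    )


@dataclass
class ClassifierReport:
    """OOB metrics (percent) with permutation p-values for one group pair."""

    group_pair: tuple[str, str]
    metrics: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    n_trees: int
    extras: dict = field(default_factory=dict)


_METRICS = ("accuracy", "sensitivity", "specificity", "auroc")


def _oob_metrics(
    x: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> dict[str, float]:
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rare never-OOB samples at few trees
        forest.fit(x, y)
        proba = forest.oob_decision_function_[:, 1]
    # samples never out of bag get an uninformative 0.5 vote
    proba = np.where(np.isnan(proba), 0.5, proba)
    pred = (proba > 0.5).astype(int)
    pos, neg = y == 1, y == 0
    return {
        "accuracy": 100.0 * float(np.mean(pred == y)),
        "sensitivity": 100.0 * float(np.mean(pred[pos] == 1)) if pos.any() else np.nan,
        "specificity": 100.0 * float(np.mean(pred[neg] == 0)) if neg.any() else np.nan,
        "auroc": 100.0 * float(roc_auc_score(y, proba)),
    }


def rf_permutation_classifier(
    table: AbundanceTable,
    labels: pd.Series | np.ndarray,
    n_trees: int = 500,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ClassifierReport:
    """Random Forest two-group classifier with a label-permutation test.

    Out-of-bag accuracy, sensitivity, specificity and AUROC are computed on
    the observed labels; for each of ``n_permutations`` label permutations
    the full forest is refit (per-permutation derived seeds) and each
    metric's p-value is ``(1 + #{permuted >= observed}) / (n_permutations+1)``.
    """
    labels = pd.Series(np.asarray(labels), index=table.data.index)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    counts = labels.value_counts()
    if counts.min() < 5:
        raise ValueError(f"class with fewer than 5 samples: {counts.to_dict()}")
    x = table.data.to_numpy(dtype=float)
    y = (labels == classes[1]).to_numpy().astype(int)

    ss = np.random.SeedSequence(seed)
    fit_seed = int(ss.generate_state(1)[0] % 2**31)
    observed = _oob_metrics(x, y, n_trees, fit_seed)

    perm_children = ss.spawn(n_permutations)
    exceed = {m: 0 for m in _METRICS}
    for child in perm_children:
        rng = np.random.default_rng(child)
        y_perm = rng.permutation(y)
        perm_seed = int(child.generate_state(2)[1] % 2**31)
        perm = _oob_metrics(x, y_perm, n_trees, perm_seed)
        for m in _METRICS:
            if perm[m] >= observed[m]:
                exceed[m] += 1
    p_values = {
        m: (1 + exceed[m]) / (n_permutations + 1) for m in _METRICS
    }
    return ClassifierReport(
        group_pair=(str(classes[0]), str(classes[1])),
        metrics=observed,
        p_values=p_values,
        n_permutations=n_permutations,
        n_trees=n_trees,
    )


def pairwise_rf_reports(
    table: AbundanceTable,
    design: StudyDesign,
    n_trees: int = 500,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """All six pairwise group classifiers, as one report table."""
    import itertools

    pairs = list(itertools.combinations(design.group_labels, 2))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pairs))
    rows = []
    for child, (a, b) in zip(children, pairs):
        samples = design.samples_in(a) + design.samples_in(b)
        sub = table.with_data(table.data.loc[samples], state=table.state)
        labels = design.groups.reindex(samples)
        report = rf_permutation_classifier(
            sub, labels, n_trees=n_trees, n_permutations=n_permutations,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        row = {"group_a": a, "group_b": b}
        for m in _METRICS:
            row[m] = report.metrics[m]
            row[f"{m}_p"] = report.p_values[m]
        rows.append(row)
    return pd.DataFrame(rows)
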