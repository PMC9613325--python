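"""Core in-memory containers shared across the pipeline.

An :class:`AbundanceTable` is a samples x proteins matrix of label-free
quantification (LFQ) intensities with explicit missingness (NaN) and a
``state`` tag tracking where the table sits in the preprocessing chain
(``raw`` -> ``log10`` -> ``log10-imputed`` -> ``scaled``).  A
:class:`StudyDesign` maps each sample to one of the four mother/child
allergy groups of the 2x2 factorial design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Allowed transform states, in pipeline order.
STATES = ("raw", "log10", "log10-imputed", "scaled")


@dataclass
class AbundanceTable:
    """Samples x proteins abundance matrix with explicit missing cells.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with protein ids as columns.
        Missing cells are ``NaN``; observed cells are positive reals
        (on the raw scale) or reals (after log transform / scaling).
    state
        One of ``raw``, ``log10``, ``log10-imputed``, ``scaled``.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown transform state {self.state!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in abundance table")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate protein ids in abundance table")
        values = self.data.to_numpy(dtype=float)
        if self.state == "raw" and np.nanmin(values, initial=np.inf) < 0:
            raise ValueError("raw abundance table contains negative values")
        if self.state in ("log10-imputed", "scaled") and np.isnan(values).any():
            raise ValueError(f"state {self.state!r} forbids missing cells")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.data.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where a cell is missing."""
        return self.data.isna()

    def with_data(self, data: pd.DataFrame, state: str) -> "AbundanceTable":
        return AbundanceTable(data=data, state=state)

    def copy(self) -> "AbundanceTable":
        return replace(self, data=self.data.copy())


@dataclass
class StudyDesign:
    """Per-sample group labels over the mother x child allergy factors.

    ``table`` is indexed by sample id with columns ``mother_allergy`` and
    ``child_allergy`` taking values ``"+"`` or ``"-"``.  The derived group
    label is ``"M{m}C{c}"``, e.g. ``"M+C-"`` for an allergic mother with a
    non-allergic child.
    """

    table: pd.DataFrame
    factors: tuple[str, str] = ("mother_allergy", "child_allergy")
    _groups: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = [f for f in self.factors if f not in self.table.columns]
        if missing:
            raise ValueError(f"design table lacks factor columns {missing}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in design table")
        for f in self.factors:
            bad = set(self.table[f].unique()) - {"+", "-"}
            if bad:
                raise ValueError(f"factor {f!r} has levels {bad}, expected '+'/'-'")
        m, c = self.factors
        self._groups = "M" + self.table[m] + "C" + self.table[c]
        self._groups.name = "group"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        """Series sample id -> group label (e.g. 'M+C-')."""
        return self._groups

    @property
    def group_labels(self) -> list[str]:
        """Group labels present, in fixed factorial order then appearance order."""
        canonical = ["M-C-", "M+C-", "M-C+", "M+C+"]
        present = set(self._groups)
        ordered = [g for g in canonical if g in present]
        ordered += [g for g in pd.unique(self._groups) if g not in canonical]
        return ordered

    def samples_in(self, group: str) -> list[str]:
        return list(self._groups.index[self._groups == group])

    def group_sizes(self) -> pd.Series:
        return self._groups.value_counts().reindex(self.group_labels)

    def check_matches(self, table: AbundanceTable) -> None:
        """Every abundance sample must carry exactly one label."""
        unlabeled = set(table.sample_ids) - set(self.sample_ids)
        if unlabeled:
            raise ValueError(f"samples without design labels: {sorted(unlabeled)[:5]}")


def split_by_group(table: AbundanceTable, design: StudyDesign) -> dict[str, pd.DataFrame]:
    """Partition the abundance matrix by design group (preserving sample order)."""
    design.check_matches(table)
    groups = design.groups.reindex(table.sample_ids)
    return {g: table.data.loc[groups == g] for g in design.group_labels}
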