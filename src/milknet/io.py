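"""Reading and writing the pipeline's three input tables.

The abundance input is either a MaxQuant-style ``proteinGroups`` export
(one protein per row, ``LFQ intensity <sample>`` columns, optional
``Reverse`` / ``Potential contaminant`` flag columns) or a plain
samples x proteins TSV; the dialect is auto-detected from the header.
Zeros and blanks are missing values, following standard LFQ semantics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable, StudyDesign
from .datasets import SyntheticTruth

LFQ_PREFIX = "LFQ intensity "
FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")
PROTEIN_ID_COLUMNS = ("Protein IDs", "Majority protein IDs", "protein_id")


def read_protein_table(
    path: str | Path,
    missing_policy: str = "zero-as-missing",
    exclude_flagged: bool = True,
) -> AbundanceTable:
    """Read an abundance table, normalising orientation to samples x proteins.

    Parameters
    ----------
    path
        TSV file.  ``LFQ intensity <sample>`` columns trigger proteinGroups
        mode; otherwise the file is read as a plain samples x proteins matrix
        with sample ids in the first column.
    missing_policy
        ``"zero-as-missing"`` (default) maps 0 and blank to NaN;
        ``"blank-only"`` keeps zeros as observed values.
    exclude_flagged
        In proteinGroups mode, drop rows flagged ``+`` in any of the
        standard reverse/contaminant columns.  The number of dropped rows
        is stored in ``table.data.attrs["n_flagged_excluded"]``.
    """
    if missing_policy not in ("zero-as-missing", "blank-only"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    lfq_cols = [c for c in frame.columns if c.startswith(LFQ_PREFIX)]
    if lfq_cols:
        table = _read_protein_groups(frame, lfq_cols, exclude_flagged)
    else:
        table = _read_plain_matrix(frame, path)
    data = table.data
    if missing_policy == "zero-as-missing":
        data = data.mask(data == 0.0)
    if data.columns.has_duplicates:
        dupes = data.columns[data.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein IDs: {dupes[:5]}")
    out = AbundanceTable(data, state="raw")
    out.data.attrs.update(table.data.attrs)
    return out


def _read_protein_groups(
    frame: pd.DataFrame, lfq_cols: list[str], exclude_flagged: bool
) -> AbundanceTable:
    id_col = next((c for c in PROTEIN_ID_COLUMNS if c in frame.columns), None)
    if id_col is None:
        raise ValueError(
            f"no protein ID column among {PROTEIN_ID_COLUMNS} in header "
            f"{list(frame.columns)[:6]}"
        )
    n_flagged = 0
    if exclude_flagged:
        flags = [c for c in FLAG_COLUMNS if c in frame.columns]
        if flags:
            flagged = (frame[flags] == "+").any(axis=1)
            n_flagged = int(flagged.sum())
            frame = frame.loc[~flagged]
    ids = frame[id_col]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein IDs: {dupes[:5]}")
    values = frame[lfq_cols].apply(pd.to_numeric, errors="coerce")
    sample_ids = [c.removeprefix(LFQ_PREFIX) for c in lfq_cols]
    # proteinGroups is proteins x samples; transpose to samples x proteins
    data = pd.DataFrame(
        values.to_numpy().T,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.Index(frame[id_col].to_numpy(), name="protein_id"),
    )
    data.attrs["n_flagged_excluded"] = n_flagged
    return AbundanceTable(data, state="raw")


def _read_plain_matrix(frame: pd.DataFrame, path: str | Path) -> AbundanceTable:
    if frame.shape[1] < 2:
        raise ValueError(
            f"no LFQ intensity columns and fewer than 2 columns in {path}; "
            f"header parsed as {list(frame.columns)}"
        )
    data = frame.set_index(frame.columns[0])
    data.index.name = "sample_id"
    data.columns.name = "protein_id"
    data = data.apply(pd.to_numeric, errors="coerce")
    return AbundanceTable(data, state="raw")


def write_protein_groups(table: AbundanceTable, path: str | Path) -> None:
    """Write a proteinGroups-style TSV (proteins x 'LFQ intensity <sample>');
    missing cells are written as 0 per LFQ convention."""
    data = table.data
    values = data.to_numpy().T
    out = pd.DataFrame(
        {
            "Protein IDs": data.columns,
            **{
                f"{LFQ_PREFIX}{sample}": np.nan_to_num(values[:, j], nan=0.0)
                for j, sample in enumerate(data.index)
            },
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> StudyDesign:
    """Design CSV with columns sample_id, mother_allergy, child_allergy."""
    frame = pd.read_csv(path, dtype=str).set_index("sample_id")
    return StudyDesign(frame)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Annotation CSV: protein_id, keyword (multiple rows per protein allowed)."""
    frame = pd.read_csv(path, dtype=str)
    expected = {"protein_id", "keyword"}
    if not expected <= set(frame.columns):
        raise ValueError(f"annotation header {list(frame.columns)} lacks {expected}")
    return frame


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, index=False)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh)


def write_synthetic_inputs(
    abundance: AbundanceTable,
    design: StudyDesign,
    annotation: pd.DataFrame,
    truth: SyntheticTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write the three pipeline inputs plus the truth JSON into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": directory / "proteinGroups.txt",
        "design": directory / "design.csv",
        "annotation": directory / "annotation.csv",
        "truth": directory / "truth.json",
    }
    write_protein_groups(abundance, paths["abundance"])
    write_design(design, paths["design"])
    write_annotation(annotation, paths["annotation"])
    write_truth(truth, paths["truth"])
    return paths
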