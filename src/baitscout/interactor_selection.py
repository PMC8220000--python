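"""Three-criterion prioritization of bait interactors from the iBAQ grid.

A protein is selected when it (i) was identified with at least
``min_unique_peptides`` unique peptide sequences, (ii) was detected in at
least ``min_detected_bait_runs`` of the bait IP runs (both cell lines
pooled), and (iii) its bait/control iBAQ ratio strictly exceeds
``min_ratio`` in every cell line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SelectionCriteria",
    "summarize_condition",
    "compute_ratios",
    "select_interactors",
    "select_from_ratio_table",
    "evaluate_against_truth",
]


@dataclass(frozen=True)
class SelectionCriteria:
    min_unique_peptides: int = 2
    min_detected_bait_runs: int = 4
    total_bait_runs: int = 6
    min_ratio: float = 30.0  # strict: ratio must EXCEED this
    require_ratio_in_all_cell_lines: bool = True
    unique_peptides_per_run: bool = False  # False: experiment-wide maximum
    aggregation: str = "mean"  # replicate summary: "mean" or "geomean"

    def __post_init__(self) -> None:
        if self.min_detected_bait_runs > self.total_bait_runs:
            raise ValueError("min_detected_bait_runs cannot exceed total_bait_runs")
        if self.min_ratio <= 0:
            raise ValueError("min_ratio must be positive")
        if self.aggregation not in ("mean", "geomean"):
            raise ValueError("aggregation must be 'mean' or 'geomean'")


def _aggregate(values: pd.Series, how: str) -> float:
    if how == "geomean":
        return float(np.exp(np.log(values).mean()))
    return float(values.mean())


def summarize_condition(
    quants: pd.DataFrame, cell_line: str, condition: str, aggregation: str = "mean"
) -> pd.Series:
    """Per-protein summary iBAQ across replicates of one (cell line, condition).

    Operates on the imputation-complete grid, so undetected replicates
    contribute the background constant.
    """
    mask = (quants["cell_line"] == cell_line) & (quants["condition"] == condition)
    if not mask.any():
        raise ValueError(f"no runs for cell_line={cell_line!r}, condition={condition!r}")
    sub = quants.loc[mask]
    return sub.groupby("protein_accession")["ibaq"].apply(lambda v: _aggregate(v, aggregation))


def compute_ratios(
    quants: pd.DataFrame,
    cell_lines: list[str] | None = None,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Per-protein bait/control summary-iBAQ ratio for each cell line.

    Both summaries are >= the background constant after imputation, so the
    ratio is always finite and strictly positive.
    """
    if cell_lines is None:
        cell_lines = list(dict.fromkeys(quants["cell_line"]))
    out = {}
    for cell in cell_lines:
        bait = summarize_condition(quants, cell, "bait", aggregation)
        control = summarize_condition(quants, cell, "control", aggregation)
        out[f"ratio_{cell}"] = bait / control
    ratios = pd.DataFrame(out)
    ratios.index.name = "protein_accession"
    return ratios


def _rank_selected(records: pd.DataFrame, ratio_cols: list[str]) -> pd.DataFrame:
    """Assign ranks 1..k to selected records: first cell line's ratio
    descending, ties by the following ratio columns, then accession."""
    records = records.copy()
    records["rank"] = pd.NA
    selected = records[records["selected"]].copy()
    if len(selected):
        order = selected.sort_values(
            by=[*ratio_cols, "protein_accession"],
            ascending=[False] * len(ratio_cols) + [True],
            kind="mergesort",
        ).index
        records.loc[order, "rank"] = np.arange(1, len(order) + 1)
    records["rank"] = records["rank"].astype("Int64")
    return records


def select_interactors(
    quants: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
    cell_lines: list[str] | None = None,
) -> pd.DataFrame:
    """Apply criteria (i)-(iii) to an imputation-complete iBAQ grid.

    Returns one row per protein with per-cell-line ratios, detection and
    unique-peptide metadata, the three criterion flags, ``selected``, and the
    rank (1..k over selected proteins, by first cell line's ratio
    descending).
    """
    criteria = criteria or SelectionCriteria()
    if cell_lines is None:
        cell_lines = list(dict.fromkeys(quants["cell_line"]))

    bait = quants[quants["condition"] == "bait"]
    n_bait_runs = bait["run_id"].nunique()
    if criteria.total_bait_runs > n_bait_runs:
        raise ValueError(
            f"criteria reference {criteria.total_bait_runs} bait runs but the "
            f"grid contains only {n_bait_runs}"
        )

    ratios = compute_ratios(quants, cell_lines, criteria.aggregation)
    ratio_cols = [f"ratio_{c}" for c in cell_lines]

    detected_bait = bait[bait["detected"]].groupby("protein_accession")["run_id"].nunique()
    # experiment-wide unique-peptide count: maximum over runs of per-run
    # distinct sequences (the grid no longer carries raw peptide identities)
    unique_pep = quants.groupby("protein_accession")["n_unique_peptides"].max()

    records = ratios.reset_index()
    genes = quants.drop_duplicates("protein_accession").set_index("protein_accession")["gene_symbol"]
    records.insert(1, "gene_symbol", records["protein_accession"].map(genes))
    records["n_detected_bait_runs"] = (
        records["protein_accession"].map(detected_bait).fillna(0).astype(int)
    )
    records["max_unique_peptides"] = (
        records["protein_accession"].map(unique_pep).fillna(0).astype(int)
    )

    if criteria.unique_peptides_per_run:
        # stricter mode: the peptide threshold must hold in every bait run
        # where the protein was detected
        bait_det = bait[bait["detected"]]
        per_run_ok = bait_det.groupby("protein_accession")["n_unique_peptides"].min()
        records["pass_i"] = (
            records["protein_accession"].map(per_run_ok).fillna(0)
            >= criteria.min_unique_peptides
        )
    else:
        records["pass_i"] = records["max_unique_peptides"] >= criteria.min_unique_peptides
    records["pass_ii"] = records["n_detected_bait_runs"] >= criteria.min_detected_bait_runs
    if criteria.require_ratio_in_all_cell_lines:
        records["pass_iii"] = (records[ratio_cols] > criteria.min_ratio).all(axis=1)
    else:
        records["pass_iii"] = (records[ratio_cols] > criteria.min_ratio).any(axis=1)
    records["selected"] = records["pass_i"] & records["pass_ii"] & records["pass_iii"]
    return _rank_selected(records, ratio_cols)


def select_from_ratio_table(
    ratios: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
) -> pd.DataFrame:
    """Apply the criteria to a precomputed per-cell-line ratio table.

    ``ratios`` must carry ``protein_accession`` plus one ``ratio_<cell>``
    column per cell line; detection / unique-peptide metadata columns
    (``n_detected_bait_runs``, ``max_unique_peptides``) are honoured when
    present and assumed passing otherwise (the precomputed-table mode exists
    for post-filter published tables).
    """
    criteria = criteria or SelectionCriteria()
    ratio_cols = [c for c in ratios.columns if c.startswith("ratio_")]
    if not ratio_cols:
        raise ValueError("ratio table has no ratio_<cell_line> columns")
    records = ratios.copy()
    if "max_unique_peptides" in records.columns:
        records["pass_i"] = records["max_unique_peptides"] >= criteria.min_unique_peptides
    else:
        records["pass_i"] = True
    if "n_detected_bait_runs" in records.columns:
        records["pass_ii"] = records["n_detected_bait_runs"] >= criteria.min_detected_bait_runs
    else:
        records["pass_ii"] = True
    if criteria.require_ratio_in_all_cell_lines:
        records["pass_iii"] = (records[ratio_cols] > criteria.min_ratio).all(axis=1)
    else:
        records["pass_iii"] = (records[ratio_cols] > criteria.min_ratio).any(axis=1)
    records["selected"] = records["pass_i"] & records["pass_ii"] & records["pass_iii"]
    if "rank" in records.columns:
        records = records.drop(columns="rank")
    return _rank_selected(records, ratio_cols)


def evaluate_against_truth(records: pd.DataFrame, truth: dict[str, str]) -> dict[str, float]:
    """Precision / recall / F1 of the selected set against simulation truth.

    Empty selections have precision 1 by convention; recall over an empty
    positive class is 1 by the same convention.
    """
    unlabeled = [a for a in records["protein_accession"] if a not in truth]
    if unlabeled:
        raise KeyError(f"protein(s) missing from truth labels: {unlabeled}")
    selected = set(records.loc[records["selected"], "protein_accession"])
    positives = {a for a, label in truth.items() if label == "true_interactor"}
    tp = len(selected & positives)
    precision = tp / len(selected) if selected else 1.0
    recall = tp / len(positives) if positives else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}
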