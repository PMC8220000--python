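"""Peptide-to-protein quantification: in-silico tryptic digestion and iBAQ.

iBAQ for a (protein, run) pair is the summed peptide precursor intensity
divided by the number of theoretically observable tryptic peptides of that
protein.  Pairs with no observed peptide are imputed to a fixed background
intensity so every downstream ratio is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import ProteinDatabase

__all__ = ["QuantConfig", "tryptic_digest", "count_theoretical_peptides", "compute_ibaq"]

_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class QuantConfig:
    """Parameters of the iBAQ computation.

    The observable-length window [7, 30] with zero missed cleavages is the
    conventional choice for the theoretical-peptide denominator; the imputed
    background of 1000 intensity units replaces undetected (protein, run)
    cells.
    """

    background_intensity: float = 1000.0
    observable_min_len: int = 7
    observable_max_len: int = 30
    missed_cleavages_for_theoretical_count: int = 0

    def __post_init__(self) -> None:
        if self.background_intensity <= 0:
            raise ValueError("background_intensity must be positive")
        if not (0 < self.observable_min_len <= self.observable_max_len):
            raise ValueError("require 0 < observable_min_len <= observable_max_len")
        if self.missed_cleavages_for_theoretical_count < 0:
            raise ValueError("missed cleavages must be >= 0")


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Digest with trypsin specificity: cleave C-terminal to K or R, except
    when the following residue is proline.

    With ``missed_cleavages = m`` the result also contains every
    concatenation of up to ``m + 1`` adjacent fully-cleaved fragments.
    Peptides are returned in N->C order of their start position (shorter
    spans first at equal start).
    """
    bad = set(sequence) - _VALID_AA
    if bad:
        raise ValueError(f"invalid residue character(s): {''.join(sorted(bad))}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")

    fragments: list[str] = []
    start = 0
    for i, residue in enumerate(sequence):
        if residue in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])

    peptides: list[str] = []
    for i in range(len(fragments)):
        for span in range(1, missed_cleavages + 2):
            if i + span > len(fragments):
                break
            peptides.append("".join(fragments[i : i + span]))
    return peptides


def count_theoretical_peptides(sequence: str, cfg: QuantConfig | None = None) -> int:
    """Number of digest peptides within the observable length window.

    Clamped to a minimum of 1 so the iBAQ denominator is never zero.
    """
    cfg = cfg or QuantConfig()
    peptides = tryptic_digest(sequence, cfg.missed_cleavages_for_theoretical_count)
    count = sum(
        cfg.observable_min_len <= len(p) <= cfg.observable_max_len for p in peptides
    )
    return max(count, 1)


def compute_ibaq(
    peptides: pd.DataFrame,
    db: ProteinDatabase,
    cfg: QuantConfig | None = None,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Compute the complete protein x run iBAQ grid.

    Parameters
    ----------
    peptides
        Validated peptide table (see :func:`baitscout.io_formats.read_peptide_table`).
    db
        Protein database covering every accession in ``peptides``.
    cfg
        Quantification parameters.
    universe
        Optional additional accessions to force into the grid (must exist in
        ``db``); defaults to the accessions observed in ``peptides``.

    Returns
    -------
    DataFrame with one row per (protein, run) cell and columns
    ``protein_accession, gene_symbol, run_id, cell_line, condition,
    replicate, ibaq, n_unique_peptides, detected, imputed``.
    """
    cfg = cfg or QuantConfig()
    observed = list(dict.fromkeys(peptides["protein_accession"]))
    missing = [a for a in observed if a not in db]
    if missing:
        raise KeyError(f"accession(s) absent from the protein database: {missing}")
    accessions = list(dict.fromkeys(observed + list(universe or [])))
    missing = [a for a in accessions if a not in db]
    if missing:
        raise KeyError(f"accession(s) absent from the protein database: {missing}")

    runs = (
        peptides[["run_id", "cell_line", "condition", "replicate"]]
        .drop_duplicates("run_id")
        .set_index("run_id")
    )

    theoretical = {
        acc: count_theoretical_peptides(db[acc].sequence, cfg) for acc in accessions
    }

    grouped = peptides.groupby(["protein_accession", "run_id"]).agg(
        total_intensity=("intensity", "sum"),
        n_unique_peptides=("peptide_sequence", "nunique"),
    )

    rows = []
    for acc in accessions:
        gene = db[acc].gene_symbol
        for run_id, run_meta in runs.iterrows():
            if (acc, run_id) in grouped.index:
                cell = grouped.loc[(acc, run_id)]
                ibaq = cell["total_intensity"] / theoretical[acc]
                n_unique = int(cell["n_unique_peptides"])
                detected = True
            else:
                ibaq = cfg.background_intensity
                n_unique = 0
                detected = False
            rows.append(
                {
                    "protein_accession": acc,
                    "gene_symbol": gene,
                    "run_id": run_id,
                    "cell_line": run_meta["cell_line"],
                    "condition": run_meta["condition"],
                    "replicate": run_meta["replicate"],
                    "ibaq": float(ibaq),
                    "n_unique_peptides": n_unique,
                    "detected": detected,
                    "imputed": not detected,
                }
            )
    return pd.DataFrame(rows)
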