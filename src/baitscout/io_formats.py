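"""Readers and writers for every external format the pipeline touches.

All tabular dialects are UTF-8, tab-separated, ``.`` decimal, no quoting, so
that outputs are bit-reproducible across platforms.  Missing intensities are
encoded by row *absence*, never by zeros or sentinels; imputation is the
quantification stage's job.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ProteinDatabase",
    "Cohort",
    "GeneSet",
    "GeneSetCollection",
    "PEPTIDE_COLUMNS",
    "read_peptide_table",
    "write_peptide_table",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_cohort",
    "write_cohort",
    "write_interactor_table",
    "write_enrichment_report",
    "write_forest_table",
    "load_interactor_ratio_fixture",
    "load_expression_fixture",
    "load_tumor_mass_fixture",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


#: required columns of the peptide-level intensity table, in canonical order
PEPTIDE_COLUMNS = [
    "run_id",
    "cell_line",
    "condition",
    "replicate",
    "protein_accession",
    "gene_symbol",
    "peptide_sequence",
    "intensity",
]

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


@dataclass(frozen=True)
class ProteinRecord:
    gene_symbol: str
    sequence: str


@dataclass
class ProteinDatabase:
    """Accession-keyed protein sequences with gene symbols."""

    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.records[accession]

    def accessions(self) -> list[str]:
        return list(self.records)

    def add(self, accession: str, gene_symbol: str, sequence: str) -> None:
        if accession in self.records:
            raise FormatError(f"duplicate accession: {accession}")
        sequence = sequence.upper().replace("*", "")
        if not sequence:
            raise FormatError(f"empty sequence for accession {accession}")
        self.records[accession] = ProteinRecord(gene_symbol, sequence)


@dataclass
class Cohort:
    """Gene x sample expression matrix joined to per-sample survival.

    ``expression`` is indexed by gene symbol with one column per sample
    (log2 scale); ``survival`` is indexed by the same sample identifiers with
    columns ``time`` (days, >= 0) and ``event`` (0/1).
    """

    cohort_id: str
    expression: pd.DataFrame
    survival: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.survival.index):
            raise FormatError(
                f"cohort {self.cohort_id}: expression samples and survival "
                "samples do not coincide"
            )
        if self.survival[["time", "event"]].isna().any().any():
            raise FormatError(f"cohort {self.cohort_id}: missing survival entries")
        if (self.survival["time"] < 0).any():
            raise FormatError(f"cohort {self.cohort_id}: negative survival time")
        if not self.survival["event"].isin([0, 1]).all():
            raise FormatError(f"cohort {self.cohort_id}: event must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise FormatError("gene set names must be unique")
        for s in self.sets:
            if not s.genes:
                raise FormatError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

def read_peptide_table(path) -> pd.DataFrame:
    """Read and validate a peptide-level intensity TSV.

    Raises :class:`FormatError` for missing columns, non-positive or
    non-numeric intensities, invalid residues, unknown conditions, or
    duplicate (run, accession, peptide) rows.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"peptide table is missing column(s): {', '.join(missing)}")
    table = table[PEPTIDE_COLUMNS].copy()
    return validate_peptide_table(table)


def validate_peptide_table(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    intensity = pd.to_numeric(table["intensity"], errors="coerce")
    bad = intensity.isna() | (intensity <= 0)
    if bad.any():
        row = table.index[bad][0]
        raise FormatError(
            "intensity must be a positive number (absence of a row encodes "
            f"missingness); offending value {table.loc[row, 'intensity']!r} "
            f"at row {row}"
        )
    table["intensity"] = intensity.astype(float)
    replicate = pd.to_numeric(table["replicate"], errors="coerce")
    if replicate.isna().any() or (replicate < 1).any() or (replicate % 1 != 0).any():
        raise FormatError("replicate must be a positive integer")
    table["replicate"] = replicate.astype(int)
    bad_cond = ~table["condition"].isin(["bait", "control"])
    if bad_cond.any():
        raise FormatError(
            f"condition must be 'bait' or 'control', got "
            f"{table.loc[bad_cond.idxmax(), 'condition']!r}"
        )
    bad_seq = ~table["peptide_sequence"].astype(str).str.fullmatch(_AA_RE.pattern)
    if bad_seq.any():
        raise FormatError(
            "invalid peptide sequence "
            f"{table.loc[bad_seq.idxmax(), 'peptide_sequence']!r}"
        )
    key = ["run_id", "protein_accession", "peptide_sequence"]
    dup = table.duplicated(key, keep=False)
    if dup.any():
        offender = table.loc[dup, key].iloc[0]
        raise FormatError(
            "duplicate peptide observation: "
            f"run={offender.run_id!r} accession={offender.protein_accession!r} "
            f"peptide={offender.peptide_sequence!r}"
        )
    return table.reset_index(drop=True)


def write_peptide_table(table: pd.DataFrame, path) -> None:
    table[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> ProteinDatabase:
    """Read protein sequences from FASTA.

    Header convention is ``>accession|gene_symbol description``; the gene
    symbol falls back to the accession when the ``|`` field is absent.
    """
    db = ProteinDatabase()
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        accession = parts[0]
        gene = parts[1] if len(parts) > 1 and parts[1] else accession
        db.add(accession, gene, str(record.seq))
    return db


def write_fasta(db: ProteinDatabase, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for accession, rec in db.records.items():
            fh.write(f">{accession}|{rec.gene_symbol}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(name, description, frozenset(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def read_cohort(expr_path, surv_path, cohort_id: str) -> Cohort:
    """Read an expression TSV + survival CSV pair, inner-joined on sample id.

    Samples present in only one of the two files are dropped (the count is
    logged); zero overlap is an error.
    """
    expr = pd.read_csv(expr_path, sep="\t", comment="#")
    if expr.columns[0] != "gene":
        raise FormatError("expression table must have 'gene' as its first column")
    expr = expr.set_index("gene")
    surv = pd.read_csv(surv_path, comment="#")
    required = {"sample_id", "time_days", "event"}
    if not required.issubset(surv.columns):
        raise FormatError(
            f"survival table must have columns {sorted(required)}"
        )
    surv = surv.set_index("sample_id")
    shared = [s for s in expr.columns if s in surv.index]
    if not shared:
        raise FormatError(
            f"cohort {cohort_id}: no overlapping samples between expression "
            "and survival"
        )
    dropped = (len(expr.columns) - len(shared)) + (len(surv.index) - len(shared))
    if dropped:
        logger.info("cohort %s: dropped %d non-overlapping sample(s)", cohort_id, dropped)
    survival = pd.DataFrame(
        {"time": surv.loc[shared, "time_days"].astype(float),
         "event": surv.loc[shared, "event"].astype(int)},
        index=pd.Index(shared, name="sample_id"),
    )
    return Cohort(cohort_id, expr[shared].astype(float), survival)


def write_cohort(cohort: Cohort, expr_path, surv_path) -> None:
    out = cohort.expression.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(expr_path, sep="\t", index=False)
    surv = pd.DataFrame(
        {
            "sample_id": cohort.survival.index,
            "time_days": cohort.survival["time"].values,
            "event": cohort.survival["event"].values,
        }
    )
    surv.to_csv(surv_path, index=False)


# ---------------------------------------------------------------------------
# result writers (stable, documented column orders)
# ---------------------------------------------------------------------------

INTERACTOR_COLUMNS = [
    "rank",
    "protein_accession",
    "gene_symbol",
    "ratio_nb4",  # placeholder names replaced by actual cell lines at write time
]


def _write_tsv(frame: pd.DataFrame, columns: list[str], path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame[columns].to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_interactor_table(records: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write the ranked interactor table.

    Column order: rank, protein_accession, gene_symbol, one ``ratio_<cell>``
    column per cell line, n_detected_bait_runs, max_unique_peptides,
    pass_i..pass_iii, selected.
    """
    ratio_cols = sorted(c for c in records.columns if c.startswith("ratio_"))
    columns = ["rank", "protein_accession", "gene_symbol", *ratio_cols]
    for extra in ["n_detected_bait_runs", "max_unique_peptides",
                  "pass_i", "pass_ii", "pass_iii", "selected"]:
        if extra in records.columns:
            columns.append(extra)
    _write_tsv(records, columns, path, header_comment)


def write_enrichment_report(results: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write ORA or GSEA results with their canonical column order."""
    if "es" in results.columns:  # GSEA
        columns = ["set_name", "size", "es", "nes", "nominal_p", "fdr_q",
                   "significant", "leading_edge"]
    else:  # ORA
        columns = ["set_name", "k", "n", "K", "N", "p_value", "q_value",
                   "significant"]
    _write_tsv(results, [c for c in columns if c in results.columns], path, header_comment)


def write_forest_table(fits: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write the per-gene, per-cohort hazard-ratio table (forest layout)."""
    columns = ["gene", "cohort_id", "beta", "se", "hr", "ci95_low", "ci95_high",
               "z", "p", "diverged", "reproducible"]
    _write_tsv(fits, [c for c in columns if c in fits.columns], path, header_comment)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _load_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("baitscout.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_interactor_ratio_fixture() -> pd.DataFrame:
    """49-row ranked interactor table with per-cell-line bait/control ratios."""
    table = _load_packaged("interactor_ratio_table.tsv")
    if len(table) != 49:
        raise FormatError("interactor ratio fixture corrupted: expected 49 rows")
    return table


def load_expression_fixture() -> pd.DataFrame:
    """Per-gene HSC vs AML log2 medians and p-values (50 printed rows)."""
    return _load_packaged("hsc_aml_expression_table.tsv")


def load_tumor_mass_fixture() -> pd.DataFrame:
    """Xenograft tumor-mass group summaries for the fold-change worked example."""
    return _load_packaged("xenograft_tumor_mass.tsv")
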