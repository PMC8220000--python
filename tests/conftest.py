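from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from baitscout.io_formats import Cohort, ProteinDatabase


@pytest.fixture
def tiny_db() -> ProteinDatabase:
    db = ProteinDatabase()
    # two observable (len 7-30) tryptic peptides each
    db.add("P1", "GENE1", "AAAAAAAKCCCCCCCCCR")
    db.add("P2", "GENE2", "DDDDDDDKEEEEEEEEEK")
    return db


def make_peptide_rows(rows):
    """Build a validated-shape peptide table from compact tuples
    (run_id, cell, cond, rep, acc, gene, peptide, intensity)."""
    return pd.DataFrame(
        rows,
        columns=["run_id", "cell_line", "condition", "replicate",
                 "protein_accession", "gene_symbol", "peptide_sequence",
                 "intensity"],
    )


@pytest.fixture
def tiny_peptides(tiny_db) -> pd.DataFrame:
    rows = []
    for cell in ("NB4", "U937"):
        for cond in ("bait", "control"):
            for rep in (1, 2, 3):
                run = f"{cell}_{cond}_{rep}"
                # P1 everywhere; P2 only in bait runs
                rows.append((run, cell, cond, rep, "P1", "GENE1",
                             "AAAAAAAK", 1.0e6))
                if cond == "bait":
                    rows.append((run, cell, cond, rep, "P2", "GENE2",
                                 "DDDDDDDK", 2.0e6))
                    rows.append((run, cell, cond, rep, "P2", "GENE2",
                                 "EEEEEEEEEK", 4.0e6))
    return make_peptide_rows(rows)


@pytest.fixture
def toy_cohort() -> Cohort:
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(5)]
    samples = [f"S{i}" for i in range(8)]
    expr = pd.DataFrame(rng.normal(8, 1, size=(5, 8)), index=genes,
                        columns=samples)
    surv = pd.DataFrame(
        {"time": rng.exponential(365, 8), "event": [1, 1, 0, 1, 1, 0, 1, 1]},
        index=pd.Index(samples, name="sample_id"),
    )
    return Cohort("TOY", expr, surv)
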