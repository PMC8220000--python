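"""Simulators with known ground truth for every downstream stage.

``simulate_ipms`` emulates a bait-vs-isotype-control IP-MS design (two cell
lines, three replicates per condition) with log-normal peptide intensities,
a bait-specific enrichment shift for true interactors, an abundant-in-both
contaminant class, and logistic intensity-dependent dropout.
``simulate_cohorts`` plants a log-linear hazard on a subset of correlated
signature genes in otherwise-noise expression cohorts with exponential event
and censoring times.  ``simulate_gene_sets`` plants one signature-derived
gene set among uniform decoys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .ibaq_quant import tryptic_digest
from .io_formats import Cohort, GeneSet, GeneSetCollection, ProteinDatabase

__all__ = [
    "IpmsSimConfig",
    "CohortSimConfig",
    "CohortTruth",
    "simulate_ipms",
    "simulate_cohorts",
    "simulate_gene_sets",
]

# residue alphabet with roughly natural frequencies; K+R together ~11% so
# random sequences carry realistic tryptic-cleavage density
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array([
    0.082, 0.014, 0.054, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058, 0.096,
    0.024, 0.041, 0.047, 0.039, 0.055, 0.066, 0.053, 0.068, 0.011, 0.033,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass(frozen=True)
class IpmsSimConfig:
    n_proteins: int = 40
    n_true_interactors: int = 8
    n_replicates: int = 3
    cell_lines: tuple[str, ...] = ("NB4", "U937")
    log2_enrichment: float = 6.0
    background_log_intensity_mean: float = 14.0  # natural-log intensity scale
    background_log_intensity_sd: float = 1.0
    replicate_log_sd: float = 0.25
    dropout_midpoint: float = -math.inf  # -inf disables dropout
    dropout_slope: float = 1.0
    peptides_per_protein: tuple[int, int] = (2, 6)
    contaminant_fraction: float = 0.1  # of background proteins, high in both
    contaminant_log_shift: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_interactors > self.n_proteins:
            raise ValueError("n_true_interactors cannot exceed n_proteins")
        if self.background_log_intensity_sd <= 0 or self.replicate_log_sd <= 0:
            raise ValueError("intensity sds must be positive")
        if self.dropout_slope < 0:
            raise ValueError("dropout_slope must be >= 0")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be a range with 1 <= lo <= hi")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must lie in [0, 1]")
        if not self.cell_lines:
            raise ValueError("at least one cell line is required")


def _random_sequence(rng: np.random.Generator, min_observable: int) -> str:
    """Random amino-acid string (length 80-600) with at least
    ``min_observable`` tryptic peptides of length 7-30."""
    for _ in range(200):
        length = int(rng.integers(80, 601))
        seq = "".join(rng.choice(_AA, size=length, p=_AA_FREQ))
        observable = [p for p in tryptic_digest(seq) if 7 <= len(p) <= 30]
        if len(observable) >= min_observable:
            return seq
    raise RuntimeError("failed to sample a digestible sequence")  # pragma: no cover


def simulate_ipms(
    cfg: IpmsSimConfig,
) -> tuple[pd.DataFrame, ProteinDatabase, dict[str, str]]:
    """Simulate a bait/control IP-MS experiment.

    Returns the peptide-level intensity table (rows already dropped according
    to the logistic missingness model), the protein database, and the truth
    labels (accession -> ``true_interactor`` | ``background``).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.peptides_per_protein

    db = ProteinDatabase()
    accessions = [f"SIM{i + 1:04d}" for i in range(cfg.n_proteins)]
    truth = {
        acc: ("true_interactor" if i < cfg.n_true_interactors else "background")
        for i, acc in enumerate(accessions)
    }
    n_background = cfg.n_proteins - cfg.n_true_interactors
    n_contaminants = int(round(cfg.contaminant_fraction * n_background))
    contaminants = set(accessions[cfg.n_true_interactors : cfg.n_true_interactors + n_contaminants])

    protein_peptides: dict[str, list[str]] = {}
    for i, acc in enumerate(accessions):
        n_pep = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, n_pep)
        db.add(acc, f"GENE{i + 1:04d}", seq)
        observable = [p for p in tryptic_digest(seq) if 7 <= len(p) <= 30]
        idx = rng.choice(len(observable), size=n_pep, replace=False)
        protein_peptides[acc] = [observable[j] for j in sorted(idx)]

    runs = [
        (f"{cell}_{cond}_{rep}", cell, cond, rep)
        for cell in cfg.cell_lines
        for cond in ("bait", "control")
        for rep in range(1, cfg.n_replicates + 1)
    ]

    enrichment_ln = cfg.log2_enrichment * math.log(2)
    rows = []
    for acc in accessions:
        gene = db[acc].gene_symbol
        base_mean = cfg.background_log_intensity_mean
        if acc in contaminants:
            base_mean += cfg.contaminant_log_shift
        for pep in protein_peptides[acc]:
            pep_mean = rng.normal(base_mean, cfg.background_log_intensity_sd)
            for run_id, cell, cond, rep in runs:
                log_int = pep_mean + rng.normal(0.0, cfg.replicate_log_sd)
                if cond == "bait" and truth[acc] == "true_interactor":
                    log_int += enrichment_ln
                p_drop = expit(cfg.dropout_slope * (cfg.dropout_midpoint - log_int))
                if rng.random() < p_drop:
                    continue
                rows.append(
                    {
                        "run_id": run_id,
                        "cell_line": cell,
                        "condition": cond,
                        "replicate": rep,
                        "protein_accession": acc,
                        "gene_symbol": gene,
                        "peptide_sequence": pep,
                        "intensity": math.exp(log_int),
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "run_id", "cell_line", "condition", "replicate",
            "protein_accession", "gene_symbol", "peptide_sequence", "intensity",
        ],
    )
    return table, db, truth


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    n_genes: int = 60
    n_signature_genes: int = 10
    n_prognostic_genes: int = 4
    n_samples: int = 300
    n_cohorts: int = 3
    latent_factor_loading: float = 0.4
    beta: float = 0.6  # log hazard per unit (z-scale) expression
    baseline_hazard: float = 1.0 / 365.0  # per day
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_prognostic_genes <= self.n_signature_genes <= self.n_genes):
            raise ValueError(
                "require n_prognostic_genes <= n_signature_genes <= n_genes"
            )
        if not -1 <= self.latent_factor_loading <= 1:
            raise ValueError("latent_factor_loading must lie in [-1, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0 < self.censor_rate < 1:
            raise ValueError("censor_rate must lie in (0, 1)")
        if self.n_samples < 2 or self.n_cohorts < 1:
            raise ValueError("need n_samples >= 2 and n_cohorts >= 1")


@dataclass(frozen=True)
class CohortTruth:
    prognostic_genes: tuple[str, ...]
    signature_genes: tuple[str, ...]
    beta: float


def _censor_hazard(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring hazard mu with mean P(censored) == censor_rate.

    For independent exponentials, P(C < T | lambda_i) = mu / (mu + lambda_i);
    solve mean_i of that = censor_rate for mu by bisection on log(mu).
    """

    def mean_censoring(log_mu: float) -> float:
        mu = math.exp(log_mu)
        return float(np.mean(mu / (mu + hazards))) - censor_rate

    lo, hi = math.log(hazards.min()) - 20, math.log(hazards.max()) + 20
    return math.exp(brentq(mean_censoring, lo, hi, xtol=1e-12))


def simulate_cohorts(
    cfg: CohortSimConfig, gene_names: list[str] | None = None
) -> tuple[list[Cohort], CohortTruth]:
    """Simulate expression cohorts with a planted prognostic signal.

    Signature genes load on one shared latent factor; prognostic genes (a
    subset of the signature) drive the hazard through the mean of their
    z-scale expression with a common coefficient ``beta`` (same sign in
    every cohort).  Event and censoring times are exponential, the censoring
    hazard calibrated so the expected censored fraction equals
    ``censor_rate``.
    """
    if gene_names is None:
        gene_names = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    elif len(gene_names) != cfg.n_genes:
        raise ValueError("gene_names length must equal n_genes")
    signature = tuple(gene_names[: cfg.n_signature_genes])
    prognostic = tuple(gene_names[: cfg.n_prognostic_genes])

    rng = np.random.default_rng(cfg.seed)
    lam = cfg.latent_factor_loading
    cohorts = []
    for c in range(cfg.n_cohorts):
        factor = rng.normal(size=cfg.n_samples)
        noise = rng.normal(size=(cfg.n_genes, cfg.n_samples))
        z = noise.copy()
        z[: cfg.n_signature_genes] = (
            lam * factor + math.sqrt(1 - lam**2) * noise[: cfg.n_signature_genes]
        )
        expression = pd.DataFrame(
            8.0 + z,
            index=pd.Index(gene_names, name="gene"),
            columns=[f"C{c + 1}S{i + 1:04d}" for i in range(cfg.n_samples)],
        )
        lp = cfg.beta * z[: cfg.n_prognostic_genes].mean(axis=0)
        hazards = cfg.baseline_hazard * np.exp(lp)
        event_times = rng.exponential(1.0 / hazards)
        mu = _censor_hazard(hazards, cfg.censor_rate)
        censor_times = rng.exponential(1.0 / mu, size=cfg.n_samples)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
        survival = pd.DataFrame(
            {"time": time, "event": event},
            index=pd.Index(expression.columns, name="sample_id"),
        )
        cohorts.append(Cohort(f"SIMCOHORT{c + 1}", expression, survival))
    return cohorts, CohortTruth(prognostic, signature, cfg.beta)


def simulate_gene_sets(
    universe: list[str],
    signature_genes: list[str],
    n_sets: int = 10,
    set_size: int = 8,
    seed: int = 0,
) -> GeneSetCollection:
    """One planted set drawn from the signature genes plus uniform decoys."""
    if set_size > len(universe):
        raise ValueError("requested set size exceeds the gene universe")
    if not signature_genes:
        raise ValueError("signature_genes must be non-empty")
    rng = np.random.default_rng(seed)
    planted_size = min(set_size, len(signature_genes))
    planted = rng.choice(signature_genes, size=planted_size, replace=False)
    sets = [GeneSet("planted", "signature-derived set", frozenset(planted))]
    for i in range(n_sets - 1):
        genes = rng.choice(universe, size=set_size, replace=False)
        sets.append(GeneSet(f"decoy_{i + 1:02d}", "uniform decoy set", frozenset(genes)))
    return GeneSetCollection(sets)
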