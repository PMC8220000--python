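"""Signature scoring, survival modelling, and group-comparison statistics.

The univariate Cox model is fit by Newton ascent on the partial
log-likelihood with Efron handling of tied event times (Breslow available),
which is exact enough for the single-covariate per-gene screens this
pipeline runs; genes are then called reproducibly prognostic when at least
``k_min`` cohorts agree in sign at p < alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Cohort

__all__ = [
    "CoxFit",
    "signature_score",
    "dichotomize_median",
    "cox_univariate",
    "logrank_test",
    "concordance_call",
    "diff_expression",
    "fold_change_summary",
    "pearson_correlation",
]


@dataclass(frozen=True)
class CoxFit:
    gene: str
    cohort_id: str
    beta: float
    se: float
    z: float
    p: float
    diverged: bool = False

    @property
    def hr(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.beta - 1.96 * self.se),
            math.exp(self.beta + 1.96 * self.se),
        )


def signature_score(cohort: Cohort, genes: list[str]) -> pd.Series:
    """Per-sample signature score: mean of per-gene z-scores (ddof=1).

    Genes absent from the matrix are logged and skipped; constant genes are
    excluded with a warning; no usable gene is an error.
    """
    present = [g for g in genes if g in cohort.expression.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) absent from cohort "
                      f"{cohort.cohort_id}: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    usable = []
    for g in present:
        row = cohort.expression.loc[g]
        sd = row.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"signature gene {g!r} has zero variance; excluded")
            continue
        usable.append((row - row.mean()) / sd)
    if not usable:
        raise ValueError("no signature gene with variance present in the cohort")
    return pd.concat(usable, axis=1).mean(axis=1)


def dichotomize_median(scores: pd.Series) -> pd.Series:
    """Label samples ``high`` (score > median) or ``low`` (<= median)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    median = scores.median()
    labels = pd.Series(
        np.where(scores > median, "high", "low"), index=scores.index, name="group"
    )
    if (labels == "low").all():
        warnings.warn("all scores at or below the median; every sample labelled low")
    return labels


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate)
# ---------------------------------------------------------------------------

def _cox_loglik_derivs(
    beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str
) -> tuple[float, float, float]:
    """Partial log-likelihood, gradient and Hessian at ``beta``.

    Arrays must be sorted by time ascending.  Risk sums are accumulated from
    the largest time downward; tied event times are handled by Efron's
    averaged-withdrawal correction or Breslow's approximation.
    """
    eta = beta * x
    w = np.exp(eta)
    wx = w * x
    wxx = wx * x
    # risk-set sums at each unique time = reverse cumulative sums taken at the
    # first index of that time block (time is sorted ascending)
    rc0 = np.cumsum(w[::-1])[::-1]
    rc1 = np.cumsum(wx[::-1])[::-1]
    rc2 = np.cumsum(wxx[::-1])[::-1]
    _, first_idx = np.unique(time, return_index=True)
    block_of = np.searchsorted(time[first_idx], time)

    ev = event == 1
    n_blocks = len(first_idx)
    d_blk = np.bincount(block_of[ev], minlength=n_blocks)
    d0_blk = np.bincount(block_of[ev], weights=w[ev], minlength=n_blocks)
    d1_blk = np.bincount(block_of[ev], weights=wx[ev], minlength=n_blocks)
    d2_blk = np.bincount(block_of[ev], weights=wxx[ev], minlength=n_blocks)

    loglik = float(eta[ev].sum())
    grad = float(x[ev].sum())
    hess = 0.0
    for b in np.nonzero(d_blk)[0]:
        i0 = first_idx[b]
        s0, s1, s2 = rc0[i0], rc1[i0], rc2[i0]
        d = int(d_blk[b])
        for ell in range(d):
            frac = ell / d if ties == "efron" else 0.0
            phi0 = s0 - frac * d0_blk[b]
            phi1 = s1 - frac * d1_blk[b]
            phi2 = s2 - frac * d2_blk[b]
            loglik -= math.log(phi0)
            grad -= phi1 / phi0
            hess -= phi2 / phi0 - (phi1 / phi0) ** 2
    return loglik, grad, hess


def cox_univariate(
    expression: pd.Series | np.ndarray,
    survival: pd.DataFrame,
    gene: str = "",
    cohort_id: str = "",
    ties: str = "efron",
) -> CoxFit:
    """Fit a one-covariate Cox proportional-hazards model.

    ``survival`` needs ``time`` and ``event`` columns aligned with
    ``expression``.  Newton ascent from beta = 0 with step halving;
    convergence when |gradient| < 1e-8 (50 iterations maximum).  Monotone
    likelihoods (separation) are flagged ``diverged`` instead of raising.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    x = np.asarray(expression, dtype=float)
    time = np.asarray(survival["time"], dtype=float)
    event = np.asarray(survival["event"], dtype=int)
    if len(x) != len(time):
        raise ValueError("expression and survival lengths differ")
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")

    order = np.argsort(time, kind="mergesort")
    x, time, event = x[order], time[order], event[order]
    # standardize for numerical stability and a scale-free divergence check;
    # beta/se are rescaled back afterwards
    scale = x.std()
    x = (x - x.mean()) / scale

    beta = 0.0
    loglik, grad, hess = _cox_loglik_derivs(beta, x, time, event, ties)
    diverged = False
    converged = False
    ll_tol = 1e-10 * (abs(loglik) + 1.0)  # rounding noise floor for ascent checks
    for _ in range(50):
        if abs(grad) < 1e-8:
            converged = True
            break
        step = -grad / hess if hess < 0 else grad
        new_beta = beta + step
        new_ll, new_grad, new_hess = _cox_loglik_derivs(new_beta, x, time, event, ties)
        halvings = 0
        while new_ll < loglik - ll_tol and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_loglik_derivs(new_beta, x, time, event, ties)
            halvings += 1
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        if abs(beta) > 15:  # per-sd log hazard; monotone likelihood signature
            diverged = True
            break
        if abs(step) < 1e-10 * (1.0 + abs(beta)):
            converged = True  # stalled within float precision of the optimum
            break
    else:
        converged = abs(grad) < 1e-8
    if not converged and not diverged:
        diverged = True

    if hess >= 0 or not np.isfinite(hess):
        diverged = True
    se = math.sqrt(-1.0 / hess) if hess < 0 else math.inf
    # huge per-sd standard error is the other face of a flat likelihood
    if not np.isfinite(se) or se > 100:
        diverged = True
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 1.0
    return CoxFit(gene, cohort_id, float(beta / scale), float(se / scale),
                  float(z), float(p), diverged)


def logrank_test(labels: pd.Series, survival: pd.DataFrame) -> dict[str, float]:
    """Two-group log-rank test (1 df) of the survival curves."""
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    time = np.asarray(survival["time"], dtype=float)
    event = np.asarray(survival["event"], dtype=int)
    g = np.asarray(labels == groups[0])
    if event.sum() < 1:
        raise ValueError("need at least 1 event")
    observed = expected = variance = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        deaths = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g).sum()
        observed += d1
        expected += deaths * n1 / n
        if n > 1:
            variance += deaths * (n1 / n) * (1 - n1 / n) * (n - deaths) / (n - 1)
    if variance == 0:
        return {"chi2": 0.0, "p": 1.0}
    chi2 = (observed - expected) ** 2 / variance
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, df=1))}


def concordance_call(
    fits: list[CoxFit], alpha: float = 0.05, k_min: int = 2
) -> pd.DataFrame:
    """Call genes reproducibly prognostic across cohorts.

    A gene is ``reproducible`` when at least ``k_min`` cohorts reach
    p < alpha with a common sign of beta.  Diverged fits are excluded.
    """
    rows = []
    by_gene: dict[str, list[CoxFit]] = {}
    for fit in fits:
        by_gene.setdefault(fit.gene, []).append(fit)
    for gene, gene_fits in by_gene.items():
        usable = [f for f in gene_fits if not f.diverged]
        sig = [f for f in usable if f.p < alpha]
        pos = sum(1 for f in sig if f.beta > 0)
        neg = sum(1 for f in sig if f.beta < 0)
        rows.append(
            {
                "gene": gene,
                "n_cohorts": len(usable),
                "n_significant_cohorts": len(sig),
                "directions": "".join("+" if f.beta > 0 else "-" for f in sig),
                "reproducible": max(pos, neg) >= k_min,
            }
        )
    return pd.DataFrame(rows)


def diff_expression(group_a: pd.DataFrame, group_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney U comparison of two expression groups.

    Exact enumeration when both groups have <= 8 samples and no ties; the
    tie-corrected normal approximation otherwise.  Direction is the sign of
    median(b) - median(a); ``significant`` means p < 0.05.
    """
    shared = [g for g in group_a.index if g in group_b.index]
    if not shared:
        raise ValueError("no shared genes between the groups")
    rows = []
    for gene in shared:
        a = group_a.loc[gene].to_numpy(dtype=float)
        b = group_b.loc[gene].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 samples per group per gene")
        median_a, median_b = float(np.median(a)), float(np.median(b))
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
        rows.append(
            {
                "gene": gene,
                "median_a": median_a,
                "median_b": median_b,
                "p": min(p, 1.0),
                "significant": p < 0.05,
                "direction": "up" if median_b > median_a else "down",
            }
        )
    return pd.DataFrame(rows)


def fold_change_summary(mean_a: float, mean_b: float, decimals: int = 1) -> float:
    """mean_a / mean_b rounded half-up to ``decimals`` places."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be positive")
    ratio = Decimal(str(mean_a)) / Decimal(str(mean_b))
    quantum = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(quantum, rounding=ROUND_HALF_UP))


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length numeric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must be non-constant")
    return float(stats.pearsonr(x, y)[0])
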