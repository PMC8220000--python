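"""Over-representation analysis and preranked gene set enrichment.

ORA uses the upper-tail hypergeometric test with Benjamini-Hochberg FDR
control at alpha = 0.05.  GSEA runs a weighted Kolmogorov-Smirnov running
sum over a fixed descending ranking, draws its null from gene-label
permutations, normalizes the enrichment score by the mean same-sign null
magnitude, and reports a sign-pooled permutation FDR with the conventional
q < 0.25 significance call.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr

from .io_formats import Cohort, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeometric_upper_tail",
    "benjamini_hochberg",
    "ora",
    "gsea_preranked",
    "rank_genes",
]


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K annotated, n drawn)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k > K:
        return 0.0
    # sf is exclusive of k; survival at k-1 gives the inclusive upper tail
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def ora(
    query: set[str] | list[str],
    universe: set[str] | list[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within each gene set.

    Genes outside ``universe`` are ignored; q-values are BH-adjusted across
    all tested sets and ``significant`` means q < alpha.
    """
    universe = set(universe)
    query = set(query) & universe
    if not universe:
        raise ValueError("universe is empty")
    rows = []
    for s in sets:
        annotated = s.genes & universe
        if not annotated:
            logger.warning("gene set %s disjoint from universe; skipped", s.name)
            continue
        k = len(query & annotated)
        rows.append(
            {
                "set_name": s.name,
                "k": k,
                "n": len(query),
                "K": len(annotated),
                "N": len(universe),
                "p_value": hypergeometric_upper_tail(k, len(query), len(annotated), len(universe)),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q_value"] = benjamini_hochberg(result["p_value"].to_numpy())
        result["significant"] = result["q_value"] < alpha
    return result


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _running_sum_extremum(weights: np.ndarray, hit: np.ndarray) -> float:
    """Signed maximal deviation of the weighted KS running sum.

    ``weights`` are |score|^exponent over the full ranking; ``hit`` is a 0/1
    (or boolean) mask of set membership, both in ranking order.
    """
    hit = hit.astype(float)
    n_hit = hit.sum()
    n_miss = len(hit) - n_hit
    hit_w = weights * hit
    total = hit_w.sum()
    if total <= 0:  # all hit weights zero: fall back to uniform increments
        hit_w = hit / n_hit
        total = 1.0
    running = np.cumsum(hit_w / total - (1.0 - hit) / n_miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _null_es(
    weights: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Gene-label-permutation null ES values, vectorized over permutations."""
    n = len(weights)
    base = np.zeros(n)
    base[:set_size] = 1.0
    masks = rng.permuted(np.tile(base, (n_perm, 1)), axis=1)
    hit_w = weights[None, :] * masks
    totals = hit_w.sum(axis=1)
    degenerate = totals <= 0
    if degenerate.any():
        hit_w[degenerate] = masks[degenerate] / set_size
        totals[degenerate] = 1.0
    running = np.cumsum(
        hit_w / totals[:, None] - (1.0 - masks) / (n - set_size), axis=1
    )
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def _leading_edge(genes: list[str], scores: np.ndarray, hit: np.ndarray, es: float,
                  weights: np.ndarray) -> list[str]:
    hit_f = hit.astype(float)
    n_miss = len(hit) - hit_f.sum()
    hit_w = weights * hit_f
    total = hit_w.sum()
    if total <= 0:
        hit_w = hit_f / hit_f.sum()
        total = 1.0
    running = np.cumsum(hit_w / total - (1.0 - hit_f) / n_miss)
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        members = [g for i, g in enumerate(genes) if hit[i] and i <= peak]
    else:
        members = [g for i, g in enumerate(genes) if hit[i] and i >= peak]
    return members


def gsea_preranked(
    ranked: list[tuple[str, float]] | pd.DataFrame,
    sets: GeneSetCollection,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    fdr_threshold: float = 0.25,
) -> pd.DataFrame:
    """Preranked GSEA over a descending (gene, score) ranking.

    The running sum rewards set members proportionally to
    ``|score| ** weight_exponent`` (exponent 0 recovers the classic
    equal-increment KS statistic) and penalizes non-members by
    ``1 / (N - |set|)``; ES is the signed maximal deviation.  The null is a
    gene-label permutation within the fixed ranking; NES divides ES by the
    mean magnitude of same-sign null ES values; nominal p uses +1 smoothing;
    the FDR q pools normalized null and observed NES across sets by sign.
    Sets disjoint from the ranked universe are skipped with a warning.
    """
    if isinstance(ranked, pd.DataFrame):
        ranked = list(ranked.itertuples(index=False, name=None))
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranking contains duplicate genes")
    if not np.all(np.isfinite(scores)):
        raise ValueError("gene scores must be finite")
    if np.any(np.diff(scores) > 0):
        raise ValueError("ranking must be sorted by score, descending")
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    weights = np.abs(scores) ** weight_exponent
    rng = np.random.default_rng(seed)

    observed, null_by_set, rows = [], [], []
    for s in sets:
        members = [gene_index[g] for g in s.genes if g in gene_index]
        if not members:
            warnings.warn(f"gene set {s.name!r} disjoint from the ranked universe; skipped")
            continue
        if len(members) >= n:
            warnings.warn(f"gene set {s.name!r} covers the whole universe; skipped")
            continue
        hit = np.zeros(n, dtype=bool)
        hit[members] = True
        es = _running_sum_extremum(weights, hit)
        null = _null_es(weights, len(members), n_perm, rng)
        same_sign = null[null > 0] if es >= 0 else null[null < 0]
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        nominal_p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + len(same_sign))
        observed.append((s.name, es, nes, len(members)))
        null_by_set.append((null, denom if denom > 0 else 1.0, es >= 0))
        rows.append(
            {
                "set_name": s.name,
                "size": len(members),
                "es": es,
                "nes": nes,
                "nominal_p": float(min(nominal_p, 1.0)),
                "leading_edge": ",".join(_leading_edge(genes, scores, hit, es, weights)),
            }
        )

    result = pd.DataFrame(rows)
    if not len(result):
        return result

    # sign-pooled FDR: normalize each set's null by its own same-sign mean,
    # pool across sets, and compare tail fractions of null vs observed NES
    pooled_null = []
    for null, _, _ in null_by_set:
        pos = null[null > 0]
        neg = null[null < 0]
        pos_mean = pos.mean() if len(pos) else 1.0
        neg_mean = np.abs(neg).mean() if len(neg) else 1.0
        norm = np.where(null >= 0, null / pos_mean, null / neg_mean)
        pooled_null.append(norm)
    pooled_null = np.concatenate(pooled_null)
    obs_nes = result["nes"].to_numpy()
    qs = []
    for nes in obs_nes:
        if nes >= 0:
            null_tail = np.mean(pooled_null >= nes)
            null_side = np.mean(pooled_null >= 0)
            obs_tail = np.mean(obs_nes >= nes)
            obs_side = np.mean(obs_nes >= 0)
        else:
            null_tail = np.mean(pooled_null <= nes)
            null_side = np.mean(pooled_null < 0)
            obs_tail = np.mean(obs_nes <= nes)
            obs_side = np.mean(obs_nes < 0)
        null_frac = null_tail / null_side if null_side > 0 else 1.0
        obs_frac = obs_tail / obs_side if obs_side > 0 else 1.0
        qs.append(min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0)
    result["fdr_q"] = qs
    result["significant"] = result["fdr_q"] < fdr_threshold
    return result


def rank_genes(
    cohort: Cohort,
    groups: pd.Series | None = None,
    reference_score: pd.Series | None = None,
) -> pd.DataFrame:
    """Build a descending (gene, score) ranking from a cohort.

    Fold-change mode (``groups`` given, labels high/low): per-gene mean
    log2-expression difference, high minus low.  Correlation mode
    (``reference_score`` given): per-gene Pearson r against the per-sample
    reference score; zero-variance genes get r = 0 with a warning.  Ties are
    broken by gene symbol.
    """
    if (groups is None) == (reference_score is None):
        raise ValueError("provide exactly one of groups or reference_score")
    expr = cohort.expression
    if groups is not None:
        groups = groups.reindex(expr.columns)
        high = expr.loc[:, groups == "high"]
        low = expr.loc[:, groups == "low"]
        if high.shape[1] < 2 or low.shape[1] < 2:
            raise ValueError("fold-change mode needs >= 2 samples per group")
        score = high.mean(axis=1) - low.mean(axis=1)
    else:
        reference_score = reference_score.reindex(expr.columns)
        if expr.shape[1] < 3:
            raise ValueError("correlation mode needs >= 3 samples")
        ref = reference_score.to_numpy(dtype=float)
        values = []
        for gene, row in expr.iterrows():
            x = row.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(f"gene {gene!r} has zero variance; r set to 0")
                values.append(0.0)
            else:
                values.append(float(pearsonr(x, ref)[0]))
        score = pd.Series(values, index=expr.index)
    out = pd.DataFrame({"gene": score.index, "score": score.to_numpy()})
    out = out.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
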