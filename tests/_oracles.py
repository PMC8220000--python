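"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: digestion is done by
regex, iBAQ by dict accumulation over raw rows, selection by a literal
transcription of the three criteria, and the small-sample statistics by
exact enumeration with rational arithmetic.
"""

from __future__ import annotations

import itertools
import re
from fractions import Fraction
from math import comb

import numpy as np


def brute_digest(sequence: str) -> list[str]:
    """Fully-cleaved tryptic fragments via regex (cleave after K/R not before P)."""
    return re.findall(r".*?[KR](?!P)|.+?$", sequence)


def brute_digest_missed(sequence: str, missed: int) -> set[str]:
    frags = brute_digest(sequence)
    out = set()
    for i in range(len(frags)):
        for j in range(i, min(i + missed + 1, len(frags))):
            out.add("".join(frags[i : j + 1]))
    return out


def brute_theoretical_count(sequence: str, min_len: int = 7, max_len: int = 30) -> int:
    count = sum(min_len <= len(p) <= max_len for p in brute_digest(sequence))
    return max(count, 1)


def brute_ibaq(rows, sequences: dict[str, str], background: float = 1000.0):
    """Dict-of-dicts iBAQ grid from raw peptide rows.

    ``rows`` iterates dicts with run_id / protein_accession /
    peptide_sequence / intensity.  Returns {(accession, run): (ibaq,
    n_unique, imputed)} over the full observed grid.
    """
    runs, accs = [], []
    sums: dict[tuple[str, str], float] = {}
    uniques: dict[tuple[str, str], set] = {}
    for row in rows:
        key = (row["protein_accession"], row["run_id"])
        if row["run_id"] not in runs:
            runs.append(row["run_id"])
        if row["protein_accession"] not in accs:
            accs.append(row["protein_accession"])
        sums[key] = sums.get(key, 0.0) + row["intensity"]
        uniques.setdefault(key, set()).add(row["peptide_sequence"])
    grid = {}
    for acc in accs:
        denom = brute_theoretical_count(sequences[acc])
        for run in runs:
            if (acc, run) in sums:
                grid[(acc, run)] = (sums[(acc, run)] / denom,
                                    len(uniques[(acc, run)]), False)
            else:
                grid[(acc, run)] = (background, 0, True)
    return grid


def brute_select(grid, run_meta, min_unique=2, min_detect=4, min_ratio=30.0):
    """Literal transcription of the three selection criteria.

    ``grid`` as returned by :func:`brute_ibaq`; ``run_meta`` maps run_id ->
    (cell_line, condition).  Detection for (ii) is counted over bait runs of
    both cell lines; (iii) needs mean-bait / mean-control > min_ratio in
    every cell line.
    """
    accs = sorted({acc for acc, _ in grid})
    cells = sorted({cell for cell, _ in run_meta.values()})
    selected = set()
    for acc in accs:
        max_unique = max(grid[(acc, run)][1] for run in run_meta)
        crit_i = max_unique >= min_unique
        n_detected = sum(
            1 for run, (cell, cond) in run_meta.items()
            if cond == "bait" and not grid[(acc, run)][2]
        )
        crit_ii = n_detected >= min_detect
        crit_iii = True
        for cell in cells:
            bait = [grid[(acc, run)][0] for run, (c, cond) in run_meta.items()
                    if c == cell and cond == "bait"]
            control = [grid[(acc, run)][0] for run, (c, cond) in run_meta.items()
                       if c == cell and cond == "control"]
            ratio = (sum(bait) / len(bait)) / (sum(control) / len(control))
            if not ratio > min_ratio:
                crit_iii = False
        if crit_i and crit_ii and crit_iii:
            selected.add(acc)
    return selected


def exact_hypergeom_upper(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) by direct summation of C(K,i) C(N-K, n-i) / C(N, n)."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        if n - i <= N - K:
            total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


def brute_bh(p_values):
    """Step-up BH by the literal min-over-larger-ranks formula."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def exact_mannwhitney_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = list(a) + list(b)
    na = len(a)
    assert len(set(pooled)) == len(pooled), "exact oracle assumes no ties"

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    mean_u = na * len(b) / 2
    dev = abs(u_obs - mean_u)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if abs(u_stat(ga, gb) - mean_u) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def classic_ks_es(ranked_genes, gene_set) -> float:
    """Unweighted running-sum enrichment score by direct stepping."""
    n = len(ranked_genes)
    hits = [g in gene_set for g in ranked_genes]
    m = sum(hits)
    running, best = 0.0, 0.0
    for is_hit in hits:
        running += (1.0 / m) if is_hit else (-1.0 / (n - m))
        if abs(running) > abs(best):
            best = running
    return best


def partial_loglik_no_ties(beta: float, x, time, event) -> float:
    """Written-out Cox partial log-likelihood (no tied event times)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for i in range(len(x)):
        if event[i] == 1:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll
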