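"""Auxiliary statistics: GSEA, the egg-laying binomial test, one-way ANOVA
with LSD letter grouping.

GSEA uses the classic Kolmogorov-Smirnov-style running sum over a ranked
gene list with a gene-set (label) permutation null: with only a handful of
biological replicates a phenotype permutation null is not supportable, so
set membership is reshuffled instead, preserving set size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GseaResult:
    gene_set: str
    es: float
    p: float
    direction: str  # 'up' (positive ES) or 'down'
    extremum_index: int
    running_sum: np.ndarray


def gsea_es(
    ranked_genes: list[str],
    scores,
    gene_set: set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score of a gene set along a ranked, scored gene list.

    Walking down the ranking, hits add ``|score|^weight`` normalized by the
    total over hits and misses subtract ``1/(N - Nh)``; the ES is the
    running-sum value of largest magnitude (the first such extremum when
    tied). When the set covers the whole list the miss term is absent and
    the ES is +1 at the final hit.
    """
    scores = np.asarray(scores, dtype=float)
    if len(ranked_genes) != scores.size:
        raise ValueError("ranked_genes and scores must align")
    hit = np.array([g in gene_set for g in ranked_genes])
    nh = int(hit.sum())
    n = hit.size
    if nh == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    wts = np.abs(scores) ** weight
    hit_total = wts[hit].sum()
    steps = np.where(
        hit,
        wts / hit_total if hit_total > 0 else 1.0 / nh,
        -1.0 / (n - nh) if n > nh else 0.0,
    )
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def gsea_p(
    ranked_genes: list[str],
    scores,
    gene_set: set[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
) -> GseaResult:
    """Permutation p-value for a gene set's enrichment score.

    The null reshuffles set membership over the ranked list (set size
    preserved); ``p = (1 + #{|ES_perm| >= |ES_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, running = gsea_es(ranked_genes, scores, gene_set, weight)
    size = sum(g in gene_set for g in ranked_genes)
    rng = np.random.default_rng(seed)
    n = len(ranked_genes)
    exceed = 0
    genes_arr = np.array(ranked_genes)
    for _ in range(n_perm):
        members = set(genes_arr[rng.choice(n, size=size, replace=False)])
        es_perm, _ = gsea_es(ranked_genes, scores, members, weight)
        if abs(es_perm) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    idx = int(np.argmax(np.abs(running)))
    return GseaResult(
        gene_set="query",
        es=es,
        p=p,
        direction="up" if es >= 0 else "down",
        extremum_index=idx,
        running_sum=running,
    )


def egg_binom_test(k: int, n: int, p0: float) -> float:
    """Exact lower-tail binomial probability P(X <= k | n, p0).

    Used to ask whether egg-laying after treatment dropped below the
    pre-treatment rate ``p0`` (alternative 'less').
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a probability")
    return float(sps.binom.cdf(k, n, p0))


@dataclass
class AnovaLsdResult:
    f: float
    p: float
    mse: float
    letters: dict[str, str]
    means: dict[str, float]


def _letter_groups(names, means, nonsig) -> dict[str, str]:
    """Assign compact-letter display from a pairwise non-significance matrix.

    Groups are ordered by descending mean; every maximal run of mutually
    non-different groups receives one letter.
    """
    k = len(names)
    order = sorted(range(k), key=lambda i: -means[i])
    runs = []
    for a in range(k):
        b = a
        while b + 1 < k and all(
            nonsig[order[i]][order[b + 1]] for i in range(a, b + 1)
        ):
            b += 1
        runs.append((a, b))
    maximal = [
        (a, b)
        for a, b in runs
        if not any(c <= a and b <= d and (c, d) != (a, b) for c, d in runs)
    ]
    letters = {name: "" for name in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (a, b) in enumerate(sorted(set(maximal))):
        for pos in range(a, b + 1):
            letters[names[order[pos]]] += alphabet[li % len(alphabet)]
    return letters


def anova_lsd(groups: dict[str, list[float]], alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA; when significant, Fisher's LSD pairwise t-tests with
    letter grouping (groups sharing a letter are not significantly
    different)."""
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(data) < 2 or any(d.size < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(d.var(ddof=1) == 0 for d in data):
        raise ValueError("zero within-group variance everywhere")
    k = len(data)
    ns = np.array([d.size for d in data])
    n_total = int(ns.sum())
    means = np.array([d.mean() for d in data])
    grand = np.concatenate(data).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((d - d.mean()) ** 2).sum() for d in data))
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    f = (ss_between / df_b) / mse if mse > 0 else np.inf
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0

    if p <= alpha:
        nonsig = [[True] * k for _ in range(k)]
        for i, j in itertools.combinations(range(k), 2):
            se = np.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
            t = abs(means[i] - means[j]) / se
            pij = 2 * sps.t.sf(t, df_w)
            nonsig[i][j] = nonsig[j][i] = pij > alpha
        letters = _letter_groups(names, means, nonsig)
    else:
        letters = {name: "a" for name in names}
    return AnovaLsdResult(
        f=float(f),
        p=p,
        mse=float(mse),
        letters=letters,
        means={g: float(m) for g, m in zip(names, means)},
    )
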