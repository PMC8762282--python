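"""Species-specific follicle-development gene and biological-process discovery.

Per stage markers come from a one-vs-rest negative-binomial Wald test; term
enrichment uses an exact hypergeometric upper tail with Benjamini-Hochberg
adjustment; cross-species comparison yields homology-overlap percentages,
ectopically expressed genes, species-specific biological processes (BPs) and
finally the species-specific gene set (for chicken: the GAL-SPGs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, ndtr
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionSet, OrthologTable

MIN_DISPERSION = 1e-8


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(group_a: np.ndarray, group_b: np.ndarray) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test between two sample groups.

    ``group_a`` / ``group_b`` are gene x replicate arrays of non-negative
    abundances (FPKM used as pseudo-counts). The gene-wise NB dispersion is
    estimated by the method of moments on the pooled within-group variance,
    floored at ``MIN_DISPERSION``; the Wald statistic is the log2 fold change
    (A over B) divided by its delta-method standard error. Returns a frame
    with columns ``log2fc``, ``p``, ``padj``. All-zero genes get p = 1 and
    log2fc = 0.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    na, nb_ = a.shape[1], b.shape[1]
    # pooled within-group moments for a common dispersion per gene
    m_pool = (ma * na + mb * nb_) / (na + nb_)
    v_pool = (va * (na - 1) + vb * (nb_ - 1)) / (na + nb_ - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (v_pool - m_pool) / np.square(m_pool)
    disp = np.where(np.isfinite(disp), disp, MIN_DISPERSION)
    disp = np.maximum(disp, MIN_DISPERSION)

    eps = 0.5  # continuity shift keeps the fold change defined at zero means
    log2fc = np.log2((ma + eps) / (mb + eps))
    # Var(log mu_hat) ~ (1/mu + alpha)/n for NB(mu, alpha)
    var_log_a = (1.0 / (ma + eps) + disp) / na
    var_log_b = (1.0 / (mb + eps) + disp) / nb_
    se_log2 = np.sqrt(var_log_a + var_log_b) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_log2 > 0, log2fc / se_log2, 0.0)
    p = 2.0 * ndtr(-np.abs(z))

    all_zero = (ma == 0) & (mb == 0)
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.where(all_zero, 1.0, p)
    return pd.DataFrame({"log2fc": log2fc, "p": p, "padj": bh_adjust(p)})


@dataclass
class StageGeneSets:
    """Per-stage marker gene sets for one species/compartment."""

    species: str
    compartment: str
    sets: dict[str, set[str]]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


def stage_markers(
    es: ExpressionSet,
    species: str,
    compartment: str,
    alpha: float = 0.05,
    min_fpkm: float = 1.0,
) -> StageGeneSets:
    """One-vs-rest differentially *highly* expressed genes per stage.

    A gene is a marker of a stage when its one-vs-rest NB Wald test gives
    log2FC > 0 and padj <= alpha and its mean FPKM in the stage is at least
    ``min_fpkm``. Stages with fewer than two replicates are skipped with a
    warning.
    """
    sub = es.select(species=species, compartment=compartment)
    meta = sub.sample_meta.sort_values("stage_order")
    stages = list(dict.fromkeys(meta["stage"]))
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    sets: dict[str, set[str]] = {}
    tables: dict[str, pd.DataFrame] = {}
    for stage in stages:
        in_stage = (sub.sample_meta["stage"] == stage).values
        if in_stage.sum() < 2 or (~in_stage).sum() < 2:
            warnings.warn(f"stage {stage!r} lacks replicates; skipped", stacklevel=2)
            continue
        res = nb_wald_test(sub.values.values[:, in_stage], sub.values.values[:, ~in_stage])
        res.index = sub.values.index
        stage_mean = sub.values.values[:, in_stage].mean(axis=1)
        res["stage_mean_fpkm"] = stage_mean
        keep = (res["log2fc"] > 0) & (res["padj"] <= alpha) & (stage_mean >= min_fpkm)
        sets[stage] = set(res.index[keep])
        tables[stage] = res
    return StageGeneSets(species, compartment, sets, tables)


def homology_overlap(
    sets_by_species: dict[str, set[str]], table: OrthologTable
) -> float:
    """Percent of ortholog groups shared by all species' marker sets.

    Maps each species' gene set to ortholog-group IDs and returns
    ``100 * |intersection| / |union|``; NaN for an empty union.
    """
    if len(sets_by_species) < 2:
        raise ValueError("need >= 2 species")
    group_sets = []
    for sp, genes in sets_by_species.items():
        g2o = table.gene_to_group(sp)
        group_sets.append({g2o[g] for g in genes if g in g2o})
    union = set.union(*group_sets)
    if not union:
        return float("nan")
    inter = set.intersection(*group_sets)
    return 100.0 * len(inter) / len(union)


def _compartment_membership(
    gc: StageGeneSets, tc: StageGeneSets, stage: str, table: OrthologTable, species: str
) -> dict[str, str]:
    """Ortholog group -> 'GC', 'TC' or 'both' for one species at one stage."""
    g2o = table.gene_to_group(species)
    gc_groups = {g2o[g] for g in gc.sets.get(stage, set()) if g in g2o}
    tc_groups = {g2o[g] for g in tc.sets.get(stage, set()) if g in g2o}
    out = {}
    for og in gc_groups | tc_groups:
        if og in gc_groups and og in tc_groups:
            out[og] = "both"
        elif og in gc_groups:
            out[og] = "GC"
        else:
            out[og] = "TC"
    return out


def ectopic_genes(
    sets_by_species: dict[str, tuple[StageGeneSets, StageGeneSets]],
    table: OrthologTable,
    stage: str,
    query_species: str,
) -> set[str]:
    """Ortholog groups whose compartment of expression flips between species.

    ``sets_by_species`` maps species -> (GC StageGeneSets, TC StageGeneSets).
    A group is ectopic when it is confined to one compartment (GC-only or
    TC-only) at ``stage`` in the query species and to the *other* compartment
    in at least one other species; groups found in both compartments in any
    species are excluded.
    """
    if query_species not in sets_by_species:
        raise ValueError("query species missing")
    membership = {
        sp: _compartment_membership(gc, tc, stage, table, sp)
        for sp, (gc, tc) in sets_by_species.items()
    }
    query = membership[query_species]
    both_anywhere = {
        og for m in membership.values() for og, side in m.items() if side == "both"
    }
    out = set()
    for og, side in query.items():
        if og in both_anywhere or side == "both":
            continue
        other = "TC" if side == "GC" else "GC"
        for sp, m in membership.items():
            if sp == query_species:
                continue
            if m.get(og) == other:
                out.add(og)
                break
    return out


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed as a combinatorial sum in log space (gammaln + logsumexp).
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N or min(N, K, n, k) < 0:
        raise ValueError("inconsistent hypergeometric counts")
    if k == 0:
        return 1.0

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    hi = min(K, n)
    terms = [
        log_comb(K, x) + log_comb(N - K, n - x) - log_comb(N, n)
        for x in range(k, hi + 1)
        if n - x <= N - K
    ]
    if not terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(terms))))


@dataclass
class EnrichmentResult:
    term: str
    term_size: int
    query_size: int
    overlap: int
    p: float
    padj: float
    hits: set[str]


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT annotation file into term -> gene-set."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = set(g for g in parts[2:] if g)
    return terms


def write_gmt(terms: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, description] + sorted(genes)) + "\n")


def go_enrich(
    query: set[str], annotation: dict[str, set[str]], background: set[str]
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms in a query set.

    Terms with no overlap with the background are skipped; results are BH
    adjusted across the tested terms and sorted by p (term ID breaks ties).
    """
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N = len(background)
    n = len(query)
    rows = []
    for term, genes in annotation.items():
        in_bg = genes & background
        if not in_bg:
            continue
        hits = in_bg & query
        p = hypergeom_tail(N, len(in_bg), n, len(hits))
        rows.append((term, len(in_bg), n, len(hits), p, hits))
    if not rows:
        return []
    padj = bh_adjust([r[4] for r in rows])
    out = [
        EnrichmentResult(term, ts, qs, ov, p, float(q), hits)
        for (term, ts, qs, ov, p, hits), q in zip(rows, padj)
    ]
    out.sort(key=lambda r: (r.p, r.term))
    return out


def species_specific_bps(
    enrichments: dict[str, list[EnrichmentResult]],
    target_species: str,
    alpha: float = 0.05,
) -> tuple[set[str], float]:
    """Terms significant in the target species and in no other species.

    Returns the specific term set and the percentage it makes of the target
    species' significant terms (NaN when the target has none).
    """
    sig = {
        sp: {r.term for r in res if r.padj <= alpha} for sp, res in enrichments.items()
    }
    target = sig.pop(target_species)
    others = set().union(*sig.values()) if sig else set()
    specific = target - others
    pct = 100.0 * len(specific) / len(target) if target else float("nan")
    return specific, pct


def bp_overlap_test(
    candidate: set[str], other: set[str], universe: set[str]
) -> float:
    """Hypergeometric upper-tail p for the overlap of two BP sets."""
    if not candidate <= universe or not other <= universe:
        raise ValueError("sets must lie within the universe")
    if not candidate:
        return 1.0
    return hypergeom_tail(len(universe), len(other), len(candidate), len(candidate & other))


def extract_spgs(
    top_bps: list[str],
    gc_only_bps: set[str],
    annotation: dict[str, set[str]],
    gc_sets: StageGeneSets,
    tc_sets: StageGeneSets,
) -> set[str]:
    """Final species-specific follicle-development genes (e.g. GAL-SPGs).

    Candidates are the genes annotated to the top BPs that are exclusive to
    the GC compartment's enrichment; a candidate survives only when it is a
    member of at least one GC stage marker set and of no TC stage set.
    """
    use = [t for t in top_bps if t in gc_only_bps]
    candidates: set[str] = set()
    for term in use:
        candidates |= annotation.get(term, set())
    gc_genes = gc_sets.all_genes()
    tc_genes = tc_sets.all_genes()
    return {g for g in candidates if g in gc_genes and g not in tc_genes}
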