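"""Cross-species expression integration.

Builds one ortholog-indexed FPKM matrix from per-species expression sets,
removes study batch effects on the log2 scale, z-scores genes, and clusters
samples hierarchically with reference-guided cluster naming.

The working scale for batch adjustment and clustering is ``log2(FPKM + 1)``;
matrices are stored as FPKM throughout and transformed on demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

META_COLUMNS = ["sample_id", "species", "compartment", "stage", "stage_order", "batch"]


@dataclass
class ExpressionSet:
    """Gene x sample FPKM matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative FPKM values, genes as the index, sample IDs
        as columns.
    sample_meta
        DataFrame indexed by sample ID with columns ``species``,
        ``compartment`` (``GC``/``TC``), ``stage``, ``stage_order`` (integer,
        non-decreasing along development within a species) and ``batch``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if list(self.values.columns) != list(self.sample_meta.index):
            if set(self.values.columns) != set(self.sample_meta.index):
                raise ValueError("sample_meta rows must match matrix columns")
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self, pseudo: float = 1.0) -> pd.DataFrame:
        """Return log2(FPKM + pseudo)."""
        return np.log2(self.values + pseudo)

    def subset_samples(self, mask: pd.Series | np.ndarray) -> "ExpressionSet":
        cols = self.values.columns[np.asarray(mask)]
        return ExpressionSet(self.values[cols], self.sample_meta.loc[cols])

    def select(self, **criteria) -> "ExpressionSet":
        """Subset samples by metadata equality, e.g. ``select(species='gal')``."""
        mask = np.ones(self.n_samples, dtype=bool)
        for key, val in criteria.items():
            mask &= (self.sample_meta[key] == val).values
        return self.subset_samples(mask)

    def to_tsv(self, expr_path, meta_path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene_id")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, expr_path, meta_path) -> "ExpressionSet":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"batch": str})
        return cls(values, meta)


@dataclass
class OrthologTable:
    """1:1 ortholog groups: one gene ID per species per group.

    ``table`` is indexed by group ID with one column per species. Any gene ID
    may appear in at most one group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for sp in self.table.columns:
            col = self.table[sp].dropna()
            if col.duplicated().any():
                raise ValueError(f"gene appears in more than one group for {sp}")

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    def gene_to_group(self, species: str) -> dict[str, str]:
        return {g: og for og, g in self.table[species].dropna().items()}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="group_id")

    @classmethod
    def from_tsv(cls, path) -> "OrthologTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def filter_expressed(es: ExpressionSet, min_fpkm: float = 1.0) -> ExpressionSet:
    """Keep genes whose maximum FPKM across samples is >= ``min_fpkm``."""
    if min_fpkm < 0:
        raise ValueError("min_fpkm must be >= 0")
    keep = es.values.max(axis=1) >= min_fpkm
    if not keep.any():
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    return ExpressionSet(es.values.loc[keep], es.sample_meta)


def map_orthologs(
    es_list: list[ExpressionSet],
    table: OrthologTable,
    min_fpkm: float = 1.0,
) -> ExpressionSet:
    """Merge per-species expression sets onto ortholog-group rows.

    A group is retained only when its gene passes the expression filter in
    every species present; columns are the union of all samples.
    """
    by_species: dict[str, ExpressionSet] = {}
    for es in es_list:
        species = es.sample_meta["species"].unique()
        if len(species) != 1:
            raise ValueError("each input ExpressionSet must hold one species")
        sp = species[0]
        if sp not in table.species:
            raise ValueError(f"species {sp!r} missing from ortholog table")
        by_species[sp] = es

    all_samples: list[str] = []
    for es in by_species.values():
        all_samples.extend(es.values.columns)
    if len(all_samples) != len(set(all_samples)):
        raise ValueError("duplicate sample IDs across species")

    keep_groups = table.table.index
    for sp, es in by_species.items():
        expressed = set(filter_expressed(es, min_fpkm).gene_ids)
        genes = table.table[sp]
        ok = genes.notna() & genes.isin(expressed)
        keep_groups = keep_groups[ok.loc[keep_groups].values]

    blocks = []
    metas = []
    for sp, es in by_species.items():
        genes = table.table.loc[keep_groups, sp]
        block = es.values.loc[genes.values]
        block.index = keep_groups
        blocks.append(block)
        metas.append(es.sample_meta)
    values = pd.concat(blocks, axis=1)
    meta = pd.concat(metas, axis=0)
    return ExpressionSet(values, meta)


def remove_batch(es: ExpressionSet, pseudo: float = 1.0) -> ExpressionSet:
    """Location-scale batch adjustment per gene on log2(FPKM + pseudo).

    Within each batch every gene is centred and scaled to the batch mean/SD,
    then the pooled mean and SD are restored, so gene-wise pooled moments are
    untouched while batch offsets vanish. Genes with zero spread inside a
    batch get the location step only. Adjusted log values are clipped at 0
    before transforming back to FPKM.
    """
    batches = es.sample_meta["batch"]
    uniq = batches.unique()
    if len(uniq) < 2:
        raise ValueError("need >= 2 batches")
    for b in uniq:
        if (batches == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    log = es.log2(pseudo).values
    pooled_mean = log.mean(axis=1, keepdims=True)
    pooled_sd = log.std(axis=1, keepdims=True)
    adjusted = np.empty_like(log)
    for b in uniq:
        idx = (batches == b).values
        sub = log[:, idx]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        centred = sub - mu
        scale = np.divide(pooled_sd, sd, out=np.ones_like(sd), where=sd > 0)
        adjusted[:, idx] = centred * scale + pooled_mean
    adjusted = np.clip(adjusted, 0.0, None)
    fpkm = np.maximum(np.exp2(adjusted) - pseudo, 0.0)
    out = pd.DataFrame(fpkm, index=es.values.index, columns=es.values.columns)
    return ExpressionSet(out, es.sample_meta)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (population SD); constant rows become all-zero."""
    arr = matrix.values.astype(float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{constant.sum()} constant row(s) emitted as zeros", stacklevel=2)
    z = np.divide(arr - mu, sd, out=np.zeros_like(arr), where=sd > 0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def cluster_samples(matrix: pd.DataFrame, k: int):
    """Agglomerative clustering of sample columns, average linkage on
    1 - Pearson correlation.

    Returns ``(labels, linkage)`` where ``labels`` is a Series of cluster ids
    (1..k) over sample columns and ``linkage`` the scipy merge tree.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = matrix.shape[1]
    if k > n:
        raise ValueError("k exceeds number of samples")
    dist = ssd.pdist(matrix.values.T, metric="correlation")
    link = sch.linkage(dist, method="average")
    labels = sch.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.columns, name="cluster"), link


def name_clusters(
    labels: pd.Series,
    reference_samples: dict[str, str],
    group_order: list[str],
) -> dict[int, str]:
    """Name each cluster by the majority stage-group of its reference samples.

    ``reference_samples`` maps sample IDs of the reference species to their
    stage-group name; ``group_order`` lists group names in developmental
    order and breaks majority ties toward the earlier group. Clusters that
    contain no reference sample are named ``"unassigned"``.
    """
    rank = {g: i for i, g in enumerate(group_order)}
    names: dict[int, str] = {}
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        groups = [reference_samples[s] for s in members if s in reference_samples]
        if not groups:
            names[int(cluster)] = "unassigned"
            continue
        counts = pd.Series(groups).value_counts()
        top = counts[counts == counts.max()].index
        names[int(cluster)] = min(top, key=lambda g: rank[g])
    return names
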