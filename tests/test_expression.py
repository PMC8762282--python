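"""Expression integration: filtering, ortholog mapping, batch removal,
z-scoring and sample clustering."""

import numpy as np
import pandas as pd
import pytest

from xfollicle import synth
from xfollicle.expression import (
    ExpressionSet,
    OrthologTable,
    cluster_samples,
    filter_expressed,
    map_orthologs,
    name_clusters,
    remove_batch,
    zscore_rows,
)

from conftest import make_expression


def _meta(n, species="gal", comp="GC", batch=None):
    return [
        {
            "sample_id": f"{species}_{comp}_s{i}",
            "species": species,
            "compartment": comp,
            "stage": f"st{i % 2}",
            "stage_order": i % 2,
            "batch": batch or species,
        }
        for i in range(n)
    ]


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "row,kept",
        [([0.5, 0.2], False), ([1.0, 0.0], True), ([2.0, 0.1], True)],
    )
    def test_max_rule(self, row, kept):
        es = make_expression(np.array([row]), _meta(2))
        out = filter_expressed(es, 1.0)
        assert (out.n_genes == 1) == kept

    def test_toy_counts_and_order(self):
        es = make_expression(np.array([[0.9, 0.5], [1.0, 0.0], [2.0, 0.1]]), _meta(2))
        out = filter_expressed(es, 1.0)
        assert out.gene_ids == ["g1", "g2"]

    def test_empty_result_warns(self):
        es = make_expression(np.array([[0.1, 0.1]]), _meta(2))
        with pytest.warns(UserWarning):
            out = filter_expressed(es, 1.0)
        assert out.n_genes == 0


def _two_species_pair(vals_a, vals_b):
    es_a = make_expression(np.asarray(vals_a), _meta(2, species="gal"))
    es_b = make_expression(np.asarray(vals_b), _meta(2, species="bta"))
    return es_a, es_b


class TestMapOrthologs:
    def table(self, n, missing=None):
        df = pd.DataFrame(
            {
                "gal": [f"g{i}" for i in range(n)],
                "bta": [f"g{i}" for i in range(n)],
            },
            index=pd.Index([f"og{i}" for i in range(n)], name="group_id"),
        )
        if missing is not None:
            df.loc[f"og{missing}", "gal"] = np.nan
        return OrthologTable(df)

    def test_all_expressed(self):
        es_a, es_b = _two_species_pair([[2, 2], [3, 3]], [[2, 2], [3, 3]])
        out = map_orthologs([es_a, es_b], self.table(2))
        assert out.n_genes == 2 and out.n_samples == 4

    def test_missing_gene_drops_group(self):
        es_a, es_b = _two_species_pair([[2, 2], [3, 3]], [[2, 2], [3, 3]])
        out = map_orthologs([es_a, es_b], self.table(2, missing=1))
        assert out.gene_ids == ["og0"]

    def test_fixture_recount(self, bundle):
        """Group count equals an independent recount of per-species passes."""
        es_list = list(bundle["expression"].values())
        table = bundle["orthologs"]
        out = map_orthologs(es_list, table, min_fpkm=1.0)
        expected = 0
        for og in table.table.index:
            ok = True
            for es in es_list:
                sp = es.sample_meta["species"].iloc[0]
                gene = table.table.loc[og, sp]
                if es.values.loc[gene].max() < 1.0:
                    ok = False
                    break
            expected += ok
        assert out.n_genes == expected

    def test_duplicate_samples_rejected(self):
        es_a = make_expression(np.array([[2, 2]]), _meta(2, species="gal"))
        es_b = make_expression(np.array([[2, 2]]), _meta(2, species="bta"))
        es_b.values.columns = es_a.values.columns
        es_b.sample_meta.index = es_a.sample_meta.index
        with pytest.raises(ValueError):
            map_orthologs([es_a, es_b], self.table(1))


def _stack_species(es_by_sp):
    """Row-stack per-species matrices on ortholog position (same row order)."""
    vals = np.hstack([es.values.values for es in es_by_sp.values()])
    cols = sum([list(es.values.columns) for es in es_by_sp.values()], [])
    meta = pd.concat([es.sample_meta for es in es_by_sp.values()])
    frame = pd.DataFrame(vals, index=[f"r{i}" for i in range(vals.shape[0])], columns=cols)
    return frame, meta


class TestRemoveBatch:
    def test_additive_offset_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(4, 1, size=(20, 8))
        log = base.copy()
        log[:, 4:] += 2.0  # constant offset on batch B
        vals = np.exp2(log) - 1
        meta = _meta(8)
        for i, row in enumerate(meta):
            row["batch"] = "A" if i < 4 else "B"
        es = make_expression(np.clip(vals, 0, None), meta)
        out = remove_batch(es)
        logout = out.log2().values
        a = logout[:, :4].mean(axis=1)
        b = logout[:, 4:].mean(axis=1)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_pooled_means_preserved(self):
        rng = np.random.default_rng(1)
        vals = np.exp2(rng.normal(5, 1, size=(30, 6)))
        meta = _meta(6)
        for i, row in enumerate(meta):
            row["batch"] = "A" if i < 3 else "B"
        es = make_expression(vals, meta)
        out = remove_batch(es)
        np.testing.assert_allclose(
            out.log2().values.mean(axis=1), es.log2().values.mean(axis=1), atol=1e-9
        )

    def test_batch_free_data_nearly_unchanged(self):
        es_by_sp, _, _ = synth.generate_expression(
            n_genes=120, batch_sd=0.0, seed=5, n_specific=0,
            n_gc_markers=10, n_tc_markers=5, n_reps=6,
        )
        merged_vals, merged_meta = _stack_species(es_by_sp)
        es = ExpressionSet(merged_vals, merged_meta)
        out = remove_batch(es)
        a, b = es.log2().values, out.log2().values
        cors = np.array(
            [np.corrcoef(a[i], b[i])[0, 1] for i in range(a.shape[0]) if a[i].std() > 0]
        )
        # genes with planted stage structure: signal dominates, adjustment is
        # a near no-op; rows 0-44 hold the marker blocks
        assert cors[:45].min() >= 0.999
        # flat genes are noise-only, so removing batch-mean sampling noise
        # necessarily costs some correlation; still near-identity overall
        assert np.median(cors) >= 0.99

    def test_planted_batch_variance_shrinks(self):
        es_by_sp, _, _ = synth.generate_expression(
            n_genes=150, batch_sd=2.0, seed=6, n_specific=0,
            n_gc_markers=10, n_tc_markers=5,
        )
        merged_vals, merged_meta = _stack_species(es_by_sp)
        es = ExpressionSet(merged_vals, merged_meta)
        out = remove_batch(es)

        def between_batch_var(mat):
            groups = [
                mat[:, (merged_meta["batch"] == b).values].mean(axis=1)
                for b in merged_meta["batch"].unique()
            ]
            return np.var(np.stack(groups), axis=0)

        null_rows = slice(90, 150)  # beyond all planted marker blocks
        before = between_batch_var(es.log2().values)[null_rows].mean()
        after = between_batch_var(out.log2().values)[null_rows].mean()
        assert after <= before / 10

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        vals = np.exp2(rng.normal(5, 1, size=(25, 6)) + np.repeat([0, 1.5], 3))
        meta = _meta(6)
        for i, row in enumerate(meta):
            row["batch"] = "A" if i < 3 else "B"
        es = make_expression(vals, meta)
        once = remove_batch(es)
        twice = remove_batch(once)
        np.testing.assert_allclose(once.values.values, twice.values.values, atol=1e-7)


class TestZscore:
    def test_closed_form(self):
        out = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(
            out.values[0], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_constant_row_zero(self):
        with pytest.warns(UserWarning):
            out = zscore_rows(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert (out.values == 0).all()

    def test_rows_standardized(self):
        rng = np.random.default_rng(3)
        out = zscore_rows(pd.DataFrame(rng.normal(size=(10, 7))))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1), 1, atol=1e-12)


def _brute_average_linkage(dist: np.ndarray):
    """O(n^3) average-linkage reference; returns sorted merge heights."""
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


class TestClusterSamples:
    def test_identical_columns_merge_first(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=12)
        mat = pd.DataFrame(
            {"a": col, "b": col, "c": rng.normal(size=12), "d": rng.normal(size=12)}
        )
        _, link = cluster_samples(mat, 2)
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_clusters_together(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        mat = pd.DataFrame(
            {"a": x, "b": x + rng.normal(0, 0.05, 30), "c": rng.normal(size=30)}
        )
        labels, _ = cluster_samples(mat, 2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_merge_heights_match_bruteforce(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(size=(15, 6)))
        _, link = cluster_samples(mat, 2)
        corr = np.corrcoef(mat.values.T)
        dist = 1 - corr
        np.testing.assert_allclose(
            sorted(link[:, 2]), _brute_average_linkage(dist), atol=1e-10
        )

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.normal(size=(12, 6)), columns=list("abcdef"))
        labels, _ = cluster_samples(mat, 3)
        perm = list("fcdbea")
        labels_p, _ = cluster_samples(mat[perm], 3)
        part = {frozenset(labels.index[labels == c]) for c in labels.unique()}
        part_p = {frozenset(labels_p.index[labels_p == c]) for c in labels_p.unique()}
        assert part == part_p

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame(np.eye(3)), 4)


class TestNameClusters:
    ORDER = ["preantral follicles", "antral follicles", "preovulatory follicles"]

    def test_majority_vote(self):
        labels = pd.Series({"HG_a1": 1, "HG_a2": 1, "GAL_F1": 1, "HG_po": 2})
        ref = {
            "HG_a1": "antral follicles",
            "HG_a2": "antral follicles",
            "HG_po": "preovulatory follicles",
        }
        names = name_clusters(labels, ref, self.ORDER)
        assert names[1] == "antral follicles"
        assert names[2] == "preovulatory follicles"

    def test_tie_breaks_to_earlier_stage(self):
        labels = pd.Series({"s1": 1, "s2": 1})
        ref = {"s1": "preovulatory follicles", "s2": "preantral follicles"}
        assert name_clusters(labels, ref, self.ORDER)[1] == "preantral follicles"

    def test_unassigned(self):
        labels = pd.Series({"x": 1})
        assert name_clusters(labels, {}, self.ORDER)[1] == "unassigned"
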