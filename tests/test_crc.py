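"""TF network construction, motif scanning, closeness centrality, hubs and
circuits."""

import itertools

import networkx as nx
import numpy as np
import pytest

from xfollicle.crc import (
    PWM,
    TFNetwork,
    analyze_network,
    build_network,
    closeness,
    find_circuits,
    hub_tfs,
    revcomp,
    scan_motifs,
)


def pwm_for(consensus: str, tf="TF", p=0.85) -> PWM:
    probs = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = p
    return PWM("M0", tf, probs)


class TestScanMotifs:
    def test_consensus_hits(self):
        pwm = pwm_for("ACGTAC")
        hits = scan_motifs("TTACGTACTT", pwm, threshold=0.8)
        assert any(h["strand"] == "+" and h["start"] == 2 for h in hits)

    def test_reverse_strand_coordinates(self):
        pwm = pwm_for("ACGTAA")
        seq = "GG" + revcomp("ACGTAA") + "GG"
        hits = scan_motifs(seq, pwm, threshold=0.9)
        assert hits and hits[0]["strand"] == "-" and hits[0]["start"] == 2

    def test_all_n_no_hits(self):
        assert scan_motifs("N" * 30, pwm_for("ACGT"), 0.5) == []

    def test_short_sequence(self):
        assert scan_motifs("AC", pwm_for("ACGTA"), 0.5) == []

    def test_matches_bruteforce_windows(self):
        """Every hit equals brute-force scoring of all windows, both strands."""
        rng = np.random.default_rng(0)
        pwm = pwm_for("ACGT", p=0.7)
        lom = pwm.log_odds
        seq = "".join(rng.choice(list("ACGT"), size=30))
        threshold = 0.5
        expected = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - 3):
                score = sum(lom[j, "ACGT".index(s[i + j])] for j in range(4))
                if score >= threshold * pwm.max_score:
                    start = i if strand == "+" else len(seq) - i - 4
                    expected.add((start, strand))
        got = {(h["start"], h["strand"]) for h in scan_motifs(seq, pwm, threshold)}
        assert got == expected

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            scan_motifs("ACGT", pwm_for("AC"), 0.0)


class TestBuildNetwork:
    def test_planted_edge(self):
        pwms = {"A": pwm_for("ACGTACGTAC", "A"), "B": pwm_for("GGATCCGGAT", "B")}
        seqs = {
            "A": ["T" * 40],
            "B": ["T" * 10 + "ACGTACGTAC" + "T" * 10],
        }
        net = build_network(seqs, pwms)
        assert ("A", "B") in net.edges
        assert ("B", "A") not in net.edges

    def test_no_motifs_no_edges(self):
        pwms = {"A": pwm_for("ACGTACGTAC", "A")}
        net = build_network({"A": ["T" * 50]}, pwms)
        assert net.edges == set()

    def test_fixture_truth_exact(self, small_epigenome):
        from xfollicle.superenh import assign_genes, rank_regions, stitch

        fx = small_epigenome
        regions = stitch(fx.peaks, 12_500, tss=fx.tss, tss_excl=2_500)
        rank_regions(regions, fx.signal)
        assign_genes(regions, fx.tss, window=50_000)
        peak_by_name = {p.name: p for p in fx.peaks}
        chrom = fx.peaks[0].chrom
        seqs = {}
        for r in regions:
            if not r.is_super:
                continue
            cons = [
                fx.genome[chrom][peak_by_name[c].start : peak_by_name[c].end]
                for c in r.constituents
            ]
            for gene in r.genes:
                if gene in fx.pwms:
                    seqs.setdefault(gene, []).extend(cons)
        net = build_network(seqs, fx.pwms)
        truth_edges = {tuple(e) for e in fx.truth.planted_network["edges"]}
        truth_edges |= {tuple(e) for e in fx.truth.planted_network["self_edges"]}
        assert net.edges == truth_edges


class TestCloseness:
    def net(self, edges, nodes=None):
        g = nx.DiGraph()
        if nodes:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return TFNetwork(graph=g)

    def test_star_out(self):
        scores = closeness(self.net([("A", "B"), ("A", "C")]), "out")
        assert scores == {"A": 1.0, "B": 0.0, "C": 0.0}

    def test_three_cycle(self):
        scores = closeness(self.net([("A", "B"), ("B", "C"), ("C", "A")]), "out")
        for v in "ABC":
            assert scores[v] == pytest.approx(0.75)

    def test_edgeless(self):
        scores = closeness(self.net([], nodes=["A", "B", "C"]), "out")
        assert all(v == 0 for v in scores.values())

    def test_in_is_out_reversed(self):
        g = nx.gnp_random_graph(6, 0.4, seed=1, directed=True)
        assert closeness(TFNetwork(graph=g), "in") == closeness(
            TFNetwork(graph=g.reverse()), "out"
        )

    def _floyd_warshall_closeness(self, g, direction):
        nodes = list(g.nodes)
        n = len(nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0)
        for a, b in g.edges:
            if a != b:
                dist[idx[a], idx[b]] = 1
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    dist[i, j] = min(dist[i, j], dist[i, k] + dist[k, j])
        out = {}
        for v in nodes:
            i = idx[v]
            row = dist[i, :] if direction == "out" else dist[:, i]
            out[v] = sum(1.0 / d for j, d in enumerate(row) if j != i and np.isfinite(d)) / (n - 1)
        return out

    def test_matches_floyd_warshall(self):
        """Exhaustive agreement with a Floyd-Warshall oracle on 200 random
        directed graphs of up to 6 nodes."""
        rng = np.random.default_rng(2)
        for trial in range(200):
            n = int(rng.integers(2, 7))
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for a in range(n):
                for b in range(n):
                    if a != b and rng.random() < 0.35:
                        g.add_edge(a, b)
            net = TFNetwork(graph=g)
            for direction in ("out", "in"):
                got = closeness(net, direction)
                expected = self._floyd_warshall_closeness(g, direction)
                for v in g.nodes:
                    assert got[v] == pytest.approx(expected[v], abs=1e-12)

    def test_adding_edge_never_decreases_out(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(7, 0.25, seed=4, directed=True)
        base = closeness(TFNetwork(graph=g), "out")
        non_edges = [e for e in itertools.permutations(g.nodes, 2) if not g.has_edge(*e)]
        a, b = non_edges[rng.integers(len(non_edges))]
        g.add_edge(a, b)
        after = closeness(TFNetwork(graph=g), "out")
        assert all(after[v] >= base[v] - 1e-12 for v in g.nodes)


class TestHubs:
    def test_closed_form_threshold(self):
        scores = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 5.0}
        assert hub_tfs(scores) == {"d"}

    def test_all_equal_none(self):
        assert hub_tfs({"a": 0.5, "b": 0.5, "c": 0.5}) == set()


class TestCircuits:
    def net(self, edges, nodes=None):
        g = nx.DiGraph()
        if nodes:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return TFNetwork(graph=g)

    def test_mutual_pair(self):
        assert find_circuits(self.net([("A", "B"), ("B", "A")])) == [{"A", "B"}]

    def test_one_way_no_circuit(self):
        assert find_circuits(self.net([("A", "B")])) == []

    def test_planted_clique_with_distractors(self):
        """Exhaustive subset check: the directed 3-clique is the only
        maximal circuit despite extra one-way edges."""
        clique = [("A", "B"), ("B", "A"), ("A", "C"), ("C", "A"), ("B", "C"), ("C", "B")]
        distractors = [("D", "A"), ("B", "D"), ("E", "C")]
        net = self.net(clique + distractors)
        assert find_circuits(net) == [{"A", "B", "C"}]
        # oracle: every subset of size >= 2 fully mutually connected
        g = net.graph
        mutual_sets = []
        for size in (2, 3, 4, 5):
            for sub in itertools.combinations(g.nodes, size):
                if all(
                    g.has_edge(a, b) and g.has_edge(b, a)
                    for a, b in itertools.combinations(sub, 2)
                ):
                    mutual_sets.append(set(sub))
        maximal = [s for s in mutual_sets if not any(s < t for t in mutual_sets)]
        assert maximal == [{"A", "B", "C"}]

    def test_circuit_members_have_internal_degree(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(8, 0.5, seed=6, directed=True)
        for circuit in find_circuits(TFNetwork(graph=g)):
            for v in circuit:
                assert any(g.has_edge(v, u) for u in circuit if u != v)
                assert any(g.has_edge(u, v) for u in circuit if u != v)


class TestAnalyze:
    def test_fixture_hub_recovery(self, small_epigenome):
        """The planted hub (motif in every SE constituent) attains strictly
        maximal out-closeness, is flagged, and the planted 3-clique is the
        only circuit."""
        from xfollicle.superenh import assign_genes, rank_regions, stitch

        fx = small_epigenome
        regions = stitch(fx.peaks, 12_500, tss=fx.tss, tss_excl=2_500)
        rank_regions(regions, fx.signal)
        assign_genes(regions, fx.tss, window=50_000)
        peak_by_name = {p.name: p for p in fx.peaks}
        chrom = fx.peaks[0].chrom
        seqs = {}
        for r in regions:
            if not r.is_super:
                continue
            cons = [
                fx.genome[chrom][peak_by_name[c].start : peak_by_name[c].end]
                for c in r.constituents
            ]
            for gene in r.genes:
                if gene in fx.pwms:
                    seqs.setdefault(gene, []).extend(cons)
        net = analyze_network(build_network(seqs, fx.pwms))
        hub = fx.truth.planted_network["hub"]
        top = max(net.closeness_out, key=net.closeness_out.get)
        assert top == hub
        others = [v for k, v in net.closeness_out.items() if k != hub]
        assert net.closeness_out[hub] > max(others)
        assert hub in net.hubs
        assert [sorted(c) for c in net.circuits] == fx.truth.planted_network["circuits"]
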