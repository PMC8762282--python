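"""Super-enhancer-based core transcriptional regulatory circuitry.

Candidate TFs (expressed and super-enhancer-associated) are connected by a
directed edge A -> B whenever a motif of A scores a hit inside any SE
constituent assigned to B. Harmonic closeness centrality (out = regulatory
reach, in = being regulated) ranks the nodes; hub TFs are outliers in
out-closeness, and regulatory circuits are maximal sets in which every
ordered pair of TFs is linked (directed cliques).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix with its background base frequencies."""

    motif_id: str
    tf: str
    probs: np.ndarray  # positions x 4, order A C G T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be positions x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.probs, 1e-9)
        return np.log2(p / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _window_scores(seq: str, lom: np.ndarray) -> list[tuple[int, float]]:
    w = lom.shape[0]
    out = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        score = 0.0
        ok = True
        for j, base in enumerate(window):
            idx = BASE_INDEX.get(base.upper())
            if idx is None:
                ok = False
                break
            score += lom[j, idx]
        if ok:
            out.append((i, score))
    return out


def scan_motifs(sequence: str, pwm: PWM, threshold: float = 0.9) -> list[dict]:
    """Log-odds scan of both strands for PWM hits.

    A window is a hit when its score is >= ``threshold`` x the maximal
    attainable score. Windows containing non-ACGT characters are skipped.
    Reverse-strand hits are reported with forward-frame start coordinates.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(sequence) < len(pwm):
        return []
    cut = threshold * pwm.max_score
    lom = pwm.log_odds
    hits = [
        {"start": i, "strand": "+", "score": s}
        for i, s in _window_scores(sequence, lom)
        if s >= cut
    ]
    w = len(pwm)
    for i, s in _window_scores(revcomp(sequence), lom):
        if s >= cut:
            hits.append({"start": len(sequence) - i - w, "strand": "-", "score": s})
    hits.sort(key=lambda h: (h["start"], h["strand"]))
    return hits


@dataclass
class TFNetwork:
    """Directed TF -> TF regulatory graph with centralities and circuits."""

    graph: nx.DiGraph
    closeness_out: dict[str, float] = field(default_factory=dict)
    closeness_in: dict[str, float] = field(default_factory=dict)
    hubs: set[str] = field(default_factory=set)
    circuits: list[set[str]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


def build_network(
    se_sequences: dict[str, list[str]],
    pwms: dict[str, PWM],
    candidate_tfs: list[str] | None = None,
    threshold: float = 0.9,
) -> TFNetwork:
    """Directed edges A -> B from motif hits of A in B's SE constituents.

    ``se_sequences`` maps a TF gene to the sequences of the constituents of
    its assigned super-enhancer(s); TFs without an SE assignment are
    excluded. Self-edges are recorded.
    """
    tfs = list(candidate_tfs) if candidate_tfs is not None else sorted(se_sequences)
    tfs = [t for t in tfs if t in se_sequences]
    for t in tfs:
        if t not in pwms:
            raise ValueError(f"candidate TF {t!r} has no PWM")
    g = nx.DiGraph()
    g.add_nodes_from(tfs)
    for b in tfs:
        for seq in se_sequences[b]:
            for a in tfs:
                if g.has_edge(a, b):
                    continue
                if scan_motifs(seq, pwms[a], threshold):
                    g.add_edge(a, b)
    return TFNetwork(graph=g)


def closeness(network: TFNetwork | nx.DiGraph, direction: str = "out") -> dict[str, float]:
    """Harmonic closeness normalized by (n - 1).

    ``out`` sums 1/d(v, u) over targets reachable from v; ``in`` sums over
    sources reaching v. Unreachable nodes contribute 0; self-edges are
    ignored.
    """
    g = network.graph if isinstance(network, TFNetwork) else network
    g = nx.DiGraph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need >= 2 nodes")
    if direction not in ("out", "in"):
        raise ValueError("direction must be 'out' or 'in'")
    source_graph = g if direction == "out" else g.reverse(copy=False)
    scores = {}
    for v in g.nodes:
        dists = nx.single_source_shortest_path_length(source_graph, v)
        scores[v] = sum(1.0 / d for u, d in dists.items() if u != v) / (n - 1)
    return scores


def hub_tfs(scores: dict[str, float], sd_multiplier: float = 1.0) -> set[str]:
    """Nodes whose out-closeness exceeds mean + ``sd_multiplier`` x pop. SD."""
    if len(scores) < 2:
        raise ValueError("need >= 2 nodes")
    vals = np.array(list(scores.values()), dtype=float)
    sd = vals.std()
    if sd == 0:
        return set()
    cut = vals.mean() + sd_multiplier * sd
    return {v for v, s in scores.items() if s > cut}


def find_circuits(network: TFNetwork | nx.DiGraph) -> list[set[str]]:
    """Maximal directed cliques of size >= 2, largest first.

    A circuit is a node set in which every ordered pair is joined by an
    edge, i.e. a maximal clique of the mutual-edge (both directions)
    undirected graph.
    """
    g = network.graph if isinstance(network, TFNetwork) else network
    mutual = nx.Graph()
    mutual.add_nodes_from(g.nodes)
    for a, b in g.edges:
        if a != b and g.has_edge(b, a):
            mutual.add_edge(a, b)
    cliques = [set(c) for c in nx.find_cliques(mutual) if len(c) >= 2]
    cliques.sort(key=lambda c: (-len(c), sorted(c)))
    return cliques


def analyze_network(network: TFNetwork, sd_multiplier: float = 1.0) -> TFNetwork:
    """Fill centralities, hub flags and circuits on a built network."""
    network.closeness_out = closeness(network, "out")
    network.closeness_in = closeness(network, "in")
    network.hubs = hub_tfs(network.closeness_out, sd_multiplier)
    network.circuits = find_circuits(network)
    return network


def read_pwms(path) -> dict[str, PWM]:
    """Read JASPAR-style PWM text: ``>motif_id tf`` then 4 base rows.

    Rows are labelled ``A``/``C``/``G``/``T`` with counts or probabilities;
    each column is normalized to probabilities.
    """
    pwms: dict[str, PWM] = {}
    with open(path) as fh:
        header = None
        rows: dict[str, list[float]] = {}
        for line in list(fh) + [">"]:
            line = line.strip()
            if line.startswith(">"):
                if header is not None and rows:
                    motif_id, tf = header
                    mat = np.array([rows[b] for b in "ACGT"]).T
                    mat = mat / mat.sum(axis=1, keepdims=True)
                    pwms[tf] = PWM(motif_id, tf, mat)
                parts = line[1:].split()
                header = (parts[0], parts[1]) if len(parts) > 1 else (parts[0] if parts else "", parts[0] if parts else "")
                rows = {}
            elif line:
                base, rest = line.split(None, 1)
                vals = rest.replace("[", " ").replace("]", " ").split()
                rows[base.upper()] = [float(v) for v in vals]
    return pwms


def write_pwms(pwms: dict[str, PWM], path) -> None:
    with open(path, "w") as fh:
        for tf, p in pwms.items():
            fh.write(f">{p.motif_id} {tf}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.6f}" for v in p.probs[:, bi])
                fh.write(f"{base} [ {vals} ]\n")
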