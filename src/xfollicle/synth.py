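"""Synthetic pipeline inputs with planted, machine-readable ground truth.

Every downstream stage of the pipeline gets a generator here that emulates
the structure of its real inputs — cross-species stage-structured FPKM
matrices with batch effects, H3K27ac peak/signal tracks with super-enhancer
clusters and planted motif occurrences, and MAF alignment blocks with
clade-structured gap patterns — together with a :class:`SyntheticTruth`
record of exactly what was planted, so parameter recovery can be scored
without any external download.

All generators are seeded and byte-stable: the same seed reproduces the
same files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionSet, OrthologTable
from .crc import PWM, revcomp
from .conserv import AlignmentBlock, AlignmentBlockSet, MafRow
from .superenh import Interval

REF_STAGES = ["selection", "differentiation", "preovulatory"]
DEFAULT_SPECIES = ["gal", "hsa", "bta"]
DEFAULT_STAGES = {
    "gal": ["ph6mm", "F5", "F1"],
    "hsa": ["antral_small", "antral_large", "preovulatory"],
    "bta": ["slct", "diff", "po"],
}
COMPARTMENTS = ["GC", "TC"]


@dataclass
class SyntheticTruth:
    """What was planted, keyed the way downstream recovery tests need it."""

    planted_stage_map: dict = field(default_factory=dict)
    planted_specific_genes: dict = field(default_factory=dict)
    planted_stage_markers: dict = field(default_factory=dict)
    planted_se_regions: list = field(default_factory=list)
    planted_network: dict = field(default_factory=dict)
    planted_clade_conserved: dict = field(default_factory=dict)
    planted_terms: dict = field(default_factory=dict)
    planted_binding: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        for name in self.__dataclass_fields__:
            mine, theirs = getattr(self, name), getattr(other, name)
            if isinstance(mine, dict):
                mine.update(theirs)
            else:
                mine.extend(theirs)
        return self

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=sorted)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


# ---------------------------------------------------------------------------
# orthologs and expression
# ---------------------------------------------------------------------------

def generate_orthologs(
    n_genes: int, species_list: list[str] | None = None
) -> OrthologTable:
    """1:1 ortholog table over ``n_genes`` groups for the given species."""
    _check_positive(n_genes=n_genes)
    species_list = species_list or DEFAULT_SPECIES
    groups = [f"og{i:05d}" for i in range(n_genes)]
    table = pd.DataFrame(
        {sp: [f"{sp}_g{i:05d}" for i in range(n_genes)] for sp in species_list},
        index=pd.Index(groups, name="group_id"),
    )
    return OrthologTable(table)


def generate_expression(
    n_genes: int = 400,
    species_list: list[str] | None = None,
    stages_per_species: dict[str, list[str]] | None = None,
    n_reps: int = 3,
    effect_fold: float = 16.0,
    batch_sd: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.2,
    n_gc_markers: int = 40,
    n_tc_markers: int = 20,
    n_specific: int = 40,
    n_specific_tc_overlap: int = 1,
    stage_map: dict[str, dict[str, int]] | None = None,
    specific_species: str = "gal",
) -> tuple[dict[str, ExpressionSet], OrthologTable, SyntheticTruth]:
    """Stage-structured log-normal FPKM matrices with planted gene blocks.

    Baseline log2 FPKM per ortholog group is Normal(3, 2), shared across
    species; per-sample noise is Normal(0, ``noise_sd``) and each species is
    one batch with additive per-gene offsets Normal(0, ``batch_sd``), all on
    the log2 scale. Per reference stage and compartment a block of marker
    genes is up-shifted by log2(``effect_fold``) in the stages mapping to
    that reference stage (the planted stage map). ``n_specific`` genes are
    silenced everywhere (FPKM < 1) except in the differentiation-stage GC
    samples of ``specific_species``; ``n_specific_tc_overlap`` of them are
    additionally expressed in the TC compartment at the same stage.

    Returns per-species expression sets, the ortholog table, and the truth.
    """
    _check_positive(n_genes=n_genes, n_reps=n_reps, effect_fold=effect_fold)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if effect_fold < 1:
        raise ValueError("effect_fold must be >= 1")
    species_list = species_list or DEFAULT_SPECIES
    stages_per_species = stages_per_species or {
        sp: DEFAULT_STAGES.get(sp, [f"s{i}" for i in range(3)]) for sp in species_list
    }
    if stage_map is None:
        stage_map = {
            sp: {st: min(i, len(REF_STAGES) - 1) for i, st in enumerate(stages)}
            for sp, stages in stages_per_species.items()
        }
    if specific_species not in species_list:
        raise ValueError("specific_species must be in species_list")

    rng = np.random.default_rng(seed)
    table = generate_orthologs(n_genes, species_list)
    groups = list(table.table.index)

    base = rng.normal(3.0, 2.0, size=n_genes)

    # planted blocks: disjoint gene index ranges
    needed = len(REF_STAGES) * (n_gc_markers + n_tc_markers) + n_specific
    if needed > n_genes:
        raise ValueError("n_genes too small for the requested planted blocks")
    cursor = 0
    marker_idx: dict[tuple[str, int], np.ndarray] = {}
    for comp, n_mark in (("GC", n_gc_markers), ("TC", n_tc_markers)):
        for ref_stage in range(len(REF_STAGES)):
            marker_idx[(comp, ref_stage)] = np.arange(cursor, cursor + n_mark)
            cursor += n_mark
    specific_idx = np.arange(cursor, cursor + n_specific)
    cursor += n_specific

    shift = np.log2(effect_fold)
    diff_stage = REF_STAGES.index("differentiation")
    low_base = -4.0  # log2 FPKM ~ 0.06, silent
    specific_high = 5.0

    truth = SyntheticTruth(seeds={"expression": int(seed)})
    truth.planted_stage_map = {
        sp: {st: int(r) for st, r in m.items()} for sp, m in stage_map.items()
    }
    truth.planted_stage_markers = {}
    spec_groups = [groups[i] for i in specific_idx]
    overlap_groups = spec_groups[:n_specific_tc_overlap]
    truth.planted_specific_genes = {
        "species": specific_species,
        "compartment": "GC",
        "ref_stage": diff_stage,
        "groups": spec_groups,
        "tc_overlap_groups": overlap_groups,
        "expected_spgs": spec_groups[n_specific_tc_overlap:],
    }

    es_by_species: dict[str, ExpressionSet] = {}
    for sp in species_list:
        stages = stages_per_species[sp]
        batch_offset = rng.normal(0.0, batch_sd, size=n_genes) if batch_sd > 0 else np.zeros(n_genes)
        cols = {}
        meta_rows = []
        for comp in COMPARTMENTS:
            for order, stage in enumerate(stages):
                ref_stage = stage_map[sp][stage]
                mean = base.copy()
                idx = marker_idx[(comp, ref_stage)]
                mean[idx] += shift
                mean[specific_idx] = low_base
                if (
                    sp == specific_species
                    and comp == "GC"
                    and ref_stage == diff_stage
                ):
                    mean[specific_idx] = specific_high
                if (
                    sp == specific_species
                    and comp == "TC"
                    and ref_stage == diff_stage
                    and n_specific_tc_overlap
                ):
                    mean[specific_idx[:n_specific_tc_overlap]] = specific_high
                for rep in range(1, n_reps + 1):
                    sample = f"{sp}_{comp}_{stage}_r{rep}"
                    logv = mean + batch_offset + rng.normal(0.0, noise_sd, n_genes)
                    cols[sample] = np.exp2(logv)
                    meta_rows.append(
                        {
                            "sample_id": sample,
                            "species": sp,
                            "compartment": comp,
                            "stage": stage,
                            "stage_order": order,
                            "batch": sp,
                        }
                    )
                if comp == "GC":
                    key = f"{sp}|{comp}|{stage}"
                    marked = [groups[i] for i in marker_idx[("GC", ref_stage)]]
                    if sp == specific_species and ref_stage == diff_stage:
                        marked = marked + spec_groups
                    truth.planted_stage_markers[key] = marked
                else:
                    key = f"{sp}|{comp}|{stage}"
                    marked = [groups[i] for i in marker_idx[("TC", ref_stage)]]
                    if sp == specific_species and ref_stage == diff_stage:
                        marked = marked + overlap_groups
                    truth.planted_stage_markers[key] = marked

        gene_ids = list(table.table[sp].values)
        values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        es_by_species[sp] = ExpressionSet(values, meta)

    return es_by_species, table, truth


def generate_annotation(
    table: OrthologTable,
    truth: SyntheticTruth,
    n_terms: int = 50,
    genes_per_specific_term: int = 10,
    term_size_range: tuple[int, int] = (15, 40),
    seed: int = 0,
) -> tuple[dict[str, set[str]], SyntheticTruth]:
    """GMT-style annotation over ortholog groups with planted enriched terms.

    The planted species-specific genes are split into terms of
    ``genes_per_specific_term`` members each (the planted enriched BPs);
    ``n_terms`` additional noise terms draw random groups.
    """
    rng = np.random.default_rng(seed)
    spec = truth.planted_specific_genes.get("groups", [])
    # noise terms never contain planted specific genes; otherwise they would
    # be genuinely enriched and the planted term list would not be the truth
    groups = np.array([g for g in table.table.index if g not in set(spec)])
    terms: dict[str, set[str]] = {}
    planted_terms = []
    for t, lo in enumerate(range(0, len(spec), genes_per_specific_term)):
        name = f"BP_planted_{t:02d}"
        terms[name] = set(spec[lo : lo + genes_per_specific_term])
        planted_terms.append(name)
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        members = rng.choice(groups, size=size, replace=False)
        terms[f"BP_noise_{t:03d}"] = set(members.tolist())
    truth.planted_terms = {"enriched": planted_terms}
    truth.seeds["annotation"] = int(seed)
    return terms, truth


# ---------------------------------------------------------------------------
# epigenome
# ---------------------------------------------------------------------------

@dataclass
class EpigenomeFixture:
    peaks: list
    signal: pd.DataFrame
    tss: list
    pwms: dict[str, PWM]
    genome: dict[str, str]
    truth: SyntheticTruth


def _random_consensus(rng: np.random.Generator, length: int, taken: set[str]) -> str:
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if seq != revcomp(seq) and seq not in taken and revcomp(seq) not in taken:
            return seq
    raise RuntimeError("could not draw a fresh consensus after 100 attempts")


def _pwm_from_consensus(motif_id: str, tf: str, consensus: str, p: float = 0.85) -> PWM:
    probs = np.full((len(consensus), 4), (1 - p) / 3)
    for i, base in enumerate(consensus):
        probs[i, "ACGT".index(base)] = p
    return PWM(motif_id, tf, probs)


def generate_epigenome(
    n_enh: int = 400,
    n_se: int = 20,
    se_cluster_size: int = 3,
    tf_genes: list[str] | None = None,
    seed: int = 0,
    stitch_dist: int = 12_500,
    motif_length: int = 12,
    n_distractor_edges: int = 2,
) -> EpigenomeFixture:
    """Peak/signal/TSS/PWM fixture with planted SEs and a known TF graph.

    ``n_enh`` isolated typical enhancers and ``n_se`` clusters of
    ``se_cluster_size`` peaks (gaps below the stitch distance) are laid on
    one chromosome, separated by more than ``stitch_dist``. Typical-peak
    signal areas are low log-normal; each SE cluster's total area is 30-60x
    the typical median. The first TF is the planted hub (its consensus in
    every SE constituent); the next three form a mutual 3-clique; remaining
    planted edges are one-directional distractors. Consensus strings arising
    by chance in the background sequence are scrubbed, so the planted edge
    list is the exact regulatory graph.
    """
    _check_positive(n_enh=n_enh, se_cluster_size=se_cluster_size)
    if n_se < 0 or n_se >= n_enh:
        raise ValueError("need 0 <= n_se < n_enh")
    if tf_genes is not None:
        tf_genes = list(tf_genes)
    else:
        tf_genes = [f"TF{i}" for i in range(8)] if n_se >= 8 else []
    if len(tf_genes) > n_se:
        raise ValueError("need at least one SE per TF gene")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    spacing = stitch_dist + 5_000
    # SE clusters carry the only TSSs; keep other SEs outside each TSS's
    # assignment window so every SE's constituents belong to one gene only
    se_margin = 50_000 + 10_000

    # interleave SE clusters among typical enhancers
    kinds = list(np.array(["typ"] * n_enh + ["se"] * n_se))
    rng.shuffle(kinds)

    peaks: list[Interval] = []
    tss: list[Interval] = []
    typical_areas = []
    se_slots: list[dict] = []
    pos = 10_000
    pk = 0
    for i, kind in enumerate(kinds):
        if kind == "typ":
            width = int(rng.integers(400, 801))
            peaks.append(Interval(chrom, pos, pos + width, f"peak_{pk:05d}"))
            typical_areas.append(1000.0 * float(rng.lognormal(0.0, 0.15)))
            pk += 1
            pos += width
        else:
            start = pos
            constituents = []
            for c in range(se_cluster_size):
                width = int(rng.integers(600, 1001))
                peaks.append(Interval(chrom, pos, pos + width, f"peak_{pk:05d}"))
                constituents.append(peaks[-1])
                pk += 1
                pos += width
                if c < se_cluster_size - 1:
                    pos += int(rng.integers(500, 2001))
            se_slots.append(
                {"start": start, "end": pos, "constituents": constituents}
            )
        next_is_se = i + 1 < len(kinds) and kinds[i + 1] == "se"
        pos += se_margin if (kind == "se" or next_is_se) else spacing
    genome_len = pos + 10_000

    typical_median = float(np.median(typical_areas))
    # peak areas: typicals get their own draw; SE constituents split the total
    area_by_peak: dict[str, float] = {}
    ti = si = i = 0
    for kind in kinds:
        if kind == "typ":
            area_by_peak[peaks[i].name] = typical_areas[ti]
            ti += 1
            i += 1
        else:
            slot = se_slots[si]
            total = typical_median * float(rng.uniform(30.0, 60.0))
            split = rng.dirichlet(np.ones(se_cluster_size)) * total
            for c, p in enumerate(slot["constituents"]):
                area_by_peak[p.name] = float(split[c])
            slot["total"] = total
            si += 1
            i += se_cluster_size

    signal = pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "value": [area_by_peak[p.name] / (p.end - p.start) for p in peaks],
        }
    )

    # TSS: one gene per SE (TF genes first), placed past the cluster end,
    # outside every peak's TSS-exclusion reach
    gene_names = tf_genes + [f"SEG{i}" for i in range(n_se - len(tf_genes))]
    tf_to_se: dict[str, int] = {}
    for si, slot in enumerate(se_slots):
        gene = gene_names[si]
        t0 = slot["end"] + 4_000
        tss.append(Interval(chrom, t0, t0 + 1, gene))
        if gene in tf_genes:
            tf_to_se[gene] = si
        slot["gene"] = gene

    # planted regulatory graph
    hub = tf_genes[0] if tf_genes else None
    clique = tf_genes[1:4] if len(tf_genes) >= 4 else []
    edges: set[tuple[str, str]] = set()
    if hub is not None:
        for b in tf_genes:
            edges.add((hub, b))
    for a in clique:
        for b in clique:
            if a != b:
                edges.add((a, b))
    pool = [
        (a, b)
        for a in tf_genes
        for b in tf_genes
        if a != b and (a, b) not in edges and (b, a) not in edges and a != hub
    ]
    rng.shuffle(pool)
    added = 0
    for a, b in pool:
        if added >= n_distractor_edges:
            break
        if (b, a) in edges:  # keep distractors one-directional
            continue
        edges.add((a, b))
        added += 1

    # PWMs with distinct consensus strings
    pwms: dict[str, PWM] = {}
    taken: set[str] = set()
    for t, tf in enumerate(tf_genes):
        cons = _random_consensus(rng, motif_length, taken)
        taken.add(cons)
        pwms[tf] = _pwm_from_consensus(f"M{t:02d}", tf, cons)

    # background genome: scrub accidental consensus copies first, then plant
    genome = list(rng.choice(list("ACGT"), size=genome_len))
    needles = [pwms[tf].consensus for tf in tf_genes]
    needles += [revcomp(c) for c in needles]
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}

    def scrub(protected: list[tuple[int, int]]) -> None:
        text = "".join(genome)
        for needle in needles:
            startpos = 0
            while True:
                hit = text.find(needle, startpos)
                if hit < 0:
                    break
                mid_candidates = [
                    hit + off
                    for off in range(len(needle))
                    if not any(lo <= hit + off < hi for lo, hi in protected)
                ]
                if mid_candidates:
                    at = mid_candidates[len(mid_candidates) // 2]
                    genome[at] = swap[genome[at]]
                    text = "".join(genome)
                startpos = hit + 1

    scrub(protected=[])

    planted_spans: list[tuple[int, int]] = []

    def plant(seq: str, lo: int, hi: int) -> None:
        if hi - lo <= len(seq):
            raise RuntimeError("constituent too small for motif")
        for _ in range(100):
            at = int(rng.integers(lo, hi - len(seq)))
            span = (at, at + len(seq))
            if all(span[1] <= s or span[0] >= e for s, e in planted_spans):
                genome[span[0] : span[1]] = list(seq)
                planted_spans.append(span)
                return
        raise RuntimeError("could not place a motif after 100 attempts")

    if hub is not None:
        for slot in se_slots:
            for c in slot["constituents"]:
                plant(pwms[hub].consensus, c.start, c.end)
    for a, b in sorted(edges):
        if a == hub:
            continue  # hub already in every constituent
        slot = se_slots[tf_to_se[b]]
        c = slot["constituents"][int(rng.integers(len(slot["constituents"])))]
        plant(pwms[a].consensus, c.start, c.end)

    # junctions around plants could recreate a consensus by chance
    scrub(protected=planted_spans)
    text = "".join(genome)

    truth = SyntheticTruth(seeds={"epigenome": int(seed)})
    truth.planted_se_regions = [
        {
            "chrom": chrom,
            "start": int(s["start"]),
            "end": int(s["end"]),
            "gene": s["gene"],
            "total_signal": float(s["total"]),
        }
        for s in se_slots
    ]
    truth.planted_network = {
        "tfs": tf_genes,
        "edges": sorted([a, b] for a, b in edges),
        "hub": hub,
        "self_edges": [[hub, hub]] if hub is not None else [],
        "circuits": [sorted(clique)] if clique else [],
    }

    return EpigenomeFixture(
        peaks=peaks,
        signal=signal,
        tss=tss,
        pwms=pwms,
        genome={chrom: text},
        truth=truth,
    )


# ---------------------------------------------------------------------------
# alignment blocks
# ---------------------------------------------------------------------------

def generate_alignment_blocks(
    n_species: int = 77,
    conserved_clade: list[str] | None = None,
    gap_rate_in: float = 0.05,
    gap_rate_out: float = 0.6,
    seed: int = 0,
    ref_length: int = 6_000,
    block_width: int = 500,
    intervals: list[tuple[int, int, str]] | None = None,
    motif: str | None = None,
) -> tuple[AlignmentBlockSet, SyntheticTruth]:
    """MAF-like blocks over pseudo-species with clade-structured gaps.

    The reference row (first species) is gap-free. Within each planted
    interval, per-column gap probability is ``gap_rate_in`` for clade
    members and ``gap_rate_out`` for the rest when the interval kind is
    ``clade``; ``in`` for everyone when ``shared``; ``out`` for everyone
    when ``none``. Outside planted intervals every non-reference species
    uses a background rate of 0.5. Clade members copy the reference base in
    their ungapped columns, so a ``motif`` planted in the reference persists
    in the clade.
    """
    if not 0 <= gap_rate_in < gap_rate_out <= 1:
        raise ValueError("need 0 <= gap_rate_in < gap_rate_out <= 1")
    _check_positive(n_species=n_species, ref_length=ref_length, block_width=block_width)
    species = ["galGal"] + [f"sp{i:02d}" for i in range(1, n_species)]
    if conserved_clade is None:
        conserved_clade = species[1:13]
    if not set(conserved_clade) <= set(species):
        raise ValueError("clade must be a subset of the species list")
    reference = species[0]
    if intervals is None:
        intervals = [
            (500, 1500, "clade"),
            (2000, 3000, "clade"),
            (3500, 4500, "shared"),
            (5000, 5800, "none"),
        ]
        intervals = [iv for iv in intervals if iv[1] <= ref_length]
        if not intervals:
            intervals = [(ref_length // 4, 3 * ref_length // 4, "clade")]
    for start, end, kind in intervals:
        if not (0 <= start < end <= ref_length):
            raise ValueError(f"interval ({start}, {end}) outside the reference")
    rng = np.random.default_rng(seed)

    ref_seq = rng.choice(list("ACGT"), size=ref_length)
    if motif:
        for start, end, kind in intervals:
            if kind == "clade" and end - start > len(motif) + 20:
                at = start + 10
                ref_seq[at : at + len(motif)] = list(motif)
    ref_seq = "".join(ref_seq)

    rate = np.full((n_species, ref_length), 0.5)
    clade_mask = np.array([sp in conserved_clade for sp in species])
    for start, end, kind in intervals:
        if kind == "clade":
            rate[:, start:end] = np.where(clade_mask, gap_rate_in, gap_rate_out)[:, None]
        elif kind == "shared":
            rate[:, start:end] = gap_rate_in
        else:
            rate[:, start:end] = gap_rate_out
    rate[0, :] = 0.0  # reference gap-free

    gaps = rng.random((n_species, ref_length)) < rate
    bases = rng.choice(list("ACGT"), size=(n_species, ref_length))
    ref_arr = np.array(list(ref_seq))
    copy_ref = clade_mask[:, None] & ~gaps
    texts = np.where(gaps, "-", np.where(copy_ref, ref_arr[None, :], bases))
    texts[0, :] = ref_arr

    blocks: list[AlignmentBlock] = []
    src_pos = np.zeros(n_species, dtype=int)
    for b0 in range(0, ref_length, block_width):
        b1 = min(b0 + block_width, ref_length)
        rows: dict[str, MafRow] = {}
        for s, sp in enumerate(species):
            text = "".join(texts[s, b0:b1])
            size = (b1 - b0) - text.count("-")
            rows[sp] = MafRow(
                species=sp,
                chrom="chr1" if sp == reference else "scaf1",
                start=int(src_pos[s]),
                size=size,
                strand="+",
                src_size=ref_length,
                text=text,
            )
            src_pos[s] += size
        blocks.append(AlignmentBlock(rows))

    truth = SyntheticTruth(seeds={"alignment": int(seed)})
    expected = {"clade": "clade-specific", "shared": "shared", "none": "not-conserved"}
    truth.planted_clade_conserved = {
        "clade": sorted(conserved_clade),
        "reference": reference,
        "intervals": {
            f"chr1:{start}-{end}": {
                "kind": kind,
                "verdict": expected[kind],
                "conserved_species": sorted(
                    sp
                    for s, sp in enumerate(species)
                    if sp != reference
                    and (texts[s, start:end] == "-").mean() <= 0.5
                ),
            }
            for start, end, kind in intervals
        },
    }
    if motif:
        truth.planted_binding = {
            sp: sum(
                "".join(texts[s, start:end][texts[s, start:end] != "-"]).count(motif)
                for start, end, kind in intervals
            )
            for s, sp in enumerate(species)
        }
    return AlignmentBlockSet(blocks, reference, species), truth


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    outdir,
    seed: int = 0,
    expression_kwargs: dict | None = None,
    epigenome_kwargs: dict | None = None,
    alignment_kwargs: dict | None = None,
) -> dict:
    """Generate and write the full pipeline fixture to ``outdir``.

    Emits per-species expression/metadata TSVs, the ortholog table, a GMT
    annotation, narrowPeak peaks, bedGraph signal, BED6 TSS, PWM text, a
    genome FASTA, a MAF alignment and ``truth.json``. Seeds for the three
    generators are derived from ``seed``. Returns a manifest of paths plus
    the in-memory objects.
    """
    from pathlib import Path

    from .crc import write_pwms
    from .specific import write_gmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_expr, s_ann, s_epi, s_aln = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )

    es_by_species, table, truth = generate_expression(
        seed=s_expr, **(expression_kwargs or {})
    )
    annotation, truth = generate_annotation(table, truth, seed=s_ann)
    epi = generate_epigenome(seed=s_epi, **(epigenome_kwargs or {}))
    blocks, aln_truth = generate_alignment_blocks(
        seed=s_aln, **(alignment_kwargs or {})
    )
    truth.merge(epi.truth).merge(aln_truth)

    paths: dict[str, str] = {}
    for sp, es in es_by_species.items():
        e, m = out / f"expr_{sp}.tsv", out / f"meta_{sp}.tsv"
        es.to_tsv(e, m)
        paths[f"expr_{sp}"] = str(e)
        paths[f"meta_{sp}"] = str(m)
    table.to_tsv(out / "orthologs.tsv")
    paths["orthologs"] = str(out / "orthologs.tsv")
    write_gmt(annotation, out / "annotation.gmt")
    paths["annotation"] = str(out / "annotation.gmt")

    with open(out / "peaks.narrowPeak", "w") as fh:
        for p in epi.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t0\t-1\t-1\t-1\n")
    paths["peaks"] = str(out / "peaks.narrowPeak")
    epi.signal.to_csv(out / "signal.bedGraph", sep="\t", header=False, index=False)
    paths["signal"] = str(out / "signal.bedGraph")
    with open(out / "tss.bed", "w") as fh:
        for t in epi.tss:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.name}\t0\t+\n")
    paths["tss"] = str(out / "tss.bed")
    write_pwms(epi.pwms, out / "motifs.pwm")
    paths["pwms"] = str(out / "motifs.pwm")
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in epi.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = str(out / "genome.fa")

    blocks.write_maf(out / "alignment.maf")
    paths["alignment"] = str(out / "alignment.maf")
    truth.to_json(out / "truth.json")
    paths["truth"] = str(out / "truth.json")

    return {
        "paths": paths,
        "expression": es_by_species,
        "orthologs": table,
        "annotation": annotation,
        "epigenome": epi,
        "alignment": blocks,
        "truth": truth,
    }
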