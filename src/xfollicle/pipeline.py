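"""End-to-end pipeline orchestration.

``run_all`` executes the stages in dependency order — integrate expression,
align stages, discover species-specific genes, call super-enhancers, build
the TF network, score conservation, run the gene-set statistics — from a
single :class:`PipelineConfig`, writing plain-file outputs per stage and a
machine-readable JSON report. When a ``truth.json`` from the synthetic
generator is listed in the config, recovery metrics against the planted
ground truth are added to the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conserv, crc, expression, specific, stagealign, stats, superenh, synth

log = logging.getLogger("xfollicle")


@dataclass
class PipelineConfig:
    paths: dict[str, str]
    species: list[str] = field(default_factory=lambda: list(synth.DEFAULT_SPECIES))
    reference_species: str = "bta"
    target_species: str = "gal"
    clade: list[str] = field(default_factory=list)
    min_fpkm: float = 1.0
    padj_alpha: float = 0.05
    gsea_alpha: float = 0.01
    gsea_nperm: int = 1000
    stitch: int = 12_500
    tss_excl: int = 2_500
    assign_window: int = 50_000
    hub_sd_multiplier: float = 1.0
    motif_threshold: float = 0.9
    max_gap: float = 0.5
    top_k_bps: int = 10
    cluster_k: int = 3
    seed: int = 0
    outdir: str = "xfollicle_out"

    def __post_init__(self) -> None:
        for name in (
            "min_fpkm", "padj_alpha", "gsea_alpha", "stitch", "tss_excl",
            "assign_window", "hub_sd_multiplier", "motif_threshold", "max_gap",
            "top_k_bps",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def require(self, *keys: str) -> None:
        for key in keys:
            if key not in self.paths:
                raise FileNotFoundError(f"config lists no path for {key!r}")
            if not Path(self.paths[key]).exists():
                raise FileNotFoundError(f"input path missing: {self.paths[key]}")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _f1_sets(called: set, truth: set) -> dict:
    tp = len(called & truth)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(truth) if truth else 0.0
    return {"precision": precision, "recall": recall, "n_called": len(called), "n_truth": len(truth)}


def stage_expression(cfg: PipelineConfig) -> dict:
    cfg.require(*[f"expr_{sp}" for sp in cfg.species], *[f"meta_{sp}" for sp in cfg.species], "orthologs")
    es_list = [
        expression.ExpressionSet.from_tsv(cfg.paths[f"expr_{sp}"], cfg.paths[f"meta_{sp}"])
        for sp in cfg.species
    ]
    table = expression.OrthologTable.from_tsv(cfg.paths["orthologs"])
    merged = expression.map_orthologs(es_list, table, min_fpkm=cfg.min_fpkm)
    corrected = expression.remove_batch(merged)
    z = expression.zscore_rows(corrected.log2())
    labels, _ = expression.cluster_samples(z, k=cfg.cluster_k)
    return {
        "es_list": es_list,
        "table": table,
        "merged": merged,
        "corrected": corrected,
        "labels": labels,
        "n_homologous_expressed": merged.n_genes,
    }


def stage_alignment(cfg: PipelineConfig, corrected: expression.ExpressionSet) -> dict:
    out = {}
    for comp in ("GC", "TC"):
        ref = stagealign.StageSeries.from_expression(corrected, cfg.reference_species, comp)
        for sp in cfg.species:
            if sp == cfg.reference_species:
                continue
            query = stagealign.StageSeries.from_expression(corrected, sp, comp)
            out[f"{sp}|{comp}"] = stagealign.align_stages(query, ref)
    return out


def stage_specific(cfg: PipelineConfig, es_list, table) -> dict:
    ann = specific.read_gmt(cfg.paths["annotation"])
    background = set(table.table.index)
    markers: dict[tuple[str, str], specific.StageGeneSets] = {}
    group_sets: dict[tuple[str, str], specific.StageGeneSets] = {}
    for es in es_list:
        sp = es.sample_meta["species"].iloc[0]
        for comp in ("GC", "TC"):
            sets = specific.stage_markers(es, sp, comp, alpha=cfg.padj_alpha, min_fpkm=cfg.min_fpkm)
            markers[(sp, comp)] = sets
            g2o = table.gene_to_group(sp)
            group_sets[(sp, comp)] = specific.StageGeneSets(
                sp, comp,
                {st: {g2o[g] for g in s if g in g2o} for st, s in sets.sets.items()},
            )

    target = cfg.target_species
    # the comparison runs on the shared reference-stage grid: stage index i of
    # each species is compared with stage index i of the others
    def stage_at(sp: str, comp: str, idx: int) -> str | None:
        keys = list(group_sets[(sp, comp)].sets)
        return keys[idx] if idx < len(keys) else None

    n_stages = len(group_sets[(target, "GC")].sets)
    overlap_pct = {}
    for comp in ("GC", "TC"):
        for idx in range(n_stages):
            per_species = {}
            for sp in cfg.species:
                st = stage_at(sp, comp, idx)
                if st is not None:
                    per_species[sp] = group_sets[(sp, comp)].sets[st]
            if len(per_species) >= 2:
                overlap_pct[f"{comp}|stage{idx}"] = specific.homology_overlap(
                    {sp: s for sp, s in per_species.items()}, _identity_table(per_species)
                )

    # enrichment of the differentiation-stage GC markers, per species
    diff_idx = 1 if n_stages > 1 else 0
    enr = {}
    for sp in cfg.species:
        st = stage_at(sp, "GC", diff_idx)
        query = group_sets[(sp, "GC")].sets.get(st, set()) & background
        enr[sp] = specific.go_enrich(query, ann, background) if query else []
    specific_bps, pct_specific = specific.species_specific_bps(enr, target, alpha=cfg.padj_alpha)
    ranked_terms = [r.term for r in enr[target] if r.term in specific_bps]
    top_bps = ranked_terms[: cfg.top_k_bps]

    tc_st = stage_at(target, "TC", diff_idx)
    tc_query = group_sets[(target, "TC")].sets.get(tc_st, set()) & background
    tc_enr = specific.go_enrich(tc_query, ann, background) if tc_query else []
    tc_sig = {r.term for r in tc_enr if r.padj <= cfg.padj_alpha}
    gc_only = set(top_bps) - tc_sig
    overlap_p = specific.bp_overlap_test(set(top_bps), tc_sig, set(ann)) if top_bps else 1.0

    spgs = specific.extract_spgs(
        top_bps, gc_only, ann, group_sets[(target, "GC")], group_sets[(target, "TC")]
    )
    return {
        "markers": markers,
        "group_sets": group_sets,
        "enrichments": enr,
        "specific_bps": sorted(specific_bps),
        "pct_specific": pct_specific,
        "top_bps": top_bps,
        "bp_overlap_p": overlap_p,
        "spgs": spgs,
        "homology_overlap_pct": overlap_pct,
    }


def _identity_table(per_species: dict[str, set[str]]) -> expression.OrthologTable:
    """Sets already on group IDs: identity ortholog table over their union."""
    union = sorted(set().union(*per_species.values()))
    return expression.OrthologTable(
        pd.DataFrame({sp: union for sp in per_species}, index=pd.Index(union, name="group_id"))
    )


def stage_superenh(cfg: PipelineConfig) -> dict:
    cfg.require("peaks", "signal", "tss")
    peaks = superenh.read_narrowpeak(cfg.paths["peaks"])
    signal = superenh.read_bedgraph(cfg.paths["signal"])
    tss = superenh.read_bed(cfg.paths["tss"])
    regions = superenh.stitch(peaks, cfg.stitch, tss, cfg.tss_excl)
    superenh.rank_regions(regions, signal)
    superenh.assign_genes(regions, tss, cfg.assign_window)
    return {"peaks": peaks, "tss": tss, "regions": regions}


def stage_crc(cfg: PipelineConfig, regions, peaks, expressed_tfs: set[str] | None = None) -> dict:
    cfg.require("pwms", "genome")
    pwms = crc.read_pwms(cfg.paths["pwms"])
    genome = read_fasta(cfg.paths["genome"])
    peak_by_name = {p.name: p for p in peaks}
    se_sequences: dict[str, list[str]] = {}
    for r in regions:
        if not r.is_super:
            continue
        seqs = [
            genome[r.chrom][peak_by_name[c].start : peak_by_name[c].end]
            for c in r.constituents
        ]
        for gene in r.genes:
            if gene in pwms:
                se_sequences.setdefault(gene, []).extend(seqs)
    candidates = sorted(se_sequences)
    if expressed_tfs is not None:
        candidates = [t for t in candidates if t in expressed_tfs]
    network = crc.build_network(se_sequences, pwms, candidates, cfg.motif_threshold)
    crc.analyze_network(network, cfg.hub_sd_multiplier)
    return {"network": network}


def stage_conserv(cfg: PipelineConfig) -> dict:
    cfg.require("alignment", "regions")
    blocks = conserv.AlignmentBlockSet.read_maf(
        cfg.paths["alignment"], reference=cfg.paths.get("maf_reference", "galGal")
    )
    regions = superenh.read_bed(cfg.paths["regions"])
    clade = set(cfg.clade)
    verdicts = {}
    fractions = {}
    for r in regions:
        hs = conserv.extract_homolog(blocks, (r.chrom, r.start, r.end))
        frac = conserv.gap_fraction(hs)
        key = f"{r.chrom}:{r.start}-{r.end}"
        fractions[key] = frac
        verdicts[key] = conserv.clade_specificity(frac, clade, blocks.reference, cfg.max_gap)
    return {"blocks": blocks, "verdicts": verdicts, "gap_fractions": fractions}


def run_all(cfg: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the JSON report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"seed": cfg.seed}}
    truth = None
    if "truth" in cfg.paths and Path(cfg.paths["truth"]).exists():
        truth = synth.SyntheticTruth.from_json(cfg.paths["truth"])

    log.info("stage 1/6: expression integration")
    ex = stage_expression(cfg)
    report["expression"] = {"n_homologous_expressed": ex["n_homologous_expressed"]}
    expression.zscore_rows(ex["corrected"].log2()).to_csv(outdir / "zscores.tsv", sep="\t")

    log.info("stage 2/6: stage alignment")
    warps = stage_alignment(cfg, ex["corrected"])
    report["stagealign"] = {
        key: {"best_match": w.best_match, "total_cost": w.total_cost}
        for key, w in warps.items()
    }
    if truth is not None and truth.planted_stage_map:
        correct = total = 0
        ref_map = truth.planted_stage_map[cfg.reference_species]
        for key, w in warps.items():
            sp = key.split("|")[0]
            for qstage, rstage in w.best_match.items():
                total += 1
                correct += int(truth.planted_stage_map[sp][qstage] == ref_map[rstage])
        report["stagealign"]["recovery_accuracy"] = correct / total if total else 0.0

    log.info("stage 3/6: species-specific genes")
    sp_out = stage_specific(cfg, ex["es_list"], ex["table"])
    report["specific"] = {
        "n_spgs": len(sp_out["spgs"]),
        "spgs": sorted(sp_out["spgs"]),
        "pct_specific_bps": sp_out["pct_specific"],
        "top_bps": sp_out["top_bps"],
        "bp_overlap_p": sp_out["bp_overlap_p"],
        "homology_overlap_pct": sp_out["homology_overlap_pct"],
    }
    if truth is not None and truth.planted_specific_genes:
        expected = set(truth.planted_specific_genes["expected_spgs"])
        report["specific"]["recovery"] = _f1_sets(sp_out["spgs"], expected)
        overlap = set(truth.planted_specific_genes["tc_overlap_groups"])
        report["specific"]["tc_overlap_excluded"] = not (overlap & sp_out["spgs"])

    log.info("stage 4/6: super-enhancers")
    se_out = stage_superenh(cfg)
    called = [r for r in se_out["regions"] if r.is_super]
    report["superenh"] = {
        "n_regions": len(se_out["regions"]),
        "n_super": len(called),
    }
    superenh.regions_to_frame(se_out["regions"]).to_csv(outdir / "stitched_regions.tsv", sep="\t", index=False)
    if truth is not None and truth.planted_se_regions:
        truth_iv = {(t["chrom"], t["start"], t["end"]) for t in truth.planted_se_regions}
        called_iv = {(r.chrom, r.start, r.end) for r in called}
        report["superenh"]["recovery"] = _f1_sets(called_iv, truth_iv)

    log.info("stage 5/6: core regulatory circuitry")
    crc_out = stage_crc(cfg, se_out["regions"], se_out["peaks"])
    net = crc_out["network"]
    report["crc"] = {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "hubs": sorted(net.hubs),
        "circuits": [sorted(c) for c in net.circuits],
        "closeness_out": {k: round(v, 6) for k, v in sorted(net.closeness_out.items())},
    }
    if truth is not None and truth.planted_network:
        tn = truth.planted_network
        truth_edges = {tuple(e) for e in tn["edges"]}
        report["crc"]["recovery"] = {
            "edges_exact": net.edges == truth_edges,
            "hub_recovered": tn["hub"] in net.hubs,
            "hub_top_out_closeness": (
                max(net.closeness_out, key=lambda v: (net.closeness_out[v], v)) == tn["hub"]
                if net.closeness_out else False
            ),
            "circuits_exact": [sorted(c) for c in net.circuits] == tn["circuits"],
        }

    log.info("stage 6/6: conservation")
    co_out = stage_conserv(cfg)
    report["conserv"] = {"verdicts": co_out["verdicts"]}
    if truth is not None and truth.planted_clade_conserved:
        planted = truth.planted_clade_conserved.get("intervals", {})
        match = [
            co_out["verdicts"].get(key) == val["verdict"] for key, val in planted.items()
        ]
        report["conserv"]["recovery_accuracy"] = (
            sum(match) / len(match) if match else float("nan")
        )

    # gene-set statistics: are the recovered SPGs coherently up-regulated
    # across the target species' differentiation-stage GC samples?
    target_sets = sp_out["markers"][(cfg.target_species, "GC")]
    stages_seen = list(target_sets.tables)
    if len(stages_seen) > 1 and sp_out["spgs"]:
        tab = target_sets.tables[stages_seen[1]]
        g2o = ex["table"].gene_to_group(cfg.target_species)
        ranked = tab.sort_values("log2fc", ascending=False)
        genes_ranked = [g2o.get(g, g) for g in ranked.index]
        gres = stats.gsea_p(
            genes_ranked,
            ranked["log2fc"].values,
            set(sp_out["spgs"]),
            n_perm=cfg.gsea_nperm,
            seed=cfg.seed,
        )
        report["stats"] = {"gsea_es": gres.es, "gsea_p": gres.p, "direction": gres.direction}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report


def demo(workdir, seed: int = 0) -> dict:
    """Generate the bundled fixture and run the full pipeline on it."""
    workdir = Path(workdir)
    bundle = synth.write_fixture_bundle(workdir / "fixture", seed=seed)
    paths = dict(bundle["paths"])
    # conservation query regions: the planted intervals are the fixture's
    # region list (an input, like the SE BED in a real run)
    regions_bed = workdir / "fixture" / "regions.bed"
    planted = bundle["truth"].planted_clade_conserved["intervals"]
    with open(regions_bed, "w") as fh:
        for key in planted:
            chrom, span = key.split(":")
            start, end = span.split("-")
            fh.write(f"{chrom}\t{start}\t{end}\tregion\n")
    paths["regions"] = str(regions_bed)
    cfg = PipelineConfig(
        paths=paths,
        clade=bundle["truth"].planted_clade_conserved["clade"],
        seed=seed,
        outdir=str(workdir / "out"),
    )
    cfg.to_yaml(workdir / "config.yaml")
    return run_all(cfg)
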