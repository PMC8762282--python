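"""Clade specificity of genomic regions from multiple-alignment blocks.

Chicken super-enhancer intervals are looked up in a MAF multiple alignment
(chicken as reference); per species the gap fraction of the homologous slice
measures conservation, ungapped slices feed the motif binding profile, and a
gap-fraction threshold turns per-species fractions into a clade-specificity
verdict ("clade-specific", "shared" or "not-conserved").

Reference bases not covered by any alignment block count as gap columns for
every non-reference species: absence of alignment is treated as deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

from .crc import PWM, revcomp, scan_motifs

GAP = "-"
DEFAULT_MAX_GAP = 0.5


@dataclass
class MafRow:
    species: str
    chrom: str
    start: int  # 0-based on source, strand-relative per MAF
    size: int
    strand: str
    src_size: int
    text: str


@dataclass
class AlignmentBlock:
    rows: dict[str, MafRow]

    def __post_init__(self) -> None:
        lengths = {len(r.text) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("rows in a block must have equal aligned length")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())).text)


@dataclass
class AlignmentBlockSet:
    """Ordered MAF blocks with a designated reference species."""

    blocks: list[AlignmentBlock]
    reference: str
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            seen: list[str] = []
            for b in self.blocks:
                for sp in b.rows:
                    if sp not in seen:
                        seen.append(sp)
            self.species = seen
        for b in self.blocks:
            ref = b.rows.get(self.reference)
            if ref is None:
                raise ValueError("every block needs a reference row")
            if set(ref.text) == {GAP}:
                raise ValueError("reference row may not be all gaps")

    @classmethod
    def read_maf(cls, path, reference: str) -> "AlignmentBlockSet":
        blocks = []
        for aln in AlignIO.parse(str(path), "maf"):
            rows: dict[str, MafRow] = {}
            for rec in aln:
                sp, _, chrom = rec.id.partition(".")
                ann = rec.annotations
                rows[sp] = MafRow(
                    species=sp,
                    chrom=chrom,
                    start=int(ann.get("start", 0)),
                    size=int(ann.get("size", 0)),
                    strand="+" if ann.get("strand", 1) in (1, "+") else "-",
                    src_size=int(ann.get("srcSize", 0)),
                    text=str(rec.seq),
                )
            block = AlignmentBlock(rows)
            ref = rows.get(reference)
            if ref is not None and ref.strand == "-":
                block = _flip_block(block)
            blocks.append(block)
        return cls(blocks, reference)

    def write_maf(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##maf version=1\n")
            for b in self.blocks:
                fh.write("a\n")
                for sp in self.species:
                    r = b.rows.get(sp)
                    if r is None:
                        continue
                    fh.write(
                        f"s {r.species}.{r.chrom} {r.start} {r.size} "
                        f"{r.strand} {r.src_size} {r.text}\n"
                    )
                fh.write("\n")


def _flip_block(block: AlignmentBlock) -> AlignmentBlock:
    """Reverse-complement a whole block so the reference row reads + strand."""
    rows = {}
    for sp, r in block.rows.items():
        rows[sp] = MafRow(
            species=sp,
            chrom=r.chrom,
            start=r.src_size - r.start - r.size if r.src_size else r.start,
            size=r.size,
            strand="+" if r.strand == "-" else "-",
            src_size=r.src_size,
            text=revcomp(r.text.replace(GAP, "\0")).replace("\0", GAP),
        )
    return AlignmentBlock(rows)


@dataclass
class HomologSlice:
    """Alignment columns of one reference interval, per species."""

    interval: tuple[str, int, int]
    aligned: dict[str, str]
    species: list[str]

    def ungapped(self, species: str) -> str:
        return self.aligned[species].replace(GAP, "").replace("N", "")


def extract_homolog(
    blocks: AlignmentBlockSet, ref_interval: tuple[str, int, int]
) -> HomologSlice:
    """Slice alignment columns whose reference position falls in an interval.

    Columns are concatenated across blocks in reference order; species
    missing from a block are filled with gaps; reference bases covered by no
    block produce a column with ``N`` on the reference row and gaps
    elsewhere.
    """
    chrom, start, end = ref_interval
    species = blocks.species
    pieces: dict[str, list[str]] = {sp: [] for sp in species}
    covered: list[tuple[int, int]] = []

    ordered = sorted(
        (b for b in blocks.blocks if b.rows[blocks.reference].chrom == chrom),
        key=lambda b: b.rows[blocks.reference].start,
    )
    for b in ordered:
        ref = b.rows[blocks.reference]
        if ref.start >= end or ref.start + ref.size <= start:
            continue
        # keep columns carrying a reference base inside the interval; columns
        # where the reference is gapped (insertions in other species) have no
        # reference position and are dropped
        keep = []
        pos = ref.start
        for col, ch in enumerate(ref.text):
            if ch != GAP:
                if start <= pos < end:
                    keep.append(col)
                pos += 1
        if not keep:
            continue
        covered.append((max(ref.start, start), min(ref.start + ref.size, end)))
        for sp in species:
            row = b.rows.get(sp)
            text = row.text if row is not None else GAP * b.width
            pieces[sp].append("".join(text[c] for c in keep))

    if not covered:
        warnings.warn("interval overlaps no alignment block", stacklevel=2)
        return HomologSlice((chrom, start, end), {sp: "" for sp in species}, species)

    n_uncovered = (end - start) - sum(e - s for s, e in covered)
    if n_uncovered > 0:
        for sp in species:
            filler = "N" * n_uncovered if sp == blocks.reference else GAP * n_uncovered
            pieces[sp].append(filler)
    aligned = {sp: "".join(parts) for sp, parts in pieces.items()}
    return HomologSlice((chrom, start, end), aligned, species)


def gap_fraction(hslice: HomologSlice) -> pd.Series:
    """Per-species fraction of gap columns in a homologous slice."""
    out = {}
    for sp in hslice.species:
        text = hslice.aligned[sp]
        if not text:
            out[sp] = float("nan")
            continue
        out[sp] = text.count(GAP) / len(text)
    return pd.Series(out, name="gap_fraction")


def binding_profile(
    hslices: dict[str, HomologSlice] | HomologSlice,
    pwms: dict[str, PWM],
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Species x TF matrix of motif hit counts on ungapped homologous
    sequence."""
    if isinstance(hslices, HomologSlice):
        hslices = {"region": hslices}
    first = next(iter(hslices.values()))
    counts = pd.DataFrame(0, index=first.species, columns=sorted(pwms), dtype=int)
    for hs in hslices.values():
        for sp in hs.species:
            seq = hs.ungapped(sp)
            if not seq:
                continue
            for tf, pwm in pwms.items():
                counts.loc[sp, tf] += len(scan_motifs(seq, pwm, threshold))
    return counts


def clade_specificity(
    fractions: pd.Series,
    clade: set[str],
    reference: str,
    max_gap: float = DEFAULT_MAX_GAP,
) -> str:
    """Verdict for one interval from per-species gap fractions.

    ``clade-specific``: every clade member at or below ``max_gap`` and every
    non-member (reference aside) above it; ``not-conserved``: no species but
    the reference at or below ``max_gap``; ``shared`` otherwise.
    """
    if not clade <= set(fractions.index):
        raise ValueError("clade must be a subset of the species list")
    members = {sp for sp in fractions.index if sp in clade and sp != reference}
    others = {sp for sp in fractions.index if sp not in clade and sp != reference}
    in_ok = all(fractions[sp] <= max_gap for sp in members)
    out_all_gap = all(fractions[sp] > max_gap for sp in others)
    conserved_any = any(
        fractions[sp] <= max_gap for sp in fractions.index if sp != reference
    )
    if in_ok and out_all_gap and members:
        return "clade-specific"
    if not conserved_any:
        return "not-conserved"
    return "shared"
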