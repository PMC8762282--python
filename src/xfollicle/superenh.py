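"""ROSE-style super-enhancer calling.

H3K27ac peaks are stitched within a fixed genomic distance (after discarding
peaks inside a TSS exclusion zone), each stitched region is scored by its
background-subtracted signal area, regions are ranked, and the hockey-stick
cutoff — the first point where the min-max-scaled rank/signal curve has a
discrete slope above 1 — separates super-enhancers from typical enhancers.
Genes are assigned to regions by TSS proximity.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_STITCH = 12_500
DEFAULT_TSS_EXCL = 2_500
DEFAULT_ASSIGN_WINDOW = 50_000


@dataclass
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class StitchedRegion:
    """A stitched enhancer region with its rank and SE flag."""

    chrom: str
    start: int
    end: int
    constituents: list[str] = field(default_factory=list)
    signal: float = 0.0
    rank: int = -1
    is_super: bool = False
    genes: list[str] = field(default_factory=list)


def read_narrowpeak(path) -> list[Interval]:
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else f"peak_{i}"
            peaks.append(Interval(f[0], int(f[1]), int(f[2]), name))
    return peaks


def read_bed(path) -> list[Interval]:
    return read_narrowpeak(path)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    for chrom, grp in df.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["end"].values[:-1] > g["start"].values[1:]).any():
            raise ValueError(f"overlapping bedGraph intervals on {chrom}")
    return df


def stitch(
    peaks: list[Interval],
    stitch_dist: int = DEFAULT_STITCH,
    tss: list[Interval] | None = None,
    tss_excl: int = DEFAULT_TSS_EXCL,
) -> list[StitchedRegion]:
    """Merge peaks whose gap is <= ``stitch_dist`` on the same chromosome.

    Peaks lying entirely inside any TSS +/- ``tss_excl`` window are removed
    before stitching. Output regions are sorted by (chrom, start).
    """
    kept = peaks
    if tss:
        zones: dict[str, list[tuple[int, int]]] = {}
        for t in tss:
            zones.setdefault(t.chrom, []).append((t.start - tss_excl, t.end + tss_excl))
        kept = [
            p for p in peaks
            if not any(z0 <= p.start and p.end <= z1 for z0, z1 in zones.get(p.chrom, []))
        ]
    regions: list[StitchedRegion] = []
    for chrom in sorted({p.chrom for p in kept}):
        chrom_peaks = sorted((p for p in kept if p.chrom == chrom), key=lambda p: p.start)
        current: StitchedRegion | None = None
        for p in chrom_peaks:
            if current is not None and p.start - current.end <= stitch_dist:
                current.end = max(current.end, p.end)
                current.constituents.append(p.name)
            else:
                current = StitchedRegion(chrom, p.start, p.end, [p.name])
                regions.append(current)
    return regions


def region_signal(
    region: StitchedRegion | Interval,
    signal: pd.DataFrame,
    control: pd.DataFrame | None = None,
) -> float:
    """Background-subtracted signal area over a region, floored at 0.

    ``signal`` / ``control`` are bedGraph frames; coverage is summed as
    value x overlap-length, the control (when given) subtracted base-wise,
    and the final area floored at 0. Bases without coverage count 0.
    """

    def area(track: pd.DataFrame) -> float:
        sub = track[track["chrom"] == region.chrom]
        ov = np.minimum(sub["end"], region.end) - np.maximum(sub["start"], region.start)
        return float((sub["value"] * ov.clip(lower=0)).sum())

    total = area(signal) - (area(control) if control is not None else 0.0)
    return max(total, 0.0)


def hockey_stick_cutoff(signals) -> tuple[float, np.ndarray]:
    """Signal threshold at the hockey-stick elbow and per-region SE flags.

    Signals are sorted ascending; ranks and signals are min-max scaled to
    [0, 1]; the threshold is the (unscaled) signal at the left end of the
    first inter-rank segment whose slope strictly exceeds 1. Regions with
    signal strictly above the threshold are flagged super. When every signal
    is equal, or no segment exceeds slope 1, no region is flagged.

    Returns ``(threshold, flags)`` with flags in the input order; the
    threshold is NaN when nothing is flagged.
    """
    s = np.asarray(signals, dtype=float)
    if s.size < 3:
        raise ValueError("need >= 3 regions")
    order = np.argsort(s, kind="stable")
    ss = s[order]
    if ss[0] == ss[-1]:
        return float("nan"), np.zeros(s.size, dtype=bool)
    x = np.arange(s.size) / (s.size - 1)
    y = (ss - ss[0]) / (ss[-1] - ss[0])
    slopes = np.diff(y) / np.diff(x)
    crossing = np.nonzero(slopes > 1.0)[0]
    if crossing.size == 0:
        return float("nan"), np.zeros(s.size, dtype=bool)
    threshold = float(ss[crossing[0]])
    return threshold, s > threshold


def rank_regions(
    regions: list[StitchedRegion],
    signal: pd.DataFrame,
    control: pd.DataFrame | None = None,
) -> list[StitchedRegion]:
    """Score, rank (1 = strongest) and SE-flag stitched regions in place."""
    for r in regions:
        r.signal = region_signal(r, signal, control)
    sig = np.array([r.signal for r in regions])
    order = np.argsort(-sig, kind="stable")
    for rank, idx in enumerate(order, start=1):
        regions[idx].rank = rank
    _, flags = hockey_stick_cutoff(sig)
    for r, f in zip(regions, flags):
        r.is_super = bool(f)
    return regions


def assign_genes(
    regions: list[StitchedRegion],
    tss: list[Interval],
    window: int = DEFAULT_ASSIGN_WINDOW,
) -> dict[str, list[str]]:
    """Map each region to genes whose TSS lies within region +/- window."""
    out: dict[str, list[str]] = {}
    for r in regions:
        key = f"{r.chrom}:{r.start}-{r.end}"
        genes = sorted(
            {
                t.name
                for t in tss
                if t.chrom == r.chrom
                and t.start < r.end + window
                and t.end > r.start - window
            }
        )
        r.genes = genes
        out[key] = genes
    return out


def regions_to_frame(regions: list[StitchedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_constituents": [len(r.constituents) for r in regions],
            "signal": [r.signal for r in regions],
            "rank": [r.rank for r in regions],
            "is_super": [r.is_super for r in regions],
            "genes": [",".join(r.genes) for r in regions],
        }
    )
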