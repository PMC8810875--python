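"""Basal-plus-extension assignment of peaks to candidate target genes.

Each gene gets a strand-aware basal regulatory domain around its TSS
(default 5 kb upstream / 1 kb downstream) which is then extended in both
directions up to 1 Mb, stopping early at the nearest neighbouring gene's
basal domain. A peak is assigned to every gene whose extended domain it
touches, and reported with its signed distance to the TSS (negative =
upstream in gene orientation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, PeakSet


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass
class RegulatoryDomain:
    gene_id: str
    strand: str
    tss: int
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        b, e = self.basal, self.extended
        if b.chrom != e.chrom or e.start > b.start or e.end < b.end:
            raise ValueError("basal domain must be contained in extended domain")


def build_domains(
    genes: Sequence[GeneModel],
    up: int = 5000,
    down: int = 1000,
    max_ext: int = 1_000_000,
    genome: Mapping[str, int] | None = None,
    curated: Mapping[str, tuple[int, int]] | None = None,
) -> list[RegulatoryDomain]:
    """Construct basal-plus-extension regulatory domains.

    Basal: ``[tss-up, tss+down)`` on the + strand, mirrored on −, clipped to
    the chromosome. Extension proceeds independently per side to the nearest
    neighbouring basal edge or by ``max_ext``, whichever is closer; basal
    domains may overlap, in which case extension on that side is nil.
    ``curated`` optionally widens a gene's extended domain to a user-supplied
    ``(start, end)`` span (merged with the computed one).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    domains: list[RegulatoryDomain] = []
    for chrom, glist in by_chrom.items():
        glist = sorted(glist, key=lambda g: g.tss)
        chrom_len = genome.get(chrom) if genome else None
        basals = []
        for g in glist:
            if g.strand == "+":
                s, e = g.tss - up, g.tss + down
            else:
                s, e = g.tss - down, g.tss + up
            s = max(0, s)
            if chrom_len is not None:
                e = min(e, chrom_len)
            basals.append((s, max(e, s + 1)))
        for i, g in enumerate(glist):
            bs, be = basals[i]
            left_bound = 0
            right_bound = chrom_len if chrom_len is not None else None
            for j, (os_, oe) in enumerate(basals):
                if j == i:
                    continue
                if os_ < bs:  # a neighbour starting to our left constrains us
                    left_bound = max(left_bound, min(oe, bs))
                if oe > be:  # a neighbour ending to our right constrains us
                    rb = max(os_, be)
                    right_bound = rb if right_bound is None else min(right_bound, rb)
            ext_s = max(bs - max_ext, left_bound)
            ext_e = be + max_ext
            if right_bound is not None:
                ext_e = min(ext_e, right_bound)
            if curated and g.gene_id in curated:
                cs, ce = curated[g.gene_id]
                ext_s, ext_e = min(ext_s, max(cs, 0)), max(ext_e, ce)
                if chrom_len is not None:
                    ext_e = min(ext_e, chrom_len)
            domains.append(
                RegulatoryDomain(
                    gene_id=g.gene_id,
                    strand=g.strand,
                    tss=g.tss,
                    basal=GenomicInterval(chrom, bs, be, name=g.gene_id),
                    extended=GenomicInterval(chrom, ext_s, ext_e, name=g.gene_id),
                )
            )
    domains.sort(key=lambda d: (d.extended.chrom, d.extended.start))
    return domains


def _anchor_pos(peak, anchor: str) -> int:
    iv = peak.interval
    if anchor == "midpoint":
        return iv.midpoint
    if anchor == "summit":
        if peak.summit_offset is None:
            return iv.midpoint
        return iv.start + peak.summit_offset
    raise ValueError(f"unknown distance anchor {anchor!r}")


def assign_genes(
    peaks: PeakSet,
    domains: Sequence[RegulatoryDomain],
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Assign each peak to every gene whose extended domain it overlaps.

    Returns one row per (peak, gene); peaks hitting no domain appear once
    with a missing ``gene_id``. ``distance_to_tss`` is measured from the
    peak's ``anchor`` point (midpoint by default, or summit) and is negative
    when the peak lies upstream of the TSS in the gene's orientation.
    """
    dom_by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        dom_by_chrom.setdefault(d.extended.chrom, []).append(d)
    rows = []
    for i, p in enumerate(peaks):
        iv = p.interval
        name = iv.name or f"peak_{i}"
        hits = [
            d
            for d in dom_by_chrom.get(iv.chrom, [])
            if d.extended.start < iv.end and d.extended.end > iv.start
        ]
        if not hits:
            rows.append(
                {
                    "peak": name,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "gene_id": pd.NA,
                    "distance_to_tss": pd.NA,
                }
            )
            continue
        pos = _anchor_pos(p, anchor)
        for d in hits:
            dist = pos - d.tss
            if d.strand == "-":
                dist = -dist
            rows.append(
                {
                    "peak": name,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "gene_id": d.gene_id,
                    "distance_to_tss": dist,
                }
            )
    return pd.DataFrame(
        rows, columns=["peak", "chrom", "start", "end", "gene_id", "distance_to_tss"]
    )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (TSS = start of the 1-bp interval, or the
    strand-appropriate end of a wider interval)."""
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: BED6 with strand required")
        chrom, start, end, name, _, strand = parts[:6]
        start, end = int(start), int(end)
        tss = start if strand == "+" else end - 1
        genes.append(GeneModel(gene_id=name, chrom=chrom, tss=tss, strand=strand))
    return sorted(genes, key=lambda g: (g.chrom, g.tss))
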