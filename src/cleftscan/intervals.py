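"""Genomic interval data model, BED I/O and the replicate-intersection rule.

All coordinates are 0-based half-open (BED convention). The central product of
this module is the set of *high-confidence peaks* (hc-peaks): regions of a
ChIP-seq replicate that are supported by the second replicate, emitted as the
base-pair intersection of the two replicates' peak calls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: Chromosomes considered "regular" by default (human autosomes + sex chroms).
DEFAULT_ALLOWED_CHROMS = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 for different chromosomes.

    Half-open semantics: abutting intervals share nothing.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class Peak:
    """A scored ChIP-seq peak call.

    ``fold_enrichment`` and ``fdr_q`` are ``None`` for plain BED records that
    carry no peak-caller statistics (e.g. reference region sets).
    """

    interval: GenomicInterval
    fold_enrichment: float | None = None
    fdr_q: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.fold_enrichment is not None and self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be > 0")
        if self.fdr_q is not None and not (0.0 <= self.fdr_q <= 1.0):
            raise ValueError("fdr_q must lie in [0, 1]")

    @property
    def name(self) -> str | None:
        return self.interval.name


class PeakSet:
    """An ordered collection of peaks from one replicate or reference source.

    Peaks are kept sorted by ``(chrom, start, end)``.  If ``genome`` (a
    chromosome → length mapping) is supplied, peaks must fit inside their
    chromosome.
    """

    def __init__(
        self,
        peaks: Iterable[Peak],
        source_label: str = "",
        genome: Mapping[str, int] | None = None,
    ) -> None:
        self.source_label = source_label
        self.genome = dict(genome) if genome is not None else None
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        if self.genome is not None:
            for p in self.peaks:
                size = self.genome.get(p.interval.chrom)
                if size is not None and p.interval.end > size:
                    raise ValueError(
                        f"peak {p.interval} exceeds chromosome length {size}"
                    )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def chroms(self) -> list[str]:
        return sorted({p.interval.chrom for p in self.peaks})

    def total_bp(self) -> int:
        """Total covered base pairs (union, overlaps counted once)."""
        return GenomeCover(self.intervals).total_bp()

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for chrom, grp in itertools.groupby(self.peaks, key=lambda p: p.interval.chrom):
            out[chrom] = list(grp)
        return out


class GenomeCover:
    """Merged per-chromosome interval cover with vectorised coverage queries.

    Touching or overlapping intervals are merged, so ``covered_bp`` counts each
    genomic base at most once — the primitive behind every overlap rule.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._cover: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, spans in per_chrom.items():
            spans.sort()
            merged_s: list[int] = []
            merged_e: list[int] = []
            for s, e in spans:
                if merged_e and s <= merged_e[-1]:
                    if e > merged_e[-1]:
                        merged_e[-1] = e
                else:
                    merged_s.append(s)
                    merged_e.append(e)
            starts = np.asarray(merged_s, dtype=np.int64)
            ends = np.asarray(merged_e, dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self._cover[chrom] = (starts, ends, cum)

    def merged(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        starts, ends, _ = self._cover.get(
            chrom, (np.empty(0, np.int64), np.empty(0, np.int64), np.zeros(1))
        )
        return starts, ends

    def total_bp(self) -> int:
        return int(sum(c[2][-1] for c in self._cover.values()))

    def _cumulative(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Covered bases in [0, pos) for each query position."""
        if chrom not in self._cover:
            return np.zeros(len(pos), dtype=np.int64)
        starts, ends, cum = self._cover[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, None)
        partial = np.clip(pos - starts[idx_c], 0, ends[idx_c] - starts[idx_c])
        out = cum[idx_c] + partial
        out[idx < 0] = 0
        return out

    def covered_bp(
        self, chrom: str, starts: np.ndarray | Sequence[int], ends: np.ndarray | Sequence[int]
    ) -> np.ndarray:
        """Bases of each query ``[start, end)`` covered by the merged set."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return self._cumulative(chrom, ends) - self._cumulative(chrom, starts)

    def covered_bp_interval(self, iv: GenomicInterval) -> int:
        return int(self.covered_bp(iv.chrom, [iv.start], [iv.end])[0])


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def read_genome(path: str | Path) -> dict[str, int]:
    """Read a bedtools-style two-column chromosome-size file."""
    genome: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
        genome[parts[0]] = int(parts[1])
    return genome


def read_bed(
    path: str | Path,
    dialect: str = "bed6",
    source_label: str | None = None,
    genome: Mapping[str, int] | None = None,
) -> PeakSet:
    """Read a BED3/BED6/ENCODE-narrowPeak file into a sorted :class:`PeakSet`.

    The narrowPeak dialect populates ``fold_enrichment`` from the signalValue
    column, ``fdr_q`` from the −log10(q) column and ``summit_offset`` from the
    summit column (``-1`` → missing).  An empty file yields an empty set.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    ncol = _DIALECT_COLUMNS[dialect]
    peaks: list[Peak] = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < ncol:
            raise ValueError(
                f"{path}:{lineno}: expected >= {ncol} columns for {dialect}, "
                f"got {len(parts)}"
            )
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
        name = parts[3] if ncol >= 6 and parts[3] != "." else None
        score = None
        if ncol >= 6 and parts[4] not in (".", ""):
            score = float(parts[4])
        iv = GenomicInterval(chrom, start, end, name=name, score=score)
        if dialect == "narrowPeak":
            fe = float(parts[6])
            neglog_q = float(parts[8])
            fdr_q = None if neglog_q < 0 else min(1.0, 10.0 ** (-neglog_q))
            summit = int(parts[9])
            peaks.append(
                Peak(
                    iv,
                    fold_enrichment=fe if fe > 0 else None,
                    fdr_q=fdr_q,
                    summit_offset=None if summit < 0 else summit,
                )
            )
        else:
            peaks.append(Peak(iv))
    return PeakSet(peaks, source_label=source_label or path.stem, genome=genome)


def write_bed(ps: PeakSet, path: str | Path, dialect: str = "bed6") -> None:
    """Write a peak set as BED; BED6 carries the peak name and score."""
    lines = []
    for i, p in enumerate(ps):
        iv = p.interval
        if dialect == "bed3":
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}")
        elif dialect == "bed6":
            name = iv.name if iv.name is not None else f"peak_{i}"
            score = iv.score if iv.score is not None else 0
            score_s = f"{score:g}"
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score_s}\t.")
        elif dialect == "narrowPeak":
            name = iv.name if iv.name is not None else f"peak_{i}"
            score = iv.score if iv.score is not None else 0
            fe = p.fold_enrichment if p.fold_enrichment is not None else 0
            q = -np.log10(p.fdr_q) if p.fdr_q else -1
            summit = p.summit_offset if p.summit_offset is not None else -1
            lines.append(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t.\t"
                f"{fe:g}\t-1\t{q:g}\t{summit}"
            )
        else:
            raise ValueError(f"unknown BED dialect {dialect!r}")
    Path(path).write_text("".join(l + "\n" for l in lines))


# ---------------------------------------------------------------------------
# Filtering and the high-confidence intersection rule
# ---------------------------------------------------------------------------


def filter_peaks(
    ps: PeakSet,
    fe_min: float = 5.0,
    fe_max: float = 50.0,
    fdr_max: float = 0.05,
    blacklist: PeakSet | None = None,
    allowed_chroms: Iterable[str] | None = DEFAULT_ALLOWED_CHROMS,
) -> PeakSet:
    """Apply peak-level quality control.

    Retains peaks with ``fe_min <= FE <= fe_max`` (inclusive bounds),
    ``fdr_q < fdr_max`` (strict), chromosome in the allowed set, and zero
    base-pair overlap with the blacklist.  Peaks lacking a fold-enrichment or
    q-value are removed when the corresponding bound applies.
    """
    if fe_min > fe_max:
        raise ValueError("fe_min must not exceed fe_max")
    allowed = set(allowed_chroms) if allowed_chroms is not None else None
    bl_cover = GenomeCover(blacklist.intervals) if blacklist is not None else None
    kept: list[Peak] = []
    for p in ps:
        iv = p.interval
        if allowed is not None and iv.chrom not in allowed:
            continue
        if p.fold_enrichment is None or not (fe_min <= p.fold_enrichment <= fe_max):
            continue
        if p.fdr_q is None or not (p.fdr_q < fdr_max):
            continue
        if bl_cover is not None and bl_cover.covered_bp_interval(iv) > 0:
            continue
        kept.append(p)
    return PeakSet(kept, source_label=ps.source_label, genome=ps.genome)


def derive_hc_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Intersect two replicates' peak calls into high-confidence peaks.

    For every ``rep1`` peak that shares at least one base with ``rep2``, the
    coordinate intersection of that peak with the union of its ``rep2``
    partners is emitted; one ``rep1`` peak spanning several disjoint partners
    yields several hc-peaks.  Abutting emitted regions are merged.  Each
    hc-peak's name records its parent peaks as ``rep1name|rep2name[,...]``,
    and the hc-peak inherits the anchor (``rep1``) peak's statistics.
    """
    rep2_by_chrom = rep2.by_chrom()
    pieces: list[tuple[GenomicInterval, Peak, list[str]]] = []
    for anchor in rep1:
        iv = anchor.interval
        partners = [
            q
            for q in rep2_by_chrom.get(iv.chrom, [])
            if q.interval.start < iv.end and q.interval.end > iv.start
        ]
        if not partners:
            continue
        cover = GenomeCover(q.interval for q in partners)
        starts, ends = cover.merged(iv.chrom)
        for s, e in zip(starts, ends):
            cs, ce = max(s, iv.start), min(e, iv.end)
            if ce > cs:
                names = [
                    q.interval.name or str(q.interval)
                    for q in partners
                    if q.interval.start < ce and q.interval.end > cs
                ]
                pieces.append((GenomicInterval(iv.chrom, cs, ce), anchor, names))

    pieces.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    hc: list[Peak] = []
    for iv, anchor, partner_names in pieces:
        if hc:
            prev = hc[-1].interval
            if prev.chrom == iv.chrom and iv.start <= prev.end:
                # merge touching/overlapping pieces (distinct rep1 parents)
                merged_name = f"{prev.name};{_provenance(anchor, partner_names)}"
                hc[-1] = replace(
                    hc[-1],
                    interval=GenomicInterval(
                        iv.chrom, prev.start, max(prev.end, iv.end), name=merged_name
                    ),
                )
                continue
        hc.append(
            Peak(
                GenomicInterval(
                    iv.chrom,
                    iv.start,
                    iv.end,
                    name=_provenance(anchor, partner_names),
                ),
                fold_enrichment=anchor.fold_enrichment,
                fdr_q=anchor.fdr_q,
            )
        )
    return PeakSet(hc, source_label="hc_peaks", genome=rep1.genome)


def _provenance(anchor: Peak, partner_names: list[str]) -> str:
    a = anchor.interval.name or str(anchor.interval)
    return f"{a}|{','.join(partner_names)}"
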