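"""Allele-specific transcription-factor binding at heterozygous SNPs.

At every heterozygous SNP inside a high-confidence peak, reference/alternative
read counts are pooled across ChIP-seq replicates and tested against a
symmetric Binomial(n, 0.5) with a two-sided exact test; a SNP is called
allele-specifically bound (ASB) when the pooled p-value is below alpha AND the
direction of allelic skew agrees across all informative replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binomtest

from .intervals import PeakSet

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"


@dataclass
class GenotypeRecord:
    """One SNP genotype; ``pos`` is 1-based (VCF convention)."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str
    peak_id: str | None = None  # filled by snps_in_peaks

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.genotype not in (HOM_REF, HET, HOM_ALT, MISSING):
            raise ValueError(f"bad genotype {self.genotype!r}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != 1 or len(self.alt_allele) != 1


@dataclass
class AlleleCountRecord:
    snp_id: str
    replicate_id: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")


@dataclass
class AsbResult:
    snp_id: str
    pooled_ref: int
    pooled_alt: int
    binomial_p: float | None
    direction: str  # 'ref' | 'alt' | 'none'
    replicate_directions: dict[str, str]
    consistent: bool
    is_asb: bool


def snps_in_peaks(
    genotypes: Iterable[GenotypeRecord], peaks: PeakSet
) -> list[GenotypeRecord]:
    """SNPs whose position falls inside a peak, annotated with the peak id.

    VCF positions are 1-based; a SNP at pos p occupies 0-based base p−1, so it
    is inside ``[start, end)`` iff ``start <= p-1 < end``.
    """
    by_chrom = peaks.by_chrom()
    out = []
    for g in genotypes:
        base = g.pos - 1
        for i, p in enumerate(by_chrom.get(g.chrom, [])):
            iv = p.interval
            if iv.start <= base < iv.end:
                g.peak_id = iv.name or str(iv)
                out.append(g)
                break
    return out


def het_filter(
    genotypes: Iterable[GenotypeRecord],
) -> tuple[list[GenotypeRecord], dict[str, int]]:
    """Keep heterozygous SNPs (SNVs only); tally the dropped categories."""
    tally = {HOM_REF: 0, HET: 0, HOM_ALT: 0, MISSING: 0, "indel": 0}
    kept = []
    for g in genotypes:
        if g.is_indel:
            tally["indel"] += 1
            continue
        tally[g.genotype] += 1
        if g.genotype == HET:
            kept.append(g)
    return kept, tally


def _direction(ref: int, alt: int) -> str:
    if ref > alt:
        return "ref"
    if alt > ref:
        return "alt"
    return "none"


def asb_test(
    counts: Sequence[AlleleCountRecord],
    alpha: float = 0.05,
    min_total: int = 10,
    per_replicate: bool = False,
) -> AsbResult:
    """Two-sided exact binomial test of allelic imbalance for one SNP.

    Counts are pooled across replicates and tested against p = 0.5
    (two-sided, minimum-likelihood method: the p-value sums all outcomes with
    point probability <= that of the observed count). Per-replicate skew
    directions must agree (ignoring balanced replicates, with at least one
    informative replicate) for an ASB call. ``min_total`` guards against
    vacuous tests at low depth; 0 disables it. With ``per_replicate=True``
    every replicate must individually reach significance and the reported
    p-value is the largest per-replicate p.
    """
    if not counts:
        raise ValueError("no allele counts supplied")
    snp_id = counts[0].snp_id
    if any(c.snp_id != snp_id for c in counts):
        raise ValueError("asb_test expects counts for a single SNP")
    pooled_ref = sum(c.ref_count for c in counts)
    pooled_alt = sum(c.alt_count for c in counts)
    total = pooled_ref + pooled_alt
    rep_dirs = {c.replicate_id: _direction(c.ref_count, c.alt_count) for c in counts}
    informative = [d for d in rep_dirs.values() if d != "none"]
    consistent = bool(informative) and len(set(informative)) == 1
    if total == 0:
        return AsbResult(
            snp_id, 0, 0, None, "none", rep_dirs, consistent=False, is_asb=False
        )
    if per_replicate:
        ps = [
            binomtest(c.ref_count, c.ref_count + c.alt_count, 0.5).pvalue
            for c in counts
            if c.ref_count + c.alt_count > 0
        ]
        p = max(ps) if ps else None
    else:
        p = binomtest(pooled_ref, total, 0.5).pvalue
    direction = _direction(pooled_ref, pooled_alt)
    is_asb = (
        p is not None
        and p < alpha
        and consistent
        and (min_total == 0 or total >= min_total)
    )
    return AsbResult(
        snp_id=snp_id,
        pooled_ref=pooled_ref,
        pooled_alt=pooled_alt,
        binomial_p=p,
        direction=direction,
        replicate_directions=rep_dirs,
        consistent=consistent,
        is_asb=bool(is_asb),
    )


def asb_scan(
    het_snps: Sequence[GenotypeRecord],
    counts: Iterable[AlleleCountRecord],
    alpha: float = 0.05,
    min_total: int = 10,
    per_replicate: bool = False,
) -> list[AsbResult]:
    """Run :func:`asb_test` for every heterozygous SNP with counts."""
    by_snp: dict[str, list[AlleleCountRecord]] = {}
    for c in counts:
        by_snp.setdefault(c.snp_id, []).append(c)
    results = []
    for g in het_snps:
        if g.snp_id in by_snp:
            results.append(
                asb_test(
                    by_snp[g.snp_id],
                    alpha=alpha,
                    min_total=min_total,
                    per_replicate=per_replicate,
                )
            )
    return results


def asb_report(
    results: Sequence[AsbResult],
    snps: Sequence[GenotypeRecord] | None = None,
    gene_assignments: pd.DataFrame | None = None,
    gwas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabulate ASB calls with peak, target genes and GWAS p when available.

    ``gene_assignments`` is the peak→gene table from the domain-assignment
    stage; ``gwas`` needs columns ``snp`` and ``p``.
    """
    peak_by_snp = {g.snp_id: g.peak_id for g in snps} if snps else {}
    genes_by_peak: dict[str, str] = {}
    if gene_assignments is not None and len(gene_assignments):
        grouped = gene_assignments.dropna(subset=["gene_id"]).groupby("peak")["gene_id"]
        genes_by_peak = {k: ",".join(sorted(set(v))) for k, v in grouped}
    gwas_p = {}
    if gwas is not None and len(gwas):
        gwas_p = dict(zip(gwas["snp"], gwas["p"]))
    rows = []
    for r in results:
        if not r.is_asb:
            continue
        peak = peak_by_snp.get(r.snp_id)
        rows.append(
            {
                "snp_id": r.snp_id,
                "peak": peak,
                "pooled_ref": r.pooled_ref,
                "pooled_alt": r.pooled_alt,
                "binomial_p": r.binomial_p,
                "direction": r.direction,
                "genes": genes_by_peak.get(peak, "") if peak else "",
                "gwas_p": gwas_p.get(r.snp_id, math.nan),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "peak",
            "pooled_ref",
            "pooled_alt",
            "binomial_p",
            "direction",
            "genes",
            "gwas_p",
        ],
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GT_MAP = {(0, 0): HOM_REF, (0, 1): HET, (1, 0): HET, (1, 1): HOM_ALT}


def read_genotypes_vcf(path: str | Path, sample: str | None = None) -> list[GenotypeRecord]:
    """Read genotypes for one sample from an (uncompressed or bgzipped) VCF."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ValueError("VCF has no sample columns")
        target = sample or samples[0]
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            gt = rec.samples[target].get("GT")
            if gt is None or None in gt:
                call = MISSING
            else:
                call = _GT_MAP.get(tuple(gt), MISSING)
            records.append(
                GenotypeRecord(
                    snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    genotype=call,
                )
            )
    return records


def read_genotypes_tsv(path: str | Path) -> list[GenotypeRecord]:
    """6-column TSV: snp_id, chrom, pos, ref, alt, genotype."""
    df = pd.read_csv(path, sep="\t")
    return [
        GenotypeRecord(
            snp_id=str(r.snp_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            genotype=str(r.genotype),
        )
        for r in df.itertuples()
    ]


def read_allele_counts(path: str | Path) -> list[AlleleCountRecord]:
    """TSV with columns snp_id, replicate, ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t")
    return [
        AlleleCountRecord(
            snp_id=str(r.snp_id),
            replicate_id=str(r.replicate),
            ref_count=int(r.ref_count),
            alt_count=int(r.alt_count),
        )
        for r in df.itertuples()
    ]
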