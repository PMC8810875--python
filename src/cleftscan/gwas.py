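"""GWAS co-localization: peaks vs summary statistics, TADs, risk loci and LD.

SNP positions in summary statistics are 1-based and converted to the package's
0-based interval convention at the boundary. LD between two biallelic SNPs is
computed from phased haplotypes via the classical D, D' and r² definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

GWAS_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "p", "info"]


def read_gwas(path: str | Path) -> pd.DataFrame:
    """Read whitespace/TSV summary statistics with a header row.

    Expected columns (any extra are kept): snp, chrom (or chr), pos, a1, a2,
    p, info.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.rename(columns={"chr": "chrom"})
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS file lacks columns: {missing}")
    if (df["p"] <= 0).any():
        raise ValueError("GWAS p-values must be > 0")
    return df


def filter_gwas(records: pd.DataFrame, info_min: float = 0.8) -> tuple[pd.DataFrame, int]:
    """Drop poorly imputed variants: keep info score strictly above the cut."""
    keep = records["info"] > info_min
    return records[keep].reset_index(drop=True), int((~keep).sum())


@dataclass(frozen=True)
class Tad:
    """A topologically associating domain."""

    interval: GenomicInterval
    tad_id: str


def read_tads(path: str | Path) -> list[Tad]:
    tads = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        tad_id = parts[3] if len(parts) > 3 else f"tad_{lineno}"
        tads.append(Tad(GenomicInterval(chrom, start, end), tad_id))
    return tads


def read_risk_loci(path: str | Path) -> pd.DataFrame:
    """TSV with columns locus_id, lead_snp, chrom, pos (1-based)."""
    return pd.read_csv(path, sep="\t")


def peaks_in_tads(
    peaks: PeakSet,
    tads: Sequence[Tad],
    loci: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Scope peaks to the TADs containing GWAS risk-locus lead SNPs.

    Each locus is mapped to the TAD holding its lead SNP (1-based position);
    peaks overlapping that TAD by >= 1 bp are listed per locus.  The summary
    reports distinct peaks, distinct TADs hit, and unassigned loci (lead SNP
    in no TAD).
    """
    rows = []
    unassigned = []
    tads_hit = set()
    peaks_hit = set()
    for loc in loci.itertuples():
        base = int(loc.pos) - 1
        tad = next(
            (
                t
                for t in tads
                if t.interval.chrom == str(loc.chrom)
                and t.interval.start <= base < t.interval.end
            ),
            None,
        )
        if tad is None:
            unassigned.append(str(loc.locus_id))
            continue
        for i, p in enumerate(peaks):
            iv = p.interval
            if iv.chrom == tad.interval.chrom and iv.start < tad.interval.end and iv.end > tad.interval.start:
                pname = iv.name or f"peak_{i}"
                tads_hit.add(tad.tad_id)
                peaks_hit.add(pname)
                rows.append(
                    {
                        "locus_id": loc.locus_id,
                        "lead_snp": loc.lead_snp,
                        "tad_id": tad.tad_id,
                        "peak": pname,
                        "peak_start": iv.start,
                        "peak_end": iv.end,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["locus_id", "lead_snp", "tad_id", "peak", "peak_start", "peak_end"],
    )
    summary = {
        "n_loci": len(loci),
        "n_loci_unassigned": len(unassigned),
        "unassigned_loci": unassigned,
        "n_peaks_in_risk_tads": len(peaks_hit),
        "n_tads_with_peaks": len(tads_hit),
    }
    return table, summary


def snp_peak_gwas_table(
    peaks: PeakSet,
    gwas: pd.DataFrame,
    thresholds: Sequence[float] = (0.01, 0.001),
    bonferroni: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Association p-values of SNPs located inside peaks.

    One row per SNP-in-peak with its peak id, raw p and a flag per p-value
    threshold; the summary counts SNPs below each threshold.  With
    ``bonferroni=True`` an extra column multiplies p by the number of
    SNPs-in-peaks (clipped at 1) for a test-wide notion of significance;
    raw p-values are never altered.
    """
    by_chrom = peaks.by_chrom()
    rows = []
    for r in gwas.itertuples():
        base = int(r.pos) - 1
        chrom = str(r.chrom)
        for i, p in enumerate(by_chrom.get(chrom, [])):
            iv = p.interval
            if iv.start <= base < iv.end:
                rows.append(
                    {
                        "snp": r.snp,
                        "chrom": chrom,
                        "pos": int(r.pos),
                        "p": float(r.p),
                        "peak": iv.name or str(iv),
                    }
                )
                break
    table = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p", "peak"])
    summary = {"n_snps_in_peaks": len(table)}
    for t in thresholds:
        col = f"below_{t:g}"
        table[col] = table["p"] < t if len(table) else pd.Series(dtype=bool)
        summary[f"n_{col}"] = int(table[col].sum()) if len(table) else 0
    if bonferroni and len(table):
        table["p_bonferroni"] = np.minimum(1.0, table["p"] * len(table))
    return table, summary


@dataclass
class LdPair:
    """Pairwise linkage disequilibrium between two biallelic SNPs."""

    snp_a: str
    snp_b: str
    d: float | None
    d_prime: float | None
    r2: float | None
    defined: bool = True


def ld_metrics(
    hap_a: Sequence[int],
    hap_b: Sequence[int],
    snp_a: str = "a",
    snp_b: str = "b",
) -> LdPair:
    """D, D' and r² from phased 0/1 haplotype vectors of two SNPs.

    D = p_AB − p_A·p_B over haplotype frequencies; D' normalises |D| by its
    maximum attainable value given the allele frequencies; r² = D² /
    (p_A p_a p_B p_b).  Both metrics are invariant to which allele is coded 1.
    A SNP monomorphic in the sample leaves LD undefined (flagged).
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length haplotype vectors (>= 2 haplotypes)")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LdPair(snp_a, snp_b, None, None, None, defined=False)
    p_ab = float((a * b).mean())
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = None
    d_prime = abs(d) / d_max if d_max else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdPair(snp_a, snp_b, d=float(d), d_prime=float(d_prime), r2=float(r2))


def read_haplotypes(path: str | Path) -> pd.DataFrame:
    """Haplotype matrix TSV: snp_id column then one 0/1 column per haplotype."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def ld_table(
    haplotypes: pd.DataFrame, pairs: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """LD metrics for the requested SNP pairs present in the haplotype matrix."""
    rows = []
    for sa, sb in pairs:
        if sa not in haplotypes.index or sb not in haplotypes.index:
            continue
        ld = ld_metrics(
            haplotypes.loc[sa].to_numpy(), haplotypes.loc[sb].to_numpy(), sa, sb
        )
        rows.append(
            {
                "snp_a": sa,
                "snp_b": sb,
                "d": ld.d,
                "d_prime": ld.d_prime,
                "r2": ld.r2,
                "defined": ld.defined,
            }
        )
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "d", "d_prime", "r2", "defined"])
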