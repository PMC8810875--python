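"""Brute-force per-base / per-pair oracles, independent of the library's
interval arithmetic. Only usable on tiny genomes."""

from __future__ import annotations

import math

import numpy as np


def base_set(intervals):
    """Set of (chrom, base) pairs covered by a list of (chrom, start, end)."""
    out = set()
    for chrom, s, e in intervals:
        out.update((chrom, b) for b in range(s, e))
    return out


def hc_base_set(rep1, rep2):
    """Per-base intersection of two replicates' covered bases."""
    return base_set(rep1) & base_set(rep2)


def covered_bp_of_query(query, references):
    """Bases of one (chrom, s, e) query covered by the union of references."""
    chrom, s, e = query
    ref = base_set(references)
    return sum(1 for b in range(s, e) if (chrom, b) in ref)


def member_fraction(query, references, threshold):
    chrom, s, e = query
    return covered_bp_of_query(query, references) / (e - s) >= threshold


def member_min_bp(query, references, threshold):
    return covered_bp_of_query(query, references) >= threshold


def assign_oracle(peaks, domains):
    """Set of (peak_name, gene_id) by per-base domain membership."""
    out = set()
    for pname, chrom, s, e in peaks:
        pb = {(chrom, b) for b in range(s, e)}
        for gene_id, dchrom, ds, de in domains:
            db = {(dchrom, b) for b in range(ds, de)}
            if pb & db:
                out.add((pname, gene_id))
    return out


def peaks_in_tads_oracle(peaks, tads, loci):
    """Set of (locus_id, peak_name) rows by brute-force scanning."""
    rows = set()
    for locus_id, lead_chrom, lead_pos1 in loci:
        base = lead_pos1 - 1
        for tad_id, tchrom, ts, te in tads:
            if tchrom == lead_chrom and ts <= base < te:
                for pname, pchrom, ps, pe in peaks:
                    if pchrom == tchrom and ps < te and pe > ts:
                        rows.add((locus_id, pname))
                break
    return rows


def binom_two_sided_p(k, n):
    """Minimum-likelihood two-sided exact binomial p at p0 = 0.5."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= obs * (1 + 1e-12)))


def nearest_rank_q75(values):
    vals = sorted(values)
    rank = math.ceil(0.75 * len(vals))
    return vals[max(rank, 1) - 1]


def random_intervals(rng, n, genome, min_len=5, max_len=200, named=None):
    """Random (chrom, start, end) triples on a tiny genome dict."""
    chroms = list(genome)
    out = []
    for i in range(n):
        c = chroms[int(rng.integers(0, len(chroms)))]
        L = int(rng.integers(min_len, min(max_len, genome[c] - 1) + 1))
        s = int(rng.integers(0, genome[c] - L))
        out.append((c, s, s + L))
    return out
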