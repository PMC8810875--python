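"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the data a TF ChIP-seq + genotype +
GWAS integration study consumes: two replicates of narrowPeak calls with a
controlled concordance fraction, reference region sets (second-cell-line TF
peaks, open chromatin, an enhancer mark) with configured coverage of the true
peaks, a 3'-mRNA-seq count table with a planted candidate-TF overlap, a
genotype VCF, per-replicate allelic ChIP read counts with planted
allele-specific binding, GWAS summary statistics, TAD tiles, risk loci and a
phased haplotype matrix with block LD structure.

Every planted effect is written to a ``truth/`` directory so recall and
precision of each stage are exactly computable.  One pseudo-random stream is
spawned per output component from the master seed, so regenerating one
component never shifts the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval, Peak, PeakSet, write_bed

_STREAMS = [
    "peaks",
    "references",
    "expression",
    "genotypes",
    "allele_counts",
    "gwas",
    "tads_loci",
    "haplotypes",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults reflect a scaled-down version of the emulated study: two ChIP
    replicates with ~70% peak concordance, ~300-bp peaks, triplicate
    expression counts, 200 heterozygous SNPs inside peaks of which 10% carry
    a planted 90:10 allelic skew at ~50x depth, and reference sets covering
    94% / 57% / 47% of the true peaks (open chromatin / enhancer mark /
    second-cell-line TF).
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    # ChIP peaks
    n_peaks: int = 400  # per replicate, after QC
    concordance: float = 0.7
    peak_len_mean: float = 300.0
    peak_len_sd: float = 80.0
    jitter_frac: float = 0.25
    n_low_quality: int = 20  # planted peaks that the FE/FDR filter removes
    n_blacklisted: int = 5
    n_irregular: int = 5  # peaks on a non-standard chromosome
    # reference region sets: label -> (probability of covering a true hc
    # region, number of background intervals)
    ref_cover: dict = field(
        default_factory=lambda: {"dnase": 0.94, "h3k27ac": 0.57, "hela_tf": 0.47}
    )
    n_ref_background: int = 150
    # expression
    n_genes: int = 300
    n_expr_replicates: int = 3
    expr_log_mean: float = 1.5
    expr_log_sd: float = 1.8
    n_candidates: int = 22
    n_candidates_expressed: int = 11
    tf_universe_extra: int = 80
    # genotypes / ASB
    n_het_in_peaks: int = 200
    n_hom_in_peaks: int = 360
    n_missing_in_peaks: int = 40
    n_snps_outside: int = 400
    asb_fraction: float = 0.1
    p_true: float = 0.9
    depth_mean: float = 50.0
    n_chip_replicates: int = 2
    # GWAS
    gwas_assoc_fraction: float = 0.05
    gwas_info_low: float = 0.7
    # TADs / loci
    n_tads: int = 40
    n_risk_loci: int = 20
    # haplotypes
    n_haplotypes: int = 200
    ld_block_length: int = 50_000
    ld_block_corr: float = 0.9

    def __post_init__(self) -> None:
        for name in ("concordance", "jitter_frac", "asb_fraction", "p_true"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.chrom_length <= 0:
            raise ValueError("chromosomes must have positive length")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    @property
    def genome(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _peak_lengths(rng, n, cfg) -> np.ndarray:
    lens = rng.normal(cfg.peak_len_mean, cfg.peak_len_sd, size=n)
    return np.clip(np.round(lens), 100, 800).astype(int)


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Write every pipeline input plus ground truth; return the manifest."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    rngs = _rngs(cfg.seed)
    genome = cfg.genome
    chroms = list(genome)

    # --- genome + slot bookkeeping -------------------------------------
    slot_len = 3600  # fits an 800-bp peak with 25% jitter and margins
    slots = [
        (c, s * slot_len)
        for c in chroms
        for s in range(genome[c] // slot_len)
    ]
    rng = rngs["peaks"]
    order = rng.permutation(len(slots))

    n_conc = int(round(cfg.concordance * cfg.n_peaks))
    n_disc = cfg.n_peaks - n_conc
    n_junk = cfg.n_low_quality + cfg.n_blacklisted
    need = n_conc + 2 * n_disc + n_junk + 4  # + blacklist-only slots
    if need > len(slots):
        raise ValueError("genome too small for the requested peak count")
    slot_iter = iter(order)

    def next_slot():
        c, s0 = slots[next(slot_iter)]
        return c, s0

    def place(rng, length):
        c, s0 = next_slot()
        margin = int(np.ceil(cfg.jitter_frac * length)) + 1
        start = int(rng.integers(s0 + margin, s0 + slot_len - length - margin))
        return c, start

    def jitter(rng, start, length):
        j = int(np.floor(cfg.jitter_frac * length))
        return start + int(rng.integers(-j, j + 1)) if j > 0 else start

    rep_peaks: dict[int, list[Peak]] = {0: [], 1: []}
    true_hc: list[GenomicInterval] = []

    def good_stats(rng):
        return float(rng.uniform(5.5, 40.0)), float(rng.uniform(1e-6, 0.04))

    lengths = _peak_lengths(rng, n_conc, cfg)
    for i in range(n_conc):
        L = int(lengths[i])
        c, s = place(rng, L)
        spans = []
        for r in (0, 1):
            rs = jitter(rng, s, L)
            fe, q = good_stats(rng)
            name = f"rep{r + 1}_conc_{i:04d}"
            rep_peaks[r].append(
                Peak(
                    GenomicInterval(c, rs, rs + L, name=name),
                    fold_enrichment=fe,
                    fdr_q=q,
                    summit_offset=L // 2,
                )
            )
            spans.append((rs, rs + L))
        hs, he = max(spans[0][0], spans[1][0]), min(spans[0][1], spans[1][1])
        true_hc.append(GenomicInterval(c, hs, he, name=f"hc_true_{i:04d}"))

    for r in (0, 1):
        lens_d = _peak_lengths(rng, n_disc, cfg)
        for i in range(n_disc):
            L = int(lens_d[i])
            c, s = place(rng, L)
            fe, q = good_stats(rng)
            rep_peaks[r].append(
                Peak(
                    GenomicInterval(c, s, s + L, name=f"rep{r + 1}_disc_{i:04d}"),
                    fold_enrichment=fe,
                    fdr_q=q,
                    summit_offset=L // 2,
                )
            )

    # QC decoys: low fold-enrichment / high q / blacklisted / irregular chrom
    blacklist_ivs: list[GenomicInterval] = []
    for i in range(cfg.n_low_quality):
        L = 300
        c, s = place(rng, L)
        bad_fe = float(rng.uniform(0.5, 4.5)) if i % 2 == 0 else float(rng.uniform(5.5, 40))
        bad_q = 0.5 if i % 2 == 1 else float(rng.uniform(1e-6, 0.04))
        rep_peaks[i % 2].append(
            Peak(
                GenomicInterval(c, s, s + L, name=f"lowq_{i:03d}"),
                fold_enrichment=bad_fe,
                fdr_q=bad_q,
                summit_offset=L // 2,
            )
        )
    for i in range(cfg.n_blacklisted):
        L = 300
        c, s = place(rng, L)
        fe, q = good_stats(rng)
        rep_peaks[i % 2].append(
            Peak(
                GenomicInterval(c, s, s + L, name=f"blk_{i:03d}"),
                fold_enrichment=fe,
                fdr_q=q,
                summit_offset=L // 2,
            )
        )
        blacklist_ivs.append(GenomicInterval(c, max(0, s - 50), s + L + 50, name=f"blacklist_{i:03d}"))
    for i in range(cfg.n_irregular):
        fe, q = good_stats(rng)
        s = 1000 + 2000 * i
        rep_peaks[i % 2].append(
            Peak(
                GenomicInterval("chrUn_synth", s, s + 300, name=f"irr_{i:03d}"),
                fold_enrichment=fe,
                fdr_q=q,
                summit_offset=150,
            )
        )

    files: dict[str, str] = {}

    def save(key, name):
        files[key] = str(outdir / name)
        return outdir / name

    genome_path = save("genome", "genome.txt")
    genome_path.write_text(
        "".join(f"{c}\t{genome[c]}\n" for c in chroms) + "chrUn_synth\t100000\n"
    )
    write_bed(PeakSet([Peak(iv) for iv in blacklist_ivs]), save("blacklist", "blacklist.bed"))
    for r in (0, 1):
        write_bed(
            PeakSet(rep_peaks[r], source_label=f"rep{r + 1}"),
            save(f"rep{r + 1}_peaks", f"rep{r + 1}_peaks.narrowPeak"),
            dialect="narrowPeak",
        )
    write_bed(
        PeakSet([Peak(iv) for iv in true_hc]),
        save("true_hc_peaks", "truth/true_hc_peaks.bed"),
    )

    # --- reference region sets ----------------------------------------
    rng = rngs["references"]
    ref_truth = {}
    for label, cover_p in cfg.ref_cover.items():
        ivs = []
        covered = rng.random(len(true_hc)) < cover_p
        for i, hc in enumerate(true_hc):
            if covered[i]:
                pad_l = int(rng.integers(20, 120))
                pad_r = int(rng.integers(20, 120))
                ivs.append(
                    GenomicInterval(
                        hc.chrom,
                        max(0, hc.start - pad_l),
                        min(genome[hc.chrom], hc.end + pad_r),
                        name=f"{label}_hit_{i:04d}",
                    )
                )
        for i in range(cfg.n_ref_background):
            c = chroms[int(rng.integers(0, len(chroms)))]
            L = int(rng.integers(200, 1200))
            s = int(rng.integers(0, genome[c] - L))
            ivs.append(GenomicInterval(c, s, s + L, name=f"{label}_bg_{i:04d}"))
        write_bed(PeakSet([Peak(iv) for iv in ivs]), save(label, f"{label}.bed"))
        ref_truth[label] = {
            "planted_cover_fraction": float(covered.mean()),
            "covered_true_hc": [true_hc[i].name for i in np.flatnonzero(covered)],
        }

    # --- expression ----------------------------------------------------
    rng = rngs["expression"]
    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    lam = rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, size=cfg.n_genes)
    cand_idx = rng.choice(cfg.n_genes, size=cfg.n_candidates, replace=False)
    expressed_cands = cand_idx[: cfg.n_candidates_expressed]
    silent_cands = cand_idx[cfg.n_candidates_expressed :]
    lam[expressed_cands] = rng.uniform(50, 500, size=len(expressed_cands))
    lam[silent_cands] = rng.uniform(0.05, 0.5, size=len(silent_cands))
    counts = rng.poisson(lam[:, None], size=(cfg.n_genes, cfg.n_expr_replicates))
    expr = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"rep{i + 1}" for i in range(cfg.n_expr_replicates)],
    )
    expr.to_csv(save("expression", "expression.tsv"), sep="\t")
    candidates = [gene_ids[i] for i in cand_idx]
    save("candidates", "candidates.txt").write_text("".join(c + "\n" for c in candidates))
    non_cand = [g for g in gene_ids if g not in set(candidates)]
    universe = sorted(
        set(candidates) | set(rng.choice(non_cand, size=cfg.tf_universe_extra, replace=False))
    )
    save("tf_universe", "tf_universe.txt").write_text("".join(g + "\n" for g in universe))

    # gene models: TSS uniform on the genome, random strand
    tss_chrom = rng.integers(0, len(chroms), size=cfg.n_genes)
    tss_pos = rng.integers(10_000, cfg.chrom_length - 10_000, size=cfg.n_genes)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    gene_rows = sorted(
        zip((chroms[i] for i in tss_chrom), tss_pos, gene_ids, strands),
        key=lambda t: (t[0], int(t[1])),
    )
    save("genes", "genes.bed").write_text(
        "".join(
            f"{c}\t{p}\t{p + 1}\t{g}\t0\t{s}\n" for c, p, g, s in gene_rows
        )
    )

    # --- genotypes -----------------------------------------------------
    rng = rngs["genotypes"]
    bases = np.array(list("ACGT"))
    snps = []  # (snp_id, chrom, pos1, ref, alt, genotype, in_peak)
    used_pos: set[tuple[str, int]] = set()

    def draw_alleles():
        r, a = rng.choice(4, size=2, replace=False)
        return bases[r], bases[a]

    gt_plan = (
        ["het"] * cfg.n_het_in_peaks
        + ["hom_ref"] * (cfg.n_hom_in_peaks // 2)
        + ["hom_alt"] * (cfg.n_hom_in_peaks - cfg.n_hom_in_peaks // 2)
        + ["missing"] * cfg.n_missing_in_peaks
    )
    k = 0
    for gt in gt_plan:
        while True:
            hc = true_hc[int(rng.integers(0, len(true_hc)))]
            pos0 = int(rng.integers(hc.start, hc.end))
            if (hc.chrom, pos0) not in used_pos:
                used_pos.add((hc.chrom, pos0))
                break
        ref, alt = draw_alleles()
        snps.append((f"snp{k:05d}", hc.chrom, pos0 + 1, ref, alt, gt, True))
        k += 1

    peak_cover_spans = {
        c: [(p.interval.start, p.interval.end) for r in (0, 1) for p in rep_peaks[r] if p.interval.chrom == c]
        for c in chroms
    }
    n_out = 0
    while n_out < cfg.n_snps_outside:
        c = chroms[int(rng.integers(0, len(chroms)))]
        pos0 = int(rng.integers(0, genome[c]))
        if (c, pos0) in used_pos:
            continue
        if any(s <= pos0 < e for s, e in peak_cover_spans[c]):
            continue
        used_pos.add((c, pos0))
        ref, alt = draw_alleles()
        gt = ["het", "hom_ref", "hom_alt"][int(rng.integers(0, 3))]
        snps.append((f"snp{k:05d}", c, pos0 + 1, ref, alt, gt, False))
        k += 1
        n_out += 1

    snps.sort(key=lambda s: (s[1], s[2]))
    gt_code = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
    vcf_lines = ["##fileformat=VCFv4.2"]
    for c in chroms:
        vcf_lines.append(f"##contig=<ID={c},length={genome[c]}>")
    vcf_lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    vcf_lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHEPM")
    for sid, c, pos1, ref, alt, gt, _ in snps:
        vcf_lines.append(
            f"{c}\t{pos1}\t{sid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt_code[gt]}"
        )
    save("genotypes", "genotypes.vcf").write_text("".join(l + "\n" for l in vcf_lines))

    # --- allelic ChIP counts ------------------------------------------
    rng = rngs["allele_counts"]
    het_in_peaks = [s for s in snps if s[5] == "het" and s[6]]
    n_asb = int(round(cfg.asb_fraction * len(het_in_peaks)))
    asb_idx = set(rng.choice(len(het_in_peaks), size=n_asb, replace=False).tolist())
    count_rows = []
    truth_rows = []
    for i, (sid, *_rest) in enumerate(het_in_peaks):
        planted = i in asb_idx
        favored_ref = bool(rng.random() < 0.5)
        p_ref = (cfg.p_true if favored_ref else 1 - cfg.p_true) if planted else 0.5
        for r in range(cfg.n_chip_replicates):
            depth = max(1, int(rng.poisson(cfg.depth_mean)))
            ref_c = int(rng.binomial(depth, p_ref))
            count_rows.append(
                {
                    "snp_id": sid,
                    "replicate": f"rep{r + 1}",
                    "ref_count": ref_c,
                    "alt_count": depth - ref_c,
                }
            )
        truth_rows.append(
            {
                "snp_id": sid,
                "planted_asb": planted,
                "favored_allele": ("ref" if favored_ref else "alt") if planted else "none",
                "p_ref_true": p_ref,
            }
        )
    pd.DataFrame(count_rows).to_csv(save("allele_counts", "allele_counts.tsv"), sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(save("asb_truth", "truth/asb_truth.tsv"), sep="\t", index=False)

    # --- GWAS summary statistics --------------------------------------
    rng = rngs["gwas"]
    gwas_rows = []
    assoc_truth = []
    for sid, c, pos1, ref, alt, _gt, _inpk in snps:
        assoc = bool(rng.random() < cfg.gwas_assoc_fraction)
        if assoc:
            p = float(10.0 ** -rng.uniform(2.5, 5.0))
            info = float(rng.uniform(0.85, 1.0))
        else:
            p = float(rng.uniform(1e-12, 1.0))
            info = float(rng.uniform(cfg.gwas_info_low, 1.0))
        gwas_rows.append(
            {"snp": sid, "chrom": c, "pos": pos1, "a1": ref, "a2": alt, "p": p, "info": info}
        )
        if assoc:
            assoc_truth.append(sid)
    pd.DataFrame(gwas_rows).to_csv(save("gwas", "gwas.tsv"), sep="\t", index=False)
    save("gwas_truth", "truth/gwas_truth.txt").write_text(
        "".join(s + "\n" for s in assoc_truth)
    )

    # --- TADs + risk loci ---------------------------------------------
    rng = rngs["tads_loci"]
    per_chrom = max(1, cfg.n_tads // cfg.n_chroms)
    tad_lines = []
    t = 0
    for c in chroms:
        size = genome[c] // per_chrom
        for j in range(per_chrom):
            s0, e0 = j * size, (j + 1) * size if j < per_chrom - 1 else genome[c]
            tad_lines.append(f"{c}\t{s0}\t{e0}\ttad_{t:03d}")
            t += 1
    save("tads", "tads.bed").write_text("".join(l + "\n" for l in tad_lines))
    lead_idx = rng.choice(len(snps), size=min(cfg.n_risk_loci, len(snps)), replace=False)
    loci_rows = [
        {
            "locus_id": f"locus{j:02d}",
            "lead_snp": snps[i][0],
            "chrom": snps[i][1],
            "pos": snps[i][2],
        }
        for j, i in enumerate(sorted(lead_idx.tolist()))
    ]
    pd.DataFrame(loci_rows).to_csv(save("risk_loci", "risk_loci.tsv"), sep="\t", index=False)

    # --- phased haplotypes with block LD ------------------------------
    rng = rngs["haplotypes"]
    H = cfg.n_haplotypes
    hap = np.zeros((len(snps), H), dtype=np.int8)
    block_of = {}
    for i, (sid, c, pos1, *_r) in enumerate(snps):
        block_of[i] = (c, (pos1 - 1) // cfg.ld_block_length)
    cores: dict[tuple, np.ndarray] = {}
    for i in range(len(snps)):
        key = block_of[i]
        if key not in cores:
            cores[key] = (rng.random(H) < 0.5).astype(np.int8)
        core = cores[key]
        noise = rng.random(H) >= cfg.ld_block_corr
        hap[i] = np.where(noise, (rng.random(H) < 0.5).astype(np.int8), core)
    hap_df = pd.DataFrame(
        hap,
        index=pd.Index([s[0] for s in snps], name="snp_id"),
        columns=[f"hap{j:03d}" for j in range(H)],
    )
    hap_df.to_csv(save("haplotypes", "haplotypes.tsv"), sep="\t")

    manifest = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "files": files,
        "truth": {
            "n_true_hc_regions": len(true_hc),
            "n_planted_asb": n_asb,
            "n_het_in_peaks": len(het_in_peaks),
            "n_gwas_associated": len(assoc_truth),
            "reference_cover": ref_truth,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
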