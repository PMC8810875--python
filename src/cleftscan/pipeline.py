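"""End-to-end orchestration: filter → hc-peaks → classify → assign → ASB → GWAS.

Each stage is an ordinary function over the library modules so it can be run
alone (the CLI exposes one subcommand per stage) or as the full pipeline,
which also emits a machine-readable run report whose counts equal the row
counts of the tables it writes.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .asb import (
    asb_report,
    asb_scan,
    het_filter,
    read_allele_counts,
    read_genotypes_vcf,
    snps_in_peaks,
)
from .domains import assign_genes, build_domains, read_gene_models
from .expression import (
    candidate_tf_report,
    classify_expression,
    read_count_table,
    read_gene_list,
)
from .gwas import (
    filter_gwas,
    ld_table,
    peaks_in_tads,
    read_gwas,
    read_haplotypes,
    read_risk_loci,
    read_tads,
    snp_peak_gwas_table,
)
from .intervals import (
    DEFAULT_ALLOWED_CHROMS,
    PeakSet,
    derive_hc_peaks,
    filter_peaks,
    read_bed,
    read_genome,
    write_bed,
)
from .overlap import OverlapRule, enrichment_chi2, percent_overlap, venn_partition

DEFAULT_PARAMS: dict[str, Any] = {
    "fe_min": 5.0,
    "fe_max": 50.0,
    "fdr_max": 0.05,
    "allowed_chroms": None,  # None -> chr1..22, X, Y
    "overlap_rules": {
        "dnase": {"mode": "min_bp", "threshold": 1},
        "h3k27ac": {"mode": "min_bp", "threshold": 1},
        "hela_tf": {"mode": "fraction_of_query", "threshold": 0.5},
    },
    "named_classes": {"craniofacial_specific": "dnase & h3k27ac & ~hela_tf"},
    "n_perm": 200,
    "mean_min": 5.0,
    "up": 5000,
    "down": 1000,
    "max_ext": 1_000_000,
    "alpha": 0.05,
    "min_total": 10,
    "per_replicate_asb": False,
    "info_min": 0.8,
    "gwas_thresholds": [0.01, 0.001],
    "distance_anchor": "midpoint",
}


class PipelineError(RuntimeError):
    """Raised with the failing stage's name; partial outputs are removed."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    cfg.setdefault("params", {})
    merged = dict(DEFAULT_PARAMS)
    merged.update(cfg["params"])
    cfg["params"] = merged
    cfg.setdefault("seed", 0)
    return cfg


def default_config(manifest: Mapping, seed: int | None = None) -> dict:
    """Pipeline configuration pointing at a `simulate_all` output directory."""
    f = manifest["files"]
    return {
        "seed": manifest["seed"] if seed is None else seed,
        "inputs": {
            "genome": f["genome"],
            "blacklist": f["blacklist"],
            "rep1_peaks": f["rep1_peaks"],
            "rep2_peaks": f["rep2_peaks"],
            "references": {
                label: f[label] for label in manifest["config"]["ref_cover"]
            },
            "expression": f["expression"],
            "candidates": f["candidates"],
            "tf_universe": f["tf_universe"],
            "genes": f["genes"],
            "genotypes": f["genotypes"],
            "allele_counts": f["allele_counts"],
            "gwas": f["gwas"],
            "tads": f["tads"],
            "risk_loci": f["risk_loci"],
            "haplotypes": f["haplotypes"],
        },
        "params": dict(DEFAULT_PARAMS),
    }


def _require(cfg: dict, stage: str, *keys: str) -> None:
    for key in keys:
        path = cfg["inputs"].get(key)
        if isinstance(path, dict):
            missing = [p for p in path.values() if not Path(p).exists()]
            if missing:
                raise PipelineError(stage, f"missing input files: {missing}")
        elif path is None or not Path(path).exists():
            raise PipelineError(stage, f"missing input {key!r}: {path}")


def _allowed(cfg: dict, genome: Mapping[str, int]) -> set[str]:
    allowed = cfg["params"]["allowed_chroms"]
    return set(allowed) if allowed is not None else set(DEFAULT_ALLOWED_CHROMS)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_hcpeaks(cfg: dict, outdir: Path) -> tuple[PeakSet, dict]:
    _require(cfg, "hcpeaks", "rep1_peaks", "rep2_peaks", "genome")
    p = cfg["params"]
    genome = read_genome(cfg["inputs"]["genome"])
    blacklist = None
    if cfg["inputs"].get("blacklist") and Path(cfg["inputs"]["blacklist"]).exists():
        blacklist = read_bed(cfg["inputs"]["blacklist"], dialect="bed6")
    allowed = _allowed(cfg, genome)
    reps = []
    counts = {}
    for key in ("rep1_peaks", "rep2_peaks"):
        ps = read_bed(cfg["inputs"][key], dialect="narrowPeak", genome=genome)
        counts[f"{key}_raw"] = len(ps)
        ps = filter_peaks(
            ps,
            fe_min=p["fe_min"],
            fe_max=p["fe_max"],
            fdr_max=p["fdr_max"],
            blacklist=blacklist,
            allowed_chroms=allowed,
        )
        counts[f"{key}_filtered"] = len(ps)
        reps.append(ps)
    hc = derive_hc_peaks(reps[0], reps[1])
    counts["n_hc_peaks"] = len(hc)
    counts["hc_total_bp"] = hc.total_bp()
    write_bed(hc, outdir / "hc_peaks.bed")
    return hc, counts


def stage_classify(cfg: dict, outdir: Path, hc: PeakSet) -> dict:
    _require(cfg, "classify", "references", "genome")
    p = cfg["params"]
    genome = read_genome(cfg["inputs"]["genome"])
    refs = {
        label: read_bed(path, dialect="bed6")
        for label, path in cfg["inputs"]["references"].items()
    }
    rules = [
        OverlapRule(label, mode=spec["mode"], threshold=spec["threshold"])
        for label, spec in p["overlap_rules"].items()
        if label in refs
    ]
    venn = venn_partition(hc, rules, refs, named_classes=p["named_classes"])
    venn.cell_counts.to_csv(outdir / "venn_cells.tsv", sep="\t", index=False)
    venn.membership.to_csv(outdir / "venn_membership.tsv", sep="\t")
    blacklist = None
    if cfg["inputs"].get("blacklist") and Path(cfg["inputs"]["blacklist"]).exists():
        blacklist = read_bed(cfg["inputs"]["blacklist"], dialect="bed6")
    enrich_rows = []
    for rule in rules:
        res = enrichment_chi2(
            hc,
            refs[rule.reference_label],
            rule,
            genome={c: L for c, L in genome.items() if c in _allowed(cfg, genome)},
            n_perm=p["n_perm"],
            seed=cfg["seed"],
            blacklist=blacklist,
        )
        enrich_rows.append({"reference": rule.reference_label, **res.to_dict()})
    enrich = pd.DataFrame(enrich_rows)
    enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    summary = {
        "per_reference_overlap": {
            label: {
                "n_overlapping": venn.count_in(label),
                "percent_of_hc": percent_overlap(venn.count_in(label), venn.total),
            }
            for label in venn.membership.columns
        },
        "venn_union": venn.union_count(),
        "venn_outside_union": venn.outside_union_count(),
        "named_classes": venn.named_class_counts,
        "enrichment": enrich_rows,
    }
    return summary


def stage_expression(cfg: dict, outdir: Path) -> dict:
    _require(cfg, "expression", "expression", "candidates", "tf_universe")
    p = cfg["params"]
    counts = read_count_table(cfg["inputs"]["expression"])
    cls = classify_expression(counts, mean_min=p["mean_min"])
    table, summary = candidate_tf_report(
        cls,
        read_gene_list(cfg["inputs"]["candidates"]),
        read_gene_list(cfg["inputs"]["tf_universe"]),
    )
    table.to_csv(outdir / "candidate_tf_report.tsv", sep="\t", index=False)
    cls.classes.rename("expression_class").to_csv(
        outdir / "expression_classes.tsv", sep="\t"
    )
    return {
        "n_genes": len(cls.classes),
        "n_expressed": int(len(cls.expressed)),
        "n_strongly_expressed": int(len(cls.strongly_expressed)),
        "upper_quartile_cut": cls.upper_quartile_cut,
        "candidates": summary,
    }


def stage_assign(cfg: dict, outdir: Path, hc: PeakSet) -> tuple[pd.DataFrame, dict]:
    _require(cfg, "assign", "genes", "genome")
    p = cfg["params"]
    genome = read_genome(cfg["inputs"]["genome"])
    genes = read_gene_models(cfg["inputs"]["genes"])
    domains = build_domains(
        genes, up=p["up"], down=p["down"], max_ext=p["max_ext"], genome=genome
    )
    assignments = assign_genes(hc, domains, anchor=p["distance_anchor"])
    assignments.to_csv(outdir / "gene_assignments.tsv", sep="\t", index=False)
    assigned = assignments.dropna(subset=["gene_id"])
    return assignments, {
        "n_assignment_rows": len(assignments),
        "n_peaks_with_gene": int(assigned["peak"].nunique()),
        "n_target_genes": int(assigned["gene_id"].nunique()),
    }


def stage_asb(
    cfg: dict,
    outdir: Path,
    hc: PeakSet,
    assignments: pd.DataFrame | None = None,
    gwas: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    _require(cfg, "asb", "genotypes", "allele_counts")
    p = cfg["params"]
    genotypes = read_genotypes_vcf(cfg["inputs"]["genotypes"])
    in_peaks = snps_in_peaks(genotypes, hc)
    het, tally = het_filter(in_peaks)
    counts = read_allele_counts(cfg["inputs"]["allele_counts"])
    results = asb_scan(
        het,
        counts,
        alpha=p["alpha"],
        min_total=p["min_total"],
        per_replicate=p["per_replicate_asb"],
    )
    report = asb_report(results, snps=het, gene_assignments=assignments, gwas=gwas)
    report.to_csv(outdir / "asb_results.tsv", sep="\t", index=False)
    return report, {
        "n_genotyped_snps": len(genotypes),
        "n_snps_in_peaks": len(in_peaks),
        "genotype_tally_in_peaks": tally,
        "n_het_in_peaks": len(het),
        "n_tested": len(results),
        "n_asb": len(report),
    }


def stage_gwas(cfg: dict, outdir: Path, hc: PeakSet) -> tuple[pd.DataFrame, dict]:
    _require(cfg, "gwas", "gwas", "tads", "risk_loci", "haplotypes")
    p = cfg["params"]
    gwas_raw = read_gwas(cfg["inputs"]["gwas"])
    gwas_df, n_dropped = filter_gwas(gwas_raw, info_min=p["info_min"])
    tads = read_tads(cfg["inputs"]["tads"])
    loci = read_risk_loci(cfg["inputs"]["risk_loci"])
    tad_table, tad_summary = peaks_in_tads(hc, tads, loci)
    tad_table.to_csv(outdir / "peaks_in_risk_tads.tsv", sep="\t", index=False)
    snp_table, snp_summary = snp_peak_gwas_table(
        hc, gwas_df, thresholds=p["gwas_thresholds"], bonferroni=True
    )
    snp_table.to_csv(outdir / "snps_in_peaks_gwas.tsv", sep="\t", index=False)

    # LD of every SNP-in-peak against the lead SNP of any risk TAD sharing it
    haplotypes = read_haplotypes(cfg["inputs"]["haplotypes"])
    pairs = []
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
            continue
        in_tad = snp_table[
            (snp_table["chrom"] == tad.interval.chrom)
            & (snp_table["pos"] - 1 >= tad.interval.start)
            & (snp_table["pos"] - 1 < tad.interval.end)
        ]
        for snp in in_tad["snp"]:
            if snp != loc.lead_snp:
                pairs.append((snp, loc.lead_snp))
    ld = ld_table(haplotypes, pairs)
    ld.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
    summary = {
        "n_gwas_records": len(gwas_raw),
        "n_dropped_low_info": n_dropped,
        "risk_tads": tad_summary,
        "snps_in_peaks": snp_summary,
        "n_ld_pairs": len(ld),
    }
    return snp_table, summary


def run_pipeline(config: str | Path | dict, outdir: str | Path) -> dict:
    """Run every stage; write tables plus ``report.json`` under ``outdir``."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    if isinstance(config, dict):
        merged = dict(DEFAULT_PARAMS)
        merged.update(cfg.get("params", {}))
        cfg = {**cfg, "params": merged}
        cfg.setdefault("seed", 0)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preexisting = {p for p in outdir.rglob("*")}
    report: dict[str, Any] = {
        "tool": "cleftscan",
        "version": __version__,
        "seed": cfg["seed"],
        "params": cfg["params"],
        "stages": {},
    }
    stage = "hcpeaks"
    try:
        t0 = time.perf_counter()
        hc, counts = stage_hcpeaks(cfg, outdir)
        report["stages"]["hcpeaks"] = {**counts, "seconds": time.perf_counter() - t0}

        stage = "classify"
        t0 = time.perf_counter()
        report["stages"]["classify"] = {
            **stage_classify(cfg, outdir, hc),
            "seconds": time.perf_counter() - t0,
        }

        stage = "expression"
        t0 = time.perf_counter()
        report["stages"]["expression"] = {
            **stage_expression(cfg, outdir),
            "seconds": time.perf_counter() - t0,
        }

        stage = "assign"
        t0 = time.perf_counter()
        assignments, asummary = stage_assign(cfg, outdir, hc)
        report["stages"]["assign"] = {**asummary, "seconds": time.perf_counter() - t0}

        stage = "gwas"
        t0 = time.perf_counter()
        gwas_table, gsummary = stage_gwas(cfg, outdir, hc)
        report["stages"]["gwas"] = {**gsummary, "seconds": time.perf_counter() - t0}

        stage = "asb"
        t0 = time.perf_counter()
        gwas_df, _ = filter_gwas(
            read_gwas(cfg["inputs"]["gwas"]), info_min=cfg["params"]["info_min"]
        )
        _, bsummary = stage_asb(cfg, outdir, hc, assignments, gwas_df)
        report["stages"]["asb"] = {**bsummary, "seconds": time.perf_counter() - t0}
    except Exception as exc:  # fail fast, naming the stage; drop partial output
        for p in outdir.rglob("*"):
            if p not in preexisting and p.is_file():
                p.unlink()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
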