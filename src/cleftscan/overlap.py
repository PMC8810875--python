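"""Classification of peaks against reference region sets.

Two overlap rules are supported, mirroring how transcription-factor peaks and
histone-mark regions are conventionally compared: a fraction-of-query rule
(e.g. at least 50% of the peak's bases covered by the reference) and a
minimum-base-pair rule (e.g. any 1-bp overlap). Membership across several
references yields a Venn partition, and enrichment over a random-placement
null is tested with a 1-df chi-square on observed vs expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeCover, PeakSet

FRACTION_OF_QUERY = "fraction_of_query"
MIN_BP = "min_bp"


@dataclass(frozen=True)
class OverlapRule:
    """How membership of a query peak in one reference set is decided.

    ``fraction_of_query``: covered bases / query length >= threshold (0,1].
    ``min_bp``: covered bases >= threshold (integer >= 1).
    Coverage is always computed against the union of the reference intervals,
    so overlapping reference regions are not double counted.
    """

    reference_label: str
    mode: str = FRACTION_OF_QUERY
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mode == FRACTION_OF_QUERY:
            if not (0.0 < self.threshold <= 1.0):
                raise ValueError("fraction threshold must lie in (0, 1]")
        elif self.mode == MIN_BP:
            if self.threshold < 1:
                raise ValueError("min_bp threshold must be >= 1")
        else:
            raise ValueError(f"unknown overlap mode {self.mode!r}")


def classify_against(
    query: PeakSet, reference: PeakSet, rule: OverlapRule
) -> np.ndarray:
    """Boolean membership flag per query peak under ``rule``."""
    cover = GenomeCover(reference.intervals)
    flags = np.zeros(len(query), dtype=bool)
    ivs = query.intervals
    for chrom in query.chroms():
        idx = np.array([i for i, iv in enumerate(ivs) if iv.chrom == chrom])
        starts = np.array([ivs[i].start for i in idx])
        ends = np.array([ivs[i].end for i in idx])
        covered = cover.covered_bp(chrom, starts, ends)
        if rule.mode == FRACTION_OF_QUERY:
            flags[idx] = covered / (ends - starts) >= rule.threshold
        else:
            flags[idx] = covered >= rule.threshold
    return flags


@dataclass
class VennResult:
    """Venn partition of query peaks over several reference sets."""

    membership: pd.DataFrame  # one bool column per reference label
    cell_counts: pd.DataFrame  # one row per cell: label columns + 'count'
    named_class_counts: dict[str, int]
    total: int

    def count_in(self, label: str) -> int:
        """Peaks overlapping one reference, regardless of the others."""
        return int(self.membership[label].sum())

    def union_count(self) -> int:
        """Peaks overlapping at least one reference."""
        return int(self.membership.any(axis=1).sum())

    def outside_union_count(self) -> int:
        """Peaks in no reference set (not displayed in a Venn diagram)."""
        return outside_union_count(self.total, self.union_count())


def percent_overlap(n_overlapping: int, n_total: int, ndigits: int = 1) -> float:
    """Share of peaks overlapping a reference, as a percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_overlapping / n_total, ndigits)


def outside_union_count(n_total: int, n_union: int) -> int:
    """Peaks falling in no reference set, from total and Venn-union counts."""
    if not (0 <= n_union <= n_total):
        raise ValueError("need 0 <= n_union <= n_total")
    return n_total - n_union


def venn_partition(
    query: PeakSet,
    rules: Sequence[OverlapRule],
    references: Mapping[str, PeakSet],
    named_classes: Mapping[str, str] | None = None,
) -> VennResult:
    """Assign every query peak to exactly one Venn cell.

    ``named_classes`` maps a class name to a boolean expression over the
    reference labels, e.g. ``"dnase & h3k27ac & ~hela_tf"`` for the
    tissue-specific class. Cell counts always sum to ``len(query)``.
    """
    if not rules:
        raise ValueError("at least one overlap rule required")
    membership = {}
    for rule in rules:
        if rule.reference_label not in references:
            raise KeyError(f"reference {rule.reference_label!r} not supplied")
        membership[rule.reference_label] = classify_against(
            query, references[rule.reference_label], rule
        )
    names = [p.interval.name or str(p.interval) for p in query]
    mdf = pd.DataFrame(membership, index=names)
    cells = mdf.groupby(list(mdf.columns), as_index=False).size()
    cells = cells.rename(columns={"size": "count"})
    named_counts = {}
    if named_classes:
        for cname, expr in named_classes.items():
            named_counts[cname] = int(mdf.eval(expr).sum())
    return VennResult(
        membership=mdf,
        cell_counts=cells,
        named_class_counts=named_counts,
        total=len(query),
    )


@dataclass
class EnrichmentResult:
    """Observed vs null-expected overlap with a 1-df chi-square."""

    observed_overlapping: int
    expected_overlapping: float
    n_total: int
    chi2_stat: float
    p_value: float
    n_perm: int
    seed: int
    degenerate: bool = False  # an expected cell was zero

    def to_dict(self) -> dict:
        return {
            "observed_overlapping": self.observed_overlapping,
            "expected_overlapping": self.expected_overlapping,
            "n_total": self.n_total,
            "chi2_stat": self.chi2_stat,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def _random_starts(
    rng: np.random.Generator,
    lengths: np.ndarray,
    chrom_len: int,
    n_perm: int,
    bl_cover: GenomeCover | None,
    chrom: str,
    max_tries: int = 50,
) -> np.ndarray:
    """Uniform starts for length-preserved placements, avoiding the blacklist."""
    span = np.maximum(chrom_len - lengths, 1)
    starts = rng.integers(0, span[None, :], size=(n_perm, len(lengths)))
    if bl_cover is not None:
        for _ in range(max_tries):
            hit = (
                bl_cover.covered_bp(
                    chrom, starts.ravel(), (starts + lengths[None, :]).ravel()
                ).reshape(starts.shape)
                > 0
            )
            if not hit.any():
                break
            starts[hit] = rng.integers(
                0, np.broadcast_to(span[None, :], starts.shape)[hit]
            )
    return starts


def enrichment_chi2(
    query: PeakSet,
    reference: PeakSet,
    rule: OverlapRule,
    genome: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    blacklist: PeakSet | None = None,
    within_chromosome: bool = True,
) -> EnrichmentResult:
    """Test enrichment of query peaks in a reference set.

    The expected overlapping count comes from placing length-preserved copies
    of the query peaks uniformly at random (by default within each peak's own
    chromosome; optionally genome-wide with chromosomes drawn proportionally
    to length) ``n_perm`` times, excluding blacklist hits.  The observed
    (overlapping, non-overlapping) pair is compared to the expected pair with
    a Pearson chi-square on 1 df, upper-tail p.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    observed = int(classify_against(query, reference, rule).sum())
    n = len(query)

    ref_cover = GenomeCover(reference.intervals)
    bl_cover = GenomeCover(blacklist.intervals) if blacklist is not None else None
    ivs = query.intervals
    null_members = np.zeros(n_perm, dtype=np.int64)

    if within_chromosome:
        chrom_groups = {}
        for iv in ivs:
            chrom_groups.setdefault(iv.chrom, []).append(iv.length)
        for chrom, lens in chrom_groups.items():
            lengths = np.asarray(lens, dtype=np.int64)
            clen = genome[chrom]
            starts = _random_starts(rng, lengths, clen, n_perm, bl_cover, chrom)
            covered = ref_cover.covered_bp(
                chrom, starts.ravel(), (starts + lengths[None, :]).ravel()
            ).reshape(starts.shape)
            if rule.mode == FRACTION_OF_QUERY:
                member = covered / lengths[None, :] >= rule.threshold
            else:
                member = covered >= rule.threshold
            null_members += member.sum(axis=1)
    else:
        chroms = list(genome)
        sizes = np.array([genome[c] for c in chroms], dtype=float)
        probs = sizes / sizes.sum()
        lengths = np.asarray([iv.length for iv in ivs], dtype=np.int64)
        pick = rng.choice(len(chroms), size=(n_perm, n), p=probs)
        for ci, chrom in enumerate(chroms):
            mask = pick == ci
            if not mask.any():
                continue
            lens = np.broadcast_to(lengths[None, :], mask.shape)[mask]
            starts = _random_starts(
                rng, lens, genome[chrom], 1, bl_cover, chrom
            ).ravel()
            covered = ref_cover.covered_bp(chrom, starts, starts + lens)
            if rule.mode == FRACTION_OF_QUERY:
                member = covered / lens >= rule.threshold
            else:
                member = covered >= rule.threshold
            contrib = np.zeros(mask.shape, dtype=np.int64)
            contrib[mask] = member
            null_members += contrib.sum(axis=1)

    expected = float(null_members.mean())
    e = np.array([expected, n - expected], dtype=float)
    o = np.array([observed, n - observed], dtype=float)
    degenerate = bool((e <= 0).any())
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((e > 0), (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
    # an empty expected cell with an empty observed cell contributes nothing;
    # the statistic is then degenerate and reported with p = 1
    chi2_stat = float(terms.sum()) if not degenerate else 0.0
    p = float(stats.chi2.sf(chi2_stat, df=1)) if chi2_stat > 0 else 1.0
    return EnrichmentResult(
        observed_overlapping=observed,
        expected_overlapping=expected,
        n_total=n,
        chi2_stat=chi2_stat,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        degenerate=degenerate,
    )
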