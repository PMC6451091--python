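"""Classify genomic binding sites by cofactor co-occupancy and enhancer
state.

Two orthogonal labels are assigned per site from ChIP-seq peak sets and a
gene-expression table.  *Binding context*: a site is co-occupied by a
cofactor when a highly reproducible peak overlaps it by at least one base
(half-open interval arithmetic); it is "alone" only when the nearest
cofactor peak -- in the permissive, relaxed-parameter peak sets -- is more
than 200 bases away for every cofactor.  *Enhancer state*: active sites sit
within 200 bases of both H3K4me1 and H3K27ac peaks with a nearest gene
2-500 kb away expressed above the median RPKM; primed sites have H3K4me1
only and a nearest gene below the median; unmarked sites have neither mark
within 200 bases.  Sites meeting none of the definitions form an explicit
"ambiguous" bucket rather than being silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALONE_DISTANCE = 200
DEFAULT_MARK_DISTANCE = 200
DEFAULT_GENE_WINDOW = (2_000, 500_000)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _as_interval(x) -> GenomicInterval:
    if isinstance(x, GenomicInterval):
        return x
    if isinstance(x, (tuple, list)) and len(x) >= 3:
        return GenomicInterval(str(x[0]), int(x[1]), int(x[2]))
    return GenomicInterval(str(x["chrom"]), int(x["start"]), int(x["end"]))


def cooccupied(a, b) -> bool:
    """True iff the two intervals share at least one base (half-open:
    [100,200) and [200,300) do NOT overlap)."""
    a, b = _as_interval(a), _as_interval(b)
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def gap_to_nearest(site, peaks: pd.DataFrame) -> float:
    """Distance in bases between closest edges of *site* and the nearest
    peak (0 if overlapping or book-ended; inf if no peak on the chrom)."""
    site = _as_interval(site)
    sub = peaks[peaks["chrom"] == site.chrom]
    if sub.empty:
        return float("inf")
    starts = sub["start"].to_numpy(int)
    ends = sub["end"].to_numpy(int)
    gaps = np.maximum(starts - site.end, site.start - ends)
    return float(max(0, gaps.min()))


def overlaps_any(site, peaks: pd.DataFrame) -> bool:
    site = _as_interval(site)
    sub = peaks[peaks["chrom"] == site.chrom]
    if sub.empty:
        return False
    return bool(
        ((sub["start"] < site.end) & (site.start < sub["end"])).any()
    )


def classify_binding_context(
    site,
    cofactors: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    alone_distance: int = DEFAULT_ALONE_DISTANCE,
) -> str:
    """Label a site by cofactor co-occupancy.

    *cofactors* maps cofactor name -> (reproducible peaks, relaxed peaks).
    Co-occupancy uses the reproducible set; "alone" requires the nearest
    relaxed-set peak to be > *alone_distance* bases away for every
    cofactor.  Sites that are neither co-occupied nor clearly alone are
    "ambiguous" and excluded from category outputs.
    """
    if not cofactors:
        raise ValueError("at least one cofactor peak set is required")
    for name, (repro, relaxed) in cofactors.items():
        if repro.empty:
            raise ValueError(f"empty reproducible peak set for cofactor {name!r}")
    occupied = [
        name
        for name, (repro, _) in cofactors.items()
        if overlaps_any(site, repro)
    ]
    if len(occupied) >= 2:
        return "with_both"
    if len(occupied) == 1:
        return f"with_{occupied[0]}"
    if all(
        gap_to_nearest(site, relaxed) > alone_distance
        for _, relaxed in cofactors.values()
    ):
        return "alone"
    return "ambiguous"


def nearest_gene(site, genes: pd.DataFrame) -> tuple[str, float, float]:
    """Nearest gene by |site midpoint - TSS|; returns (gene, distance, rpkm)."""
    site = _as_interval(site)
    sub = genes[genes["chrom"] == site.chrom]
    if sub.empty:
        return "", float("inf"), float("nan")
    dist = np.abs(sub["tss"].to_numpy(float) - site.midpoint)
    k = int(np.argmin(dist))
    row = sub.iloc[k]
    return str(row["gene"]), float(dist[k]), float(row["rpkm"])


def classify_enhancer_state(
    site,
    h3k4me1_peaks: pd.DataFrame,
    h3k27ac_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    mark_distance: int = DEFAULT_MARK_DISTANCE,
    gene_window: tuple[int, int] = DEFAULT_GENE_WINDOW,
    median_rpkm: float | None = None,
) -> str:
    """Label a site active / primed / unmarked by mark proximity and
    nearest-gene expression; anything else is "ambiguous" (including
    expression exactly at the median)."""
    if genes.empty:
        raise ValueError("gene table is empty")
    if median_rpkm is None:
        median_rpkm = float(genes["rpkm"].median())
    d4 = gap_to_nearest(site, h3k4me1_peaks)
    d27 = gap_to_nearest(site, h3k27ac_peaks)
    has_k4 = d4 <= mark_distance
    has_k27 = d27 <= mark_distance
    if not has_k4 and not has_k27:
        return "unmarked"
    _, gene_dist, rpkm = nearest_gene(site, genes)
    gene_ok = gene_window[0] <= gene_dist <= gene_window[1]
    if has_k4 and has_k27 and gene_ok and rpkm > median_rpkm:
        return "active"
    if has_k4 and not has_k27 and gene_ok and rpkm < median_rpkm:
        return "primed"
    return "ambiguous"


def annotate_sites(
    sites: pd.DataFrame,
    cofactors: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    h3k4me1_peaks: pd.DataFrame,
    h3k27ac_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    alone_distance: int = DEFAULT_ALONE_DISTANCE,
    mark_distance: int = DEFAULT_MARK_DISTANCE,
    gene_window: tuple[int, int] = DEFAULT_GENE_WINDOW,
) -> pd.DataFrame:
    """Per-site annotation table: binding context, enhancer state, nearest
    gene and its expression.  *sites* needs chrom/start/end and optionally
    a name column (else row order ids)."""
    median_rpkm = float(genes["rpkm"].median())
    rows = []
    for idx, row in sites.iterrows():
        site = _as_interval(row)
        site_id = row["name"] if "name" in sites.columns else f"site{idx}"
        gene, gene_dist, rpkm = nearest_gene(site, genes)
        rows.append(
            {
                "site_id": site_id,
                "chrom": site.chrom,
                "start": site.start,
                "end": site.end,
                "binding_context": classify_binding_context(
                    site, cofactors, alone_distance
                ),
                "enhancer_state": classify_enhancer_state(
                    site,
                    h3k4me1_peaks,
                    h3k27ac_peaks,
                    genes,
                    mark_distance,
                    gene_window,
                    median_rpkm,
                ),
                "nearest_gene": gene,
                "gene_distance": gene_dist,
                "rpkm": rpkm,
            }
        )
    return pd.DataFrame(rows)


def stratified_zscore_report(
    annotated: pd.DataFrame,
    group_col: str = "binding_context",
    value_col: str = "z",
    pairs: Sequence[tuple[str, str]] | None = None,
    min_n: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category z-score distributions plus pairwise two-sided
    Wilcoxon-Mann-Whitney tests.

    Categories with fewer than *min_n* members are excluded from testing
    with a warning.  Returns (summary table, pairwise-test table).
    """
    groups = {
        name: sub[value_col].to_numpy(float)
        for name, sub in annotated.groupby(group_col)
    }
    summary = pd.DataFrame.from_dict(
        {
            name: {
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
            }
            for name, v in groups.items()
        },
        orient="index",
    )
    testable = {}
    for name, v in groups.items():
        if len(v) < min_n:
            warnings.warn(
                f"category {name!r} has n={len(v)} < {min_n}; excluded from testing"
            )
        else:
            testable[name] = v
    if pairs is None:
        pairs = list(combinations(sorted(testable), 2))
    tests = []
    for a, b in pairs:
        if a not in testable or b not in testable:
            continue
        res = stats.mannwhitneyu(testable[a], testable[b], alternative="two-sided")
        tests.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(testable[a]),
                "n_b": len(testable[b]),
                "median_diff": float(
                    np.median(testable[a]) - np.median(testable[b])
                ),
                "u_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    return summary, pd.DataFrame(tests)
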