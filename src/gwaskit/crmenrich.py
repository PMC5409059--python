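"""Regulatory-region construction and P-value enrichment testing.

Builds combinatorial cis-regulatory-module interval sets from peak tracks
and tests, via a one-sided trend test on binned association P-values,
whether small P-values are over-represented inside annotated regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwasio import AnnotationTrack

__all__ = [
    "BinningScheme",
    "EnrichmentResult",
    "define_crms",
    "bin_pvalues",
    "annotate_overlap",
    "trend_enrichment_test",
    "enrichment_analysis",
]


@dataclass(frozen=True)
class BinningScheme:
    """Ordered P-value categories.

    "groups": nine categories 10^(-k+1) >= P > 10^(-k) for k = 1..8 plus
    P <= 10^-8 (upper bounds inclusive). "nominal": P > 0.05 and P <= 0.05.
    Category indices run from 1 (largest P) upward.
    """

    name: str

    def __post_init__(self):
        if self.name not in ("groups", "nominal"):
            raise ValueError(f"unknown binning scheme {self.name!r}")

    @property
    def n_categories(self) -> int:
        return 9 if self.name == "groups" else 2

    def assign(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise ValueError("P-values must lie in (0, 1]")
        if self.name == "nominal":
            return np.where(p <= 0.05, 2, 1)
        bins = 10.0 ** np.arange(-8, 0)  # 1e-8 .. 1e-1 ascending
        # right-inclusive: bins[i-1] < p <= bins[i]; category k = 9 - i
        return 9 - np.digitize(p, bins, right=True)


GROUPS = BinningScheme("groups")
NOMINAL = BinningScheme("nominal")


@dataclass
class EnrichmentResult:
    """Trend-test result for one annotation track and binning scheme."""

    scheme: str
    table: np.ndarray  # (n_categories, 2): columns (inside, outside)
    z: float
    chi2: float
    p_one_sided: float
    n_regions: int
    n_snps: int
    reason: str = ""


def define_crms(
    p300: AnnotationTrack,
    tfap2a: AnnotationTrack,
    k27ac: AnnotationTrack,
    k4me1: AnnotationTrack,
    proximity_bp: int = 1000,
) -> tuple[AnnotationTrack, AnnotationTrack]:
    """Combinatorial cis-regulatory-module maps from four peak tracks.

    Active modules: p300 or TFAP2A peaks with a K27ac peak within
    ``proximity_bp`` of their nearest edges (overlap counts as distance 0).
    Active-and-primed modules additionally include the K27ac peaks that
    overlap a K4me1 peak (emitted as the K27ac intervals). Both outputs are
    sorted and merged.
    """
    bound = p300.union(tfap2a)
    active_iv = [
        (c, s, e)
        for c, s, e in bound
        if k27ac.distance_to_nearest(c, s, e) <= proximity_bp
    ]
    primed_iv = [
        (c, s, e)
        for c, s, e in k27ac
        if k4me1.distance_to_nearest(c, s, e) == 0
    ]
    active = AnnotationTrack(active_iv) if active_iv else AnnotationTrack([])
    both = AnnotationTrack(active_iv + primed_iv) if (active_iv or primed_iv) else AnnotationTrack([])
    return active, both


def bin_pvalues(stats_table: pd.DataFrame, scheme: BinningScheme) -> np.ndarray:
    """Category index (1-based, 1 = largest P) for each variant."""
    return scheme.assign(stats_table["p"].to_numpy(dtype=float))


def annotate_overlap(stats_table: pd.DataFrame, track: AnnotationTrack) -> np.ndarray:
    """Boolean in-annotation flag per variant (half-open intervals).

    Variant positions are 1-based; the corresponding 0-based point pos-1 is
    tested for membership. A variant on a chromosome absent from a
    non-empty track raises a warning-level report via the returned flags'
    companion (see ``enrichment_analysis``); here mismatches simply map to
    False but are detectable through ``track.chromosomes()``.
    """
    flags = np.zeros(len(stats_table), dtype=bool)
    track_chroms = track.chromosomes()
    unmatched = set()
    for chrom, sub in stats_table.groupby("chr", sort=False):
        chrom = str(chrom)
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
        if chrom not in track_chroms:
            if len(track):
                unmatched.add(chrom)
            continue
        flags[sub.index.to_numpy()] = track.contains(chrom, pos0)
    if unmatched:
        import warnings

        warnings.warn(
            f"chromosomes {sorted(unmatched)} absent from the annotation track"
        )
    return flags


def contingency_table(categories: np.ndarray, inside: np.ndarray, n_categories: int) -> np.ndarray:
    """(category x in/out) counts; row k-1 is category k, columns (in, out)."""
    categories = np.asarray(categories)
    inside = np.asarray(inside, dtype=bool)
    table = np.zeros((n_categories, 2), dtype=np.int64)
    for k in range(1, n_categories + 1):
        sel = categories == k
        table[k - 1, 0] = int((sel & inside).sum())
        table[k - 1, 1] = int((sel & ~inside).sum())
    return table


def trend_statistic(table: np.ndarray) -> float:
    """Signed trend Z for the proportion inside annotation across ordered
    categories (scores 1..K from largest-P to smallest-P category).

    Positive Z means the in-annotation fraction rises toward smaller
    P-value categories (enrichment). Returns nan for degenerate tables.
    """
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    scores = np.arange(1, k + 1, dtype=float)
    n_cat = table.sum(axis=1)
    n_in = table[:, 0]
    n = n_cat.sum()
    total_in = n_in.sum()
    if n == 0 or total_in == 0 or total_in == n:
        return float("nan")
    p_bar = total_in / n
    num = (scores * (n_in - n_cat * p_bar)).sum()
    var = p_bar * (1 - p_bar) * ((scores**2 * n_cat).sum() - (scores * n_cat).sum() ** 2 / n)
    if var <= 0:
        return float("nan")
    return float(num / np.sqrt(var))


def trend_enrichment_test(
    table: np.ndarray,
    scheme_name: str = "groups",
    n_regions: int = 0,
) -> EnrichmentResult:
    """One-sided Cochran-Armitage trend test on a (categories x 2) table.

    Category rows are ordered from largest-P to smallest-P; column 0 counts
    variants inside the annotation. The one-sided P is for enrichment
    (higher inside fraction at smaller P); for 2 categories the two-sided
    version coincides with the 1-df chi-square test.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError("expected a (>=2 categories) x 2 count table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    n_snps = int(table.sum())
    nonzero = int(np.count_nonzero(table.sum(axis=1)))
    if nonzero < 2 or np.count_nonzero(table) == 1:
        return EnrichmentResult(
            scheme=scheme_name, table=table, z=float("nan"), chi2=float("nan"),
            p_one_sided=float("nan"), n_regions=n_regions, n_snps=n_snps,
            reason="degenerate table",
        )
    z = trend_statistic(table)
    if not np.isfinite(z):
        return EnrichmentResult(
            scheme=scheme_name, table=table, z=z, chi2=float("nan"),
            p_one_sided=float("nan"), n_regions=n_regions, n_snps=n_snps,
            reason="degenerate table",
        )
    return EnrichmentResult(
        scheme=scheme_name,
        table=table,
        z=z,
        chi2=float(z**2),
        p_one_sided=float(stats.norm.sf(z)),
        n_regions=n_regions,
        n_snps=n_snps,
    )


def enrichment_analysis(
    stats_table: pd.DataFrame,
    track: AnnotationTrack,
    scheme: BinningScheme = GROUPS,
) -> EnrichmentResult:
    """End-to-end enrichment test: bin P-values, overlap with the track,
    build the contingency table and run the one-sided trend test."""
    categories = bin_pvalues(stats_table, scheme)
    inside = annotate_overlap(stats_table, track)
    table = contingency_table(categories, inside, scheme.n_categories)
    return trend_enrichment_test(table, scheme.name, n_regions=len(track))
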