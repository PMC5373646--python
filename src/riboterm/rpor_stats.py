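"""Relative post-ORF ribosome occupancy (RPOR).

RPOR is the average footprint density in a window 20-60 nt past the stop
codon divided by the average density within the ORF; it roughly estimates
the fraction of ribosomes continuing past the stop (readthrough or
frameshifting).  Genes are eligible when they are well separated from the
downstream gene (>= 65 nt intergenic) and sufficiently expressed in both
footprint and mRNA signal (>= 0.1 RPM/nt), so that post-ORF ribosomes can
be attributed unambiguously.  Distributions are compared with the
two-sample Kolmogorov-Smirnov test after removing RPOR = 0 genes (a zero
cannot be resolved between no recoding and insufficient depth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation import OrfRecord
from .regions import orf_values, post_orf_values
from .tracks import DensityTrack

POST_WINDOW = (20, 60)  # half-open offsets after the last stop-codon base


@dataclass(frozen=True)
class RporRecord:
    gene_id: str
    orf_mean: float   # RPM/nt, first/last 5 codons masked
    post_mean: float  # RPM/nt over the post-ORF window
    rpor: float


@dataclass(frozen=True)
class KsResult:
    d_statistic: float
    p_value: float
    n1: int
    n2: int


def eligible_genes(orfs: list[OrfRecord], fp_track: DensityTrack,
                   mrna_track: DensityTrack, min_gap: int = 65,
                   min_density: float = 0.1) -> list[OrfRecord]:
    """Genes retained for post-ORF analysis (all bounds inclusive):
    downstream_gap >= min_gap, unmasked mean footprint AND mRNA density
    over the ORF >= min_density, and stop codon not overlapped by another
    feature."""
    # inclusive bound, robust to rounding in the mean of values at the cutoff
    tol = min_density * 1e-9
    out = []
    for orf in orfs:
        if orf.overlaps_next:
            continue
        if orf.downstream_gap is None or orf.downstream_gap < min_gap:
            continue
        if float(orf_values(fp_track, orf).mean()) < min_density - tol:
            continue
        if float(orf_values(mrna_track, orf).mean()) < min_density - tol:
            continue
        out.append(orf)
    return out


def rpor(orf: OrfRecord, fp_track: DensityTrack,
         window: tuple[int, int] = POST_WINDOW,
         mask_codons: int = 5) -> RporRecord | None:
    """RPOR for one gene, or None when the ORF mean is zero.

    The post-ORF window is half-open [+20, +60) counted from the first
    base after the stop codon (40 nt); the denominator is the ORF mean
    with the first and last 5 codons masked, matching the gene-occupancy
    convention of the expression module.
    """
    m = mask_codons if orf.length > 2 * mask_codons * 3 else 0
    orf_mean = float(orf_values(fp_track, orf, mask_codons=m).mean())
    if orf_mean == 0:
        return None
    post = post_orf_values(fp_track, orf, *window)
    post_mean = float(post.mean()) if post.size else 0.0
    return RporRecord(orf.gene_id, orf_mean, post_mean, post_mean / orf_mean)


def rpor_table(orfs: list[OrfRecord], fp_track: DensityTrack,
               window: tuple[int, int] = POST_WINDOW,
               mask_codons: int = 5) -> list[RporRecord]:
    records = []
    for orf in orfs:
        rec = rpor(orf, fp_track, window, mask_codons)
        if rec is not None:
            records.append(rec)
    return records


def rpor_distribution(records, drop_zeros: bool = True) -> np.ndarray:
    """Sorted RPOR values, with zeros removed by default."""
    vals = np.asarray([r.rpor if isinstance(r, RporRecord) else float(r)
                       for r in records], dtype=float)
    if drop_zeros:
        vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("no RPOR values remain after zero removal")
    return np.sort(vals)


def ks_two_sample(a, b) -> KsResult:
    """Two-sample K-S test: D = sup |ECDF_a - ECDF_b|, two-sided
    asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("K-S test needs non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KsResult(float(res.statistic), float(res.pvalue), a.size, b.size)


def rpor_histogram(records, min_value: float = 0.2, bin_width: float = 0.2,
                   max_value: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """(bin left edges, counts) over half-open bins [lo, lo+width) for
    values >= min_value; the last bin absorbs values >= max_value so the
    total equals the number of values >= min_value."""
    vals = np.asarray([r.rpor if isinstance(r, RporRecord) else float(r)
                       for r in records], dtype=float)
    vals = vals[vals >= min_value]
    edges = np.arange(min_value, max_value + bin_width / 2, bin_width)
    counts = np.zeros(edges.size, dtype=int)
    idx = np.floor((vals - min_value) / bin_width).astype(int)
    idx = np.minimum(idx, edges.size - 1)
    for i in idx:
        counts[i] += 1
    return edges, counts
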