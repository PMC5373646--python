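"""Gene-level quantification: RPKM with 5-codon end masking, translation
efficiency, replicate averaging, overlapping-pair TE ratios, and the
two-ORF programmed-frameshift estimator.

RPKM is computed directly from RPM-normalized tracks: because the
per-million denominator of the track equals the RPKM depth denominator,
RPKM = (mean RPM/nt over the feature) * 1e3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import OrfPair, OrfRecord
from .regions import orf_values
from .tracks import DensityTrack


@dataclass
class GeneExpression:
    gene_id: str
    fp_counts: float
    fp_rpkm: float
    mrna_counts: float = np.nan
    mrna_rpkm: float = np.nan
    te: float = np.nan
    comparable: bool = False
    mask_fallback: bool = False  # ORF too short to mask; quantified unmasked


@dataclass(frozen=True)
class FrameshiftLocus:
    """A programmed-frameshift locus declared as two sub-ORF intervals
    (0-based half-open genomic), orf1 upstream of orf2 in transcription
    direction."""
    chrom: str
    strand: str
    orf1: tuple[int, int]
    orf2: tuple[int, int]


def _interval_stats(track: DensityTrack, chrom: str, strand: str,
                    start: int, end: int) -> tuple[float, float]:
    """(raw counts, RPKM) over a genomic interval of an RPM track."""
    vals = track.values(chrom, strand, start, end)
    counts = float(vals.sum()) * track.total_mass / 1e6
    rpkm = float(vals.mean()) * 1e3
    return counts, rpkm


def rpkm(orf: OrfRecord, track: DensityTrack, mask_codons: int = 5
         ) -> tuple[float, float, bool]:
    """(raw counts, RPKM, mask_fallback) over the ORF with the first and
    last ``mask_codons`` codons masked.

    ORFs too short to mask fall back to the unmasked interval with
    ``mask_fallback=True``.
    """
    if track.units != "rpm":
        raise ValueError("rpkm expects an RPM-normalized track")
    fallback = orf.length <= 2 * mask_codons * 3
    m = 0 if fallback else mask_codons
    vals = orf_values(track, orf, mask_codons=m)
    counts = float(vals.sum()) * track.total_mass / 1e6
    return counts, float(vals.mean()) * 1e3, fallback


def quantify(orfs: list[OrfRecord], fp_track: DensityTrack,
             mrna_track: DensityTrack | None = None,
             mask_codons: int = 5, min_counts: float = 100.0
             ) -> list[GeneExpression]:
    """Per-gene expression; TE defined when mRNA is supplied and nonzero.

    Genes are marked ``comparable`` only when both signals carry at least
    ``min_counts`` raw counts (the between-sample comparison gate).
    """
    out = []
    for orf in orfs:
        fp_c, fp_r, fb = rpkm(orf, fp_track, mask_codons)
        g = GeneExpression(orf.gene_id, fp_c, fp_r, mask_fallback=fb)
        if mrna_track is not None:
            g.mrna_counts, g.mrna_rpkm, _ = rpkm(orf, mrna_track, mask_codons)
            if g.mrna_rpkm > 0:
                g.te = g.fp_rpkm / g.mrna_rpkm
            g.comparable = (fp_c >= min_counts) and (g.mrna_counts >= min_counts)
        else:
            g.comparable = fp_c >= min_counts
        out.append(g)
    return out


def expression_table(expr: list[GeneExpression]) -> pd.DataFrame:
    return pd.DataFrame([vars(g) for g in expr])


def average_replicates(values) -> tuple[float, float]:
    """Arithmetic mean and SEM (= sd / sqrt(n)) across replicates.

    A single replicate yields (value, nan): the SEM is undefined.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no replicate values")
    if v.size == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def frameshift_percent(locus: FrameshiftLocus, track: DensityTrack) -> float:
    """Percent frameshifting at a two-ORF locus.

    100 * RPKM(orf2) / RPKM(orf1), each computed without end masking on
    the declared sub-intervals.  The upstream sub-ORF is typically too
    short for end masking (prfB's first ORF is ~26 codons), and the ratio
    is depth-invariant.
    """
    if track.units != "rpm":
        raise ValueError("frameshift_percent expects an RPM-normalized track")
    _, r1 = _interval_stats(track, locus.chrom, locus.strand, *locus.orf1)
    _, r2 = _interval_stats(track, locus.chrom, locus.strand, *locus.orf2)
    if r1 == 0:
        raise ValueError("upstream sub-ORF has zero density")
    return 100.0 * r2 / r1


def pair_te_ratio(pair: OrfPair, te_map: dict[str, float],
                  flag_below: float = 0.5) -> tuple[float, bool] | None:
    """downstream TE / upstream TE for an overlapping ORF pair.

    Returns (ratio, flagged) with ``flagged`` marking pairs below
    ``flag_below`` (the stratum where downstream translation depends on the
    upstream ribosome).  Pairs with an undefined or zero upstream TE are
    skipped (None).
    """
    up = te_map.get(pair.upstream.gene_id)
    down = te_map.get(pair.downstream.gene_id)
    if up is None or down is None or not np.isfinite(up) or not np.isfinite(down) \
            or up <= 0:
        return None
    ratio = down / up
    return ratio, ratio < flag_below


def pair_te_ratios(pairs: list[OrfPair], te_map: dict[str, float],
                   flag_below: float = 0.5) -> pd.DataFrame:
    rows = []
    for p in pairs:
        res = pair_te_ratio(p, te_map, flag_below)
        if res is None:
            continue
        rows.append({"upstream": p.upstream.gene_id,
                     "downstream": p.downstream.gene_id,
                     "overlap_type": p.overlap_type,
                     "te_ratio": res[0], "flagged": res[1]})
    return pd.DataFrame(rows, columns=["upstream", "downstream", "overlap_type",
                                       "te_ratio", "flagged"])
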