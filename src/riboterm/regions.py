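"""Gene-relative views of density tracks.

All accessors return signal in the gene's 5'->3' (transcription)
direction, reading the strand the gene lives on.
"""

from __future__ import annotations

import numpy as np

from .annotation import OrfRecord
from .tracks import DensityTrack


def orf_values(track: DensityTrack, orf: OrfRecord,
               mask_codons: int = 0) -> np.ndarray:
    """Per-nt signal over the ORF, optionally masking the first and last
    ``mask_codons`` codons (removes initiation/termination peaks)."""
    m = 3 * mask_codons
    if orf.length <= 2 * m:
        raise ValueError(f"{orf.gene_id}: ORF too short to mask {mask_codons} codons")
    # mask is symmetric, so the genomic slice is the same on either strand
    return track.values(orf.chrom, orf.strand, orf.start + m, orf.end - m,
                        reverse=(orf.strand == "-"))


def stop_aligned_values(track: DensityTrack, orf: OrfRecord,
                        lo: int = -100, hi: int = 60) -> np.ndarray | None:
    """Signal at offsets ``lo..hi`` (inclusive) relative to the first base
    of the stop codon (offset 0).  Returns None when the window extends
    beyond the chromosome."""
    first = orf.stop_first_base()
    n = track.chrom_lengths[orf.chrom]
    if orf.strand == "+":
        a, b = first + lo, first + hi + 1
        if a < 0 or b > n:
            return None
        return track.values(orf.chrom, "+", a, b)
    a, b = first - hi, first - lo + 1
    if a < 0 or b > n:
        return None
    return track.values(orf.chrom, "-", a, b, reverse=True)


def post_orf_values(track: DensityTrack, orf: OrfRecord,
                    start_off: int, end_off: int) -> np.ndarray:
    """Signal at half-open offsets [start_off, end_off) counted from the
    first base after the stop codon; clipped at the chromosome boundary."""
    n = track.chrom_lengths[orf.chrom]
    if orf.strand == "+":
        a, b = orf.end + start_off, orf.end + end_off
        return track.values(orf.chrom, "+", max(a, 0), min(b, n))
    a, b = orf.start - end_off, orf.start - start_off
    return track.values(orf.chrom, "-", max(a, 0), min(b, n), reverse=True)


def post_orf_raw_counts(track: DensityTrack, orf: OrfRecord,
                        start_off: int, end_off: int) -> float:
    """Raw weighted counts over a post-ORF offset window."""
    n = track.chrom_lengths[orf.chrom]
    if orf.strand == "+":
        a, b = orf.end + start_off, orf.end + end_off
        return track.raw_counts(orf.chrom, "+", max(a, 0), min(b, n))
    a, b = orf.start - end_off, orf.start - start_off
    return track.raw_counts(orf.chrom, "-", max(a, 0), min(b, n))
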