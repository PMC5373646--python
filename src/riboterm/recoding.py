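"""Automated detection of recoding (stop-codon readthrough / frameshift).

If the ribosomes seen downstream of an annotated stop codon are actively
translating, their density must fall after the next stop codon in the
reading frame being translated.  The detector therefore enumerates every
stop codon in all three frames of the post-ORF region, scores the density
drop across each (mean density after / mean density before), and
classifies genes:

* ``likely``        -- a strong drop (ratio <= threshold), no confounders
* ``possible``      -- a strong drop, but confounding signal is present
* ``non-recoding``  -- no candidate shows a strong drop
* ``unclassifiable``-- too few post-ORF reads to judge
* ``misannotation-suspect`` -- a user-supplied downstream feature accounts
  for essentially all post-ORF signal

Frames follow offset mod 3: 0 -> in-frame readthrough, 1 -> +1 frameshift,
2 -> -1 frameshift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeSequence, OrfRecord, STOP_CODONS, post_orf_sequence
from .regions import post_orf_raw_counts, post_orf_values
from .tracks import DensityTrack

_FRAME = {0: 0, 1: +1, 2: -1}
_SD_MOTIF = re.compile("GGAGG")
_STARTS = ("ATG", "GTG")


@dataclass(frozen=True)
class StopCandidate:
    offset: int  # nt from the first base after the annotated stop codon
    frame: int   # {0, +1, -1}
    codon: str


@dataclass
class RecodingCall:
    gene_id: str
    best_candidate: StopCandidate | None
    drop_ratio: float
    label: str
    flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: dict[str, int]
    expected: dict[str, float]
    chi2: float
    df: int
    p_value: float


def candidate_stops(post_orf_seq: str) -> list[StopCandidate]:
    """Every stop-codon occurrence in the post-ORF sequence, all frames.

    The sequence must be in transcription direction starting at the first
    base after the annotated stop codon.  Sorted by offset.
    """
    seq = post_orf_seq.upper()
    out = []
    for off in range(len(seq) - 2):
        codon = seq[off:off + 3]
        if codon in STOP_CODONS:
            out.append(StopCandidate(off, _FRAME[off % 3], codon))
    return out


def drop_score(post_values: np.ndarray, offset: int,
               pre_window: int = 30, post_window: int = 30) -> float | None:
    """Density drop across a candidate stop within the post-ORF region.

    ratio = mean over [offset+3, offset+3+post_window) divided by mean
    over [max(0, offset-pre_window), offset), both clipped to the region.
    None when the pre-window mean is 0 or either window is empty.
    """
    pre = post_values[max(0, offset - pre_window):offset]
    post = post_values[offset + 3:offset + 3 + post_window]
    if pre.size == 0 or post.size == 0:
        return None
    pre_mean = float(pre.mean())
    if pre_mean == 0:
        return None
    return float(post.mean()) / pre_mean


def drop_score_for_gene(track: DensityTrack, orf: OrfRecord,
                        candidate: StopCandidate, pre_window: int = 30,
                        post_window: int = 30) -> float | None:
    """`drop_score` evaluated on a gene's post-ORF track signal."""
    region_len = orf.downstream_gap if orf.downstream_gap else 0
    vals = post_orf_values(track, orf, 0, region_len)
    return drop_score(vals, candidate.offset, pre_window, post_window)


def _interval_overlap(intervals, chrom: str, lo: int, hi: int) -> bool:
    return any(c == chrom and s < hi and e > lo for c, s, e in intervals)


def _post_region_interval(orf: OrfRecord, region_len: int) -> tuple[int, int]:
    if orf.strand == "+":
        return orf.end, orf.end + region_len
    return orf.start - region_len, orf.start


def _sd_proximal(seq: str, max_spacer: int = 15, min_spacer: int = 4) -> bool:
    """Shine-Dalgarno-like motif (GGAGG, the complement of the 16S anti-SD
    CCUCC) followed by a start codon 4-15 nt downstream: post-ORF signal
    may be initiation at an unannotated downstream gene."""
    for m in _SD_MOTIF.finditer(seq.upper()):
        for spacer in range(min_spacer, max_spacer + 1):
            s = m.end() + spacer
            if seq[s:s + 3] in _STARTS:
                return True
    return False


def classify_gene(orf: OrfRecord, genome: dict[str, GenomeSequence],
                  track: DensityTrack,
                  confounders: dict[str, list[tuple[str, int, int]]] | None = None,
                  drop_threshold: float = 0.3,
                  min_pre_density: float = 0.2,
                  min_region_counts: float = 10.0,
                  pre_window: int = 30, post_window: int = 30) -> RecodingCall:
    """Classify one gene's post-ORF region.

    The post-ORF region runs from the base after the stop codon to the
    downstream feature (``downstream_gap`` nt).  The best candidate is the
    stop with the minimal drop ratio among candidates whose pre-stop mean
    density is at least ``min_pre_density`` RPM/nt.  Confounder intervals
    (REP elements, sRNAs, unannotated features...) are supplied per class
    name; any overlap with the post-ORF region flags the call.  A special
    ``"downstream_features"`` interval set that covers >= 90% of the
    post-ORF signal mass marks the gene ``misannotation-suspect``.
    """
    if track.units != "rpm":
        raise ValueError("classify_gene expects an RPM-normalized track")
    if orf.downstream_gap is None:
        raise ValueError(f"{orf.gene_id}: downstream_gap not computed")
    confounders = confounders or {}
    region_len = orf.downstream_gap
    raw = post_orf_raw_counts(track, orf, 0, region_len)
    if raw < min_region_counts:
        return RecodingCall(orf.gene_id, None, float("nan"), "unclassifiable",
                            {"low-reads"})

    vals = post_orf_values(track, orf, 0, region_len)
    seq = post_orf_sequence(orf, genome, region_len)
    lo, hi = _post_region_interval(orf, region_len)

    # misannotation: user-declared downstream features explain the signal
    feats = confounders.get("downstream_features", [])
    if feats and vals.sum() > 0:
        covered = np.zeros(region_len, dtype=bool)
        for c, s, e in feats:
            if c != orf.chrom:
                continue
            a, b = max(s, lo) - lo, min(e, hi) - lo
            if b > a:
                if orf.strand == "+":
                    covered[a:b] = True
                else:  # vals are in transcription direction
                    covered[region_len - b:region_len - a] = True
        if vals[covered].sum() / vals.sum() >= 0.9:
            return RecodingCall(orf.gene_id, None, float("nan"),
                                "misannotation-suspect", {"user-interval-overlap"})

    best, best_ratio = None, float("inf")
    for cand in candidate_stops(seq):
        if cand.offset + 3 > region_len:
            continue
        pre = vals[max(0, cand.offset - pre_window):cand.offset]
        if pre.size == 0 or float(pre.mean()) < min_pre_density:
            continue
        ratio = drop_score(vals, cand.offset, pre_window, post_window)
        if ratio is not None and ratio < best_ratio:
            best, best_ratio = cand, ratio

    flags: set[str] = set()
    for name, intervals in confounders.items():
        if name == "downstream_features":
            continue
        if _interval_overlap(intervals, orf.chrom, lo, hi):
            flags.add("user-interval-overlap")
    if best is not None and region_len - (best.offset + 3) < post_window:
        flags.add("downstream-feature")  # drop window truncated by next gene
    if _sd_proximal(seq):
        flags.add("SD-proximal")

    if best is None or not best_ratio <= drop_threshold:
        return RecodingCall(orf.gene_id, best,
                            best_ratio if best is not None else float("nan"),
                            "non-recoding", flags)
    label = "likely" if not flags else "possible"
    return RecodingCall(orf.gene_id, best, best_ratio, label, flags)


def classify_genes(orfs: list[OrfRecord], genome, track, **kwargs
                   ) -> list[RecodingCall]:
    return [classify_gene(o, genome, track, **kwargs) for o in orfs]


def calls_table(calls: list[RecodingCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({"gene_id": c.gene_id, "label": c.label,
                     "drop_ratio": c.drop_ratio,
                     "offset": c.best_candidate.offset if c.best_candidate else -1,
                     "frame": c.best_candidate.frame if c.best_candidate else 0,
                     "codon": c.best_candidate.codon if c.best_candidate else "",
                     "flags": ",".join(sorted(c.flags))})
    return pd.DataFrame(rows, columns=["gene_id", "label", "drop_ratio",
                                       "offset", "frame", "codon", "flags"])


def enrichment_chi2(stop_codons, genome_freqs: dict[str, float]
                    ) -> EnrichmentResult:
    """Pearson chi-square test of stop-codon usage among recoding calls
    against genome-wide stop-codon frequencies.

    ``stop_codons`` is the annotated stop codon of each called gene
    (DNA or RNA alphabet); expected counts are n * frequency.
    """
    codons = [c.replace("U", "T") for c in stop_codons]
    freqs = {k.replace("U", "T"): v for k, v in genome_freqs.items()}
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError("genome stop-codon frequencies must sum to 1")
    n = len(codons)
    if n == 0:
        raise ValueError("no recoding calls to test")
    observed = {c: codons.count(c) for c in STOP_CODONS}
    expected = {c: n * freqs[c] for c in STOP_CODONS}
    if any(e == 0 for e in expected.values()):
        raise ValueError("expected count of 0 for some stop codon")
    obs = np.array([observed[c] for c in STOP_CODONS], dtype=float)
    exp = np.array([expected[c] for c in STOP_CODONS], dtype=float)
    chi2, p = stats.chisquare(obs, f_exp=exp)
    return EnrichmentResult(observed, expected, float(chi2), 2, float(p))
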