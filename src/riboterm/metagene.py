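"""Stop-codon-aligned metagene profiles.

Each gene's density over the window [-100, +60] nt around the first base
of its stop codon is normalized by its own mean density over the upstream
offsets [-100, -70] (31 nt, inclusive), making genes of different
expression comparable; the profile is the per-offset median across genes.
Two gene filters apply: a minimum raw read count in the normalization
window, and a minimum distance to the downstream coding frame so that the
post-stop part of the window is not contaminated by the next gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import OrfRecord
from .regions import stop_aligned_values
from .tracks import DensityTrack

PLOT_WINDOW = (-100, 60)
NORM_WINDOW = (-100, -70)
STOP_PEAK_WINDOW = (-2, 4)


@dataclass
class MetageneProfile:
    """Per-offset median normalized density for one stratum of genes."""

    offsets: np.ndarray
    median_density: np.ndarray
    n_genes: int
    stratum: str = "all"
    stderr: np.ndarray | None = None  # across replicates, after combining

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets,
                           "median_density": self.median_density})
        df["stderr"] = self.stderr if self.stderr is not None else np.nan
        df["n_genes"] = self.n_genes
        df["stratum"] = self.stratum
        return df


def gene_normalized_window(orf: OrfRecord, track: DensityTrack,
                           window: tuple[int, int] = PLOT_WINDOW,
                           norm_window: tuple[int, int] = NORM_WINDOW
                           ) -> np.ndarray | None:
    """Stop-aligned density normalized to the gene's upstream window mean.

    Returns None (gene ineligible) when the window leaves the chromosome,
    when the stop-aligned upstream span does not fit inside the ORF, or
    when the normalization-window mean is 0 (the division is never done).
    """
    lo, hi = window
    if orf.length < -lo + 3:      # upstream offsets must stay inside the ORF
        return None
    vals = stop_aligned_values(track, orf, lo, hi)
    if vals is None:
        return None
    nlo, nhi = norm_window
    norm = vals[nlo - lo: nhi - lo + 1].mean()
    if norm == 0:
        return None
    return vals / norm


def metagene_profile(orfs: list[OrfRecord], track: DensityTrack,
                     min_window_counts: float = 1.0,
                     min_downstream_gap: int = 50,
                     count_filter: bool = True,
                     gap_filter: bool = True,
                     stratum: str = "all",
                     window: tuple[int, int] = PLOT_WINDOW,
                     norm_window: tuple[int, int] = NORM_WINDOW
                     ) -> MetageneProfile:
    """Median stop-aligned profile across genes surviving the filters.

    Filters (individually switchable): raw weighted counts in the
    normalization window >= ``min_window_counts``, and
    ``downstream_gap >= min_downstream_gap``.  The track must be RPM
    normalized; counts for the filter are recovered from the track's raw
    mass so the filter operates on sequencing counts, not on RPM.
    """
    if track.units != "rpm":
        raise ValueError("metagene_profile expects an RPM-normalized track")
    lo, hi = window
    nlo, nhi = norm_window
    attrition = {"total": len(orfs), "gap": 0, "counts": 0, "window": 0, "norm": 0}
    rows = []
    for orf in orfs:
        if gap_filter:
            if orf.downstream_gap is None or orf.downstream_gap < min_downstream_gap:
                attrition["gap"] += 1
                continue
        vals = stop_aligned_values(track, orf, lo, hi)
        if vals is None or orf.length < -lo + 3:
            attrition["window"] += 1
            continue
        window_vals = vals[nlo - lo: nhi - lo + 1]
        if count_filter:
            raw = window_vals.sum() * track.total_mass / 1e6
            if raw < min_window_counts:
                attrition["counts"] += 1
                continue
        norm = window_vals.mean()
        if norm == 0:
            attrition["norm"] += 1
            continue
        rows.append(vals / norm)
    if not rows:
        raise ValueError(f"no genes survive metagene filters (attrition: {attrition})")
    stacked = np.vstack(rows)
    return MetageneProfile(offsets=np.arange(lo, hi + 1),
                           median_density=np.median(stacked, axis=0),
                           n_genes=len(rows), stratum=stratum)


def stratify(orfs: list[OrfRecord],
             te: dict[str, float] | None = None,
             top_decile: float = 0.10) -> dict[str, list[OrfRecord]]:
    """Partition genes by stop codon and by stop codon + fourth base.

    Strata are named with RNA alphabet ("UAA", ..., "UGAA", ...).  When a
    translation-efficiency map is supplied, a "top-TE decile" stratum with
    the top 10% most efficiently translated genes is added.
    """
    out: dict[str, list[OrfRecord]] = {}
    for codon in ("TAA", "TAG", "TGA"):
        rna = codon.replace("T", "U")
        out[rna] = [o for o in orfs if o.stop_codon == codon]
        for fourth in "ACGT":
            out[rna + fourth.replace("T", "U")] = \
                [o for o in orfs if o.stop_codon == codon and o.fourth_base == fourth]
    if te is not None:
        scored = [o for o in orfs if o.gene_id in te]
        scored.sort(key=lambda o: te[o.gene_id], reverse=True)
        k = max(1, int(round(top_decile * len(scored))))
        out["top-TE decile"] = scored[:k]
    return out


def combine_replicates(profiles: list[MetageneProfile]) -> MetageneProfile:
    """Per-offset mean of replicate medians; stderr = sd / sqrt(n)."""
    if not profiles:
        raise ValueError("no profiles to combine")
    first = profiles[0]
    for p in profiles[1:]:
        if p.stratum != first.stratum or not np.array_equal(p.offsets, first.offsets):
            raise ValueError("replicate profiles differ in stratum or offsets")
    stacked = np.vstack([p.median_density for p in profiles])
    n = len(profiles)
    stderr = (stacked.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 \
        else np.zeros(first.offsets.size)
    return MetageneProfile(offsets=first.offsets.copy(),
                           median_density=stacked.mean(axis=0),
                           n_genes=int(round(np.mean([p.n_genes for p in profiles]))),
                           stratum=first.stratum, stderr=stderr)


def stop_occupancy(profile: MetageneProfile,
                   window: tuple[int, int] = STOP_PEAK_WINDOW,
                   mode: str = "max") -> float:
    """Scalar stop-codon occupancy of a profile.

    ``mode="max"``: maximum of the median profile over offsets [-2, +4]
    (captures the center-mapped stop peak); ``mode="mean"``: mean over the
    three stop-codon offsets [0, 2].
    """
    lo = profile.offsets[0]
    if mode == "max":
        a, b = window
        return float(profile.median_density[a - lo: b - lo + 1].max())
    if mode == "mean":
        return float(profile.median_density[0 - lo: 3 - lo].mean())
    raise ValueError("mode must be 'max' or 'mean'")


def stop_occupancy_ratio(profile_a: MetageneProfile, profile_b: MetageneProfile,
                         window: tuple[int, int] = STOP_PEAK_WINDOW,
                         mode: str = "max") -> float:
    """Fold change in stop-codon occupancy between two profiles."""
    if profile_a.stratum != profile_b.stratum or \
            not np.array_equal(profile_a.offsets, profile_b.offsets):
        raise ValueError("profiles differ in stratum or offsets")
    denom = stop_occupancy(profile_b, window, mode)
    if denom == 0:
        raise ValueError("reference profile has zero stop occupancy")
    return stop_occupancy(profile_a, window, mode) / denom
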