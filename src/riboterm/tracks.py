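"""Per-nucleotide density tracks from aligned ribosome-footprint reads.

Footprint reads are converted to signal by center mapping: each read is
trimmed by 10 nt on each side and the remaining interval receives uniform
weight summing to 1, which compensates for the imprecise MNase trimming of
bacterial footprints.  A 3'-end mapping and a full-read coverage mapping
(for fragmented mRNA-seq) are provided as alternatives.  Tracks are
strand-separated and carry a normalization state (raw weighted counts vs
reads-per-million per nucleotide).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

TRIM = 10  # nt trimmed from each read end before center mapping


@dataclass(frozen=True)
class AlignedRead:
    chrom: str
    left: int       # leftmost aligned base, 0-based
    length: int     # aligned span in nt
    strand: str     # '+' or '-'
    mismatches: int = 0
    multimapped: bool = False

    def __post_init__(self):
        if self.length < 1 or self.left < 0:
            raise ValueError("read must have length >= 1 and left >= 0")


class DensityTrack:
    """Per-(chrom, strand), per-nucleotide nonnegative signal.

    ``units`` is ``"raw"`` (weighted read counts) or ``"rpm"`` (per-million
    normalized).  ``total_mass`` is always the raw weighted mass, so raw
    counts can be recovered from an RPM track (raw = rpm * total_mass/1e6).
    """

    def __init__(self, chrom_lengths: dict[str, int], units: str = "raw",
                 total_mass: float | None = None):
        if units not in ("raw", "rpm"):
            raise ValueError("units must be 'raw' or 'rpm'")
        self.chrom_lengths = dict(chrom_lengths)
        self.units = units
        self._total_mass = total_mass
        self._data: dict[tuple[str, str], np.ndarray] = {}
        for chrom, n in self.chrom_lengths.items():
            for strand in "+-":
                self._data[(chrom, strand)] = np.zeros(n, dtype=float)

    def array(self, chrom: str, strand: str) -> np.ndarray:
        return self._data[(chrom, strand)]

    @property
    def total_mass(self) -> float:
        if self._total_mass is None:
            return float(sum(a.sum() for a in self._data.values()))
        return self._total_mass

    def freeze_mass(self) -> None:
        """Record the current raw mass (call after accumulation)."""
        self._total_mass = float(sum(a.sum() for a in self._data.values()))

    def copy(self) -> "DensityTrack":
        t = DensityTrack(self.chrom_lengths, self.units, self._total_mass)
        for k, a in self._data.items():
            t._data[k] = a.copy()
        return t

    def scale(self, factor: float) -> "DensityTrack":
        """Uniformly rescaled copy (models a change of sequencing depth)."""
        t = self.copy()
        for a in t._data.values():
            a *= factor
        if t._total_mass is not None:
            t._total_mass *= factor
        return t

    def values(self, chrom: str, strand: str, start: int, stop: int,
               reverse: bool = False) -> np.ndarray:
        v = self._data[(chrom, strand)][start:stop]
        return v[::-1] if reverse else v

    def raw_counts(self, chrom: str, strand: str, start: int, stop: int) -> float:
        """Raw weighted counts over a genomic slice, whatever the units."""
        s = float(self._data[(chrom, strand)][start:stop].sum())
        if self.units == "rpm":
            return s * self.total_mass / 1e6
        return s


def filter_reads(reads: Iterable[AlignedRead], min_len: int = 20,
                 max_len: int = 40, max_mm: int = 2) -> Iterator[AlignedRead]:
    """Retain uniquely-mapping reads with length in [min_len, max_len]
    (inclusive) and at most ``max_mm`` mismatches."""
    for r in reads:
        if min_len <= r.length <= max_len and r.mismatches <= max_mm \
                and not r.multimapped:
            yield r


def center_map(read: AlignedRead, keep_short: bool = True) -> list[tuple[int, float]]:
    """Center-mapped (position, weight) list for one read; weights sum to 1.

    The read is trimmed by 10 nt on each side; the remaining w = length-20
    positions each receive 1/w.  Reads of length 20 (trimmed width 0) go to
    their midpoint with weight 1 unless ``keep_short=False``, which drops
    them instead.
    """
    w = read.length - 2 * TRIM
    if w >= 1:
        lo = read.left + TRIM
        return [(lo + i, 1.0 / w) for i in range(w)]
    if not keep_short:
        return []
    return [(read.left + read.length // 2, 1.0)]


def three_prime_map(read: AlignedRead) -> tuple[int, float]:
    """3'-end position of the read with weight 1."""
    if read.strand == "+":
        return read.left + read.length - 1, 1.0
    return read.left, 1.0


def coverage_map(read: AlignedRead) -> list[tuple[int, float]]:
    """Full-read coverage: each covered nt gets 1/length (mRNA-seq mapping)."""
    w = 1.0 / read.length
    return [(read.left + i, w) for i in range(read.length)]


def build_track(reads: Iterable[AlignedRead], chrom_lengths: dict[str, int],
                mapping: str = "center", keep_short: bool = True) -> DensityTrack:
    """Accumulate mapped read weights into a raw DensityTrack.

    ``mapping`` is one of "center", "threeprime", "coverage".  Each read
    contributes total weight 1 to its own strand only, so the raw mass of
    the track equals the number of mapped reads (minus dropped length-20
    reads when ``keep_short=False``).
    """
    track = DensityTrack(chrom_lengths, units="raw")
    for r in reads:
        arr = track.array(r.chrom, r.strand)
        if mapping == "center":
            placed = center_map(r, keep_short=keep_short)
        elif mapping == "threeprime":
            placed = [three_prime_map(r)]
        elif mapping == "coverage":
            placed = coverage_map(r)
        else:
            raise ValueError(f"unknown mapping {mapping!r}")
        for pos, wt in placed:
            arr[pos] += wt
    track.freeze_mass()
    return track


def normalize_per_million(track: DensityTrack) -> DensityTrack:
    """Scale a raw track by 1e6 / total mass; units become RPM per nt."""
    if track.units == "rpm":
        raise ValueError("track is already per-million normalized")
    mass = track.total_mass
    if mass <= 0:
        raise ValueError("empty track: total mass is 0")
    out = track.copy()
    for a in out._data.values():
        a *= 1e6 / mass
    out.units = "rpm"
    out._total_mass = mass
    return out


# --- SAM / tabular read input -------------------------------------------------

def read_sam(path: str, min_mapq_unique: int = 1) -> Iterator[AlignedRead]:
    """Yield AlignedRead records from a SAM/BAM file.

    Mismatches come from the NM tag (0 when absent).  A read is treated as
    multimapped when it is flagged secondary/supplementary, carries NH > 1,
    or has mapping quality below ``min_mapq_unique``.
    """
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            multi = (rec.is_secondary or rec.is_supplementary
                     or (rec.has_tag("NH") and rec.get_tag("NH") > 1)
                     or rec.mapping_quality < min_mapq_unique)
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            yield AlignedRead(rec.reference_name, rec.reference_start,
                              rec.reference_length or rec.query_length,
                              "-" if rec.is_reverse else "+",
                              mismatches=int(nm), multimapped=bool(multi))


def read_tsv_reads(path: str) -> Iterator[AlignedRead]:
    """Plain tabular read dialect: chrom, left, length, strand, mm, multi."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, left, length, strand, mm, multi = line.split("\t")
            yield AlignedRead(chrom, int(left), int(length), strand,
                              int(mm), multi.strip() in ("1", "True", "true"))


def write_tsv_reads(reads: Iterable[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tleft\tlength\tstrand\tmismatches\tmultimapped\n")
        for r in reads:
            fh.write(f"{r.chrom}\t{r.left}\t{r.length}\t{r.strand}\t"
                     f"{r.mismatches}\t{int(r.multimapped)}\n")


# --- wiggle / bedGraph text I/O ----------------------------------------------
# One file per strand; a comment header carries the normalization state so
# that a write->read round trip restores the track exactly.

def _header(track: DensityTrack) -> str:
    return (f"#riboterm units={track.units} total_mass={track.total_mass!r}\n")


def write_wiggle(track: DensityTrack, strand: str, path: str) -> None:
    """variableStep wiggle (1-based positions) for one strand."""
    with open(path, "w") as fh:
        fh.write(_header(track))
        for chrom in sorted(track.chrom_lengths):
            arr = track.array(chrom, strand)
            nz = np.nonzero(arr)[0]
            fh.write(f"variableStep chrom={chrom}\n")
            for i in nz:
                fh.write(f"{i + 1} {float(arr[i])!r}\n")


def read_wiggle(path: str, strand: str, chrom_lengths: dict[str, int],
                into: DensityTrack | None = None) -> DensityTrack:
    track = into if into is not None else DensityTrack(chrom_lengths)
    chrom = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#riboterm"):
                fields = dict(p.split("=", 1) for p in line.split()[1:])
                track.units = fields["units"]
                track._total_mass = float(fields["total_mass"])
                continue
            if line.startswith("variableStep"):
                chrom = line.split("chrom=")[1].split()[0]
                continue
            if not line.strip() or line.startswith(("track", "#")):
                continue
            pos, val = line.split()
            track.array(chrom, strand)[int(pos) - 1] = float(val)
    return track


def write_bedgraph(track: DensityTrack, strand: str, path: str) -> None:
    """bedGraph (0-based half-open runs) for one strand."""
    with open(path, "w") as fh:
        fh.write(_header(track))
        for chrom in sorted(track.chrom_lengths):
            arr = track.array(chrom, strand)
            if arr.size == 0:
                continue
            # run-length encode
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(arr[s])!r}\n")


def read_bedgraph(path: str, strand: str, chrom_lengths: dict[str, int],
                  into: DensityTrack | None = None) -> DensityTrack:
    track = into if into is not None else DensityTrack(chrom_lengths)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#riboterm"):
                fields = dict(p.split("=", 1) for p in line.split()[1:])
                track.units = fields["units"]
                track._total_mass = float(fields["total_mass"])
                continue
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, val = line.split()
            track.array(chrom, strand)[int(s):int(e)] = float(val)
    return track
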