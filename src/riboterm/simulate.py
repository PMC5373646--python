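"""Synthetic genomes, annotations and density tracks with known truth.

The generator emulates the features of bacterial ribosome-profiling data
that the termination analyses consume: per-gene expression heterogeneity
(log-normal), per-nucleotide dwell variation (gamma, mean 1), an elevated
dwell at the stop codon (pause factor s), post-ORF translation extensions
(readthrough in frame 0 or +/-1 frameshifts) that plateau at a fraction f
of the ORF density and terminate at a planted downstream stop codon, and
Poisson count noise.  Every quantity is recorded in a truth table so each
pipeline stage can be checked against known parameters.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .annotation import (GenomeSequence, OrfRecord, STOP_CODONS, compute_gaps,
                         revcomp)
from .tracks import TRIM, AlignedRead, DensityTrack

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in STOP_CODONS]
# residue of the planted-stop offset (mod 3) for each extension frame
_FRAME_RESIDUE = {0: 0, +1: 1, -1: 2}


@dataclass
class SimParams:
    """Study conditions for the generator.

    Defaults describe a small E. coli-like cohort: 200 genes of 100-400
    codons, intergenic gaps of 100-220 nt, stop-codon usage 0.62/0.09/0.29
    (TAA/TAG/TGA), log-normal expression with mean 2 expected counts per
    nt (sigma_ln 0.8), gamma dwell noise of shape 5 (mean 1), a 2-fold
    stop-codon pause, and Poisson count noise.  ``readthrough_fraction``
    is the per-gene fraction f of ribosomes continuing past the stop;
    ``recoding_fraction`` is the fraction of genes carrying a planted
    extension when f > 0.  Planted stops sit 60-90 nt past the ORF
    (recoding genes draw gaps of at least 120 nt so the element plus a
    30 nt post-drop window fits in the intergenic region).
    """

    n_genes: int = 200
    orf_codon_range: tuple[int, int] = (100, 400)
    gap_range: tuple[int, int] = (100, 220)
    stop_freqs: dict[str, float] = field(
        default_factory=lambda: {"TAA": 0.62, "TAG": 0.09, "TGA": 0.29})
    expression_mean: float = 2.0   # expected counts per nt
    expression_sigma: float = 0.8  # sigma of log expression
    dwell_shape: float | None = 5.0  # gamma shape (mean 1); None = no dwell noise
    stop_pause_factor: float = 2.0
    readthrough_fraction: float = 0.0
    recoding_fraction: float = 1.0
    extension_frame: int = 0       # {0, +1, -1}
    extension_offset_range: tuple[int, int] = (60, 90)
    count_noise: str = "poisson"   # {"poisson", "none"}
    minus_strand_fraction: float = 0.5
    read_length_range: tuple[int, int] = (20, 40)
    seed: int = 0
    chrom_id: str = "simchrom"

    def __post_init__(self):
        if abs(sum(self.stop_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("stop_freqs must sum to 1")
        if not 0.0 <= self.readthrough_fraction <= 1.0:
            raise ValueError("readthrough_fraction must be in [0, 1]")
        if self.stop_pause_factor < 1.0:
            raise ValueError("stop_pause_factor must be >= 1")
        if self.dwell_shape is not None and self.dwell_shape <= 0:
            raise ValueError("dwell_shape must be > 0")
        if self.extension_frame not in _FRAME_RESIDUE:
            raise ValueError("extension_frame must be 0, +1 or -1")
        if self.count_noise not in ("poisson", "none"):
            raise ValueError("count_noise must be 'poisson' or 'none'")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _draw_stop(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    codons = list(freqs)
    return codons[rng.choice(len(codons), p=[freqs[c] for c in codons])]


def _post_sequence(rng: np.random.Generator, gap: int, params: SimParams,
                   ext_offset: int | None) -> str:
    """Intergenic sequence; for recoding genes the extension frame has no
    stop before ``ext_offset`` and a planted stop codon exactly there."""
    seq = list(_random_seq(rng, gap))
    if ext_offset is not None:
        r = _FRAME_RESIDUE[params.extension_frame]
        for p in range(r, ext_offset, 3):
            if "".join(seq[p:p + 3]) in STOP_CODONS:
                seq[p:p + 3] = list(_SENSE_CODONS[rng.integers(len(_SENSE_CODONS))])
        seq[ext_offset:ext_offset + 3] = list(_draw_stop(rng, params.stop_freqs))
    return "".join(seq)


def simulate_genome(params: SimParams
                    ) -> tuple[dict[str, GenomeSequence], list[OrfRecord],
                               pd.DataFrame]:
    """Random genome with planted non-overlapping ORFs and a truth table.

    Returns (genome dict, ORF records with gaps computed, truth).  Truth
    columns: gene_id, strand, expression, pause, readthrough_f, ext_frame,
    ext_offset (-1 when no extension), gap, orf_len.
    """
    rng = np.random.default_rng(params.seed)
    gap_lo, gap_hi = params.gap_range
    if gap_hi < 120 and params.readthrough_fraction > 0:
        raise ValueError("gap_range too small to plant extensions (need >= 120)")

    parts = [_random_seq(rng, 50)]
    pos = 50
    orfs: list[OrfRecord] = []
    truth_rows = []
    n_digits = len(str(params.n_genes))
    for i in range(params.n_genes):
        gene_id = f"g{i:0{n_digits}d}"
        strand = "-" if rng.random() < params.minus_strand_fraction else "+"
        n_codons = int(rng.integers(params.orf_codon_range[0],
                                    params.orf_codon_range[1] + 1))
        recoding = (params.readthrough_fraction > 0
                    and rng.random() < params.recoding_fraction)
        if recoding:
            gap = int(rng.integers(max(gap_lo, 120), gap_hi + 1))
            off_lo, off_hi = params.extension_offset_range
            off_hi = min(off_hi, gap - 33)
            d0 = int(rng.integers(off_lo, off_hi - 1))
            ext_offset = d0 + (_FRAME_RESIDUE[params.extension_frame] - d0) % 3
        else:
            gap = int(rng.integers(gap_lo, gap_hi + 1))
            ext_offset = None

        stop = _draw_stop(rng, params.stop_freqs)
        body = [_SENSE_CODONS[j]
                for j in rng.integers(len(_SENSE_CODONS), size=n_codons - 2)]
        orf_seq = "ATG" + "".join(body) + stop
        post_seq = _post_sequence(rng, gap, params, ext_offset)
        block_tx = orf_seq + post_seq
        L = len(orf_seq)
        if strand == "+":
            start, end = pos, pos + L
            parts.append(block_tx)
        else:
            start, end = pos + gap, pos + gap + L
            parts.append(revcomp(block_tx))
        pos += len(block_tx)
        orfs.append(OrfRecord(gene_id, params.chrom_id, strand, start, end))

        e = float(rng.lognormal(np.log(params.expression_mean)
                                - params.expression_sigma ** 2 / 2,
                                params.expression_sigma))
        truth_rows.append({
            "gene_id": gene_id, "strand": strand, "expression": e,
            "pause": params.stop_pause_factor,
            "readthrough_f": params.readthrough_fraction if recoding else 0.0,
            "ext_frame": params.extension_frame if recoding else 0,
            "ext_offset": ext_offset if recoding else -1,
            "gap": gap, "orf_len": L})

    parts.append(_random_seq(rng, 50))
    genome = {params.chrom_id: GenomeSequence(params.chrom_id, "".join(parts))}
    chrom_lengths = {params.chrom_id: genome[params.chrom_id].length}
    # validate stop codons / fourth bases against the built genome
    from .annotation import _annotate_from_genome
    annotated = []
    for orf in orfs:
        ann = _annotate_from_genome(orf, genome)
        assert ann is not None, f"simulator produced invalid ORF {orf.gene_id}"
        annotated.append(ann)
    annotated = compute_gaps(annotated, chrom_lengths)
    truth = pd.DataFrame(truth_rows).set_index("gene_id", drop=False)
    return genome, annotated, truth


def _tx_positions(orf: OrfRecord) -> np.ndarray:
    if orf.strand == "+":
        return np.arange(orf.start, orf.end)
    return np.arange(orf.end - 1, orf.start - 1, -1)


def _post_positions(orf: OrfRecord, n: int) -> np.ndarray:
    if orf.strand == "+":
        return np.arange(orf.end, orf.end + n)
    return np.arange(orf.start - 1, orf.start - 1 - n, -1)


def simulate_tracks(orfs: list[OrfRecord], truth: pd.DataFrame,
                    params: SimParams, seed: int | None = None,
                    chrom_lengths: dict[str, int] | None = None
                    ) -> tuple[DensityTrack, DensityTrack]:
    """(footprint, mRNA) raw-count tracks for a simulated annotation.

    Expected footprint density within the ORF is expression x gamma dwell
    noise, with the three stop-codon nucleotides multiplied by the pause
    factor; extension nucleotides (through the planted stop codon) sit at
    f x expression and the region beyond the planted stop is empty.  mRNA
    density is uniform over the ORF.  Poisson count noise is applied when
    ``count_noise == "poisson"``.
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    if chrom_lengths is None:
        # cover the trailing post-ORF region of the last gene
        pad = max(params.gap_range[1], 220) + 80
        chrom_lengths = {c: max(o.end for o in orfs if o.chrom == c) + pad
                         for c in {o.chrom for o in orfs}}
    fp = DensityTrack(chrom_lengths, units="raw")
    mrna = DensityTrack(chrom_lengths, units="raw")

    for orf in orfs:
        row = truth.loc[orf.gene_id]
        e = float(row["expression"])
        pos = _tx_positions(orf)
        if params.dwell_shape is not None:
            lam = e * rng.gamma(params.dwell_shape, 1.0 / params.dwell_shape,
                                size=orf.length)
        else:
            lam = np.full(orf.length, e)
        lam[-3:] *= float(row["pause"])
        fp.array(orf.chrom, orf.strand)[pos] += lam
        mrna.array(orf.chrom, orf.strand)[pos] += e
        if row["ext_offset"] >= 0 and row["readthrough_f"] > 0:
            n_ext = int(row["ext_offset"]) + 3  # through the planted stop codon
            ppos = _post_positions(orf, n_ext)
            fp.array(orf.chrom, orf.strand)[ppos] += row["readthrough_f"] * e

    if params.count_noise == "poisson":
        for track in (fp, mrna):
            for key in sorted(track._data):
                track._data[key] = rng.poisson(track._data[key]).astype(float)
    fp.freeze_mass()
    mrna.freeze_mass()
    return fp, mrna


def simulate_reads(expected: DensityTrack, params: SimParams, n_reads: int,
                   seed: int | None = None) -> Iterator[AlignedRead]:
    """Aligned reads whose center-mapped mass reproduces ``expected``.

    For each genomic position, a Poisson number of reads proportional to
    the expected density is drawn; each read gets a length uniform in the
    read-length range and is placed so the position falls uniformly within
    its trimmed center interval.  Reads are unique, mismatch-free, and
    emitted in deterministic genome order.
    """
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)
    mass = expected.total_mass
    if mass <= 0:
        return
    lmin, lmax = params.read_length_range
    for key in sorted(expected._data):
        chrom, strand = key
        n = expected.chrom_lengths[chrom]
        counts = rng.poisson(expected._data[key] * (n_reads / mass))
        for p in np.nonzero(counts)[0]:
            for _ in range(int(counts[p])):
                length = int(rng.integers(lmin, lmax + 1))
                w = length - 2 * TRIM
                if w >= 1:
                    left = int(p) - TRIM - int(rng.integers(0, w))
                else:
                    left = int(p) - length // 2
                if left < 0 or left + length > n:
                    continue
                yield AlignedRead(chrom, left, length, strand)


# --- text output --------------------------------------------------------------

def write_fasta(genome: dict[str, GenomeSequence], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom].sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_gff3(orfs: list[OrfRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            fh.write(f"{o.chrom}\triboterm-sim\tCDS\t{o.start + 1}\t{o.end}\t.\t"
                     f"{o.strand}\t0\tID={o.gene_id}\n")


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")
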