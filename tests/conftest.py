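"""Shared fixtures: tiny hand-built genomes/tracks and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from riboterm.annotation import GenomeSequence, OrfRecord, compute_gaps, revcomp
from riboterm.simulate import SimParams, simulate_genome, simulate_tracks
from riboterm.tracks import DensityTrack, normalize_per_million

SENSE = "GCT"  # codon used to pad hand-built ORFs


def make_orf_genome(n_genes=3, orf_len=300, gap=100, strand="+",
                    stop="TAA", chrom="toy"):
    """Deterministic hand-built genome with identical evenly spaced ORFs.

    Returns (genome dict, list of OrfRecord with gaps computed).
    Plus-strand ORF blocks are ATG + GCT... + stop followed by an A-run
    intergenic spacer (fourth base 'A').
    """
    orf_seq = "ATG" + SENSE * ((orf_len - 6) // 3) + stop
    assert len(orf_seq) == orf_len
    block = orf_seq + "A" * gap
    orfs = []
    parts = ["A" * 50]
    pos = 50
    for i in range(n_genes):
        if strand == "+":
            start = pos
            parts.append(block)
        else:
            start = pos + gap
            parts.append(revcomp(block))
        orfs.append(OrfRecord(f"t{i}", chrom, strand, start, start + orf_len,
                              stop_codon=stop, fourth_base="A"))
        pos += len(block)
    parts.append("A" * 50)
    genome = {chrom: GenomeSequence(chrom, "".join(parts))}
    orfs = compute_gaps(orfs, {chrom: genome[chrom].length})
    return genome, orfs


def uniform_track(genome, orfs, density=1.0, stop_factor=1.0, post=None,
                  normalized=True):
    """Track with constant density over each ORF (optionally boosted over
    the stop codon) and optional (offset_start, offset_end, value) post-ORF
    signal; mRNA-style."""
    chrom_lengths = {c: g.length for c, g in genome.items()}
    track = DensityTrack(chrom_lengths)
    for o in orfs:
        arr = track.array(o.chrom, o.strand)
        arr[o.start:o.end] += density
        lo, hi = o.stop_interval()
        arr[lo:hi] += density * (stop_factor - 1.0)
        if post is not None:
            a, b, v = post
            if o.strand == "+":
                arr[o.end + a:o.end + b] += v
            else:
                arr[o.start - b:o.start - a] += v
    track.freeze_mass()
    return normalize_per_million(track) if normalized else track


def simulated_cohort(**kwargs):
    """(genome, orfs, truth, fp_rpm, mrna_rpm) for a SimParams setting."""
    params = SimParams(**kwargs)
    genome, orfs, truth = simulate_genome(params)
    chrom_lengths = {c: g.length for c, g in genome.items()}
    fp, mrna = simulate_tracks(orfs, truth, params, chrom_lengths=chrom_lengths)
    return genome, orfs, truth, normalize_per_million(fp), normalize_per_million(mrna)


def five_gene_eligibility_toy():
    """5 genes probing the post-ORF eligibility rule: pass, gap-fail (64),
    density-fail (0.0999), overlap-fail, boundary-pass (gap 65, density
    exactly 0.1).  Returns (orfs, fp_rpm, mrna_rpm)."""
    import dataclasses

    genome, orfs = make_orf_genome(n_genes=5, orf_len=300, gap=200)
    chrom_lengths = {c: g.length for c, g in genome.items()}
    fp = DensityTrack(chrom_lengths, units="rpm", total_mass=1e6)
    mrna = DensityTrack(chrom_lengths, units="rpm", total_mass=1e6)
    densities = [1.0, 1.0, 0.0999, 1.0, 0.1]
    for orf, d in zip(orfs, densities):
        fp.array(orf.chrom, orf.strand)[orf.start:orf.end] = d
        mrna.array(orf.chrom, orf.strand)[orf.start:orf.end] = 1.0
    orfs[1] = dataclasses.replace(orfs[1], downstream_gap=64)
    orfs[3] = dataclasses.replace(orfs[3], overlaps_next=True,
                                  downstream_gap=0)
    orfs[4] = dataclasses.replace(orfs[4], downstream_gap=65)
    return orfs, fp, mrna


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed cohort reused by several test modules."""
    return simulated_cohort(n_genes=60, readthrough_fraction=0.5,
                            recoding_fraction=0.5, seed=4)
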