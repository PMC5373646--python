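"""Genome and ORF annotation model.

Coordinates are 0-based half-open on the forward strand throughout the
package; GFF3 input (1-based closed) is converted on read.  All
gene-relative accessors return sequence/signal in the gene's 5'->3'
(transcription) direction, reverse-complemented for minus-strand genes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """A single chromosome/replicon sequence (alphabet A,C,G,T,N)."""

    chrom_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"{self.chrom_id}: non-ACGTN characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class OrfRecord:
    """One annotated coding region.

    ``start``/``end`` are genomic, 0-based half-open on the forward strand.
    ``stop_codon`` and ``fourth_base`` are read in transcription direction.
    ``downstream_gap`` is the distance in nt from the base immediately after
    the stop codon to the first base of the nearest downstream annotated
    feature (transcription direction); None until :func:`compute_gaps` runs.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    stop_codon: str = ""
    fourth_base: str = ""
    downstream_gap: int | None = None
    overlaps_next: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty or inverted interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    def stop_interval(self) -> tuple[int, int]:
        """Genomic half-open interval of the stop codon."""
        if self.strand == "+":
            return self.end - 3, self.end
        return self.start, self.start + 3

    def stop_first_base(self) -> int:
        """Genomic position of the first stop-codon base (transcription order)."""
        return self.end - 3 if self.strand == "+" else self.start + 2


@dataclass(frozen=True)
class OrfPair:
    upstream: OrfRecord
    downstream: OrfRecord
    overlap_type: str  # {"stop-start overlap", "adjacent", "gapped"}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def load_genome(fasta_path: str) -> dict[str, GenomeSequence]:
    genomes = {}
    for rec in SeqIO.parse(fasta_path, "fasta"):
        genomes[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not genomes:
        raise ValueError(f"no sequences in {fasta_path}")
    return genomes


def orf_sequence(orf: OrfRecord, genome: dict[str, GenomeSequence]) -> str:
    """ORF sequence in transcription direction (includes the stop codon)."""
    seq = genome[orf.chrom].sequence[orf.start:orf.end]
    return seq if orf.strand == "+" else revcomp(seq)


def post_orf_sequence(orf: OrfRecord, genome: dict[str, GenomeSequence],
                      length: int) -> str:
    """Sequence downstream of the stop codon, transcription direction.

    Starts at the first base after the stop codon; truncated at the
    chromosome boundary.
    """
    chrom_seq = genome[orf.chrom].sequence
    if orf.strand == "+":
        return chrom_seq[orf.end:orf.end + length]
    lo = max(0, orf.start - length)
    return revcomp(chrom_seq[lo:orf.start])


def _annotate_from_genome(orf: OrfRecord, genome: dict[str, GenomeSequence]) -> OrfRecord | None:
    """Fill stop_codon/fourth_base; return None for records excluded by validation."""
    if orf.chrom not in genome:
        raise ValueError(f"feature {orf.gene_id}: unknown chromosome {orf.chrom!r}")
    g = genome[orf.chrom]
    if orf.start < 0 or orf.end > g.length:
        raise ValueError(
            f"feature {orf.gene_id} [{orf.start},{orf.end}) outside {orf.chrom} "
            f"bounds [0,{g.length})")
    if orf.length % 3 != 0:
        log.warning("excluding %s: length %d not a multiple of 3", orf.gene_id, orf.length)
        return None
    seq = orf_sequence(orf, genome)
    stop = seq[-3:]
    if stop not in STOP_CODONS:
        log.warning("excluding %s: terminal codon %s is not a stop", orf.gene_id, stop)
        return None
    fourth = post_orf_sequence(orf, genome, 1)
    return replace(orf, stop_codon=stop, fourth_base=fourth)


def _parse_bed(path: str) -> list[OrfRecord]:
    rows = pd.read_csv(path, sep="\t", header=None, comment="#",
                       usecols=range(6),
                       names=["chrom", "start", "end", "name", "score", "strand"],
                       dtype={"chrom": str, "name": str, "strand": str})
    return [OrfRecord(r.name, r.chrom, r.strand, int(r.start), int(r.end))
            for r in rows.itertuples(index=False)]


def _parse_gff3(path: str, feature_types=("CDS", "gene")) -> list[OrfRecord]:
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    present = set(db.featuretypes())
    use_type = next((t for t in feature_types if t in present), None)
    if use_type is None:
        raise ValueError(f"{path}: no {feature_types} features found")
    orfs = []
    for feat in db.features_of_type(use_type):
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("Name")
                   or feat.attributes.get("locus_tag") or [feat.id])[0]
        # GFF3 is 1-based closed; convert to 0-based half-open
        orfs.append(OrfRecord(gene_id, feat.seqid, feat.strand,
                              feat.start - 1, feat.end))
    return orfs


def load_annotation(genome: str | dict[str, GenomeSequence],
                    annotation_path: str) -> list[OrfRecord]:
    """Load ORFs from GFF3 or BED, validate against the genome.

    Every returned record carries ``stop_codon`` and ``fourth_base`` read
    from the genome in transcription direction.  Records whose length is not
    a multiple of 3, or whose terminal codon is not a stop, are excluded
    with a logged warning.  Features outside chromosome bounds are a hard
    error.  Records are sorted by (chrom, start).
    """
    if isinstance(genome, str):
        genome = load_genome(genome)
    ext = os.path.splitext(annotation_path)[1].lower()
    if ext in (".bed", ".bed6", ".bed12"):
        raw = _parse_bed(annotation_path)
    else:
        raw = _parse_gff3(annotation_path)
    orfs = []
    for orf in raw:
        ann = _annotate_from_genome(orf, genome)
        if ann is not None:
            orfs.append(ann)
    orfs.sort(key=lambda o: (o.chrom, o.start, o.end))
    return orfs


def write_bed(orfs: list[OrfRecord], path: str) -> None:
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f"{o.chrom}\t{o.start}\t{o.end}\t{o.gene_id}\t0\t{o.strand}\n")


def orf_table(orfs: list[OrfRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": o.gene_id, "chrom": o.chrom, "strand": o.strand,
          "start": o.start, "end": o.end, "stop_codon": o.stop_codon,
          "fourth_base": o.fourth_base, "downstream_gap": o.downstream_gap,
          "overlaps_next": o.overlaps_next} for o in orfs])


def compute_gaps(orfs: list[OrfRecord],
                 chrom_lengths: dict[str, int],
                 same_strand_only: bool = False) -> list[OrfRecord]:
    """Fill ``downstream_gap``/``overlaps_next`` for every record.

    The gap is measured from the base immediately after the stop codon to
    the first base of the nearest downstream annotated feature in
    transcription direction.  By default features on either strand count as
    neighbours (the conservative reading: smaller gaps); pass
    ``same_strand_only=True`` to restrict to same-strand neighbours.  A gene
    whose stop codon is overlapped by another feature gets
    ``overlaps_next=True`` and gap 0.  The last gene on a chromosome gets
    the gap to the sequence end.  Idempotent.
    """
    out = []
    by_chrom: dict[str, list[OrfRecord]] = {}
    for o in orfs:
        by_chrom.setdefault(o.chrom, []).append(o)
    for o in orfs:
        neighbours = [n for n in by_chrom[o.chrom]
                      if n is not o and (not same_strand_only or n.strand == o.strand)]
        stop_lo, stop_hi = o.stop_interval()
        overlaps = any(n.start < stop_hi and n.end > stop_lo for n in neighbours)
        if o.strand == "+":
            # downstream = increasing coordinates; feature's nearest edge is its start
            dists = [n.start - o.end for n in neighbours if n.start >= o.end]
            edge = chrom_lengths[o.chrom] - o.end
        else:
            # downstream = decreasing coordinates; feature's nearest edge is its end
            dists = [o.start - n.end for n in neighbours if n.end <= o.start]
            edge = o.start
        gap = min(dists) if dists else edge
        out.append(replace(o, downstream_gap=0 if overlaps else max(gap, 0),
                           overlaps_next=overlaps))
    return out


def overlapping_pairs(orfs: list[OrfRecord]) -> list[OrfPair]:
    """Consecutive same-strand ORF pairs labelled by stop/start geometry.

    "stop-start overlap" iff the downstream gene's start codon interval
    intersects the upstream gene's stop codon interval (the classic 1- or
    4-nt overlaps of coupled bacterial ORFs); "adjacent" when the start
    codon begins at the base immediately after the stop codon; "gapped"
    otherwise.
    """
    pairs = []
    by_cs: dict[tuple[str, str], list[OrfRecord]] = {}
    for o in sorted(orfs, key=lambda o: (o.chrom, o.start)):
        by_cs.setdefault((o.chrom, o.strand), []).append(o)
    for (chrom, strand), group in sorted(by_cs.items()):
        ordered = group if strand == "+" else list(reversed(group))
        for up, down in zip(ordered, ordered[1:]):
            stop_lo, stop_hi = up.stop_interval()
            if strand == "+":
                start_lo, start_hi = down.start, down.start + 3
                dist = down.start - up.end
            else:
                start_lo, start_hi = down.end - 3, down.end
                dist = up.start - down.end
            if start_lo < stop_hi and start_hi > stop_lo:
                kind = "stop-start overlap"
            elif dist == 0:
                kind = "adjacent"
            else:
                kind = "gapped"
            pairs.append(OrfPair(up, down, kind))
    return pairs


def stop_codon_frequencies(orfs: list[OrfRecord]) -> dict[str, float]:
    """Genome-wide stop-codon usage proportions over the annotation."""
    counts = {c: 0 for c in STOP_CODONS}
    for o in orfs:
        counts[o.stop_codon] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no annotated stop codons")
    return {c: counts[c] / n for c in STOP_CODONS}
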