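# Methods

## Coordinate and signal conventions

All coordinates are 0-based half-open on the forward strand; GFF3 input
(1-based closed) is converted on read. Every gene-relative accessor
returns sequence or signal in the gene's 5′→3′ direction, so minus-strand
genes are handled by one reversal in one place. Density tracks are
strand-separated, per-nucleotide, nonnegative arrays with an explicit
normalization state: `raw` (weighted read counts) or `rpm` (counts per
million). A track always carries its raw total mass, so raw counts can be
recovered from an RPM track; count-based filters (the 1-count metagene
window filter, the 100-count comparison gate, the 10-count recoding gate)
always operate on raw counts, never on RPM values.

## Footprint mapping

Bacterial MNase footprints have ragged ends, so a read's position is
assigned by **center mapping**: reads of 20–40 nt are trimmed by 10 nt on
each side and the remaining w = length − 20 positions each receive weight
1/w. Length-20 reads (trimmed width 0) are assigned to their midpoint
with weight 1 rather than silently dropped; a flag (`keep_short=False`)
discards them instead. Each read therefore contributes exactly weight 1,
and the track mass equals the retained read count (tested to 1e-9).
The weighting within the trimmed interval is uniform; nothing sharper is
claimed for MNase data. A 3′-end mapping (one position, weight 1) is
provided as the alternative with better frame information, and mRNA-seq
uses full-read coverage mapping (1/length per covered nt), since
fragmented RNA has no ribosome geometry to centre on.

SAM input takes mismatches from the `NM` tag and treats a read as
multimapped when it is secondary/supplementary, carries `NH > 1`, or has
mapping quality below 1. Filters: 20 ≤ length ≤ 40 (inclusive),
mismatches ≤ 2, uniquely mapped.

## Metagene profiles

Genes are aligned at the first base of their stop codon (offset 0) over
the window [−100, +60]. Each gene is normalized by its own mean density
over offsets [−100, −70] — a 31-nt inclusive window; the quoted
"70–100 nt upstream" span does not fix endpoints, and the symmetric
inclusive reading is used (configurable). The profile is the per-offset
median across genes. Gene filters, both individually switchable:
≥1 raw count in the normalization window, and downstream gap ≥ 50 nt so
the post-stop window is not contaminated by the next coding region.
Replicate profiles are combined as the per-offset mean of replicate
medians with stderr = sd/√n.

The scalar **stop occupancy** of a profile is the maximum of the median
profile over offsets [−2, +4], which captures the stop peak under center
mapping; a window mean over the three stop-codon offsets is available as
`mode="mean"`. Which scalar underlies a published fold change is
generally unstated, so both are exposed and the default is the peak
maximum.

## RPOR

Eligibility: downstream gap ≥ 65 nt (to the nearest downstream annotated
feature on either strand; a switch restricts to same-strand neighbours),
unmasked mean ORF density ≥ 0.1 RPM/nt in **both** footprint and mRNA
signal, stop codon not overlapped by another feature. All bounds are
inclusive, with a 1e-9 relative tolerance so values sitting exactly at a
cutoff are not lost to floating rounding.

RPOR = (mean density over post-ORF offsets [+20, +60), 40 nt half-open,
counted from the first base after the stop codon) / (mean ORF density
with the first and last 5 codons masked). The 20-nt standoff keeps the
stop-codon peak itself out of the numerator; the masked denominator
matches the gene-occupancy convention used for RPKM. The post-ORF window
inclusivity is a convention choice (a "20–60 bp" window does not fix it)
and is configurable.

Zeros are removed before distribution comparison — a zero cannot be
resolved between no recoding and insufficient depth, and zeros inflate
the K-S statistic. The K-S test is the standard two-sample two-sided
asymptotic form (scipy); the test suite checks its D statistic against an
independent brute-force ECDF scan to 1e-12.

## Recoding detector

The biological argument: if post-ORF ribosomes are actively translating,
their density must fall after the next stop codon in whichever frame they
are reading. The detector enumerates all stop codons in all three frames
of the post-ORF region (frame = offset mod 3 → {0, +1, −1}) and scores
each candidate with drop ratio = mean density over the 30 nt after the
candidate / mean over the 30 nt before it, clipped to the region.
Classification:

* fewer than 10 raw post-ORF counts → `unclassifiable` (low-reads flag);
* otherwise the best candidate is the minimal drop ratio among candidates
  with pre-stop mean ≥ 0.2 RPM/nt;
* ratio ≤ 0.3 with no confounder flags → `likely`; with flags →
  `possible`; otherwise `non-recoding`;
* a user-declared downstream feature covering ≥ 90 % of the post-ORF
  signal mass → `misannotation-suspect`.

The published analysis this formalizes was manual; the thresholds
(0.3 drop ratio, 0.2 RPM/nt pre-density, 10 counts) are this package's
operational defaults, chosen so that the detector separates planted
extensions from clean genes on synthetic cohorts, and all are
configurable. Confounder flags: user interval sets (REP elements, sRNAs,
unannotated ORFs) that overlap the post-ORF region; a built-in
`downstream-feature` flag when the post-drop window is truncated by the
next gene; and a flag-only Shine–Dalgarno scan (GGAGG — the complement of
the 16S anti-SD CCUCC — followed by ATG/GTG at a 4–15 nt spacing),
marking possible initiation at an unannotated downstream start.

Stop-codon enrichment among likely+possible calls is a Pearson
chi-square goodness of fit (df 2) of observed per-call stop codons
against genome-wide stop-codon usage computed from the annotation.

## Expression

RPKM is computed from RPM tracks directly: because the track's
per-million denominator equals the RPKM depth denominator,
RPKM = mean RPM/nt × 10³. The first and last 5 codons of each ORF are
masked (initiation/termination peaks); ORFs too short to mask fall back
to the unmasked interval with a flag. Translation efficiency
= footprint RPKM / mRNA RPKM, defined only when mRNA RPKM > 0, and
between-sample comparison requires ≥ 100 raw counts in both signals.
The two-ORF frameshift estimator uses **unmasked** sub-interval RPKMs —
the upstream sub-ORF of a programmed-frameshift locus is typically ~26
codons, which 5-codon masking would gut — and is depth-invariant by
construction. Replicates are summarized as mean ± SEM (sd/√n; undefined
for a single replicate).

## Synthetic-data generator

The generator emulates what the estimators consume, with known truth:

| parameter | default | meaning |
|---|---|---|
| n_genes | 200 | genes per cohort |
| orf_codon_range | 100–400 | ORF length (codons), uniform |
| gap_range | 100–220 nt | intergenic gap, uniform |
| stop_freqs | 0.62 / 0.09 / 0.29 | TAA/TAG/TGA usage (E. coli-like) |
| expression_mean, sigma | 2.0 counts/nt, 0.8 | log-normal per-gene expression |
| dwell_shape | 5.0 | gamma dwell noise per nt (mean 1); None = off |
| stop_pause_factor | 2.0 | dwell multiplier on the 3 stop-codon nts |
| readthrough_fraction | 0.0 | fraction f of ribosomes continuing past the stop |
| recoding_fraction | 1.0 | fraction of genes carrying an extension when f > 0 |
| extension_frame | 0 | frame of the planted extension (0, +1, −1) |
| extension_offset_range | 60–90 nt | planted stop offset past the ORF |
| count_noise | poisson | per-nt count noise |

Expected footprint density in an ORF is expression × gamma dwell noise,
with the stop codon multiplied by the pause factor; extension
nucleotides (through the planted stop) sit at f × expression and the
region beyond the planted stop is empty, so RPOR ≈ f by construction —
which is exactly the interpretation the statistic is meant to carry.
mRNA density is uniform over the ORF. Planted extensions are guaranteed
to contain no earlier stop in the extension frame, and recoding genes
draw gaps ≥ 120 nt so the element plus a 30-nt post-drop window fits in
the intergenic region; offsets start at 60 nt so the extension spans the
whole RPOR window. Everything is deterministic under a fixed seed
(numpy `default_rng`; genome from `seed`, tracks from `seed+1`, reads
from `seed+2`).

A read-level simulator places reads (lengths uniform 20–40 nt) so their
center-mapped mass reproduces an expected-value track; reconstruction is
exact in expectation up to the ±10 nt center-interval smearing, which is
why its fidelity check uses a dwell-noise-free track (white per-nt noise
is unrecoverable through any read-level representation).

**What the generator does not emulate:** MNase sequence bias, ribosome
queuing (the −28 nt "shadow" peak), operonic mRNA structure, 3′UTR
background signal, or translational coupling. Passing tests therefore
demonstrate estimator correctness under a clean generative model, not
robustness to every artifact of real libraries.

## Study conditions for the recovery checks

The validation module fixes the problem sizes used by the test suite and
`scripts/acceptance.py`: 200-gene cohorts for RPOR recovery (readthrough
fractions 0, 0.05, 0.2, 0.5), 300-gene cohorts for the 5× vs 2× pause
fold change, a 200-gene half-planted cohort for the detector operating
point, and a 1000 + 3000 nt planted locus for the frameshift estimator —
sized so the Poisson sampling error of the RPKM ratio (~1 percentage
point s.d. at 2 counts/nt) is small against the ±3-point recovery bound.

The detector's operating point is evaluated over genes whose true ORF
coverage is ≥ 1 RPM/nt. Below that, the post-ORF region of even a true
readthrough gene carries too few reads to classify and the detector
deliberately abstains (`unclassifiable`); treating abstentions on
under-covered genes as errors would measure sequencing depth, not the
classifier.

## Numerical notes and limitations

* Median profiles on integer Poisson counts at desk-scale coverage carry
  a small discreteness bias: the median of Poisson(λ) sits below λ by up
  to ~⅓ count, which inflates a 5×/2× stop-occupancy ratio by ~5 % at
  2 counts/nt. At real sequencing depth (fractional center-mapped
  weights, much higher counts) the effect is negligible.
* Threshold comparisons at eligibility cutoffs use a 1e-9 relative
  tolerance so that "inclusive bound" survives floating-point means.
* The wiggle/bedGraph writers emit full-precision `repr` values plus a
  header recording units and raw mass, making write→read round trips
  bit-exact.
* K-S p-values use the asymptotic two-sided form, appropriate for the
  ~10³-gene samples the statistic is designed for; exact small-sample
  p-values are not implemented.
* The detector classifies against a single footprint track; it does not
  pool replicates or model overdispersion. Genes the eligibility rule
  excludes (close downstream neighbours, low expression) are invisible to
  it, a selection the RPOR analysis shares.
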