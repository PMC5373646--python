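# riboterm

Analysis of **translation termination** in bacterial ribosome-profiling
data: how long ribosomes dwell on stop codons, how many of them continue
past the stop, and where the resulting readthrough / frameshift
("recoding") products end.

Ribosome footprint density at a position is proportional to ribosome dwell
time, so termination defects — e.g. weakened release factors — show up as
(i) elevated occupancy over stop codons and (ii) extra density in the
post-ORF region, the intergenic span between a gene's stop codon and the
next annotated feature. `riboterm` turns aligned footprint reads into
per-nucleotide density tracks and computes the statistics that quantify
these signatures. It is aimed at microbial translation labs doing
ribo-seq in organisms (like *E. coli*) where MNase footprinting destroys
reading-frame information and recoding has to be inferred from density
profiles.

## What it computes

* **Density tracks** — center mapping (reads of length 20–40 nt trimmed by
  10 nt per side, remaining positions weighted uniformly to sum to 1),
  3′-end and full-coverage mappings, read filters (≤2 mismatches, unique),
  per-million normalization; strand-separated wiggle/bedGraph text I/O.
* **Stop-aligned metagene profiles** — for each gene, density over
  offsets [−100, +60] around the first stop-codon base, normalized by the
  gene's own mean over [−100, −70]; the profile is the per-offset
  **median** across genes (raw-count and downstream-gap filters applied),
  with per-stop-codon and fourth-base (e.g. UGAA) strata and replicate
  averaging. A scalar *stop occupancy* (peak of the median profile over
  offsets [−2, +4]) summarizes each profile, and ratios of it compare
  conditions.
* **RPOR** (relative post-ORF ribosome occupancy) — for genes with a ≥65 nt
  downstream gap and ≥0.1 RPM/nt in both footprint and mRNA signal:

  ```
  RPOR = mean density over [+20, +60) past the stop codon
         ─────────────────────────────────────────────────
         mean density over the ORF (first/last 5 codons masked)
  ```

  RPOR roughly estimates the fraction of ribosomes reading through the
  stop. Distributions (zeros removed) are compared between conditions with
  the two-sample Kolmogorov–Smirnov test.
* **Recoding detector** — enumerates every stop codon in all three frames
  of the post-ORF sequence, scores the density drop across each
  (mean after / mean before), and classifies genes as *likely*, *possible*
  (confounded), *non-recoding*, *unclassifiable* (too few reads) or
  *misannotation-suspect*; stop-codon usage among calls is tested against
  genome-wide frequencies with a chi-square goodness of fit.
* **Expression** — RPKM with 5-codon end masking, translation efficiency
  (footprint RPKM / mRNA RPKM) with a 100-count comparison gate, replicate
  mean ± SEM, overlapping-ORF-pair TE ratios, and a two-ORF
  programmed-frameshift estimator (percent = 100 × RPKM of the post-shift
  ORF / RPKM of the pre-shift ORF).
* **Synthetic data** — a generator that plants genes with known
  expression, dwell noise, stop-codon pause factors and post-ORF
  extensions terminating at planted stop codons, so every estimator can be
  validated against ground truth.

## Worked example

```python
import numpy as np
from riboterm import (SimParams, simulate_genome, simulate_tracks,
                      normalize_per_million, metagene_profile, stop_occupancy,
                      eligible_genes, rpor_table, classify_genes)

params = SimParams(n_genes=100, readthrough_fraction=0.2, recoding_fraction=0.3,
                   stop_pause_factor=5.0, seed=7)
genome, orfs, truth = simulate_genome(params)
chrom_lengths = {c: g.length for c, g in genome.items()}
fp_raw, mrna_raw = simulate_tracks(orfs, truth, params, chrom_lengths=chrom_lengths)
fp, mrna = normalize_per_million(fp_raw), normalize_per_million(mrna_raw)

profile = metagene_profile(orfs, fp)
print(f"metagene: {profile.n_genes} genes, stop occupancy "
      f"{stop_occupancy(profile):.2f}x the gene body")

eligible = eligible_genes(orfs, fp, mrna)
records = rpor_table(eligible, fp)
rpors = np.array([r.rpor for r in records])
print(f"RPOR: {len(records)} eligible genes, "
      f"{(rpors == 0).sum()} with zero post-ORF signal, "
      f"median RPOR of readthrough genes {np.median(rpors[rpors > 0.05]):.3f}")

calls = classify_genes(eligible, genome, fp)
likely = [c for c in calls if c.label == "likely"]
print(f"detector: {len(likely)} likely recoding calls")
```

prints

```
metagene: 100 genes, stop occupancy 5.45x the gene body
RPOR: 100 eligible genes, 67 with zero post-ORF signal, median RPOR of readthrough genes 0.201
detector: 24 likely recoding calls
```

The simulated 5-fold stop pause appears as a ~5× peak in the median
metagene profile; the 30 % of genes simulated with readthrough fraction
0.2 have median RPOR ≈ 0.2 (RPOR estimates the readthrough fraction); and
the detector recovers them, e.g. gene `g005` is called at post-ORF offset
60 with drop ratio 0.000 — exactly where its extension stop codon was
planted.

A command-line interface mirrors the stages:

```sh
riboterm simulate --preset termination-defect --seed 7 --out-dir sim/
riboterm metagene --genome sim/genome.fa --annotation sim/annotation.gff3 \
    --fp-plus sim/fp_plus.wig --fp-minus sim/fp_minus.wig --stratify stop
riboterm rpor   ... --min-gap 65 --min-density 0.1
riboterm recoding ... --drop-threshold 0.3
riboterm run --config run.yaml      # whole pipeline from a YAML config
```

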