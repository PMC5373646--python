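"""Recoding detector: 3-frame stop enumeration (vs exhaustive oracle),
drop scoring, gene classification, and stop-codon enrichment testing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riboterm.annotation import STOP_CODONS
from riboterm.recoding import (StopCandidate, candidate_stops, classify_gene,
                               classify_genes, drop_score, enrichment_chi2)
from riboterm.rpor_stats import eligible_genes
from riboterm.tracks import DensityTrack

from conftest import make_orf_genome, uniform_track


def oracle_stops(seq):
    """Exhaustive 3-frame scan, written independently of the detector."""
    found = []
    for frame_offset in (0, 1, 2):
        for p in range(frame_offset, len(seq) - 2, 3):
            if seq[p:p + 3] in STOP_CODONS:
                frame = {0: 0, 1: 1, 2: -1}[frame_offset]
                found.append((p, frame, seq[p:p + 3]))
    return sorted(found)


class TestCandidateStops:
    def test_worked_example(self):
        assert candidate_stops("AAATGAATAA") == \
            [StopCandidate(3, 0, "TGA"), StopCandidate(7, 1, "TAA")]

    def test_no_stops(self):
        assert candidate_stops("ACGCAGCAGCAG") == []

    def test_tandem_frame0_stops(self):
        cands = candidate_stops("TAATAGTGA")
        assert [(c.offset, c.frame, c.codon) for c in cands] == \
            [(0, 0, "TAA"), (3, 0, "TAG"), (6, 0, "TGA")]

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_matches_exhaustive_oracle(self, seq):
        got = sorted((c.offset, c.frame, c.codon) for c in candidate_stops(seq))
        assert got == oracle_stops(seq)


class TestDropScore:
    def test_flat_density_is_one(self):
        vals = np.ones(120)
        assert drop_score(vals, 60) == pytest.approx(1.0)

    def test_hand_ratio(self):
        vals = np.concatenate([np.full(60, 5.0), np.zeros(63)])
        vals[63:93] = 0.5
        assert drop_score(vals, 60) == pytest.approx(0.1)

    def test_signal_entirely_before_candidate(self):
        vals = np.concatenate([np.full(60, 5.0), np.zeros(63)])
        assert drop_score(vals, 60) == 0.0

    def test_zero_pre_window_undefined(self):
        assert drop_score(np.zeros(120), 60) is None


class TestClassifyGene:
    def test_planted_readthrough_called_likely_at_exact_offset(self, small_cohort):
        genome, orfs, truth, fp, mrna = small_cohort
        elig = eligible_genes(orfs, fp, mrna)
        calls = {c.gene_id: c for c in classify_genes(elig, genome, fp)}
        planted = truth[(truth.ext_offset >= 0) & (truth.expression >= 1.0)]
        hits = [calls[g] for g in planted.gene_id if g in calls]
        assert hits, "no planted genes eligible"
        for call in hits:
            assert call.label in ("likely", "possible")
            assert call.best_candidate.offset == \
                truth.loc[call.gene_id, "ext_offset"]

    def test_flat_plateau_without_stop_drop_is_non_recoding(self):
        # uniform post-ORF plateau across the whole region: every candidate
        # sees equal density before and after, ratio ~1
        genome, orfs = make_orf_genome(n_genes=1, gap=150)
        track = uniform_track(genome, orfs, post=(0, 150, 1.0))
        call = classify_gene(orfs[0], genome, track)
        assert call.label == "non-recoding"

    def test_too_few_reads_is_unclassifiable(self):
        genome, orfs = make_orf_genome(n_genes=1, gap=150)
        chrom_lengths = {c: g.length for c, g in genome.items()}
        # 9 raw counts in the post-ORF region -> below the 10-count gate
        track = DensityTrack(chrom_lengths, units="rpm", total_mass=1e6)
        o = orfs[0]
        track.array(o.chrom, o.strand)[o.start:o.end] = 1.0
        track.array(o.chrom, o.strand)[o.end:o.end + 9] = 1.0
        call = classify_gene(o, genome, track)
        assert call.label == "unclassifiable"
        assert call.flags == {"low-reads"}

    def test_likely_calls_carry_no_flags(self, small_cohort):
        genome, orfs, truth, fp, mrna = small_cohort
        calls = classify_genes(eligible_genes(orfs, fp, mrna), genome, fp)
        for c in calls:
            if c.label == "likely":
                assert not c.flags
            if c.label == "unclassifiable":
                assert "low-reads" in c.flags

    def test_user_confounder_interval_downgrades_to_possible(self, small_cohort):
        genome, orfs, truth, fp, mrna = small_cohort
        elig = eligible_genes(orfs, fp, mrna)
        calls = {c.gene_id: c for c in classify_genes(elig, genome, fp)}
        likely = [g for g, c in calls.items() if c.label == "likely"]
        assert likely
        target = next(o for o in elig if o.gene_id == likely[0])
        if target.strand == "+":
            interval = (target.chrom, target.end + 5, target.end + 25)
        else:
            interval = (target.chrom, target.start - 25, target.start - 5)
        confounders = {"rep_elements": [interval]}
        call = classify_gene(target, genome, fp, confounders=confounders)
        assert call.label == "possible"
        assert "user-interval-overlap" in call.flags

    def test_covering_downstream_feature_marks_misannotation(self):
        genome, orfs = make_orf_genome(n_genes=1, gap=150)
        o = orfs[0]
        track = uniform_track(genome, orfs, post=(30, 120, 2.0))
        feature = (o.chrom, o.end + 25, o.end + 130) if o.strand == "+" else \
            (o.chrom, o.start - 130, o.start - 25)
        call = classify_gene(o, genome, track,
                             confounders={"downstream_features": [feature]})
        assert call.label == "misannotation-suspect"


class TestEnrichmentChi2:
    FREQS = {"TAA": 0.6, "TAG": 0.1, "TGA": 0.3}

    def hand_chi2(self, observed, freqs, n):
        return sum((observed[c] - n * freqs[c]) ** 2 / (n * freqs[c])
                   for c in observed)

    def test_observed_equal_expected(self):
        codons = ["TAA"] * 6 + ["TAG"] * 1 + ["TGA"] * 3
        res = enrichment_chi2(codons, self.FREQS)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_example(self):
        # observed (10, 5, 15) against freqs (0.6, 0.1, 0.3), n=30:
        # expected (18, 3, 9), chi2 = 64/18 + 4/3 + 36/9 = 8.889
        codons = ["TAA"] * 10 + ["TAG"] * 5 + ["TGA"] * 15
        res = enrichment_chi2(codons, self.FREQS)
        assert res.expected == {"TAA": 18, "TAG": 3, "TGA": 9}
        assert res.chi2 == pytest.approx(8.888888888888888, abs=1e-9)
        assert res.df == 2

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(["TAA", "TAG", "TGA"]), min_size=1,
                    max_size=200))
    def test_matches_hand_formula(self, codons):
        res = enrichment_chi2(codons, self.FREQS)
        assert res.chi2 == pytest.approx(
            self.hand_chi2(res.observed, self.FREQS, len(codons)), abs=1e-9)
        assert abs(sum(res.observed.values()) - sum(res.expected.values())) \
            < 1e-9

    def test_invariant_to_relabeling(self):
        codons = ["TAA"] * 12 + ["TAG"] * 2 + ["TGA"] * 6
        res1 = enrichment_chi2(codons, self.FREQS)
        swapped = [{"TAA": "TGA", "TGA": "TAA", "TAG": "TAG"}[c] for c in codons]
        res2 = enrichment_chi2(swapped, {"TAA": 0.3, "TAG": 0.1, "TGA": 0.6})
        assert res1.chi2 == pytest.approx(res2.chi2, abs=1e-12)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            enrichment_chi2(["TAA"], {"TAA": 0.5, "TAG": 0.1, "TGA": 0.3})
        with pytest.raises(ValueError):
            enrichment_chi2([], self.FREQS)
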