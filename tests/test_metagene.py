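"""Stop-aligned metagene profiles: normalization, filters, strata,
replicate combination, and the stop-occupancy scalar."""

import numpy as np
import pytest

from riboterm.annotation import OrfRecord
from riboterm.metagene import (MetageneProfile, combine_replicates,
                               gene_normalized_window, metagene_profile,
                               stop_occupancy, stop_occupancy_ratio, stratify)
from riboterm.tracks import DensityTrack, normalize_per_million

from conftest import make_orf_genome, uniform_track


class TestGeneNormalizedWindow:
    def test_uniform_density_self_normalizes_to_one(self):
        genome, orfs = make_orf_genome(n_genes=1)
        track = uniform_track(genome, orfs, density=3.0)
        vals = gene_normalized_window(orfs[0], track)
        # post-stop offsets fall in the empty intergenic region
        assert np.allclose(vals[:103], 1.0)

    def test_stop_peak_scales_relative_to_body(self):
        genome, orfs = make_orf_genome(n_genes=1)
        track = uniform_track(genome, orfs, density=1.0, stop_factor=2.0)
        vals = gene_normalized_window(orfs[0], track)
        assert np.allclose(vals[100:103], 2.0)   # offsets 0..2 = stop codon
        assert np.allclose(vals[:100], 1.0)

    def test_hand_built_vector_rescaled_by_window_mean(self):
        genome, orfs = make_orf_genome(n_genes=1, strand="-")
        orf = orfs[0]
        chrom_lengths = {c: g.length for c, g in genome.items()}
        track = DensityTrack(chrom_lengths, units="rpm", total_mass=1e6)
        rng = np.random.default_rng(1)
        raw161 = rng.random(161)
        raw161[0:31] = 0.5  # normalization window [-100,-70] mean = 0.5
        # plant the window on the genome (minus strand, transcription order)
        first = orf.stop_first_base()
        for off, v in zip(range(-100, 61), raw161):
            track.array(orf.chrom, "-")[first - off] = v
        vals = gene_normalized_window(orf, track)
        assert np.allclose(vals, raw161 * 2.0)

    def test_zero_window_marks_gene_ineligible(self):
        genome, orfs = make_orf_genome(n_genes=1)
        track = uniform_track(genome, orfs, post=(0, 30, 1.0))
        track.array(orfs[0].chrom, "+")[:] = 0
        assert gene_normalized_window(orfs[0], track) is None


class TestMetageneProfile:
    def test_uniform_genes_give_flat_profile(self):
        genome, orfs = make_orf_genome(n_genes=3)
        track = uniform_track(genome, orfs, density=2.0)
        profile = metagene_profile(orfs, track)
        assert profile.n_genes == 3
        assert np.allclose(profile.median_density[:103], 1.0)

    def test_downstream_gap_filter(self):
        genome, orfs = make_orf_genome(n_genes=3, gap=100)
        short = orfs[1]
        orfs[1] = OrfRecord(short.gene_id, short.chrom, short.strand,
                            short.start, short.end, short.stop_codon,
                            short.fourth_base, downstream_gap=30)
        track = uniform_track(genome, orfs)
        profile = metagene_profile(orfs, track)
        assert profile.n_genes == 2

    def test_count_filter_and_monotonicity(self):
        genome, orfs = make_orf_genome(n_genes=3)
        raw = uniform_track(genome, orfs, normalized=False)
        # starve one gene's normalization window below 1 raw count
        g = orfs[0]
        raw.array(g.chrom, g.strand)[g.start:g.end] *= 0.001
        raw.freeze_mass()
        track = normalize_per_million(raw)
        with_filter = metagene_profile(orfs, track, count_filter=True)
        without = metagene_profile(orfs, track, count_filter=False)
        assert with_filter.n_genes == 2
        assert without.n_genes >= with_filter.n_genes

    def test_median_matches_naive_oracle(self):
        genome, orfs = make_orf_genome(n_genes=5)
        raw = uniform_track(genome, orfs, normalized=False)
        for g in orfs[:2]:  # plant a 3x stop peak in two genes
            lo, hi = g.stop_interval()
            raw.array(g.chrom, g.strand)[lo:hi] *= 3.0
        raw.freeze_mass()
        track = normalize_per_million(raw)
        profile = metagene_profile(orfs, track)
        # independent per-offset median oracle
        rows = [gene_normalized_window(g, track) for g in orfs]
        for j in range(161):
            column = sorted(r[j] for r in rows)
            naive = (column[2])  # median of 5
            assert profile.median_density[j] == pytest.approx(naive, abs=1e-12)

    def test_no_surviving_genes_raises_with_attrition(self):
        genome, orfs = make_orf_genome(n_genes=2, gap=10)
        track = uniform_track(genome, orfs)
        with pytest.raises(ValueError, match="attrition"):
            metagene_profile(orfs, track, min_downstream_gap=100)

    def test_scaling_invariance_and_gene_order(self):
        genome, orfs = make_orf_genome(n_genes=4)
        raw = uniform_track(genome, orfs, stop_factor=2.5, normalized=False)
        p1 = metagene_profile(orfs, normalize_per_million(raw))
        p2 = metagene_profile(orfs[::-1], normalize_per_million(raw.scale(7.3)))
        assert np.allclose(p1.median_density, p2.median_density)


class TestStratify:
    def _orfs(self, codons, fourths=None):
        fourths = fourths or ["A"] * len(codons)
        return [OrfRecord(f"g{i}", "c", "+", 100 * i, 100 * i + 30, c, f)
                for i, (c, f) in enumerate(zip(codons, fourths))]

    def test_partition_by_stop_codon(self):
        groups = stratify(self._orfs(["TAA", "TAA", "TGA"]))
        assert (len(groups["UAA"]), len(groups["UGA"]), len(groups["UAG"])) == \
            (2, 1, 0)

    def test_four_base_stratum_naming(self):
        groups = stratify(self._orfs(["TGA"], ["A"]))
        assert [o.gene_id for o in groups["UGAA"]] == ["g0"]

    def test_top_te_decile_matches_sort_oracle(self):
        orfs = self._orfs(["TAA"] * 20)
        te = {f"g{i}": float(i % 13) + i * 0.01 for i in range(20)}
        groups = stratify(orfs, te=te)
        expected = sorted(te, key=te.get, reverse=True)[:2]
        assert sorted(o.gene_id for o in groups["top-TE decile"]) == \
            sorted(expected)


class TestCombineReplicates:
    def _profile(self, values, stratum="all"):
        n = len(values)
        return MetageneProfile(np.arange(n), np.asarray(values, float), 10,
                               stratum)

    def test_identical_replicates(self):
        combined = combine_replicates([self._profile([1, 2]), self._profile([1, 2])])
        assert np.allclose(combined.median_density, [1, 2])
        assert np.allclose(combined.stderr, 0.0)

    def test_two_replicate_mean(self):
        combined = combine_replicates([self._profile([1.0]), self._profile([3.0])])
        assert combined.median_density[0] == pytest.approx(2.0)

    def test_four_replicates_match_hand_formula(self):
        vals = [2.0, 4.0, 6.0, 8.0]
        combined = combine_replicates([self._profile([v]) for v in vals])
        sd = np.std(vals, ddof=1)
        assert combined.stderr[0] == pytest.approx(sd / 2.0)

    def test_mismatched_strata_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            combine_replicates([self._profile([1]), self._profile([1], "UAA")])


class TestStopOccupancy:
    def test_identical_profiles_ratio_one(self):
        genome, orfs = make_orf_genome(n_genes=3)
        track = uniform_track(genome, orfs, stop_factor=2.0)
        p = metagene_profile(orfs, track)
        assert stop_occupancy_ratio(p, p) == pytest.approx(1.0)

    def test_constructed_fold_change(self):
        genome, orfs = make_orf_genome(n_genes=3)
        a = metagene_profile(orfs, uniform_track(genome, orfs, stop_factor=5.0))
        b = metagene_profile(orfs, uniform_track(genome, orfs, stop_factor=2.0))
        assert stop_occupancy_ratio(a, b) == pytest.approx(2.5)

    def test_mean_mode_uses_stop_codon_offsets(self):
        genome, orfs = make_orf_genome(n_genes=3)
        p = metagene_profile(orfs, uniform_track(genome, orfs, stop_factor=4.0))
        assert stop_occupancy(p, mode="mean") == pytest.approx(4.0)
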