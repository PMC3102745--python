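"""Conservation-calling rules on hand-built fixtures and simulated bundles."""

import numpy as np
import pandas as pd
import pytest

from tfbsc.conservation import (
    between_species_call,
    detect_gained_sites,
    edge_conserved,
    flanking_divergence,
    snps_per_bp,
    strain_site_sequence,
    within_species_call,
)
from tfbsc.io_formats import BindingSite, StrainVariantTable
from tfbsc.motif_scoring import PSSM, strength


@pytest.fixture()
def setup():
    """One strong 4-bp site (consensus ACGT) in a small genome."""
    probs = np.tile([0.91, 0.03, 0.03, 0.03], (4, 1))
    for i, b in enumerate("ACGT"):
        probs[i] = 0.03
        probs[i, "ACGT".index(b)] = 0.91
    pssm = PSSM("tf1", probs)
    genome = {"chr1": "TTTTTACGTTTTTTTTTTTT"}
    site = BindingSite("s1", "chr1", 5, 9, "tf1", "+", "ACGT")
    return pssm, genome, site


def _variants(rows):
    return StrainVariantTable(pd.DataFrame(
        rows, columns=["strain_id", "chrom", "pos", "ref", "alt", "qual_p"]
    ))


class TestStrainSequence:
    def test_no_variants_returns_reference(self, setup):
        pssm, genome, site = setup
        assert strain_site_sequence(site, "sA", _variants([]), genome) == "ACGT"

    def test_passing_snp_substituted(self, setup):
        pssm, genome, site = setup
        v = _variants([("sA", "chr1", 8, "T", "G", 1e-5)])
        assert strain_site_sequence(site, "sA", v, genome) == "ACGG"

    def test_failing_quality_snp_ignored(self, setup):
        pssm, genome, site = setup
        v = _variants([("sA", "chr1", 8, "T", "G", 0.01)])
        assert strain_site_sequence(site, "sA", v, genome) == "ACGT"

    def test_quality_boundary_is_strict(self, setup):
        # the filter keeps p < 1e-3, so p == 1e-3 is rejected
        pssm, genome, site = setup
        v = _variants([("sA", "chr1", 8, "T", "G", 1e-3)])
        assert strain_site_sequence(site, "sA", v, genome) == "ACGT"

    def test_ref_mismatch_raises(self, setup):
        pssm, genome, site = setup
        v = _variants([("sA", "chr1", 8, "C", "G", 1e-5)])
        with pytest.raises(ValueError, match="chr1:9"):
            strain_site_sequence(site, "sA", v, genome)

    def test_minus_strand_orientation(self, setup):
        pssm, genome, _ = setup
        site = BindingSite("s2", "chr1", 5, 9, "tf1", "-", "ACGT")
        v = _variants([("sA", "chr1", 5, "A", "G", 1e-5)])
        # genomic A at the site's left edge is the last base on '-'
        assert strain_site_sequence(site, "sA", v, genome) == "ACGC"


class TestWithinSpecies:
    STRAINS = [f"s{i}" for i in range(4)]

    def test_zero_snps_conserved(self, setup):
        pssm, genome, site = setup
        ok, n = within_species_call(site, self.STRAINS, _variants([]), genome, pssm)
        assert ok and n == 4

    def test_single_breaking_strain_flips_call(self, setup):
        pssm, genome, site = setup
        # two worst-base changes drive strength far below 0.6
        v = _variants([("s2", "chr1", 5, "A", "C", 1e-5),
                       ("s2", "chr1", 6, "C", "A", 1e-5)])
        ok, _ = within_species_call(site, self.STRAINS, v, genome, pssm)
        assert not ok

    def test_benign_snp_keeps_call(self, setup):
        pssm, genome, site = setup
        big = PSSM("big", np.tile([0.91, 0.03, 0.03, 0.03], (10, 1)))
        genome = {"chr1": "TTTTT" + "A" * 10 + "TTTTT"}
        site = BindingSite("s1", "chr1", 5, 15, "big", "+", "A" * 10)
        v = _variants([("s1", "chr1", 9, "A", "G", 1e-5)])
        assert strength("AAAAGAAAAA", big) > 0.6
        ok, _ = within_species_call(site, self.STRAINS, v, genome, big)
        assert ok

    def test_zero_strains_is_an_error(self, setup):
        pssm, genome, site = setup
        with pytest.raises(ValueError):
            within_species_call(site, [], _variants([]), genome, pssm)


class TestBetweenSpecies:
    SPECIES = ["sp1", "sp2", "sp3"]

    @pytest.mark.parametrize("n_conserved,expected", [(3, True), (2, True),
                                                      (1, False), (0, False)])
    def test_two_of_three_rule(self, setup, n_conserved, expected):
        pssm, _genome, site = setup
        seqs = {}
        for i, sp in enumerate(self.SPECIES):
            seqs[(site.site_id, sp)] = "ACGT" if i < n_conserved else "CAGT"
        assert strength("CAGT", pssm) < 0.6
        assert between_species_call(site, seqs, self.SPECIES, pssm) is expected

    def test_missing_sequences_count_as_not_conserved(self, setup):
        pssm, _genome, site = setup
        assert between_species_call(site, {}, self.SPECIES, pssm) is False
        one = {(site.site_id, "sp1"): "ACGT"}
        assert between_species_call(site, one, self.SPECIES, pssm) is False


class TestEdge:
    def test_any_conserved_site_retains_the_edge(self):
        assert edge_conserved([False, True, False]) is True

    def test_all_lost(self):
        assert edge_conserved([False, False]) is False

    def test_no_sites_is_undefined(self):
        with pytest.raises(ValueError):
            edge_conserved([])

    def test_adding_a_conserved_site_is_monotone(self):
        for flags in ([True], [False, True], [True, False, False]):
            assert edge_conserved(flags + [True])


class TestSnpsPerBp:
    def test_count_over_nongap_length(self):
        probs = np.tile([0.91, 0.03, 0.03, 0.03], (10, 1))
        probs[3] = probs[6] = 0.25
        pssm = PSSM("g", probs, gap_positions={3, 6})
        genome = {"chr1": "T" * 5 + "A" * 10 + "T" * 5}
        site = BindingSite("s1", "chr1", 5, 15, "g", "+", "A" * 10)
        v = _variants([("sA", "chr1", 6, "A", "G", 1e-5),
                       ("sB", "chr1", 9, "A", "C", 1e-5),   # offset 4, non-gap
                       ("sB", "chr1", 8, "A", "C", 0.5)])   # fails quality
        assert snps_per_bp(site, v, [site], pssm) == pytest.approx(2 / 8)

    def test_gap_position_excluded_from_numerator(self):
        probs = np.tile([0.91, 0.03, 0.03, 0.03], (4, 1))
        probs[1] = 0.25
        pssm = PSSM("g", probs, gap_positions={1})
        genome = {"chr1": "TTTTAAAATTTT"}
        site = BindingSite("s1", "chr1", 4, 8, "g", "+", "AAAA")
        v = _variants([("sA", "chr1", 5, "A", "G", 1e-5)])  # the gap base
        assert snps_per_bp(site, v, [site], pssm) == 0.0

    def test_overlapping_sites_return_sentinel(self, setup):
        pssm, _genome, site = setup
        other = BindingSite("s2", "chr1", 8, 12, "tf1", "+", "TTTT")
        assert np.isnan(snps_per_bp(site, _variants([]), [site, other], pssm))

    def test_no_snps_is_zero(self, setup):
        pssm, _genome, site = setup
        assert snps_per_bp(site, _variants([]), [site], pssm) == 0.0


class TestFlankingDivergence:
    CHROMS = {"chr1": 30}

    def test_clean_flank(self, setup):
        pssm, _genome, site = setup
        v = _variants([("sA", "chr1", 12, "T", "G", 1e-5)])
        assert flanking_divergence(site, v, [site], self.CHROMS) == pytest.approx(0.1)

    def test_neighboring_site_shrinks_denominator(self, setup):
        pssm, _genome, site = setup
        # neighbor covers 4 of the 10 downstream flank bases [9, 19)
        other = BindingSite("s2", "chr1", 15, 19, "tf1", "+", "TTTT")
        v = _variants([("sA", "chr1", 10, "T", "G", 1e-5)])
        assert flanking_divergence(site, v, [site, other], self.CHROMS) == \
            pytest.approx(1 / 6)

    def test_zero_retained_bases_is_sentinel(self, setup):
        pssm, _genome, site = setup
        end_site = BindingSite("s3", "chr1", 26, 30, "tf1", "+", "TTTT")
        assert np.isnan(
            flanking_divergence(end_site, _variants([]), [end_site], self.CHROMS)
        )

    def test_minus_strand_flank_is_upstream_in_genome(self, setup):
        pssm, _genome, _ = setup
        site = BindingSite("s4", "chr1", 15, 19, "tf1", "-", "AAAA")
        v = _variants([("sA", "chr1", 7, "T", "G", 1e-5)])
        assert flanking_divergence(site, v, [site], self.CHROMS) == pytest.approx(0.1)


class TestGainedSites:
    def test_snps_creating_a_motif_are_detected(self, setup):
        pssm, genome, _site = setup
        genome = {"chr1": "TTTTTTTTTTTTTTTTTTTT"}
        # strain sA acquires ACG at positions 10-12 -> ACGT consensus at 10
        v = _variants([("sA", "chr1", 10, "T", "A", 1e-5),
                       ("sA", "chr1", 11, "T", "C", 1e-5),
                       ("sA", "chr1", 12, "T", "G", 1e-5)])
        gains = detect_gained_sites(("chr1", 0, 20), "tf1", pssm,
                                    ["sA", "sB"], v, genome)
        assert any(g["strain_id"] == "sA" and g["offset"] == 10 for g in gains)

    def test_reference_identical_strains_gain_nothing(self, setup):
        pssm, genome, _site = setup
        gains = detect_gained_sites(("chr1", 0, 20), "tf1", pssm,
                                    ["sA"], _variants([]), genome)
        assert gains == []


class TestPipelineTruthAgreement:
    def test_calls_match_generator_truth_exactly(self, small_sim, small_calls):
        m = small_calls.merge(
            small_sim.truth[["site_id", "within_true", "between_true"]],
            on="site_id",
        )
        assert (m["within"].astype(bool) == m["within_true"].astype(bool)).all()
        assert (m["between"].astype(bool) == m["between_true"].astype(bool)).all()

    def test_identical_implies_conserved(self, small_calls):
        ident = small_calls[small_calls["identical_in_all_strains"]
                            & ~small_calls["reference_below_threshold"]]
        assert ident["within"].astype(bool).all()

    def test_snps_per_bp_zero_iff_identical(self, small_calls):
        sub = small_calls.dropna(subset=["snps_per_bp"])
        assert ((sub["snps_per_bp"] == 0)
                == sub["identical_in_all_strains"]).all()

    def test_planted_gains_are_detected(self, small_sim):
        from tfbsc.synthetic_data import _promoter_interval

        bundle = small_sim.bundle
        genes = {g.gene_id: g for g in bundle.genes}
        assert len(small_sim.gains) > 0
        for rec in small_sim.gains.itertuples(index=False):
            gene = genes[rec.gene_id]
            p_lo, p_hi = _promoter_interval(
                gene, bundle.thresholds.promoter_bp,
                bundle.chrom_lengths[gene.chrom],
            )
            gains = detect_gained_sites(
                (gene.chrom, p_lo, p_hi), rec.tf_id, bundle.pssms[rec.tf_id],
                bundle.strain_ids, bundle.variants, bundle.genome,
            )
            assert any(g["strain_id"] == rec.strain_id for g in gains)
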