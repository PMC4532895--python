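"""The 14 site features and their trimmed scaling."""
import math

import numpy as np
import pytest

from contextpp.features import (
    CATEGORICAL_FEATURES,
    MODEL_FEATURES,
    NN_STACK_KCAL,
    ScalingTable,
    default_scaling_table,
    expand_design_row,
    feature_vector,
    local_au,
    min_dist,
    scale_feature,
    seed_pairing_stability,
    structural_accessibility,
    target_site_abundance,
    threep_score,
)
from contextpp.accessibility import PartitionFunctionProvider
from contextpp.types import IsoformProfile, MirnaFamily, Site, TranscriptModel


class TestTargetSiteAbundance:
    def test_log10(self):
        assert target_site_abundance(1000) == pytest.approx(3.0)
        assert target_site_abundance(1) == 0.0

    def test_published_anchor_vicinity(self):
        # 1300 sites lands by the published 8mer 5th-percentile anchor (3.113)
        assert target_site_abundance(1300) == pytest.approx(3.1139, abs=1e-4)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            target_site_abundance(0)


class TestSeedPairingStability:
    def test_matches_hand_summed_stack_table(self):
        member = "UGGAAUGUAAAGAAGUAUGUAU"
        span = member[1:8]  # GGAAUGU
        by_hand = sum(NN_STACK_KCAL[a + b] for a, b in zip(span, span[1:]))
        assert seed_pairing_stability(member, "8mer") == pytest.approx(by_hand)

    def test_gc_seed_more_stable_than_au_seed(self):
        gc = "A" + "GCGCGCG" + "A" * 14
        au = "A" + "AUAUAUA" + "A" * 14
        assert seed_pairing_stability(gc, "8mer") < seed_pairing_stability(au, "8mer")

    def test_8mer_vs_6mer_differ_by_nt7_nt8_stack(self):
        member = "UGGAAUGUAAAGAAGUAUGUAU"
        diff = seed_pairing_stability(member, "8mer") - seed_pairing_stability(member, "6mer")
        assert diff == pytest.approx(NN_STACK_KCAL[member[6] + member[7]])

    def test_non_acgu_rejected(self):
        with pytest.raises(ValueError):
            seed_pairing_stability("ANNNNNNNNN", "8mer")


class TestLocalAU:
    def site(self, start=30, end=36):
        return Site("t", "f", "6mer", start, end)

    def test_all_au_flanks(self):
        utr = "U" * 30 + "CAUUCC" + "A" * 30
        assert local_au(utr, self.site()) == 1.0

    def test_all_gc_flanks(self):
        utr = "G" * 30 + "CAUUCC" + "C" * 30
        assert local_au(utr, self.site()) == 0.0

    def test_truncated_flank_weight_arithmetic(self):
        # 4-nt upstream flank only, A nearest the site edge, everything
        # else G/C: (1/1) / (1 + 1/2 + 1/3 + 1/4)
        utr = "GGGA" + "CAUUCC"
        got = local_au(utr, self.site(4, 10))
        assert got == pytest.approx(1.0 / (1 + 1 / 2 + 1 / 3 + 1 / 4), abs=1e-12)

    def test_n_in_flank_is_missing(self):
        utr = "G" * 29 + "N" + "CAUUCC" + "C" * 30
        assert math.isnan(local_au(utr, self.site()))


class TestThreePScore:
    # member with an A-only 3' tail pairs nothing in a C background
    inert = "U" + "GGAAUGU" + "A" * 14

    def site(self, s):
        return Site("t", "f", "7mer-m8", s, s + 7)

    def build(self, member, pair_positions, s=24, offset=0):
        """Place complements of the given miRNA positions (1-based) opposite
        the site's 3' region in an otherwise inert C background."""
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        utr = list("C" * 40)
        utr[s : s + 7] = "ACAUUCC"
        for pos in pair_positions:
            j = pos - 9
            utr[s - 1 - j - offset] = comp[member[pos - 1]]
        return "".join(utr)

    def test_no_complementarity(self):
        utr = "C" * 24 + "ACAUUCC" + "C" * 9
        assert threep_score(self.inert, utr, self.site(24)) == 0.0

    def test_perfect_core_pairing_scores_four(self):
        member = "U" + "GGAAUGU" + "AAAA" + "GUGU" + "AAAAAA"  # nt 13-16 = GUGU
        utr = self.build(member, [13, 14, 15, 16])
        assert threep_score(member, utr, self.site(24)) == 4.0

    def test_tail_pairing_scores_half_weight(self):
        member = "U" + "GGAAUGU" + "AAAAAAAA" + "GUGU" + "AA"  # nt 17-20 = GUGU
        utr = self.build(member, [17, 18, 19, 20])
        assert threep_score(member, utr, self.site(24)) == 2.0

    def test_offset_penalty(self):
        member = "U" + "GGAAUGU" + "AAAA" + "GUGU" + "AAAAAA"
        utr = self.build(member, [13, 14, 15, 16], offset=2)
        assert threep_score(member, utr, self.site(24)) == 4.0 - 0.5 * 2


class TestStructuralAccessibility:
    def test_probability_one_gives_zero(self):
        site = Site("t", "f", "7mer-m8", 20, 27)
        assert structural_accessibility("A" * 60, site) == pytest.approx(0.0)

    def test_probability_powers_map_to_log10(self):
        class Fixed:
            def __init__(self, p):
                self.p = p

            def window_probability(self, seq, start, length):
                return self.p

        site = Site("t", "f", "7mer-m8", 20, 27)
        assert structural_accessibility("A" * 60, site, Fixed(1e-2)) == pytest.approx(-2.0)

    def test_window_overlapping_helix_less_accessible(self):
        # a strong hairpin 5' of the site depresses the unpaired probability
        stem = "GGGGGGG" + "AAAA" + "CCCCCCC"
        seq_helix = stem + "A" * 10 + "ACAUUCC" + "A" * 10
        seq_open = "A" * len(stem) + "A" * 10 + "ACAUUCC" + "A" * 10
        site = Site("t", "f", "7mer-m8", len(stem) + 10, len(stem) + 17)
        assert structural_accessibility(seq_helix, site) < structural_accessibility(seq_open, site)


class TestMinDist:
    def test_edge_distance_arithmetic(self):
        prof = IsoformProfile("t", [1000], [1.0])
        site = Site("t", "f", "7mer-m8", 100, 107)
        assert min_dist(site, prof) == pytest.approx(2.0)

    def test_site_at_stop_codon_clamps_to_one(self):
        prof = IsoformProfile("t", [1000], [1.0])
        site = Site("t", "f", "7mer-m8", 0, 7)
        assert min_dist(site, prof) == 0.0

    def test_distance_to_isoform_end_wins_when_closer(self):
        prof = IsoformProfile("t", [120], [1.0])
        site = Site("t", "f", "7mer-m8", 100, 107)
        assert min_dist(site, prof) == pytest.approx(math.log10(13))


class TestScaling:
    def test_published_anchors_map_to_unit_interval(self):
        table = default_scaling_table()
        assert scale_feature(-11.130, "SPS", "8mer", table) == pytest.approx(0.0)
        assert scale_feature(-5.520, "SPS", "8mer", table) == pytest.approx(1.0)

    def test_midpoint(self):
        table = default_scaling_table()
        assert scale_feature(-8.325, "SPS", "8mer", table) == pytest.approx(0.5)

    def test_not_clipped_and_affine(self):
        table = default_scaling_table()
        lo, hi = table.lookup("SA", "6mer")
        below = scale_feature(lo - 1.0, "SA", "6mer", table)
        assert below < 0.0  # trimmed normalization does not clip
        # affine: equal raw increments give equal scaled increments
        a, b, c = (scale_feature(v, "SA", "6mer", table) for v in (-3.0, -2.0, -1.0))
        assert b - a == pytest.approx(c - b)

    def test_counts_pass_through(self):
        table = default_scaling_table()
        assert scale_feature(3.0, "Off6m", "8mer", table) == 3.0

    def test_missing_entry_rejected(self):
        with pytest.raises(KeyError):
            default_scaling_table().lookup("SPS", "offset-6mer")

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            ScalingTable({("X", "8mer"): (1.0, 1.0)})


class TestFeatureVector:
    def assemble(self, transcript, family, pct=None):
        prof = IsoformProfile("tx1", [len(transcript.utr3)], [1.0])
        site = Site("tx1", "miR-ex", "8mer", 20, 28)
        return feature_vector(
            site, transcript, family, family.members[0], prof, census=1300,
            pct_lookup=pct,
        )

    def test_all_fourteen_features_populated(self, transcript, family):
        fv = self.assemble(transcript, family)
        assert set(MODEL_FEATURES) <= set(fv.scaled)
        assert fv.scorable

    def test_pct_defaults_to_zero_and_lookup_applies(self, transcript, family):
        assert self.assemble(transcript, family).raw["P_CT"] == 0.0
        fv = self.assemble(transcript, family, pct={("tx1", "miR-ex", 20): 0.5})
        assert fv.raw["P_CT"] == 0.5

    def test_pct_zero_for_non_broadly_conserved(self, transcript, family):
        weak = MirnaFamily("miR-ex", family.seed7, family.members, "poorly_conserved")
        prof = IsoformProfile("tx1", [len(transcript.utr3)], [1.0])
        site = Site("tx1", "miR-ex", "8mer", 20, 28)
        fv = feature_vector(site, transcript, weak, weak.members[0], prof, 1300,
                            pct_lookup={("tx1", "miR-ex", 20): 0.5})
        assert fv.raw["P_CT"] == 0.0

    def test_no_offset_6mers_gives_zero(self, transcript, family):
        assert self.assemble(transcript, family).raw["Off6m"] == 0.0

    def test_recomputation_is_bit_identical(self, transcript, family):
        a = self.assemble(transcript, family)
        b = self.assemble(transcript, family)
        for k in MODEL_FEATURES:
            assert a.scaled[k] == b.scaled[k]

    def test_categorical_expansion_u_reference(self):
        row = expand_design_row(
            {"sRNA1": "U", "sRNA8": "G", "site8": "A"},
            features=CATEGORICAL_FEATURES,
        )
        assert row["sRNA1_A"] == row["sRNA1_C"] == row["sRNA1_G"] == 0.0
        assert row["sRNA8_G"] == 1.0 and row["site8_A"] == 1.0
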