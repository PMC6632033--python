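"""HGVS parsing, speed ratios and cross-model effect classification."""

import numpy as np
import pytest

from trnatempo import (
    CodingSequence,
    classify_across_models,
    codon_speed_ratio,
    gen_snv_scenario,
    local_profile_delta,
    parse_hgvs,
    velocity_profile,
)
from trnatempo.snv_effect import (
    NonSynonymousVariant,
    PositionOutOfRange,
    ReferenceMismatch,
    SynonymousVariant,
)
from .conftest import uniformish_codon_fractions


def toy_cds(n=80):
    codons = ["AUG"] + ["AAA"] * (n - 1)
    codons[39] = "ACU"  # variant site at codon 40
    return CodingSequence("toy", tuple(codons))


def thr_variant(codon_index=40):
    pos = codon_index * 3  # third position of the codon
    return SynonymousVariant(
        transcript_id="toy",
        hgvs_c=f"c.{pos}U>G",
        position=pos,
        codon_index=codon_index,
        wt_codon="ACU",
        mut_codon="ACG",
        amino_acid="T",
    )


class TestParseHGVS:
    def test_third_position_swap_with_spaced_notation(self):
        cds = toy_cds()
        var = parse_hgvs("c.120 T > G", cds)
        assert (var.codon_index, var.wt_codon, var.mut_codon) == (40, "ACU", "ACG")
        assert var.amino_acid == "T"

    def test_position_out_of_range(self):
        with pytest.raises(PositionOutOfRange):
            parse_hgvs("c.9999A>G", toy_cds())

    def test_reference_mismatch(self):
        with pytest.raises(ReferenceMismatch):
            parse_hgvs("c.120A>G", toy_cds())  # CDS has U at c.120

    def test_non_synonymous_change_rejected(self):
        # c.3G>A turns AUG (Met) into AUA (Ile)
        cds = CodingSequence("toy", ("AUG", "GCU", "AAA"))
        with pytest.raises(NonSynonymousVariant):
            parse_hgvs("c.3G>A", cds)

    def test_codon_index_is_ceil_of_position_thirds(self):
        # position 240 is the third nucleotide of codon 80 (AAA -> AAG, Lys)
        cds = toy_cds(n=80)
        var = parse_hgvs("c.240A>G", cds)
        assert var.codon_index == (240 + 2) // 3 == 80
        assert (var.wt_codon, var.mut_codon) == ("AAA", "AAG")

    def test_cftr_like_fixture_maps_printed_residues(self):
        from trnatempo import cftr_like_cds

        cds = cftr_like_cds()
        v1 = parse_hgvs("c.2562T>G", cds)
        assert (v1.codon_index, v1.amino_acid) == (854, "T")
        assert (v1.wt_codon, v1.mut_codon) == ("ACU", "ACG")
        v2 = parse_hgvs("c.3870A>G", cds)
        assert (v2.codon_index, v2.amino_acid) == (1290, "P")
        v3 = parse_hgvs("c.1584G>A", cds)
        assert (v3.codon_index, v3.wt_codon, v3.mut_codon) == (528, "GAG", "GAA")


class TestCodonSpeedRatio:
    def test_ratio_is_wt_over_mut(self):
        cf = uniformish_codon_fractions(overrides={"ACU": 0.02, "ACG": 0.005})
        r = codon_speed_ratio(thr_variant(), cf)
        assert r == pytest.approx(4.0, rel=1e-9)

    def test_degenerate_same_codon_gives_one(self):
        var = thr_variant()
        var = SynonymousVariant(
            var.transcript_id, var.hgvs_c, var.position, var.codon_index,
            "ACU", "ACU", "T",
        )
        cf = uniformish_codon_fractions()
        assert codon_speed_ratio(var, cf) == pytest.approx(1.0)

    def test_ambiguous_codon_is_unresolvable(self):
        cf = uniformish_codon_fractions(ambiguous={"ACG"})
        assert codon_speed_ratio(thr_variant(), cf) is None


class TestClassifyAcrossModels:
    def test_reference_against_itself_is_same(self):
        cf = uniformish_codon_fractions("REF", {"ACU": 0.04, "ACG": 0.01})
        call = classify_across_models(thr_variant(), {"REF": cf}, "REF")
        assert call.per_model["REF"][1] == "same"

    def test_no_effect_when_mutant_trna_not_scarcer(self):
        ref = uniformish_codon_fractions("REF", {"ACU": 0.04, "ACG": 0.01})
        alt = uniformish_codon_fractions("ALT", {"ACU": 0.02, "ACG": 0.022})
        call = classify_across_models(thr_variant(), {"REF": ref, "ALT": alt}, "REF")
        assert call.per_model["ALT"][1] == "no_effect"

    def test_reverted_when_variant_speeds_up_while_reference_slows(self):
        ref = uniformish_codon_fractions("REF", {"ACU": 0.04, "ACG": 0.01})
        alt = uniformish_codon_fractions("ALT", {"ACU": 0.01, "ACG": 0.04})
        call = classify_across_models(thr_variant(), {"REF": ref, "ALT": alt}, "REF")
        assert call.per_model["ALT"][1] == "reverted"

    def test_stronger_when_mutant_trna_far_lower_than_reference(self):
        ref = uniformish_codon_fractions("REF", {"ACU": 0.04, "ACG": 0.02})
        alt = uniformish_codon_fractions("ALT", {"ACU": 0.04, "ACG": 0.002})
        call = classify_across_models(thr_variant(), {"REF": ref, "ALT": alt}, "REF")
        assert call.per_model["ALT"][1] == "stronger"

    def test_unresolvable_reference_is_error(self):
        ref = uniformish_codon_fractions("REF", {"ACU": 0.04}, ambiguous={"ACG"})
        with pytest.raises(ValueError, match="unresolvable"):
            classify_across_models(thr_variant(), {"REF": ref}, "REF")

    def test_class_monotone_in_mutant_scarcity(self):
        """As f_mut falls (R_m rises), the class walks reverted -> no_effect ->
        weaker -> same -> stronger without skipping backwards."""
        order = {"reverted": 0, "no_effect": 1, "weaker": 2, "same": 3, "stronger": 4}
        ref = uniformish_codon_fractions("REF", {"ACU": 0.04, "ACG": 0.01})
        seen = []
        for r_m in np.geomspace(0.1, 40.0, 60):
            alt = uniformish_codon_fractions("ALT", {"ACU": 0.04, "ACG": 0.04 / r_m})
            call = classify_across_models(thr_variant(), {"REF": ref, "ALT": alt}, "REF")
            seen.append(order[call.per_model["ALT"][1]])
        assert seen == sorted(seen)

    @pytest.mark.parametrize(
        "kind", ["same", "stronger", "weaker", "reverted", "no_effect", "unresolvable"]
    )
    def test_scenario_closed_loop(self, kind):
        for seed in range(10):
            models, variant, expected = gen_snv_scenario(kind, seed)
            call = classify_across_models(variant, models, "REF")
            assert call.per_model["ALT"][1] == expected


class TestLocalProfileDelta:
    def test_identical_fractions_give_identical_segments(self):
        cf = uniformish_codon_fractions(overrides={"ACU": 0.02, "ACG": 0.02})
        wt, mut = local_profile_delta(thr_variant(), toy_cds(), cf, window=10)
        np.testing.assert_allclose(wt, mut)

    def test_exactly_window_values_differ(self):
        cf = uniformish_codon_fractions(overrides={"ACU": 0.05, "ACG": 0.001})
        window = 12
        seq = toy_cds()
        wt, mut = local_profile_delta(thr_variant(), seq, cf, window=window)
        assert len(wt) == len(mut) == window
        assert np.all(wt != mut)
        # and outside the returned segment nothing changes
        full_wt = velocity_profile(seq, cf, window=window)
        full_mut = velocity_profile(seq.substitute(40, "ACG"), cf, window=window)
        diff_idx = np.nonzero(full_wt.values != full_mut.values)[0]
        assert len(diff_idx) == window

    def test_changed_values_match_brute_force(self):
        from .test_ribotempo import brute_force_profile

        cf = uniformish_codon_fractions(overrides={"ACU": 0.05, "ACG": 0.001})
        window = 8
        seq = toy_cds()
        _, mut = local_profile_delta(thr_variant(), seq, cf, window=window)
        mut_codons = list(seq.codons)
        mut_codons[39] = "ACG"
        _, oracle_vals = brute_force_profile(mut_codons, cf.per_codon, window)
        # windows containing codon 40 start at codons 33..40 (0-based 32..39)
        oracle_segment = oracle_vals[40 - window : 40]
        np.testing.assert_allclose(mut, oracle_segment, rtol=1e-12)

    def test_variant_too_close_to_ends_is_error(self):
        cf = uniformish_codon_fractions()
        var = thr_variant()
        short = CodingSequence("s", ("AUG",) * 0 + ("AAA",) * 40)
        with pytest.raises(ValueError, match="too close"):
            local_profile_delta(var, short, cf, window=39)
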