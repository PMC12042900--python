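import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chkit.variant_filtering import (
    AnnotatedVariant,
    GenePanel,
    PanelThresholds,
    WesThresholds,
    build_carrier_profiles,
    collapse_frameshift_clusters,
    evaluate_chip_rules,
    evaluate_lymphoid_rules,
    evaluate_panel_rules,
    filter_chip_panel,
    filter_chip_wes,
    filter_lymphoid_wes,
)

import oracles


class TestChipRules:
    def test_gnomad_above_threshold_fails_r2(self, make_variant, chip_panel):
        v = make_variant(gnomad_max_pop_af=0.002)
        assert evaluate_chip_rules(v, chip_panel).failed_rules == ("R2",)

    def test_jak2_v617f_hotspot_exempt_from_r2(self, make_variant, chip_panel):
        v = make_variant(
            gene="JAK2", chrom="chr9", pos=5_073_770, protein_change="V617F",
            gnomad_max_pop_af=0.002,
        )
        assert evaluate_chip_rules(v, chip_panel).verdict == "pass"

    @pytest.mark.parametrize("change", ["R882H", "R882C"])
    def test_dnmt3a_codon_882_exempt(self, make_variant, chip_panel, change):
        v = make_variant(gene="DNMT3A", protein_change=change, gnomad_max_pop_af=0.002)
        assert evaluate_chip_rules(v, chip_panel).verdict == "pass"

    def test_dnmt3a_other_codon_not_exempt(self, make_variant, chip_panel):
        v = make_variant(gene="DNMT3A", protein_change="R736H", gnomad_max_pop_af=0.002)
        assert "R2" in evaluate_chip_rules(v, chip_panel).failed_rules

    def test_single_strand_alt_fails_r7(self, make_variant, chip_panel):
        v = make_variant(alt_fwd=3, alt_rev=0, alt_depth=3)
        assert evaluate_chip_rules(v, chip_panel).failed_rules == ("R7",)

    def test_depth_and_alt_rules(self, make_variant, chip_panel):
        v = make_variant(total_depth=9, alt_depth=2, ref_fwd=3, ref_rev=4, alt_fwd=1, alt_rev=1)
        assert evaluate_chip_rules(v, chip_panel).failed_rules == ("R6",)
        v = make_variant(total_depth=10, alt_depth=2, ref_fwd=4, ref_rev=4, alt_fwd=1, alt_rev=1)
        assert evaluate_chip_rules(v, chip_panel).verdict == "pass"

    def test_quality_rules(self, make_variant, chip_panel):
        assert evaluate_chip_rules(make_variant(somatic_quality=2.9), chip_panel).failed_rules == ("R4",)
        assert evaluate_chip_rules(make_variant(somatic_quality=3.0), chip_panel).verdict == "pass"
        assert evaluate_chip_rules(make_variant(germline_quality=10.0), chip_panel).failed_rules == ("R5",)
        assert evaluate_chip_rules(make_variant(germline_quality=9.9), chip_panel).verdict == "pass"
        assert evaluate_chip_rules(make_variant(caller_label="LowQual"), chip_panel).failed_rules == ("R3",)

    def test_off_panel_gene_fails_r1(self, make_variant, chip_panel):
        v = make_variant(gene="BRCA1")
        assert evaluate_chip_rules(v, chip_panel).failed_rules == ("R1",)

    def test_splice_distance_rule(self, make_variant, chip_panel):
        ok = make_variant(consequence="splice", splice_distance_bp=2)
        assert evaluate_chip_rules(ok, chip_panel).verdict == "pass"
        far = make_variant(consequence="splice", splice_distance_bp=3)
        assert evaluate_chip_rules(far, chip_panel).failed_rules == ("R8",)

    def test_splice_missing_distance_fails_conservatively(self, make_variant, chip_panel):
        v = make_variant(consequence="splice", splice_distance_bp=None)
        assert "R8" in evaluate_chip_rules(v, chip_panel).failed_rules

    def test_frameshift_cohort_frequency_rule(self, make_variant, chip_panel):
        v = make_variant(consequence="frameshift", ref="CT", alt="C")
        assert evaluate_chip_rules(v, chip_panel, cohort_frameshift_freq=0.006).failed_rules == ("R9",)
        # boundary: exactly 0.05% is not "more than"
        assert evaluate_chip_rules(v, chip_panel, cohort_frameshift_freq=0.0005).verdict == "pass"

    def test_no_vaf_floor_in_wes_mode(self, make_variant, chip_panel):
        v = make_variant(total_depth=200, alt_depth=2, alt_fwd=1, alt_rev=1,
                         ref_fwd=99, ref_rev=99)  # VAF 1%
        assert evaluate_chip_rules(v, chip_panel).verdict == "pass"

    def test_optional_vaf_floor_flag(self, make_variant, chip_panel):
        v = make_variant(total_depth=200, alt_depth=2, alt_fwd=1, alt_rev=1,
                         ref_fwd=99, ref_rev=99)
        t = WesThresholds(vaf_floor=0.02)
        assert "VF" in evaluate_chip_rules(v, chip_panel, thresholds=t).failed_rules

    def test_all_failed_rules_reported(self, make_variant, chip_panel):
        v = make_variant(gene="BRCA1", caller_label="x", somatic_quality=0.0,
                         germline_quality=99.0, gnomad_max_pop_af=0.5)
        failed = set(evaluate_chip_rules(v, chip_panel).failed_rules)
        assert failed == {"R1", "R2", "R3", "R4", "R5"}

    def test_missing_strand_counts_rejected(self, make_variant, chip_panel):
        v = make_variant(alt_fwd=None)
        with pytest.raises(ValueError, match="alt_fwd"):
            evaluate_chip_rules(v, chip_panel)

    def test_negative_count_rejected(self, make_variant, chip_panel):
        v = make_variant(ref_rev=-1)
        with pytest.raises(ValueError, match="ref_rev"):
            evaluate_chip_rules(v, chip_panel)


class TestLymphoidRules:
    def test_missense_with_cosmic_evidence_passes(self, make_variant, lymphoid_panel):
        v = make_variant(gene="KMT2D", cosmic_count=3, total_depth=50, alt_depth=5,
                         alt_fwd=3, alt_rev=2)
        assert evaluate_lymphoid_rules(v, lymphoid_panel).verdict == "pass"

    def test_vaf_window(self, make_variant, lymphoid_panel):
        v = make_variant(gene="KMT2D", total_depth=100, alt_depth=40,
                         ref_fwd=30, ref_rev=30, alt_fwd=20, alt_rev=20)
        assert evaluate_lymphoid_rules(v, lymphoid_panel).failed_rules == ("L1",)

    def test_nonsense_exempt_from_evidence_rule(self, make_variant, lymphoid_panel):
        v = make_variant(gene="KMT2D", consequence="nonsense", cosmic_count=0,
                         total_depth=100, alt_depth=5, ref_fwd=47, ref_rev=48,
                         alt_fwd=3, alt_rev=2)
        assert evaluate_lymphoid_rules(v, lymphoid_panel).verdict == "pass"

    def test_missense_without_evidence_fails_l2(self, make_variant, lymphoid_panel):
        v = make_variant(gene="KMT2D", cosmic_count=2)
        assert evaluate_lymphoid_rules(v, lymphoid_panel).failed_rules == ("L2",)

    @pytest.mark.parametrize("flag", ["reported_lchip", "reported_all"])
    def test_lchip_or_all_report_satisfies_l2(self, make_variant, lymphoid_panel, flag):
        v = make_variant(gene="KMT2D", cosmic_count=0, **{flag: True})
        assert evaluate_lymphoid_rules(v, lymphoid_panel).verdict == "pass"


class TestPanelRules:
    def test_depth_99_fails_p4(self, make_variant, chip_panel):
        v = make_variant(total_depth=99, alt_depth=10, ref_fwd=44, ref_rev=45,
                         alt_fwd=5, alt_rev=5)
        assert evaluate_panel_rules(v, chip_panel).failed_rules == ("P4",)

    def test_vaf_041_fails_p6(self, make_variant, chip_panel):
        v = make_variant(total_depth=1000, alt_depth=410, ref_fwd=295, ref_rev=295,
                         alt_fwd=205, alt_rev=205)
        assert evaluate_panel_rules(v, chip_panel).failed_rules == ("P6",)

    def test_vaf_0019_fails_p8(self, make_variant, chip_panel):
        v = make_variant(total_depth=1000, alt_depth=19, ref_fwd=490, ref_rev=491,
                         alt_fwd=10, alt_rev=9)
        assert evaluate_panel_rules(v, chip_panel).failed_rules == ("P8",)

    def test_cohort_frequency_fails_p3(self, make_variant, chip_panel):
        v = make_variant(total_depth=1000, alt_depth=100, ref_fwd=450, ref_rev=450,
                         alt_fwd=50, alt_rev=50)
        assert evaluate_panel_rules(v, chip_panel, cohort_allele_freq=0.02).failed_rules == ("P3",)
        assert evaluate_panel_rules(v, chip_panel, cohort_allele_freq=0.01).verdict == "pass"

    def test_no_hotspot_exemption_in_panel_mode(self, make_variant, chip_panel):
        v = make_variant(gene="JAK2", protein_change="V617F", gnomad_max_pop_af=0.002,
                         total_depth=1000, alt_depth=100, ref_fwd=450, ref_rev=450,
                         alt_fwd=50, alt_rev=50)
        assert "P2" in evaluate_panel_rules(v, chip_panel).failed_rules


class TestCollapse:
    def test_pairwise_collapse_keeps_higher_vaf(self, make_variant):
        a = make_variant(consequence="frameshift", pos=100, total_depth=100, alt_depth=12,
                         alt_fwd=6, alt_rev=6, ref_fwd=44, ref_rev=44)
        b = make_variant(consequence="frameshift", pos=103, total_depth=100, alt_depth=5,
                         alt_fwd=3, alt_rev=2, ref_fwd=47, ref_rev=48, alt="G")
        out = collapse_frameshift_clusters([a, b])
        assert out == [a]

    def test_single_frameshift_unchanged(self, make_variant):
        v = make_variant(consequence="frameshift")
        assert collapse_frameshift_clusters([v]) == [v]

    def test_transitive_chain_collapses_to_one(self, make_variant):
        def fs(pos, alt_depth):
            return make_variant(consequence="frameshift", pos=pos, total_depth=100,
                                alt_depth=alt_depth, alt_fwd=alt_depth // 2,
                                alt_rev=alt_depth - alt_depth // 2,
                                ref_fwd=40, ref_rev=40)
        chain = [fs(100, 3), fs(104, 10), fs(108, 4)]  # 100-108 > 5 but chained via 104
        out = collapse_frameshift_clusters(chain)
        assert [v.pos for v in out] == [104]

    def test_non_frameshifts_untouched(self, make_variant):
        m = make_variant(consequence="missense", pos=101)
        f = make_variant(consequence="frameshift", pos=100)
        out = collapse_frameshift_clusters([m, f])
        assert set(out) == {m, f}

    def test_empty_input(self):
        assert collapse_frameshift_clusters([]) == []

    def test_multiple_samples_rejected(self, make_variant):
        with pytest.raises(ValueError, match="one sample"):
            collapse_frameshift_clusters(
                [make_variant(sample_id="A"), make_variant(sample_id="B")]
            )

    @given(
        positions=st.lists(st.integers(min_value=1, max_value=60), min_size=0, max_size=12),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_transitive_oracle(self, positions, data):
        variants = []
        for i, pos in enumerate(positions):
            alt_depth = data.draw(st.integers(min_value=2, max_value=40))
            variants.append(
                AnnotatedVariant(
                    sample_id="S1", chrom="chr1", pos=pos, ref="AT", alt=f"A{i}",
                    gene="TET2", consequence="frameshift", total_depth=100,
                    alt_depth=alt_depth, ref_fwd=30, ref_rev=30,
                    alt_fwd=alt_depth // 2, alt_rev=alt_depth - alt_depth // 2,
                )
            )
        got = {(v.pos, v.alt) for v in collapse_frameshift_clusters(variants)}
        keep = oracles.oracle_collapse(variants)
        want = {(variants[i].pos, variants[i].alt) for i in keep}
        assert got == want


def _random_variant(rnd, i, genes):
    """A variant with each field drawn near its rule threshold."""
    consequence = rnd.choice(
        ["missense", "nonsense", "frameshift", "splice", "inframe_indel", "synonymous"]
    )
    total = rnd.randint(5, 120)
    alt = rnd.randint(0, max(1, total // 2))
    ref = total - alt
    alt_fwd = rnd.randint(0, alt) if alt else 0
    ref_fwd = rnd.randint(0, ref) if ref else 0
    return AnnotatedVariant(
        sample_id=f"S{rnd.randint(0, 40)}",
        chrom=rnd.choice(["chr1", "chr2"]),
        pos=rnd.randint(1, 300),
        ref="A",
        alt=rnd.choice(["T", "G", "C", "TA"]) + str(i),
        gene=rnd.choice(genes),
        consequence=consequence,
        caller_label=rnd.choice(["PASS", "PASS", "PASS", "LowQual"]),
        somatic_quality=rnd.uniform(0, 10),
        germline_quality=rnd.uniform(0, 20),
        total_depth=total,
        alt_depth=alt,
        ref_fwd=ref_fwd,
        ref_rev=ref - ref_fwd,
        alt_fwd=alt_fwd,
        alt_rev=alt - alt_fwd,
        gnomad_max_pop_af=rnd.choice([0.0, 0.0005, 0.002, 0.01]),
        cosmic_count=rnd.randint(0, 5),
        reported_lchip=rnd.random() < 0.2,
        reported_all=rnd.random() < 0.2,
        splice_distance_bp=rnd.choice([None, 0, 1, 2, 3, 10]) if consequence == "splice" else None,
        protein_change=rnd.choice([None, "V617F", "R882H", "R100Q"]),
    )


@pytest.fixture(scope="module")
def random_table():
    rnd = random.Random(99)
    genes = ["TET2", "DNMT3A", "JAK2", "OFFPANEL"]
    return [_random_variant(rnd, i, genes) for i in range(1000)]


class TestOracleEquivalence:
    N_SAMPLES = 50_000  # large denominator: single-sample frameshifts pass R9

    def test_wes_cascade_matches_oracle(self, random_table, chip_panel):
        decisions, _ = filter_chip_wes(random_table, chip_panel, self.N_SAMPLES)
        got = {
            (d.variant.sample_id, d.variant.chrom, d.variant.pos, d.variant.ref, d.variant.alt)
            for d in decisions if d.verdict == "pass"
        }
        want = oracles.oracle_wes_pass(random_table, chip_panel, self.N_SAMPLES)
        assert got == want

    def test_wes_per_rule_failures_match_oracle(self, random_table, chip_panel):
        ctx = {"fs_freq": oracles.cohort_fs_freq(random_table, self.N_SAMPLES)}
        rules = oracles.wes_rule_predicates(chip_panel)
        for v in random_table[:300]:
            d = evaluate_chip_rules(
                v, chip_panel, ctx["fs_freq"].get((v.chrom, v.pos, v.ref, v.alt), 0.0)
            )
            assert set(d.failed_rules) == oracles.oracle_failed_rules(v, rules, ctx)

    def test_lymphoid_cascade_matches_oracle(self, random_table, lymphoid_panel):
        table = [v for v in random_table]
        decisions = filter_lymphoid_wes(table, lymphoid_panel, self.N_SAMPLES)
        ctx = {"fs_freq": oracles.cohort_fs_freq(table, self.N_SAMPLES)}
        rules = oracles.lymphoid_rule_predicates(lymphoid_panel)
        got = {i for i, d in enumerate(decisions) if d.verdict == "pass"}
        want = oracles.oracle_pass_set(table, rules, ctx)
        assert got == want

    def test_panel_cascade_matches_oracle(self, random_table, chip_panel):
        decisions, _ = filter_chip_panel(random_table, chip_panel, self.N_SAMPLES)
        ctx = {"af": oracles.cohort_af(random_table, self.N_SAMPLES)}
        rules = oracles.panel_rule_predicates(chip_panel)
        got = {i for i, d in enumerate(decisions) if d.verdict == "pass"}
        want = oracles.oracle_pass_set(random_table, rules, ctx)
        assert got == want


class TestCascadeProperties:
    def test_monotonicity_in_thresholds(self, random_table, chip_panel):
        base = WesThresholds()
        relaxed = WesThresholds(min_total_depth=5, min_somatic_quality=1.0,
                                max_germline_quality=20.0, max_gnomad_af=0.01)
        tightened = WesThresholds(min_total_depth=30, min_somatic_quality=8.0,
                                  max_germline_quality=5.0, max_gnomad_af=0.0001)
        def passes(th):
            d, _ = filter_chip_wes(random_table, chip_panel, 50_000, thresholds=th)
            return {i for i, x in enumerate(d) if x.verdict == "pass"}
        assert passes(base) <= passes(relaxed)
        assert passes(tightened) <= passes(base)

    def test_idempotence(self, random_table, chip_panel):
        decisions, _ = filter_chip_wes(random_table, chip_panel, 50_000)
        survivors = [d.variant for d in decisions if d.verdict == "pass"]
        again, _ = filter_chip_wes(survivors, chip_panel, 50_000)
        assert all(d.verdict == "pass" for d in again)

    def test_row_order_invariance(self, random_table, chip_panel):
        decisions, _ = filter_chip_wes(random_table, chip_panel, 50_000)
        shuffled = list(random_table)
        random.Random(7).shuffle(shuffled)
        decisions2, _ = filter_chip_wes(shuffled, chip_panel, 50_000)
        key = lambda d: (d.variant.sample_id, d.variant.chrom, d.variant.pos, d.variant.alt)
        a = sorted(((key(d), tuple(sorted(d.failed_rules))) for d in decisions))
        b = sorted(((key(d), tuple(sorted(d.failed_rules))) for d in decisions2))
        assert a == b

    def test_counting_identities(self, random_table, chip_panel):
        decisions, profiles = filter_chip_wes(random_table, chip_panel, 50_000)
        n_pass = sum(d.verdict == "pass" for d in decisions)
        assert sum(p.n_variants for p in profiles) == n_pass
        assert sum(p.carrier for p in profiles) == sum(1 for p in profiles if p.n_variants)

    def test_n_samples_smaller_than_distinct_rejected(self, random_table, chip_panel):
        with pytest.raises(ValueError, match="n_samples"):
            filter_chip_wes(random_table, chip_panel, 2)

    def test_empty_table_no_carriers(self, chip_panel):
        decisions, profiles = filter_chip_wes([], chip_panel, 10, samples=["A", "B"])
        assert decisions == []
        assert all(not p.carrier for p in profiles)

    def test_recurrent_frameshift_fails_r9(self, make_variant, chip_panel):
        # the same frameshift allele in 6 of 1000 samples (0.6%) fails in all 6
        table = [
            make_variant(sample_id=f"S{i}", consequence="frameshift", ref="CT", alt="C")
            for i in range(6)
        ]
        decisions, _ = filter_chip_wes(table, chip_panel, 1000)
        assert all(d.failed_rules == ("R9",) for d in decisions)


class TestCarrierProfiles:
    def _decisions(self, variants, panel):
        return [evaluate_chip_rules(v, panel) for v in variants]

    def test_low_vaf_stratum(self, make_variant, chip_panel):
        a = make_variant(total_depth=100, alt_depth=4, alt_fwd=2, alt_rev=2, ref_fwd=48, ref_rev=48)
        b = make_variant(pos=999, total_depth=100, alt_depth=8, alt_fwd=4, alt_rev=4,
                         ref_fwd=46, ref_rev=46)
        profiles = build_carrier_profiles(self._decisions([a, b], chip_panel), ["S1"])
        (p,) = profiles
        assert p.carrier and p.vaf_stratum == "lt10" and p.max_vaf == pytest.approx(0.08)

    def test_non_carrier(self, chip_panel):
        (p,) = build_carrier_profiles([], ["S9"])
        assert not p.carrier and p.max_vaf is None and p.vaf_stratum is None
        assert not any(p.gene_groups.values())

    def test_gene_group_flags(self, make_variant, chip_panel):
        tet2 = make_variant(gene="TET2", total_depth=100, alt_depth=5, alt_fwd=3,
                            alt_rev=2, ref_fwd=47, ref_rev=48)
        dnmt = make_variant(gene="DNMT3A", chrom="chr2", pos=25_234_000, total_depth=100,
                            alt_depth=12, alt_fwd=6, alt_rev=6, ref_fwd=44, ref_rev=44)
        (p,) = build_carrier_profiles(self._decisions([tet2, dnmt], chip_panel), ["S1"])
        assert p.gene_groups == {
            "DNMT3A": True, "TET2": True, "JAK2": False,
            "non_DNMT3A": True, "non_DNMT3A_non_JAK2": True,
        }
        assert p.vaf_stratum == "ge10"

    def test_dnmt3a_only_carrier(self, make_variant, chip_panel):
        v = make_variant(gene="DNMT3A", chrom="chr2", pos=25_234_000)
        (p,) = build_carrier_profiles(self._decisions([v], chip_panel), ["S1"])
        assert p.gene_groups["DNMT3A"]
        assert not p.gene_groups["non_DNMT3A"]
        assert not p.gene_groups["non_DNMT3A_non_JAK2"]

    def test_jak2_only_carrier(self, make_variant, chip_panel):
        v = make_variant(gene="JAK2", chrom="chr9", pos=5_073_770)
        (p,) = build_carrier_profiles(self._decisions([v], chip_panel), ["S1"])
        assert p.gene_groups["JAK2"]
        assert p.gene_groups["non_DNMT3A"]
        assert not p.gene_groups["non_DNMT3A_non_JAK2"]

    def test_duplicate_passing_rows_rejected(self, make_variant, chip_panel):
        v = make_variant()
        with pytest.raises(ValueError, match="duplicate"):
            build_carrier_profiles(self._decisions([v, v], chip_panel), ["S1"])
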