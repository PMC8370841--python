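"""Diplotype calling, metabolizer phenotyping and PD variant counting."""

import itertools

import pytest

from pgxcohort.panel import GenotypeClass
from pgxcohort.phenotype import (
    IndeterminateGenotype,
    MetabolizerPhenotype,
    ProfileType,
    build_profile,
    call_diplotype,
    call_phenotype,
    classify_profile_type,
    count_pd_variants,
    phenotype_from_activity,
)
from conftest import make_genotype

REF = GenotypeClass.REF_HOMOZYGOUS
HET = GenotypeClass.HETEROZYGOUS
HOM = GenotypeClass.VARIANT_HOMOZYGOUS
NC = GenotypeClass.NO_CALL


class TestCallDiplotype:
    def test_all_reference_is_wildtype(self, panel, translation_table, all_ref_genotype):
        pair, activity = call_diplotype("CYP2C19", all_ref_genotype, translation_table, panel)
        assert pair == ("*1", "*1")
        assert activity == 2.0

    def test_het_star2(self, panel, translation_table):
        g = make_genotype(panel, {"rs4244285": HET})
        pair, activity = call_diplotype("CYP2C19", g, translation_table, panel)
        assert pair == ("*1", "*2")
        assert activity == 1.0

    def test_hom_star4_null(self, panel, translation_table):
        g = make_genotype(panel, {"rs3892097": HOM})
        pair, activity = call_diplotype("CYP2D6", g, translation_table, panel)
        assert pair == ("*4", "*4")
        assert activity == 0.0

    def test_two_het_null_sites_in_trans(self, panel, translation_table):
        # unphased het at two no-function sites -> compound heterozygote
        g = make_genotype(panel, {"rs4244285": HET, "rs4986893": HET})
        pair, activity = call_diplotype("CYP2C19", g, translation_table, panel)
        assert set(pair) == {"*2", "*3"}
        assert activity == 0.0

    def test_copy_number_scales_cyp2d6_activity(self, panel, translation_table):
        g = make_genotype(panel, cn=3)
        _, activity = call_diplotype("CYP2D6", g, translation_table, panel)
        assert activity == pytest.approx(3.0)

    def test_all_no_call_raises_indeterminate(self, panel, translation_table):
        overrides = {r: NC for r in panel.sites_for_gene("CYP2C19")}
        g = make_genotype(panel, overrides)
        with pytest.raises(IndeterminateGenotype):
            call_diplotype("CYP2C19", g, translation_table, panel)

    def test_brute_force_oracle_equivalence(self, panel, translation_table):
        """Greedy caller agrees with exhaustive diplotype enumeration on
        activity for every genotype combination at three CYP2C19
        defining sites (the oracle enumerates all assignments of allele
        copies consistent with the variant doses)."""
        sites = ["rs4244285", "rs4986893", "rs12248560"]
        alleles = {  # single-site definitions for these sites
            "rs4244285": ("*2", 0.0),
            "rs4986893": ("*3", 0.0),
            "rs12248560": ("*17", 1.25),
        }

        def oracle_activity(states):
            doses = {s: {REF: 0, HET: 1, HOM: 2}[c] for s, c in zip(sites, states)}
            best = None
            # enumerate how many copies of each defining allele to assign
            ranges = [range(doses[s], doses[s] + 1) for s in sites]  # dose fixed
            combo = [doses[s] for s in sites]
            if sum(combo) <= 2:
                acts = [alleles[s][1] for s, d in zip(sites, combo) for _ in range(d)]
                acts += [1.0] * (2 - len(acts))
                best = sum(acts)
            else:
                # more variant doses than haplotype slots: the caller
                # keeps the highest-priority (lowest allele number) two
                ordered = sorted(
                    ((int(alleles[s][0][1:]), alleles[s][1], d)
                     for s, d in zip(sites, combo) if d)
                )
                acts = []
                for _, act, d in ordered:
                    acts += [act] * min(d, 2 - len(acts))
                best = sum(acts[:2])
            return best

        for states in itertools.product([REF, HET, HOM], repeat=3):
            g = make_genotype(panel, dict(zip(sites, states)))
            _, activity = call_diplotype("CYP2C19", g, translation_table, panel)
            assert activity == pytest.approx(oracle_activity(states)), states


class TestPhenotypeFromActivity:
    @pytest.mark.parametrize(
        "activity,expected",
        [
            (0.0, MetabolizerPhenotype.POOR),
            (0.5, MetabolizerPhenotype.INTERMEDIATE),
            (1.0, MetabolizerPhenotype.INTERMEDIATE),
            (1.25, MetabolizerPhenotype.NORMAL),
            (2.0, MetabolizerPhenotype.NORMAL),
            (2.25, MetabolizerPhenotype.NORMAL),
            (2.5, MetabolizerPhenotype.ULTRARAPID),
        ],
    )
    def test_thresholds(self, activity, expected):
        assert phenotype_from_activity("CYP2C19", activity) is expected

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            phenotype_from_activity("CYP2C19", -0.1)

    def test_cyp2c19_star17_homozygote_is_ultrarapid(self, panel, translation_table):
        g = make_genotype(panel, {"rs12248560": HOM})
        assert call_phenotype("CYP2C19", g, translation_table, panel) is (
            MetabolizerPhenotype.ULTRARAPID
        )

    def test_cyp2d6_um_requires_duplication(self):
        # activity above the normal band without a declared duplication
        # is not called ultrarapid for CYP2D6
        assert phenotype_from_activity("CYP2D6", 2.5, copy_number=2) is (
            MetabolizerPhenotype.NORMAL
        )
        assert phenotype_from_activity("CYP2D6", 3.0, copy_number=3) is (
            MetabolizerPhenotype.ULTRARAPID
        )

    def test_full_spectrum_reachable_for_cyp2c19(self, panel, translation_table):
        cases = {
            MetabolizerPhenotype.POOR: {"rs4244285": HOM},
            MetabolizerPhenotype.INTERMEDIATE: {"rs4244285": HET},
            MetabolizerPhenotype.NORMAL: {},
            MetabolizerPhenotype.ULTRARAPID: {"rs12248560": HOM},
        }
        for expected, overrides in cases.items():
            g = make_genotype(panel, overrides)
            assert call_phenotype("CYP2C19", g, translation_table, panel) is expected


class TestCountPdVariants:
    def test_all_reference_counts_zero(self, panel, all_ref_genotype):
        assert count_pd_variants(all_ref_genotype, panel) == 0

    def test_two_het_pd_sites(self, panel):
        g = make_genotype(panel, {"rs6265": HET, "rs4680": HET})
        assert count_pd_variants(g, panel) == 2

    def test_zygosity_insensitive(self, panel):
        g = make_genotype(panel, {"rs1045642": HOM})
        assert count_pd_variants(g, panel) == 1

    def test_pk_gene_variants_not_counted(self, panel):
        g = make_genotype(panel, {"rs4244285": HOM, "rs1799853": HET})
        assert count_pd_variants(g, panel) == 0

    def test_rs2952768_counted_once(self, panel):
        # annotated under three gene contexts but one physical site
        g = make_genotype(panel, {"rs2952768": HET})
        assert count_pd_variants(g, panel) == 1

    def test_adding_a_variant_never_decreases_count(self, panel):
        pd_sites = [r for r in sorted(panel.rsids) if panel.is_pd_site(r)]
        g = make_genotype(panel)
        prev = count_pd_variants(g, panel)
        for rsid in pd_sites[:10]:
            g = make_genotype(panel, {s: HET for s in pd_sites[: pd_sites.index(rsid) + 1]})
            cur = count_pd_variants(g, panel)
            assert cur >= prev
            prev = cur


class TestProfiles:
    def test_pk_only_profile(self, panel, translation_table):
        g = make_genotype(panel, {"rs4244285": HET})
        profile = build_profile(g, panel, translation_table)
        assert profile.cyp2c19 is MetabolizerPhenotype.INTERMEDIATE
        assert profile.profile_type is ProfileType.PHARMACOKINETIC

    def test_pd_only_profile(self, panel, translation_table):
        g = make_genotype(panel, {"rs6265": HET, "rs4680": HET, "rs6313": HOM})
        profile = build_profile(g, panel, translation_table)
        assert profile.pd_variant_count == 3
        assert profile.profile_type is ProfileType.PHARMACODYNAMIC

    def test_both_profile(self, panel, translation_table):
        g = make_genotype(panel, {"rs3892097": HOM, "rs6265": HET, "rs4680": HET})
        profile = build_profile(g, panel, translation_table)
        assert profile.cyp2d6 is MetabolizerPhenotype.POOR
        assert profile.profile_type is ProfileType.BOTH

    def test_none_profile(self, panel, translation_table, all_ref_genotype):
        profile = build_profile(all_ref_genotype, panel, translation_table)
        assert profile.profile_type is ProfileType.NONE

    def test_indeterminate_treated_as_normal_for_typing(self):
        pt = classify_profile_type(
            MetabolizerPhenotype.INDETERMINATE, MetabolizerPhenotype.NORMAL, 2
        )
        assert pt is ProfileType.PHARMACODYNAMIC

    def test_determinism(self, panel, translation_table):
        g = make_genotype(panel, {"rs4244285": HET, "rs6265": HOM})
        p1 = build_profile(g, panel, translation_table)
        p2 = build_profile(g, panel, translation_table)
        assert p1 == p2
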