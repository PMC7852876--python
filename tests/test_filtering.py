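"""Variant-filtering criteria: boundary behaviour of each rule, the
classification map, extrapolation arithmetic, callable-site counting, and
the monotonicity property of the quality/depth thresholds."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sibline.errors import ConfigError, InputError
from sibline.filtering import (
    FAIL,
    NOT_EVALUATED,
    PASS,
    CallableSiteTally,
    FilterThresholds,
    SampleRoleMap,
    SiteCall,
    apply_primary_criteria,
    apply_secondary_criteria,
    build_observed_sfs,
    classify_focal_genotypes,
    count_callable_sites,
    filter_strain,
    sample_and_extrapolate,
)
from sibline.sfs import SFSVector

ROLES = SampleRoleMap(
    strains={"C3H": ("C3H_A", "C3H_B"), "BL6": ("BL6_A", "BL6_B")},
    bait=("WILD_01", "WILD_02"),
)
SAMPLES = ROLES.all_samples()


def make_site(
    pos=1000,
    qual=500.0,
    alts=("T",),
    ref="A",
    focal=("0/1", "0/0"),
    dp=30,
    bait_alt=0,
    nonfocal_alt=0,
    het_ad=None,
    chrom="chr1",
    ps=None,
):
    """A C3H-focal site over the fixture role map; other samples hom-ref."""
    gts, dps, ads, pss = {}, {}, {}, {}

    def parse_gt(s):
        a, b = s.replace("|", "/").split("/")
        return (int(a), int(b))

    n_alleles = 1 + len(alts)
    for s in SAMPLES:
        gts[s] = parse_gt("0/0")
        dps[s] = dp
        ads[s] = tuple([dp] + [0] * (n_alleles - 1))
        pss[s] = None
    gts["C3H_A"], gts["C3H_B"] = parse_gt(focal[0]), parse_gt(focal[1])
    for s, gt in (("C3H_A", gts["C3H_A"]), ("C3H_B", gts["C3H_B"])):
        n_alt = sum(1 for a in gt if a > 0)
        if n_alt == 1:
            ad = het_ad if het_ad is not None else (dp // 2, dp - dp // 2)
            ads[s] = tuple(list(ad) + [0] * (n_alleles - 1 - (len(ad) - 1)))
            dps[s] = sum(ad)
        elif n_alt == 2:
            ads[s] = tuple([0, dp] + [0] * (n_alleles - 2))
    if bait_alt:
        ads["WILD_01"] = (dp - bait_alt, bait_alt)
    if nonfocal_alt:
        ads["BL6_A"] = (dp - nonfocal_alt, nonfocal_alt)
    if ps:
        pss["C3H_A"] = pss["C3H_B"] = ps
    return SiteCall(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), qual=qual,
                    gts=gts, dp=dps, ad=ads, ps=pss)


class TestClassifyFocalGenotypes:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 1), (0, 0), "RARR"),
            ((1, 1), (0, 1), "AARA"),
            ((0, 0), (0, 0), None),
            ((1, 1), (1, 1), None),
        ],
    )
    def test_table_mapping(self, a, b, expected):
        assert classify_focal_genotypes(a, b) == expected

    def test_missing_genotype_not_classifiable(self):
        assert classify_focal_genotypes(None, (0, 0)) is None
        assert classify_focal_genotypes((-1, 0), (0, 0)) is None


class TestPrimaryCriteria:
    def test_clean_het_site_passes_and_is_classified(self):
        d = apply_primary_criteria(make_site(), ROLES, "C3H")
        assert d.overall_primary and d.element == "RARR"

    def test_qual_boundary(self):
        assert apply_primary_criteria(make_site(qual=89.0), ROLES, "C3H").flags["c1"] == FAIL
        assert apply_primary_criteria(make_site(qual=90.0), ROLES, "C3H").flags["c1"] == PASS

    def test_depth_boundary_applies_to_every_inbred(self):
        site = make_site()
        site.dp["BL6_B"] = 9
        d = apply_primary_criteria(site, ROLES, "C3H")
        assert d.flags["c2"] == FAIL
        site.dp["BL6_B"] = 10
        assert apply_primary_criteria(site, ROLES, "C3H").flags["c2"] == PASS

    def test_bait_purity_allows_single_stray_read(self):
        assert apply_primary_criteria(make_site(bait_alt=1), ROLES, "C3H").flags["c3"] == PASS
        assert apply_primary_criteria(make_site(bait_alt=2), ROLES, "C3H").flags["c3"] == FAIL

    def test_nonfocal_purity_counts_reads_not_genotypes(self):
        site = make_site(nonfocal_alt=2)  # genotype still 0/0
        d = apply_primary_criteria(site, ROLES, "C3H")
        assert d.flags["c4"] == FAIL

    def test_fixed_strain_difference_fails_copy_cap(self):
        d = apply_primary_criteria(make_site(focal=("1/1", "1/1")), ROLES, "C3H")
        assert d.flags["c5"] == FAIL  # four copies exceeds the cap of three

    def test_three_copies_passes_copy_cap(self):
        d = apply_primary_criteria(make_site(focal=("1/1", "0/1")), ROLES, "C3H")
        assert d.flags["c5"] == PASS and d.element == "AARA"

    def test_nonfocal_alt_genotype_fails_background(self):
        site = make_site()
        site.gts["BL6_A"] = (0, 1)
        assert apply_primary_criteria(site, ROLES, "C3H").flags["c5"] == FAIL

    def test_missing_focal_genotype_fails_closed(self):
        site = make_site()
        site.gts["C3H_A"] = (-1, -1)
        d = apply_primary_criteria(site, ROLES, "C3H")
        assert d.flags["c5"] == FAIL and not d.overall_primary

    def test_indel_fails_snv_rule(self):
        d = apply_primary_criteria(make_site(alts=("AT",)), ROLES, "C3H")
        assert d.flags["c6"] == FAIL

    def test_missing_bait_ad_is_not_evaluated_and_fails_closed(self):
        site = make_site()
        site.ad["WILD_01"] = None
        d = apply_primary_criteria(site, ROLES, "C3H")
        assert d.flags["c3"] == NOT_EVALUATED and not d.overall_primary


class TestSecondaryCriteria:
    def _primary(self, site):
        d = apply_primary_criteria(site, ROLES, "C3H")
        assert d.overall_primary
        return d

    def test_allele_balance_boundary(self):
        low = make_site(het_ad=(9, 2))  # 2/11 ~ 0.18
        d = apply_secondary_criteria(low, self._primary(low), ROLES, [], 60.0)
        assert d.flags["c7"] == FAIL
        ok = make_site(het_ad=(9, 3))  # exactly 0.25
        d = apply_secondary_criteria(ok, self._primary(ok), ROLES, [], 60.0)
        assert d.flags["c7"] == PASS

    def test_depth_cap_against_genomic_mean(self):
        site = make_site(het_ad=(75, 75))  # pair depth 150 + 30
        d = apply_secondary_criteria(site, self._primary(site), ROLES, [], 2 * 30.0)
        assert d.flags["c8"] == FAIL

    def test_proximity_cluster_within_window(self):
        a, b = make_site(pos=1000), make_site(pos=1040)
        da = apply_secondary_criteria(a, self._primary(a), ROLES, [b], 60.0)
        db = apply_secondary_criteria(b, self._primary(b), ROLES, [a], 60.0)
        assert da.flags["c9"] == FAIL and db.flags["c9"] == FAIL

    def test_distant_candidates_pass_proximity(self):
        a, b = make_site(pos=1000), make_site(pos=5000)
        d = apply_secondary_criteria(a, self._primary(a), ROLES, [b], 60.0)
        assert d.flags["c9"] == PASS

    def test_shared_phase_set_fails_even_when_distant(self):
        a, b = make_site(pos=1000, ps=7), make_site(pos=50_000, ps=7)
        d = apply_secondary_criteria(a, self._primary(a), ROLES, [b], 60.0)
        assert d.flags["c9"] == FAIL

    def test_multiallelic_fails_allele_cap(self):
        site = make_site(alts=("T", "G"), focal=("0/1", "0/2"))
        d = apply_secondary_criteria(site, self._primary(site), ROLES, [], 60.0)
        assert d.flags["c10"] == FAIL

    def test_mate_placement_never_evaluated_at_vcf_level(self):
        site = make_site()
        d = apply_secondary_criteria(site, self._primary(site), ROLES, [], 60.0)
        assert d.flags["c11"] == NOT_EVALUATED
        assert d.overall_secondary  # c11 does not gate the decision


class TestExtrapolation:
    @pytest.mark.parametrize(
        "n_pre,frac,expected",
        [(500, 0.98, 490), (1000, 0.52, 520), (250, 1.0, 250), (0, 0.5, 0)],
    )
    def test_rounded_scaling(self, n_pre, frac, expected):
        assert sample_and_extrapolate(n_pre, frac) == expected

    def test_zero_sample_size_is_error(self):
        with pytest.raises(ConfigError):
            sample_and_extrapolate(100, 0.5, sample_size=0)


class TestObservedSFS:
    def _decisions(self, elements):
        from sibline.filtering import FilterDecision

        out = []
        for i, e in enumerate(elements):
            d = FilterDecision(chrom="chr1", pos=100 * (i + 1), strain="C3H")
            d.element = e
            out.append(d)
        return out

    def test_single_site(self):
        v, (na, nb) = build_observed_sfs(self._decisions(["RARR"]))
        assert v.as_dict()["RARR"] == 1 and v.total == 1
        assert (na, nb) == (1, 0)

    def test_per_individual_carrier_counts(self):
        v, (na, nb) = build_observed_sfs(self._decisions(["RARR", "RRRA", "AARA"]))
        assert (na, nb) == (2, 2)


class TestCallableSites:
    def _nonvariant(self, pos, dp=30, chrom="chr1"):
        return SiteCall(
            chrom=chrom, pos=pos, ref="A", alts=(), qual=None,
            gts={s: (0, 0) for s in SAMPLES},
            dp={s: dp for s in SAMPLES},
            ad={s: (dp,) for s in SAMPLES},
        )

    def test_low_depth_site_not_callable(self):
        sites = [self._nonvariant(p) for p in range(1, 11)]
        sites[3].dp["C3H_A"] = 9
        tally = count_callable_sites(sites, ROLES)
        assert tally.total == 9

    def test_all_records_passing_count_fully(self):
        sites = [self._nonvariant(p) for p in range(1, 6)]
        assert count_callable_sites(sites, ROLES).total == 5

    def test_variant_only_input_is_error(self):
        with pytest.raises(InputError):
            count_callable_sites([make_site()], ROLES)

    def test_tsv_round_trip(self, tmp_path):
        tally = CallableSiteTally({"chr1": 100, "chr2": 250})
        p = tmp_path / "callable.tsv"
        tally.to_tsv(p)
        assert CallableSiteTally.from_tsv(p).per_chromosome == tally.per_chromosome


class TestRoleMap:
    def test_nonfocal_inbred_excludes_focal_pair(self):
        assert set(ROLES.nonfocal_inbred("C3H")) == {"BL6_A", "BL6_B"}

    def test_single_focal_sample_rejected(self):
        with pytest.raises(ConfigError):
            SampleRoleMap(strains={"X": ("a",)}, bait=("w",))

    def test_missing_bait_warns(self):
        with pytest.warns(UserWarning):
            SampleRoleMap(strains={"X": ("a", "b")})

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "roles.yaml"
        ROLES.to_yaml(p)
        loaded = SampleRoleMap.from_yaml(p)
        assert loaded.strains == ROLES.strains and loaded.bait == ROLES.bait


class TestMonotonicity:
    @given(
        qual=st.floats(min_value=0, max_value=200),
        dp=st.integers(min_value=0, max_value=40),
        dq=st.floats(min_value=0, max_value=50),
        ddp=st.integers(min_value=0, max_value=10),
    )
    def test_raising_thresholds_never_admits_more_sites(self, qual, dp, dq, ddp):
        site = make_site(qual=qual, dp=max(dp, 1))
        loose = FilterThresholds()
        strict = FilterThresholds(min_qual=loose.min_qual + dq, min_dp_inbred=loose.min_dp_inbred + ddp)
        if apply_primary_criteria(site, ROLES, "C3H", strict).overall_primary:
            assert apply_primary_criteria(site, ROLES, "C3H", loose).overall_primary

    def test_every_rejected_site_reports_a_failing_criterion(self):
        bad_sites = [
            make_site(qual=10),
            make_site(alts=("AT",)),
            make_site(bait_alt=3),
            make_site(focal=("1/1", "1/1")),
        ]
        for site in bad_sites:
            d = apply_primary_criteria(site, ROLES, "C3H")
            assert not d.overall_primary and d.first_failing is not None
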