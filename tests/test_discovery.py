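"""Concordance scoring, classification, false-positive screening."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sexlink import (
    Sex,
    classify_sexlinked,
    false_positive_test,
    filter_call_ratio,
    locus_call_stats,
    pa_concordance,
    snp_concordance,
    summarize_discovery,
)
from sexlink.discovery import SexLinkedLocus, SexLinkedSet

M, F = Sex.MALE, Sex.FEMALE


# ---------------------------------------------------------------------------
# per-locus call statistics and the call-ratio filter
# ---------------------------------------------------------------------------

class TestCallStats:
    def test_complete_data(self, snp_factory):
        calls = [[1] * 10 + [0] * 10]
        stats = locus_call_stats(snp_factory(calls, "M" * 10 + "F" * 10), "L1")
        assert stats.call_ratio == 1.0
        assert stats.male_geno == (0, 10, 0)
        assert stats.female_geno == (10, 0, 0)

    def test_partial_missingness(self, snp_factory):
        calls = [[-1] * 4 + [0] * 16]
        stats = locus_call_stats(snp_factory(calls, "M" * 10 + "F" * 10), "L1")
        assert stats.call_ratio == pytest.approx(0.8)

    def test_all_missing_locus(self, snp_factory):
        stats = locus_call_stats(snp_factory([[-1, -1]], "MF"), "L1")
        assert stats.call_ratio == 0.0
        assert stats.n_called == 0

    def test_unknown_sex_excluded(self, snp_factory):
        stats = locus_call_stats(snp_factory([[1, 0, 2]], "MFU"), "L1")
        assert stats.n_male == 1 and stats.n_female == 1
        assert stats.n_called == 2

    def test_unknown_locus_errors(self, snp_factory):
        with pytest.raises(KeyError, match="nope"):
            locus_call_stats(snp_factory([[0, 0]], "MF"), "nope")


class TestCallRatioFilter:
    def test_boundary_locus_is_retained(self, snp_factory):
        calls = [[-1] * 4 + [0] * 16,   # exactly 0.8
                 [-1] * 5 + [0] * 15]   # 0.75, below
        out = filter_call_ratio(snp_factory(calls, "M" * 10 + "F" * 10), 0.8)
        assert out.locus_ids == ["L1"]

    def test_full_matrix_identity_at_threshold_one(self, snp_factory):
        matrix = snp_factory([[0, 1], [2, 1]], "MF")
        out = filter_call_ratio(matrix, 1.0)
        assert out.locus_ids == matrix.locus_ids

    def test_preserves_order(self, snp_factory):
        calls = np.zeros((5, 4), dtype=np.int8)
        out = filter_call_ratio(snp_factory(calls, "MMFF"), 0.8)
        assert out.locus_ids == [f"L{i}" for i in range(1, 6)]


# ---------------------------------------------------------------------------
# concordance: worked examples
# ---------------------------------------------------------------------------

class TestSnpConcordance:
    def test_mixed_locus_xy(self, snp_factory):
        # males {het, het, hom_ref}, females {hom_ref, hom_ref, het}
        stats = locus_call_stats(
            snp_factory([[1, 1, 0, 0, 0, 1]], "MMMFFF"), "L1")
        r = snp_concordance(stats, M)
        assert r.concordance == pytest.approx(4 / 6)
        assert r.system == "XY"

    def test_same_locus_under_zw(self, snp_factory):
        stats = locus_call_stats(
            snp_factory([[1, 1, 0, 0, 0, 1]], "MMMFFF"), "L1")
        r = snp_concordance(stats, F)
        assert r.concordance == pytest.approx(2 / 6)
        assert r.system == "ZW"

    def test_perfect_xy_locus(self, snp_factory):
        stats = locus_call_stats(
            snp_factory([[1] * 9 + [0] * 10], "M" * 9 + "F" * 10), "L1")
        r = snp_concordance(stats, M)
        assert r.concordance == 1.0
        assert r.sex_limited_allele == "alt"

    def test_sex_limited_allele_ref_when_females_hom_alt(self, snp_factory):
        stats = locus_call_stats(
            snp_factory([[1] * 3 + [2] * 3], "MMMFFF"), "L1")
        r = snp_concordance(stats, M)
        assert r.sex_limited_allele == "ref"

    def test_homozygote_tie_leaves_allele_undefined(self, snp_factory):
        stats = locus_call_stats(
            snp_factory([[1, 1, 0, 2]], "MMFF"), "L1")
        r = snp_concordance(stats, M)
        assert r.sex_limited_allele is None and r.allele_tie

    def test_zero_called_sex_raises(self, snp_factory):
        stats = locus_call_stats(snp_factory([[1, -1]], "MF"), "L1")
        with pytest.raises(ValueError, match="zero called"):
            snp_concordance(stats, M)


class TestPaConcordance:
    def test_perfect_male_fragment(self, pa_factory):
        stats = locus_call_stats(
            pa_factory([[1] * 8 + [0] * 8], "M" * 8 + "F" * 8), "P1")
        assert pa_concordance(stats, M).concordance == 1.0

    def test_partial_fragment(self, pa_factory):
        calls = [[1] * 6 + [0] * 2 + [0] * 7 + [1]]
        stats = locus_call_stats(pa_factory(calls, "M" * 8 + "F" * 8), "P1")
        assert pa_concordance(stats, M).concordance == pytest.approx(13 / 16)

    def test_uninformative_marker(self, pa_factory):
        stats = locus_call_stats(
            pa_factory([[1] * 16], "M" * 8 + "F" * 8), "P1")
        assert pa_concordance(stats, M).concordance == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# concordance: brute-force oracle and symmetry (property tests)
# ---------------------------------------------------------------------------

def brute_force_snp_concordance(calls_row, sexes, heterogametic):
    conf = called = 0
    for call, sex in zip(calls_row, sexes):
        if sex == "U" or call == -1:
            continue
        called += 1
        if sex == heterogametic:
            conf += call == 1
        else:
            conf += call in (0, 2)
    return conf / called


def brute_force_pa_concordance(calls_row, sexes, limited_to):
    conf = called = 0
    for call, sex in zip(calls_row, sexes):
        if sex == "U" or call == -1:
            continue
        called += 1
        conf += (call == 1) if sex == limited_to else (call == 0)
    return conf / called


matrix_shape = st.tuples(st.integers(1, 6), st.integers(2, 8))


@st.composite
def snp_case(draw):
    n_loci, n_ind = draw(matrix_shape)
    sexes = draw(st.lists(st.sampled_from("MFU"), min_size=n_ind,
                          max_size=n_ind))
    calls = draw(st.lists(
        st.lists(st.integers(-1, 2), min_size=n_ind, max_size=n_ind),
        min_size=n_loci, max_size=n_loci))
    return calls, "".join(sexes)


@st.composite
def pa_case(draw):
    n_loci, n_ind = draw(matrix_shape)
    sexes = draw(st.lists(st.sampled_from("MFU"), min_size=n_ind,
                          max_size=n_ind))
    calls = draw(st.lists(
        st.lists(st.integers(-1, 1), min_size=n_ind, max_size=n_ind),
        min_size=n_loci, max_size=n_loci))
    return calls, "".join(sexes)


def _called_per_sex_ok(row, sexes):
    m = sum(1 for c, s in zip(row, sexes) if s == "M" and c != -1)
    f = sum(1 for c, s in zip(row, sexes) if s == "F" and c != -1)
    return m >= 1 and f >= 1


class TestConcordanceProperties:
    @given(snp_case())
    def test_snp_matches_exhaustive_count(self, case):
        from conftest import build_snp
        calls, sexes = case
        matrix = build_snp(calls, sexes)
        for i, lid in enumerate(matrix.locus_ids):
            if not _called_per_sex_ok(calls[i], sexes):
                continue
            stats = locus_call_stats(matrix, lid)
            for het, het_char in ((M, "M"), (F, "F")):
                assert snp_concordance(stats, het).concordance == \
                    pytest.approx(
                        brute_force_snp_concordance(calls[i], sexes, het_char))

    @given(pa_case())
    def test_pa_matches_exhaustive_count(self, case):
        from conftest import build_pa
        calls, sexes = case
        matrix = build_pa(calls, sexes)
        for i, lid in enumerate(matrix.locus_ids):
            if not _called_per_sex_ok(calls[i], sexes):
                continue
            stats = locus_call_stats(matrix, lid)
            for sex, char in ((M, "M"), (F, "F")):
                assert pa_concordance(stats, sex).concordance == \
                    pytest.approx(
                        brute_force_pa_concordance(calls[i], sexes, char))

    @given(snp_case())
    def test_sex_label_swap_symmetry(self, case):
        from conftest import build_snp
        calls, sexes = case
        swapped = sexes.translate(str.maketrans("MF", "FM"))
        a = build_snp(calls, sexes)
        b = build_snp(calls, swapped)
        for i, lid in enumerate(a.locus_ids):
            if not _called_per_sex_ok(calls[i], sexes):
                continue
            ra = snp_concordance(locus_call_stats(a, lid), M)
            rb = snp_concordance(locus_call_stats(b, lid), F)
            assert ra.concordance == pytest.approx(rb.concordance)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _ten_ten(calls_row):
    return [calls_row], "M" * 10 + "F" * 10


class TestClassify:
    def test_perfect_xy_snp_is_male_het(self, snp_factory):
        calls, sexes = _ten_ten([1] * 10 + [0] * 10)
        sls = classify_sexlinked(snp_factory(calls, sexes))
        assert len(sls) == 1
        assert sls.members[0].category == "male_het_snp"

    def test_boundary_concordance_passes(self, snp_factory):
        # 16/20 conforming = 0.8 exactly under XY
        calls, sexes = _ten_ten([1] * 8 + [0, 0] + [0] * 8 + [1, 1])
        sls = classify_sexlinked(snp_factory(calls, sexes))
        assert len(sls) == 1
        assert sls.members[0].concordance == pytest.approx(0.8)

    def test_all_het_autosomal_locus_excluded(self, snp_factory):
        calls, sexes = _ten_ten([1] * 20)
        sls = classify_sexlinked(snp_factory(calls, sexes))
        assert len(sls) == 0

    def test_xy_zw_tie_is_dropped(self, snp_factory):
        # every called individual conforms to exactly one system, so
        # c_XY + c_ZW = 1 and a tie (both 0.5) is only reachable when the
        # threshold is relaxed to 0.5; the tied locus is dropped as ambiguous
        calls, sexes = _ten_ten([0] * 20)
        sls = classify_sexlinked(snp_factory(calls, sexes),
                                 concordance_threshold=0.5)
        assert len(sls) == 0

    def test_min_called_per_sex_enforced(self, snp_factory):
        matrix = snp_factory([[1, 1, 0, 0]], "MMFF")
        assert len(classify_sexlinked(matrix, min_called_per_sex=3)) == 0
        assert len(classify_sexlinked(matrix, min_called_per_sex=2)) == 1

    def test_pa_and_snp_classified_together(self, snp_factory, pa_factory):
        calls, sexes = _ten_ten([1] * 10 + [0] * 10)
        pa_calls = [[0] * 10 + [1] * 10]
        sls = classify_sexlinked(snp_factory(calls, sexes),
                                 pa_factory(pa_calls, sexes))
        cats = {m.category for m in sls}
        assert cats == {"male_het_snp", "female_present_pa"}

    def test_shared_locus_ids_rejected(self, snp_factory, pa_factory):
        snp = snp_factory([[1, 0]], "MF", locus_ids=["X1"])
        pa = pa_factory([[1, 0]], "MF", locus_ids=["X1"])
        with pytest.raises(ValueError, match="X1"):
            classify_sexlinked(snp, pa)

    def test_threshold_monotonicity(self, snp_factory):
        rng = np.random.default_rng(5)
        calls = rng.integers(-1, 3, size=(40, 12))
        matrix = snp_factory(calls, "M" * 6 + "F" * 6)
        sizes = [len(classify_sexlinked(matrix, concordance_threshold=t))
                 for t in (0.5, 0.7, 0.8, 0.9, 1.0)]
        assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# false-positive screen
# ---------------------------------------------------------------------------

class TestFalsePositive:
    def test_perfect_locus_not_flagged(self, snp_factory):
        calls, sexes = _ten_ten([1] * 10 + [0] * 10)
        matrix = snp_factory(calls, sexes)
        sls = false_positive_test(classify_sexlinked(matrix), matrix)
        (m,) = sls.members
        assert m.fp_statistic == 0.0 and not m.fp_flag

    def test_two_homozygotes_in_twenty_flagged(self, snp_factory):
        # b = alt; two females are alt/alt homozygotes -> 2/20 = 0.1 > 0.05
        calls, sexes = _ten_ten([1] * 10 + [0] * 8 + [2, 2])
        matrix = snp_factory(calls, sexes)
        sls = false_positive_test(
            classify_sexlinked(matrix, concordance_threshold=0.8), matrix)
        (m,) = sls.members
        assert m.fp_statistic == pytest.approx(0.1)
        assert m.fp_flag

    def test_undefined_allele_is_flagged(self, snp_factory):
        # homogametic homozygotes split 2/2 between classes
        calls, sexes = _ten_ten([1] * 10 + [0, 0, 2, 2] + [1] * 6)
        matrix = snp_factory(calls, sexes)
        sls = false_positive_test(
            classify_sexlinked(matrix, concordance_threshold=0.5), matrix)
        (m,) = sls.members
        assert m.sex_limited_allele is None
        assert m.fp_flag and m.fp_statistic is None

    def test_pa_members_exempt(self, snp_factory, pa_factory):
        calls, sexes = _ten_ten([1] * 10 + [0] * 10)
        pa_calls = [[1] * 10 + [0] * 10]
        snp = snp_factory(calls, sexes)
        sls = classify_sexlinked(snp, pa_factory(pa_calls, sexes))
        sls = false_positive_test(sls, snp)
        pa_member = next(m for m in sls if m.marker_class == "PA")
        assert not pa_member.fp_flag and pa_member.fp_statistic is None

    def test_fp_threshold_monotonicity(self, snp_factory):
        rng = np.random.default_rng(9)
        calls = rng.integers(-1, 3, size=(60, 20))
        matrix = snp_factory(calls, "M" * 10 + "F" * 10)
        base = classify_sexlinked(matrix, concordance_threshold=0.5)
        flagged = [sum(m.fp_flag for m in
                       false_positive_test(base, matrix, fp_threshold=t))
                   for t in (0.0, 0.05, 0.1, 0.5, 1.0)]
        assert flagged == sorted(flagged, reverse=True)


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

def synthetic_set(counts):
    """Build a classified set with given (initial, flagged) per category."""
    members = []
    for cat, (n_init, n_fp) in counts.items():
        mc = "SNP" if cat.endswith("snp") else "PA"
        system = "XY" if cat.startswith("male") else "ZW"
        for i in range(n_init):
            members.append(SexLinkedLocus(
                locus_id=f"{cat}_{i}", marker_class=mc, system=system,
                category=cat, concordance=1.0, fp_flag=i < n_fp,
                fp_statistic=0.5 if i < n_fp else 0.0))
    return SexLinkedSet(members=members, concordance_threshold=0.8,
                        min_called_per_sex=3, fp_threshold=0.05)


class TestSummary:
    def test_initial_minus_flagged(self):
        sls = synthetic_set({"male_het_snp": (197, 8), "male_present_pa": (17, 0),
                             "female_het_snp": (13, 0), "female_present_pa": (3, 0)})
        summary = summarize_discovery(sls)
        assert summary.categories["male_het_snp"].n_true == 189
        assert summary.n_true_total == 222

    def test_empty_set_is_all_zero(self):
        summary = summarize_discovery(synthetic_set({}))
        assert summary.n_true_total == 0
        assert all(c.n_initial == 0 for c in summary.categories.values())

    def test_bookkeeping_identity_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            counts = {}
            for cat in ("male_het_snp", "female_het_snp",
                        "male_present_pa", "female_present_pa"):
                n = int(rng.integers(0, 30))
                k = int(rng.integers(0, n + 1)) if cat.endswith("snp") else 0
                counts[cat] = (n, k)
            summary = summarize_discovery(synthetic_set(counts))
            for cat, (n, k) in counts.items():
                c = summary.categories[cat]
                assert c.n_true == c.n_initial - c.n_false_positive == n - k
            assert summary.n_true_total == sum(
                c.n_true for c in summary.categories.values())
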