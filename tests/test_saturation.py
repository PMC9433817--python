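"""Sectioning arithmetic, coverage oracles, threshold rules, correlation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repsat import (CoverageTable, Repertoire, accumulated_proportion,
                    build_sections, correlate_overlap, coverage, cutoff_50,
                    detection_threshold, geometric_mean)


def rep_from_counts(counts, isotypes=None, sample_id="rep", prefix="ACGT"):
    counts = list(counts)
    if isotypes is None:
        isotypes = ["IgM"] * len(counts)
    seqs = [f"{prefix}{i:06d}" for i in range(len(counts))]
    return Repertoire.from_counts(seqs, isotypes, counts, sample_id=sample_id)


@pytest.fixture()
def decade_reference():
    """Depth 10 000 with frequencies spanning exactly 1e-4 .. 1e-2."""
    counts = [1, 10, 89] + [100] * 99  # sums to 10 000
    return rep_from_counts(counts)


class TestSections:
    def test_boundary_arithmetic(self, decade_reference):
        sections = build_sections(decade_reference, 10)
        assert sections.boundaries[0] == pytest.approx(1e-4, rel=1e-12)
        assert sections.boundaries[-1] == pytest.approx(1e-2, rel=1e-12)
        # bin width 0.2 decades; 1e-3 lands in section 6 = floor(5)+1
        assert sections.section_of(1e-3) == 6
        assert sections.section_of(1e-4) == 1
        assert sections.section_of(1e-2) == 10

    def test_membership_matches_section_of(self, decade_reference):
        sections = build_sections(decade_reference, 10)
        t = decade_reference.table
        for seq, iso, f in zip(t["sequence"], t["isotype"], t["frequency"]):
            s = sections.section_of(f)
            assert (seq, iso) in sections.members[s - 1]

    def test_partition_invariant(self, decade_reference):
        sections = build_sections(decade_reference, 10)
        assert sections.counts.sum() == decade_reference.richness
        all_members = set().union(*sections.members)
        assert all_members == decade_reference.keys()

    def test_degenerate_equal_frequencies(self):
        rep = rep_from_counts([5] * 8)
        sections = build_sections(rep, 10)
        assert sections.counts.tolist() == [0] * 9 + [8]
        assert np.all(np.diff(sections.boundaries) > 0)

    def test_geometric_mean_by_hand(self):
        assert geometric_mean([1e-3, 1e-4]) == pytest.approx(10 ** -3.5, rel=1e-12)

    def test_representative_frequency_within_bounds(self, decade_reference):
        sections = build_sections(decade_reference, 10)
        for s in range(1, 11):
            rf = sections.representative_frequency[s - 1]
            if np.isnan(rf):
                assert len(sections.members[s - 1]) == 0
                continue
            assert sections.boundaries[s - 1] * (1 - 1e-9) <= rf
            assert rf <= sections.boundaries[s] * (1 + 1e-9)

    def test_empty_reference_rejected(self):
        from repsat import collapse_fus

        with pytest.raises(ValueError):
            build_sections(collapse_fus([]), 10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.integers(1, 400), min_size=2, max_size=60),
           st.integers(1, 12))
    def test_every_fus_in_exactly_one_section(self, counts, n_sections):
        rep = rep_from_counts(counts)
        sections = build_sections(rep, n_sections)
        assert sections.counts.sum() == rep.richness


class TestCoverage:
    def test_self_coverage_is_one(self, decade_reference):
        sections = build_sections(decade_reference, 10)
        cov = coverage(decade_reference, decade_reference, sections)
        populated = sections.counts > 0
        np.testing.assert_allclose(cov.coverage[populated], 1.0)

    def test_disjoint_query_is_zero(self, decade_reference):
        sections = build_sections(decade_reference, 10)
        query = rep_from_counts([3, 3, 3], prefix="TTTT")
        cov = coverage(decade_reference, query, sections)
        populated = sections.counts > 0
        np.testing.assert_allclose(cov.coverage[populated], 0.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(11)
        ref = rep_from_counts(rng.integers(1, 200, size=50))
        # query shares a subset of reference keys plus some foreign ones
        q_counts = list(rng.integers(1, 50, size=20))
        q_seqs = [f"ACGT{i:06d}" for i in range(0, 40, 2)]
        query = Repertoire.from_counts(q_seqs, ["IgM"] * 20, q_counts,
                                       sample_id="query")
        sections = build_sections(ref, 10)
        cov = coverage(ref, query, sections)

        qkeys = set(zip(query.table["sequence"], query.table["isotype"]))
        for s in range(1, 11):
            members = sections.members[s - 1]
            if not members:
                assert np.isnan(cov.coverage[s - 1])
                continue
            n_ov = sum(1 for k in members for qk in qkeys if k == qk)
            assert cov.coverage[s - 1] == pytest.approx(n_ov / len(members))

    def test_bounded_in_unit_interval(self, decade_reference):
        sections = build_sections(decade_reference, 10)
        query = rep_from_counts([2] * 30)
        cov = coverage(decade_reference, query, sections).coverage
        defined = ~np.isnan(cov)
        assert ((cov[defined] >= 0) & (cov[defined] <= 1)).all()


class TestAccumulatedProportion:
    def test_identity_query(self, decade_reference):
        sections = build_sections(decade_reference, 10)
        acc = accumulated_proportion(decade_reference, decade_reference, sections)
        assert acc[0] == pytest.approx(1.0)  # all sections accumulated
        diffs = np.diff(acc)
        assert (diffs <= 1e-12).all()  # non-increasing read from the top

    def test_no_overlap(self, decade_reference):
        sections = build_sections(decade_reference, 10)
        query = rep_from_counts([1, 1], prefix="GGGG")
        acc = accumulated_proportion(query, decade_reference, sections)
        np.testing.assert_allclose(acc, 0.0)

    def test_cumulative_tally_oracle(self):
        rng = np.random.default_rng(21)
        ref = rep_from_counts(rng.integers(1, 300, size=40))
        q_seqs = [f"ACGT{i:06d}" for i in range(0, 60, 3)]
        query = Repertoire.from_counts(q_seqs, ["IgM"] * 20,
                                       rng.integers(1, 40, size=20),
                                       sample_id="q")
        sections = build_sections(ref, 8)
        acc = accumulated_proportion(query, ref, sections)
        qkeys = set(zip(query.table["sequence"], query.table["isotype"]))
        for s in range(1, 9):
            expected = sum(len(m & qkeys) for m in sections.members[s - 1:])
            assert acc[s - 1] == pytest.approx(expected / query.richness)

    def test_empty_query_undefined(self, decade_reference):
        from repsat import collapse_fus

        sections = build_sections(decade_reference, 10)
        acc = accumulated_proportion(collapse_fus([]), decade_reference, sections)
        assert np.isnan(acc).all()


def cov_table(values, sections):
    values = np.asarray(values, dtype=float)
    n_ref = np.where(np.isnan(values), 0, 10).astype(np.int64)
    n_ov = np.where(np.isnan(values), 0, (values * 10)).astype(np.int64)
    return CoverageTable("ref", "q", values, n_ref, n_ov)


class TestThresholdRules:
    @pytest.fixture()
    def sections(self, decade_reference):
        return build_sections(decade_reference, 10)

    def test_all_covered_gives_global_minimum(self, sections):
        cov = cov_table([1.0] * 10, sections)
        assert detection_threshold(cov, sections) == sections.boundaries[0]
        assert cutoff_50(cov, sections) == sections.boundaries[0]

    def test_run_from_top_example(self, sections):
        values = [0.2, 0.4, 0.6, 0.8, 0.9, 0.95, 1, 1, 1, 1]
        cov = cov_table(values, sections)
        # sections 7-10 fully covered: threshold = lower boundary of 7
        assert detection_threshold(cov, sections) == sections.lower_boundary(7)

    def test_incomplete_top_section_is_undefined(self, sections):
        cov = cov_table([1, 1, 1, 1, 1, 1, 1, 1, 1, 0.9], sections)
        assert detection_threshold(cov, sections) is None

    def test_undefined_sections_do_not_break_run(self, sections):
        values = [0.2, 1.0, np.nan, 1.0, 1.0, np.nan, 1.0, 1.0, 1.0, 1.0]
        cov = cov_table(values, sections)
        assert detection_threshold(cov, sections) == sections.lower_boundary(2)

    def test_cutoff_50_traced_example(self, sections):
        values = [0.1, 0.3, 0.6, 0.4, 0.7, 0.8, 1, 1, 1, 1]
        cov = cov_table(values, sections)
        # sections 5-10 all >= 0.5; section 4 (0.4) breaks the run
        assert cutoff_50(cov, sections) == sections.lower_boundary(5)

    def test_cutoff_50_none_when_top_below_half(self, sections):
        cov = cov_table([0.1] * 9 + [0.4], sections)
        assert cutoff_50(cov, sections) is None


class TestCorrelation:
    def test_self_correlation(self, decade_reference):
        res = correlate_overlap(decade_reference, decade_reference)
        assert res.r == pytest.approx(1.0)
        assert res.n_overlapping == decade_reference.richness

    def test_exact_linearity_raw(self):
        a = rep_from_counts([1, 2, 3])
        b = rep_from_counts([2, 4, 6])
        res = correlate_overlap(a, b, transform="raw")
        assert res.r == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(31)
        a = rep_from_counts(rng.integers(1, 500, size=20))
        b = rep_from_counts(rng.integers(1, 500, size=20))
        res = correlate_overlap(a, b, transform="log10")
        merged = a.table.merge(b.table, on=["sequence", "isotype"])
        x = np.log10(merged["frequency_x"].to_numpy())
        y = np.log10(merged["frequency_y"].to_numpy())
        r_manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert res.r == pytest.approx(r_manual, abs=1e-12)
        assert res.n_overlapping == 20

    def test_isotype_strata(self):
        isotypes = ["IgM", "IgD", "IgG", "IgA"] * 5
        a = rep_from_counts(range(1, 21), isotypes=isotypes)
        b = rep_from_counts(range(21, 41), isotypes=isotypes)
        res_naive = correlate_overlap(a, b, "IgM/D")
        res_sw = correlate_overlap(a, b, "class-switched")
        assert res_naive.n_overlapping == 10
        assert res_sw.n_overlapping == 10

    def test_frequency_strata_respect_cutoff(self):
        a = rep_from_counts([1, 2, 30, 40, 50])
        b = rep_from_counts([2, 1, 35, 45, 55])
        cut = 10 / a.depth
        hi = correlate_overlap(a, b, "high-frequency", cutoff=cut)
        lo = correlate_overlap(a, b, "low-frequency", cutoff=cut)
        assert hi.n_overlapping == 3 and lo.n_overlapping == 2
        with pytest.raises(ValueError):
            correlate_overlap(a, b, "high-frequency")  # cutoff required

    def test_insufficient_overlap_undefined(self):
        a = rep_from_counts([5])
        b = rep_from_counts([5])
        res = correlate_overlap(a, b)
        assert not res.defined and "1 overlapping" in res.reason

    def test_zero_variance_undefined(self):
        a = rep_from_counts([3, 3, 3])
        b = rep_from_counts([1, 2, 3])
        res = correlate_overlap(a, b)
        assert not res.defined and "variance" in res.reason
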