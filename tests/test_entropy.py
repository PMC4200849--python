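"""Relative-entropy components, totals, backgrounds and outlier flags."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aacontext import (
    ProteinRecord,
    background_from_records,
    background_from_table,
    component_entropy,
    component_outliers,
    extract_contexts,
    per_offset_background,
    profile,
    site_entropy,
)
from aacontext.alphabet import AA_INDEX
from aacontext.entropy import BackgroundDistribution

from conftest import kl_oracle


def vec(**freqs):
    out = np.zeros(20)
    for aa, value in freqs.items():
        out[AA_INDEX[aa]] = value
    return out


class TestComponentEntropy:
    def test_hand_value(self):
        # 0.5 * log2(0.5 / 0.05) = 0.5 * log2(10)
        assert component_entropy(0.5, 0.05) == pytest.approx(0.5 * math.log2(10))

    def test_zero_observed_is_zero_by_limit(self):
        assert component_entropy(0.0, 0.3) == 0.0

    def test_identical_frequencies_are_zero(self):
        assert component_entropy(0.2, 0.2) == 0.0

    def test_zero_background_with_mass_rejected(self):
        with pytest.raises(ValueError):
            component_entropy(0.1, 0.0)


class TestSiteEntropy:
    def test_two_residue_hand_value(self, uniform_background):
        counts = vec(A=5, L=5)
        total, components = site_entropy(counts, uniform_background)
        assert total == pytest.approx(math.log2(10))
        assert components[AA_INDEX["A"]] == pytest.approx(0.5 * math.log2(10))
        assert components[AA_INDEX["L"]] == pytest.approx(0.5 * math.log2(10))
        assert np.count_nonzero(components) == 2

    def test_counts_matching_background_give_zero(self):
        background = vec(A=0.25, C=0.75)
        total, _ = site_entropy(vec(A=1, C=3), background)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_on_matching_background(self):
        total, _ = site_entropy(vec(A=4), vec(A=1.0))
        assert total == 0.0

    def test_all_zero_counts_rejected(self, uniform_background):
        with pytest.raises(ValueError):
            site_entropy(np.zeros(20), uniform_background)

    def test_zero_background_support_names_residue(self):
        with pytest.raises(ValueError, match="L"):
            site_entropy(vec(A=1, L=1), vec(A=1.0))

    def test_counts_exceeding_n_rejected(self, uniform_background):
        with pytest.raises(ValueError):
            site_entropy(vec(A=5), uniform_background, n=3)


counts_strategy = st.lists(st.integers(0, 40), min_size=20, max_size=20).filter(
    lambda c: sum(c) > 0
)
background_counts = st.lists(st.integers(1, 60), min_size=20, max_size=20)


class TestEntropyProperties:
    @given(counts=counts_strategy, bg_counts=background_counts)
    @settings(derandomize=True, max_examples=150)
    def test_matches_high_precision_oracle(self, counts, bg_counts):
        background = np.array(bg_counts, float) / sum(bg_counts)
        total, components = site_entropy(np.array(counts, float), background)
        oracle_total, oracle_comps = kl_oracle(counts, background)
        assert total == pytest.approx(oracle_total, abs=1e-10)
        assert np.allclose(components, oracle_comps, atol=1e-10)

    @given(counts=counts_strategy, bg_counts=background_counts)
    @settings(derandomize=True, max_examples=150)
    def test_nonnegative_and_zero_iff_background(self, counts, bg_counts):
        background = np.array(bg_counts, float) / sum(bg_counts)
        total, _ = site_entropy(np.array(counts, float), background)
        assert total >= -1e-12
        p = np.array(counts, float) / sum(counts)
        if np.allclose(p, background, atol=1e-12):
            assert total <= 1e-9
        if total <= 1e-12:
            # Gibbs: zero only when observed frequencies equal background
            assert np.allclose(p, background, atol=1e-6)


class TestBackgrounds:
    def test_global_frequencies(self):
        bg = background_from_records([ProteinRecord("p", "AAAA")])
        assert bg.at(0)[AA_INDEX["A"]] == 1.0
        bg = background_from_records(
            [ProteinRecord("p1", "AC"), ProteinRecord("p2", "CA")]
        )
        assert bg.at(0)[AA_INDEX["A"]] == 0.5
        assert bg.at(0)[AA_INDEX["C"]] == 0.5

    def test_unknowns_excluded_from_both_sides_of_the_ratio(self):
        bg = background_from_records([ProteinRecord("p", "AAXX")])
        assert bg.at(0)[AA_INDEX["A"]] == 1.0

    def test_structure_scope_without_class_rejected(self):
        rec = ProteinRecord("p", "ACDE", structure_track="CCCC")
        with pytest.raises(ValueError):
            background_from_records([rec], scope="structure", structure_class="H")

    def test_per_offset_from_flanks(self):
        records = [ProteinRecord("p1", "CAD"), ProteinRecord("p2", "CAD")]
        bg = per_offset_background(records, "A", 1)
        assert bg.at(-1)[AA_INDEX["C"]] == 1.0
        assert bg.at(1)[AA_INDEX["D"]] == 1.0
        for off in (-1, 1):
            assert bg.at(off).sum() == pytest.approx(1.0)

    def test_missing_focal_rejected(self):
        with pytest.raises(ValueError):
            per_offset_background([ProteinRecord("p", "CCD")], "A", 1)

    def test_pseudocount_fills_zero_offsets(self):
        bg = per_offset_background([ProteinRecord("p", "CAD")], "A", 1, pseudocount=True)
        assert bg.at(-1).min() > 0


class TestProfile:
    def test_single_context_concentrates_each_offset(self, uniform_background):
        table = extract_contexts([ProteinRecord("p", "ACDEF")], "D", 2)
        bg = BackgroundDistribution(mode="global", q=uniform_background)
        prof = profile(table, bg)
        assert sorted(prof.sites) == [-2, -1, 1, 2]
        for site in prof.sites.values():
            assert site.total == pytest.approx(math.log2(20))

    def test_empty_side_absent_not_zero(self, uniform_background):
        table = extract_contexts([ProteinRecord("p", "ACD")], "D", 2)
        bg = BackgroundDistribution(mode="global", q=uniform_background)
        prof = profile(table, bg)
        assert sorted(prof.sites) == [-2, -1]

    def test_counts_matching_background_all_zero(self):
        records = [ProteinRecord("p", "CADACAD" * 3)]
        table = extract_contexts(records, "A", 1)
        bg = background_from_table(table)
        prof = profile(table, bg)
        for site in prof.sites.values():
            assert site.total == pytest.approx(0.0, abs=1e-12)

    def test_totals_invariant_under_record_relabeling(self, uniform_background):
        recs = [ProteinRecord("a", "ACDEFGA"), ProteinRecord("b", "GGADCFA")]
        relabeled = [ProteinRecord("x9", recs[0].sequence), ProteinRecord("q", recs[1].sequence)]
        bg = BackgroundDistribution(mode="global", q=uniform_background)
        p1 = profile(extract_contexts(recs, "A", 2), bg)
        p2 = profile(extract_contexts(relabeled, "A", 2), bg)
        assert p1.totals() == p2.totals()


class TestComponentOutliers:
    def test_single_spike_flagged_high(self):
        values = np.full(20, 0.1)
        values[AA_INDEX["G"]] = 5.0
        assert component_outliers(values) == [("G", "high")]

    def test_equal_values_have_no_outliers(self):
        assert component_outliers(np.full(20, 0.3)) == []

    def test_low_outlier_flagged(self):
        values = np.linspace(1.0, 1.19, 20)
        values[AA_INDEX["W"]] = -5.0
        assert ("W", "low") in component_outliers(values)

    @given(st.permutations(list(range(20))))
    @settings(derandomize=True, max_examples=30)
    def test_flagged_values_invariant_under_input_permutation(self, perm):
        # the 1.5*IQR fences depend only on the multiset of values, so the
        # flagged (value, direction) pairs must not depend on input order
        rng = np.random.default_rng(3)
        values = rng.normal(size=20)
        values[4] = 8.0
        permuted = values[np.array(perm)]

        def flagged_values(vals):
            return sorted(
                (vals[AA_INDEX[aa]], direction)
                for aa, direction in component_outliers(vals)
            )

        assert flagged_values(permuted) == flagged_values(values)
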