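"""ΔE_A selectivity: pairing, classification, summaries, Mann–Whitney."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from chesel.selectivity import (
    A_SELECTIVE,
    B_SELECTIVE,
    NONSELECTIVE,
    classify,
    mann_whitney,
    pair_screens,
    summarize_screen,
    SelectivityRecord,
)
from chesel.reference_data import CAFESTROL_ENERGIES, FDA_ACHE_SELECTIVE


def _records_from_pairs(pairs, threshold=0.1):
    ea = {f"l{i}": a for i, (a, _) in enumerate(pairs)}
    eb = {f"l{i}": b for i, (_, b) in enumerate(pairs)}
    return pair_screens(ea, eb, threshold).records


class TestPairing:
    def test_cafestrol_large_box_is_nonselective(self):
        """At the strict |s| > 0.1 threshold, s = +0.1 is not a call."""
        ea, eb = CAFESTROL_ENERGIES["large_box"]
        (rec,) = _records_from_pairs([(ea, eb)])
        assert rec.s_signed == pytest.approx(0.1)
        assert rec.label == NONSELECTIVE

    def test_cafestrol_small_box_flips_b_selective(self):
        ea, eb = CAFESTROL_ENERGIES["small_box"]
        (rec,) = _records_from_pairs([(ea, eb)])
        assert rec.s_signed == pytest.approx(1.6)
        assert rec.delta_ea == pytest.approx(1.6)
        assert rec.label == B_SELECTIVE

    def test_equal_energies_are_nonselective(self):
        (rec,) = _records_from_pairs([(-9.0, -9.0)])
        assert rec.s_signed == 0.0
        assert rec.label == NONSELECTIVE

    def test_ambrisentan_row_inverts_to_a_selective(self):
        """ΔE_A = 1.9 with E(A) = −10.8 implies E(B) = −8.9, an A call."""
        _, delta, first_ea, *_ = FDA_ACHE_SELECTIVE[0]
        eb = first_ea + delta  # -8.9: weaker (less negative) B binding
        (rec,) = _records_from_pairs([(first_ea, eb)])
        assert rec.ea_target_b == pytest.approx(-8.9)
        assert rec.delta_ea == pytest.approx(1.9)
        assert rec.label == A_SELECTIVE

    def test_unpaired_ligands_are_reported_not_dropped(self):
        result = pair_screens({"x": -9.0, "only_a": -8.0}, {"x": -9.5, "only_b": -7.0})
        assert [r.ligand_id for r in result.records] == ["x"]
        assert result.unpaired_a == ["only_a"]
        assert result.unpaired_b == ["only_b"]

    def test_zero_overlap_errors(self):
        with pytest.raises(ValueError):
            pair_screens({"a": -9.0}, {"b": -9.0})

    def test_classification_is_a_partition(self, rng):
        records = _records_from_pairs(
            [(round(a, 3), round(b, 3))
             for a, b in rng.normal(-9, 1, size=(500, 2))]
        )
        labels = {A_SELECTIVE, B_SELECTIVE, NONSELECTIVE}
        assert all(r.label in labels for r in records)
        counts = {lab: sum(r.label == lab for r in records) for lab in labels}
        assert sum(counts.values()) == len(records) == 500

    def test_antisymmetry_under_screen_swap(self, rng):
        pairs = [(round(a, 3), round(b, 3)) for a, b in rng.normal(-9, 1, size=(200, 2))]
        fwd = _records_from_pairs(pairs)
        rev = _records_from_pairs([(b, a) for a, b in pairs])
        swap = {A_SELECTIVE: B_SELECTIVE, B_SELECTIVE: A_SELECTIVE,
                NONSELECTIVE: NONSELECTIVE}
        for f, r in zip(fwd, rev):
            assert r.s_signed == pytest.approx(-f.s_signed)
            assert r.delta_ea == pytest.approx(f.delta_ea)
            assert r.label == swap[f.label]


class TestClassify:
    @pytest.mark.parametrize(
        "s,expected",
        [(-0.11, A_SELECTIVE), (-0.1, NONSELECTIVE), (0.0, NONSELECTIVE),
         (0.1, NONSELECTIVE), (0.11, B_SELECTIVE), (-105.0, A_SELECTIVE)],
    )
    def test_strict_threshold(self, s, expected):
        assert classify(s, threshold=0.1) == expected


class TestSummary:
    def test_published_screen_counts_round_to_percentages(self):
        """779 of 1,614 A-selective and 739 B-selective → 48% / 46%."""
        records = (
            [SelectivityRecord(f"a{i}", -9.0, -8.5, -0.5, 0.5, A_SELECTIVE)
             for i in range(779)]
            + [SelectivityRecord(f"b{i}", -8.5, -9.0, 0.5, 0.5, B_SELECTIVE)
               for i in range(739)]
            + [SelectivityRecord(f"n{i}", -9.0, -9.0, 0.0, 0.0, NONSELECTIVE)
               for i in range(1614 - 779 - 739)]
        )
        s = summarize_screen(records)
        assert s.n_paired == 1614
        assert (s.pct_a, s.pct_b) == (48, 46)
        assert s.pct_a_exact == pytest.approx(100 * 779 / 1614)

    def test_all_nonselective_concentrates_first_bin(self):
        records = [
            SelectivityRecord(f"n{i}", -9.0, -9.0 - 0.01 * i, 0.01 * i, 0.01 * i,
                              NONSELECTIVE)
            for i in range(10)
        ]
        s = summarize_screen(records, bin_width=0.1)
        assert s.pct_a == s.pct_b == 0
        assert s.max_delta_a is None and s.max_delta_b is None
        hist = s.class_histograms[NONSELECTIVE]
        assert hist[0][1] == 10  # all mass in [0, bin_width)

    def test_histogram_conservation_with_overflow(self, rng):
        values = np.round(rng.gamma(2.0, 1.5, size=400) + 0.102, 3)
        records = [
            SelectivityRecord(f"b{i}", -9.0, -9.0 - v, v, v, B_SELECTIVE)
            for i, v in enumerate(values)
        ] + [SelectivityRecord("big", -9.0, -129.0, 120.0, 120.0, B_SELECTIVE)]
        s = summarize_screen(records, bin_width=0.1, histogram_cutoff=100.0)
        for hist in (s.histogram, s.class_histograms[B_SELECTIVE]):
            assert sum(c for _, c in hist) == len(records)
        # the >cutoff case sits in the pooled overflow bin at the cutoff edge
        assert s.class_histograms[B_SELECTIVE][-1] == (100.0, 1)
        assert s.max_delta_b == pytest.approx(120.0)

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            summarize_screen([])


def _exact_p_oracle(x, y, u_obs):
    """Enumerate all C(n, n1) first-sample placements of the pooled ranks."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    devs = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        devs.append(abs(u - mu))
    obs = abs(u_obs - mu)
    return np.mean([d >= obs - 1e-12 for d in devs])


class TestMannWhitney:
    def test_identical_samples_are_central(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == pytest.approx(4.5)
        assert res.z_statistic == 0.0
        assert res.p_two_sided == 1.0

    def test_disjoint_samples_exact_p(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u_statistic == 0.0
        assert res.p_exact == pytest.approx(2 / 6)

    def test_u_sum_identity(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=7)
        u1 = mann_whitney(x, y).u_statistic
        u2 = mann_whitney(y, x).u_statistic
        assert u1 + u2 == pytest.approx(63)
        assert 0 <= u1 <= 63

    def test_degenerate_all_ties(self):
        res = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.degenerate
        assert res.p_two_sided == 1.0

    def test_exact_p_matches_enumeration_all_small_splits(self, rng):
        """The reported exact p equals a from-scratch enumeration, n1+n2 ≤ 10."""
        for n1 in range(1, 10):
            for n2 in range(1, 11 - n1):
                x = np.round(rng.normal(size=n1), 1)
                y = np.round(rng.normal(0.5, 1, size=n2), 1)
                res = mann_whitney(x, y)
                oracle = _exact_p_oracle(x, y, res.u_statistic)
                assert res.p_exact == pytest.approx(oracle, abs=1e-12)

    def test_normal_approx_close_to_exact_at_8v8(self, rng):
        """|p_normal − p_exact| < 0.05 at n1 = n2 = 8; U's lattice is fine
        enough there for the bound to hold whatever the data."""
        for _ in range(10):
            x = np.round(rng.normal(size=8), 1)
            y = np.round(rng.normal(0.5, 1, size=8), 1)
            res = mann_whitney(x, y)
            if not res.degenerate:
                assert abs(res.p_two_sided - _exact_p_oracle(x, y, res.u_statistic)) < 0.05

    def test_z_monotone_in_u(self):
        zs = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            x = np.arange(8.0)
            res = mann_whitney(x, x + shift)
            zs.append(res.z_statistic)
        assert all(a >= b for a, b in zip(zs, zs[1:]))

    def test_matches_scipy_with_ties(self, rng):
        """Independent cross-check: scipy's tie-corrected asymptotic test."""
        x = np.round(rng.gamma(2, 0.5, size=60), 1)
        y = np.round(rng.gamma(2, 0.8, size=45), 1)
        res = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
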