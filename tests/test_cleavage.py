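"""Unit and property tests for the protease-specificity PSSM analysis."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from thaggfip import cleavage
from thaggfip.cleavage import (
    AMINO_ACIDS,
    CleavageProfile,
    CleavageWindow,
    PeptideFragment,
    build_pssm,
    edge_enrichment_test,
    proximal_mask,
    score_sequence,
    score_to_probability,
)

UNIFORM_BG = np.full(20, 0.05)


def random_windows(rng, n):
    aa = list(AMINO_ACIDS)
    return ["".join(rng.choice(aa, size=8)) for _ in range(n)]


class TestBuildPssm:
    def test_uniform_windows_uniform_background_give_zero_scores(self):
        # one window per residue at every position -> counts uniform
        windows = ["".join([a] * 8) for a in AMINO_ACIDS]
        pssm = build_pssm(windows, pseudocount=5, background=UNIFORM_BG)
        assert np.allclose(pssm.log_odds, 0.0, atol=1e-12)

    def test_conserved_position_log_odds_value(self):
        # 20 windows, all with 'A' at P1 (window index 3), rest spread evenly
        rows = []
        for i, a in enumerate(AMINO_ACIDS):
            w = list(a * 8)
            w[3] = "A"
            rows.append("".join(w))
        pssm = build_pssm(rows, pseudocount=5, background=UNIFORM_BG)
        expected = math.log((20 + 5) / (20 + 100) / 0.05)  # ~1.427
        i_a = AMINO_ACIDS.index("A")
        assert pssm.log_odds[3, i_a] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.4271, abs=1e-4)

    def test_pseudocount_keeps_all_cells_finite(self, rng):
        pssm = build_pssm(random_windows(rng, 5), pseudocount=5)
        assert np.all(np.isfinite(pssm.log_odds))

    def test_probability_reconstruction_sums_to_one(self, rng):
        for n in (1, 7, 40):
            pssm = build_pssm(random_windows(rng, n), pseudocount=5)
            recon = pssm.background[np.newaxis, :] * np.exp(pssm.log_odds)
            assert np.allclose(recon.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            build_pssm([])

    def test_bad_window_length_rejected(self):
        with pytest.raises(ValueError):
            CleavageWindow("ACDE")

    def test_zero_background_rejected(self):
        bg = np.full(20, 0.05)
        bg[0] = 0.0
        bg[1] = 0.1
        with pytest.raises(ValueError):
            build_pssm(["A" * 8], background=bg)


class TestScoreSequence:
    def test_matches_bruteforce_enumeration(self, rng):
        """Profile equals an independent window-by-window re-scoring."""
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
        pssms = [
            build_pssm(random_windows(rng, 15), protease_id="B"),
            build_pssm(random_windows(rng, 25), protease_id="D"),
        ]
        profile = score_sequence(seq, pssms)
        L = len(seq)
        for i in range(1, L + 1):  # 1-based P1 positions
            if i < 4 or i > L - 4:
                assert not profile.valid_mask[i - 1]
                assert np.isnan(profile.scores[i - 1])
                continue
            window = seq[i - 4 : i + 4]
            brute = max(
                sum(
                    m.log_odds[j, AMINO_ACIDS.index(a)]
                    for j, a in enumerate(window)
                )
                for m in pssms
            )
            assert profile.scores[i - 1] == pytest.approx(brute, abs=1e-12)

    def test_single_pssm_max_is_identity(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=30))
        pssm = build_pssm(random_windows(rng, 10))
        one = score_sequence(seq, pssm)
        listed = score_sequence(seq, [pssm])
        np.testing.assert_array_equal(one.valid_mask, listed.valid_mask)
        np.testing.assert_allclose(
            one.scores[one.valid_mask], listed.scores[listed.valid_mask]
        )

    def test_dominant_pssm_determines_profile(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        weak = build_pssm(random_windows(rng, 10))
        dominant = build_pssm(random_windows(rng, 10))
        dominant.log_odds = weak.log_odds + 10.0  # dominates at every window
        combined = score_sequence(seq, [weak, dominant])
        alone = score_sequence(seq, dominant)
        np.testing.assert_allclose(
            combined.scores[combined.valid_mask], alone.scores[alone.valid_mask]
        )

    def test_short_sequence_warns_and_is_empty(self, rng):
        pssm = build_pssm(random_windows(rng, 5))
        with pytest.warns(UserWarning):
            profile = score_sequence("ACDEFG", pssm)
        assert not profile.valid_mask.any()


class TestScoreToProbability:
    def test_anchor_value(self):
        assert score_to_probability(1.5) == pytest.approx(0.817, abs=1e-3)

    def test_zero_maps_to_half(self):
        assert score_to_probability(0.0) == 0.5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-700, max_value=700, allow_nan=False))
    def test_symmetry(self, s):
        assert score_to_probability(s) + score_to_probability(-s) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_stable_for_large_scores(self):
        assert score_to_probability(1e4) == 1.0
        assert score_to_probability(-1e4) == 0.0


class TestProximalMask:
    def test_no_fragments_all_false(self):
        assert not proximal_mask([], 50).any()

    def test_single_fragment_exact_positions(self):
        mask = proximal_mask([PeptideFragment("p", 10, 30)], 100)
        expected = {8, 9, 10, 11, 29, 30, 31, 32}
        assert {i + 1 for i in np.nonzero(mask)[0]} == expected

    def test_n_terminal_clipping(self):
        mask = proximal_mask([PeptideFragment("p", 1, 30)], 100)
        n_side = {i + 1 for i in np.nonzero(mask)[0] if i + 1 < 20}
        assert n_side == {1, 2}

    def test_overlapping_fragments_merge(self):
        a = proximal_mask([PeptideFragment("p", 10, 20)], 60)
        b = proximal_mask([PeptideFragment("p", 18, 40)], 60)
        both = proximal_mask(
            [PeptideFragment("p", 10, 20), PeptideFragment("p", 18, 40)], 60
        )
        np.testing.assert_array_equal(both, a | b)

    def test_out_of_bounds_fragment_named_in_error(self):
        with pytest.raises(ValueError, match=r"\[5, 80\]"):
            proximal_mask([PeptideFragment("p", 5, 80)], 50)


def _profile_from_groups(edge_vals, distal_vals):
    scores = np.array(list(edge_vals) + list(distal_vals), dtype=float)
    mask = np.zeros(len(scores), dtype=bool)
    mask[: len(edge_vals)] = True
    profile = CleavageProfile("p", scores, np.ones(len(scores), dtype=bool))
    return profile, mask


class TestEdgeEnrichment:
    def test_maximal_separation_exact_p(self):
        profile, mask = _profile_from_groups([5, 6, 7], [1, 2, 3])
        res = edge_enrichment_test(profile, mask)
        assert res.exact
        assert res.U == 9  # maximal U = n1*n2
        assert res.p_value == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 7))
            edge = rng.normal(size=n1)
            distal = rng.normal(size=n2)
            profile, mask = _profile_from_groups(edge, distal)
            res = edge_enrichment_test(profile, mask)
            ref = stats.mannwhitneyu(edge, distal, alternative="greater", method="exact")
            assert res.exact
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            assert res.U == pytest.approx(ref.statistic)

    def test_exact_with_ties_matches_enumeration(self, rng):
        """Tied data: p equals the fraction of group assignments with U >= U_obs."""
        for _ in range(10):
            pooled = rng.integers(0, 3, size=8).astype(float)  # heavy ties
            n1 = 3
            profile, mask = _profile_from_groups(pooled[:n1], pooled[n1:])
            res = edge_enrichment_test(profile, mask)
            ranks = stats.rankdata(pooled)
            u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            hits = total = 0
            for combo in itertools.combinations(range(8), n1):
                u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
                total += 1
                hits += u >= u_obs - 1e-12
            assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_large_groups_use_normal_approximation(self, rng):
        profile, mask = _profile_from_groups(rng.normal(1, 1, 30), rng.normal(0, 1, 40))
        res = edge_enrichment_test(profile, mask)
        assert not res.exact
        assert 0 < res.p_value <= 1
        assert 0 <= res.U <= res.n_edge * res.n_nonedge

    def test_empty_group_rejected(self):
        profile, mask = _profile_from_groups([1.0, 2.0], [])
        with pytest.raises(ValueError, match="non-empty"):
            edge_enrichment_test(profile, mask)

    def test_significance_threshold(self):
        profile, mask = _profile_from_groups([5, 6, 7], [1, 2, 3])
        res = edge_enrichment_test(profile, mask)
        assert res.significant(alpha=0.051)
        assert not res.significant(alpha=0.05)  # p == 0.05 is not < 0.05
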