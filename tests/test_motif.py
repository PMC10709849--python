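"""PWM model, exact score null, pair scanning and motif-level statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from asbkit.fixtures import simulate_motif_windows
from asbkit.motif import (
    BASES,
    PWMModel,
    disruption_profile,
    enrichment_test,
    motif_position_of_center,
    ratio_score_correlation,
    scan_pair,
    scan_window,
    score_pvalue_table,
)
from asbkit.types import AllelePairWindows, HetSNP, WINDOW_CENTER, WINDOW_LENGTH
from tests.conftest import make_count

REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]


def enumerate_score_null(pwm, granularity):
    """Brute-force oracle: exact tail over all 4^w words."""
    int_matrix = np.rint(pwm.logodds_matrix / granularity).astype(np.int64)
    scores, weights = [], []
    for word in itertools.product(range(4), repeat=pwm.width):
        s = sum(int_matrix[b, j] for j, b in enumerate(word))
        w = np.prod([pwm.background[b] for b in word])
        scores.append(s)
        weights.append(w)
    scores = np.array(scores)
    weights = np.array(weights)

    def tail(s):
        return float(weights[scores >= s].sum())

    return tail


class TestPWMModel:
    def test_information_content_bounds(self):
        uniform = PWMModel("u", np.full((4, 1), 0.25), np.full(4, 0.25))
        assert uniform.ic_per_position[0] == pytest.approx(0.0, abs=1e-12)
        onehot = PWMModel(
            "o", np.array([[1.0], [0.0], [0.0], [0.0]]), np.full(4, 0.25)
        )
        assert onehot.ic_per_position[0] == pytest.approx(2.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), width=st.integers(1, 12))
    def test_columns_sum_to_one_and_ic_in_range(self, seed, width):
        rng = np.random.default_rng(seed)
        counts = rng.uniform(0, 100, size=(4, width))
        pwm = PWMModel.from_counts(counts, pseudocount=rng.uniform(0.01, 5))
        np.testing.assert_allclose(pwm.prob_matrix.sum(axis=0), 1.0,
                                   atol=1e-12)
        assert np.all(pwm.ic_per_position >= -1e-12)
        assert np.all(pwm.ic_per_position <= 2.0 + 1e-12)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            PWMModel.from_counts(np.full((3, 4), 1.0))
        with pytest.raises(ValueError):
            PWMModel.from_counts(-np.ones((4, 3)))
        with pytest.raises(ValueError):
            PWMModel.from_counts(np.ones((4, 0)))


class TestScoreNull:
    def test_width_one_top_score_tail(self):
        pwm = PWMModel(
            "w1", np.array([[0.97], [0.01], [0.01], [0.01]]), np.full(4, 0.25)
        )
        null = score_pvalue_table(pwm)
        assert null.tail_at(null.max_sum) == pytest.approx(0.25, abs=1e-12)

    def test_support_bounds(self, sharp_pwm):
        null = score_pvalue_table(sharp_pwm)
        assert null.tail_at(null.min_sum) == pytest.approx(1.0, abs=1e-12)
        assert null.tail_at(null.max_sum + 1) == 0.0

    @pytest.mark.parametrize("width,seed", [(1, 0), (3, 1), (6, 2)])
    def test_equals_exhaustive_enumeration(self, width, seed,
                                           random_pwm_factory):
        pwm = random_pwm_factory(width, seed)
        gran = 1e-3
        null = score_pvalue_table(pwm, gran)
        oracle = enumerate_score_null(pwm, gran)
        for s in range(null.min_sum, null.max_sum + 1, max(1, (null.max_sum
                       - null.min_sum) // 200)):
            assert null.tail_at(s) == pytest.approx(oracle(s), abs=1e-12)

    def test_nonuniform_background(self):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        counts = np.array([[5.0, 1.0], [1.0, 8.0], [2.0, 1.0], [1.0, 1.0]])
        pwm = PWMModel.from_counts(counts, pseudocount=1.0, background=bg)
        null = score_pvalue_table(pwm, 1e-3)
        oracle = enumerate_score_null(pwm, 1e-3)
        for s in (null.min_sum, 0, null.max_sum):
            assert null.tail_at(s) == pytest.approx(oracle(s), abs=1e-12)

    def test_invalid_granularity(self, sharp_pwm):
        with pytest.raises(ValueError):
            score_pvalue_table(sharp_pwm, 0.0)


def _pair_with(ref_window: str, alt_base: str) -> AllelePairWindows:
    ref_base = ref_window[WINDOW_CENTER]
    alt_window = (ref_window[:WINDOW_CENTER] + alt_base
                  + ref_window[WINDOW_CENTER + 1:])
    snp = HetSNP("chr1", 1000, "rsX", ref_base, alt_base)
    return AllelePairWindows(snp, ref_window, alt_window)


class TestScanPair:
    def _embed(self, pwm, offset, rng):
        seq = "".join(rng.choice(list(BASES), size=WINDOW_LENGTH))
        return (seq[:offset] + pwm.consensus
                + seq[offset + pwm.width:])[:WINDOW_LENGTH]

    def test_constructed_disruption(self, sharp_pwm):
        rng = np.random.default_rng(0)
        offset = WINDOW_CENTER - sharp_pwm.width // 2
        ref_win = self._embed(sharp_pwm, offset, rng)
        motif_pos = WINDOW_CENTER - offset
        weakest = BASES[sharp_pwm.prob_matrix[:, motif_pos].argmin()]
        res = scan_pair(_pair_with(ref_win, weakest), sharp_pwm)
        assert res.in_motif
        assert res.score_change > 0
        assert res.anchor == (offset, "+")

    def test_hit_missing_center_excluded(self, sharp_pwm):
        # consensus planted entirely left of the center
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(BASES), size=WINDOW_LENGTH))
        win = sharp_pwm.consensus + seq[sharp_pwm.width:]
        null = score_pvalue_table(sharp_pwm)
        hits = scan_window(win, sharp_pwm, null)
        assert hits == []  # significant offsets exist but none cover center

    def test_random_windows_mostly_not_in_motif(self, sharp_pwm):
        rng = np.random.default_rng(2)
        null = score_pvalue_table(sharp_pwm)
        n_hit = 0
        for _ in range(50):
            win = "".join(rng.choice(list(BASES), size=WINDOW_LENGTH))
            alt = next(b for b in BASES if b != win[WINDOW_CENTER])
            res = scan_pair(_pair_with(win, alt), sharp_pwm, null=null)
            n_hit += res.in_motif
        assert n_hit <= 2

    def test_non_acgt_scores_minus_inf(self, sharp_pwm):
        rng = np.random.default_rng(3)
        win = "N" * WINDOW_LENGTH
        null = score_pvalue_table(sharp_pwm)
        assert scan_window(win, sharp_pwm, null) == []

    def test_too_wide_pwm_rejected(self, random_pwm_factory):
        pwm = random_pwm_factory(3, 0)
        wide = PWMModel.from_counts(np.ones((4, 60)), pseudocount=1.0)
        pair = _pair_with("A" * WINDOW_CENTER + "C" + "A" * WINDOW_CENTER, "G")
        with pytest.raises(ValueError):
            scan_pair(pair, wide)
        scan_pair(pair, pwm)  # narrow PWM is fine

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 5000))
    def test_strand_symmetry(self, seed):
        """A window and its reverse complement give mirror hits with
        identical scores and p-values."""
        rng0 = np.random.default_rng(seed % 7)
        pwm = PWMModel.from_counts(rng0.uniform(1.0, 50.0, size=(4, 6)),
                                   pseudocount=0.5)
        null = score_pvalue_table(pwm)
        rng = np.random.default_rng(seed)
        win = "".join(rng.choice(list(BASES), size=WINDOW_LENGTH))
        fwd = scan_window(win, pwm, null, alpha=0.05)
        rev = scan_window(revcomp(win), pwm, null, alpha=0.05)
        key = lambda h: (round(h.score, 9), round(h.pvalue, 12))
        fwd_set = sorted(map(key, fwd))
        rev_set = sorted(map(key, rev))
        assert fwd_set == rev_set
        # offsets mirror: offset' = L - w - offset, strand flips
        mirrored = sorted((WINDOW_LENGTH - pwm.width - h.offset,
                           "+" if h.strand == "-" else "-") for h in fwd)
        assert mirrored == sorted((h.offset, h.strand) for h in rev)


class TestEnrichment:
    def _scan(self, in_motif, rsid):
        snp = HetSNP("chr1", 100, rsid, "A", "G")
        return type("R", (), {"in_motif": in_motif, "snp": snp})()

    def _results(self, flags, prefix):
        from asbkit.motif import PairScanResult

        return [
            PairScanResult(HetSNP("chr1", 100 + i, f"{prefix}{i}", "A", "G"),
                           in_motif=f)
            for i, f in enumerate(flags)
        ]

    def test_moments_match_hypergeometric(self):
        asb = self._results([True, True, False], "a")
        nonasb = self._results([True, True, True, False, False, False], "n")
        res = enrichment_test(asb, nonasb, iterations=20_000, seed=0)
        # drawing 3 from 6 with 3 successes: hypergeom(M=6, n=3, N=3)
        hg = stats.hypergeom(6, 3, 3)
        mc_se = hg.std() / np.sqrt(res.iterations)
        assert res.control_mean == pytest.approx(hg.mean(), abs=3 * mc_se)
        assert res.control_sd == pytest.approx(hg.std(), rel=0.05)

    def test_zero_z_gives_p_one(self):
        asb = self._results([True, False], "a")
        nonasb = self._results([True, False, True, False], "n")
        res = enrichment_test(asb, nonasb, iterations=5000, seed=1)
        if res.z == 0.0:
            assert res.pvalue == 1.0
        else:  # at least: two-sided normal p consistent with z
            assert res.pvalue == pytest.approx(
                min(1.0, 2 * stats.norm.sf(abs(res.z))), abs=1e-12
            )

    def test_degenerate_sd_flagged(self):
        asb = self._results([True, True, True], "a")
        nonasb = self._results([False] * 6, "n")
        res = enrichment_test(asb, nonasb, iterations=100, seed=2)
        assert res.degenerate_sd
        assert res.pvalue <= np.finfo(float).tiny
        assert res.control_mean == 0.0 and res.control_sd == 0.0

    def test_pool_size_validation(self):
        asb = self._results([True] * 4, "a")
        nonasb = self._results([False] * 3, "n")
        with pytest.raises(ValueError):
            enrichment_test(asb, nonasb, iterations=10, seed=0)

    def test_deterministic_given_seed(self):
        asb = self._results([True, False, True], "a")
        nonasb = self._results([True, False] * 5, "n")
        a = enrichment_test(asb, nonasb, iterations=500, seed=7)
        b = enrichment_test(asb, nonasb, iterations=500, seed=7)
        assert (a.control_mean, a.control_sd, a.z, a.pvalue) == (
            b.control_mean, b.control_sd, b.z, b.pvalue
        )


def _scan_result(snp, score_change):
    from asbkit.motif import PairScanResult

    return PairScanResult(snp, in_motif=True, anchor=(15, "+"),
                          ref_score=score_change, alt_score=0.0)


class TestRatioScoreCorrelation:
    def _joined(self, ratios, changes):
        out = []
        for i, (r, c) in enumerate(zip(ratios, changes)):
            total = 20
            ref = int(round(r * total))
            count = make_count(ref, total - ref, pos=100 + i, rsid=f"rs{i}")
            out.append((_scan_result(count.snp, c), count))
        return out

    def test_perfect_linearity(self):
        ratios = [0.1, 0.3, 0.5, 0.7, 0.9]
        changes = [2 * (r - 0.5) for r in ratios]
        res = ratio_score_correlation(self._joined(ratios, changes))
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_constant_change_flagged(self):
        res = ratio_score_correlation(self._joined([0.2, 0.5, 0.8],
                                                   [1.0, 1.0, 1.0]))
        assert res.r is None and res.flag == "zero_variance"

    def test_too_few_records_flagged(self):
        res = ratio_score_correlation(self._joined([0.2, 0.8], [0.1, 0.9]))
        assert res.flag == "too_few_records"

    def test_hand_listed_pairs_match_closed_form(self):
        ratios = [0.05, 0.35, 0.5, 0.75, 0.9]
        changes = [-1.2, 0.3, 0.1, 0.8, 2.0]
        joined = self._joined(ratios, changes)
        # recompute ratios from the integerized counts used in the join
        x = np.array([c.ref_ratio for _, c in joined])
        y = np.array(changes)
        r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        res = ratio_score_correlation(joined)
        assert res.r == pytest.approx(r_manual, abs=1e-12)


class TestDisruptionProfile:
    def test_minus_strand_position_via_rc_oracle(self, sharp_pwm):
        """The strand mirror rule agrees with explicitly locating the SNP
        column in the reverse-complemented motif."""
        w = sharp_pwm.width
        for offset in range(WINDOW_CENTER - w + 1, WINDOW_CENTER + 1):
            plus = motif_position_of_center(offset, "+", w)
            minus = motif_position_of_center(offset, "-", w)
            assert plus == WINDOW_CENTER - offset
            assert minus == w - 1 - plus

    def test_freq_proportional_to_ic_gives_consistency_one(self,
                                                           random_pwm_factory):
        from asbkit.motif import DisruptionProfile, PairScanResult

        pwm = random_pwm_factory(8, 3)
        ic = pwm.ic_per_position
        # plant disruption counts proportional to IC
        freq = np.maximum(1, np.round(ic * 50)).astype(int)
        results = []
        i = 0
        for pos, n in enumerate(freq):
            offset = WINDOW_CENTER - pos
            for _ in range(n):
                snp = HetSNP("chr1", 10 + i, f"rs{i}", "A", "G")
                results.append(PairScanResult(snp, in_motif=True,
                                              anchor=(offset, "+"),
                                              ref_score=1.0, alt_score=0.0))
                i += 1
        prof = disruption_profile(results, pwm)
        np.testing.assert_array_equal(prof.freq_per_position, freq)
        # rounding keeps proportionality only approximately; r must be high
        assert prof.pearson_r > 0.99
        if np.array_equal(freq, ic * 50):  # exact proportionality
            assert prof.consistency_ratio == 1.0

    def test_exact_proportionality_consistency(self):
        from asbkit.motif import PairScanResult

        # IC pattern with clear high/low split
        probs = np.column_stack([
            np.array([0.97, 0.01, 0.01, 0.01]),
            np.full(4, 0.25),
            np.array([0.7, 0.1, 0.1, 0.1]),
            np.full(4, 0.25),
        ])
        pwm = PWMModel("toy", probs, np.full(4, 0.25))
        ic = pwm.ic_per_position
        order = np.argsort(-ic)
        counts = np.zeros(4, dtype=int)
        counts[order] = [40, 20, 2, 1]  # same ranking as IC
        results = []
        i = 0
        for pos, n in enumerate(counts):
            for _ in range(n):
                snp = HetSNP("chr1", 10 + i, f"rs{i}", "A", "G")
                results.append(PairScanResult(
                    snp, in_motif=True, anchor=(WINDOW_CENTER - pos, "+"),
                    ref_score=1.0, alt_score=0.0))
                i += 1
        prof = disruption_profile(results, pwm)
        assert prof.consistency_ratio == 1.0

    def test_consistency_invariant_under_affine_rescale(self):
        # rescaling the planted frequencies by any positive affine map
        # cannot change which side of the mean each position falls on
        freq = np.array([5.0, 1.0, 8.0, 2.0])
        for a, b in [(1.0, 0.0), (3.5, 2.0), (0.2, 10.0)]:
            scaled = a * freq + b
            assert np.array_equal(freq >= freq.mean(),
                                  scaled >= scaled.mean())

    def test_empty_profile_flagged(self, sharp_pwm):
        prof = disruption_profile([], sharp_pwm)
        assert prof.flag == "no_in_motif_records"


class TestMotifFixtures:
    def test_planted_disruptions_all_flagged(self, sharp_pwm):
        sim = simulate_motif_windows(sharp_pwm, 8, 0, seed=5)
        for pair in sim.pairs:
            res = scan_pair(pair, sharp_pwm)
            assert res.in_motif and res.score_change > 0

    def test_deterministic(self, sharp_pwm):
        a = simulate_motif_windows(sharp_pwm, 3, 3, seed=9)
        b = simulate_motif_windows(sharp_pwm, 3, 3, seed=9)
        assert [p.ref_window for p in a.pairs] == [p.ref_window
                                                  for p in b.pairs]

    def test_background_hit_rate_bounded_by_tail_mass(self, sharp_pwm):
        """Expected in-motif rate of background windows is bounded by the
        per-window union bound 2*w_offsets*tail(threshold)."""
        null = score_pvalue_table(sharp_pwm)
        sim = simulate_motif_windows(sharp_pwm, 0, 200, seed=11)
        n_hit = sum(scan_pair(p, sharp_pwm, null=null).in_motif
                    for p in sim.pairs)
        n_offsets = sharp_pwm.width  # offsets covering the center
        bound = 2 * 2 * n_offsets * 1e-4 * 200  # both windows, both strands
        assert n_hit <= max(3.0, 5 * bound)
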