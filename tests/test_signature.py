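"""Signed signature, patient scoring, KM/log-rank, bootstrap FDR."""

import numpy as np
import pandas as pd
import pytest

from turnoverkit import signature as sg
from turnoverkit import synthetic as syn


def _sig(n_up=5, n_down=5):
    genes = [f"U{i}" for i in range(n_up)] + [f"D{i}" for i in range(n_down)]
    w = np.array([1.0] * n_up + [-1.0] * n_down)
    return sg.SignedSignature(genes=genes, weights=w)


class TestBuildSignature:
    @staticmethod
    def _profiles(n_up, n_down, n_flat, amp=2.0):
        tps = [1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0]
        rows, idx = [], []
        for i in range(n_up):
            rows.append([0, amp / 2, amp, amp, amp, amp, amp]); idx.append(f"UP{i}")
        for i in range(n_down):
            rows.append([0, -amp / 2, -amp, -amp, -amp, -amp, -amp]); idx.append(f"DN{i}")
        for i in range(n_flat):
            rows.append([0.05, -0.03, 0.02, 0.0, 0.01, -0.02, 0.04]); idx.append(f"NC{i}")
        return pd.DataFrame(rows, index=idx, columns=tps)

    def test_planted_responders_enter_with_correct_signs(self):
        prof = self._profiles(50, 50, 200)
        sig = sg.build_signature(prof, fold_cutoff=2.0)
        assert len(sig) == 100
        assert (sig.weights == 1).sum() == 50 and (sig.weights == -1).sum() == 50
        assert all(g.startswith("UP") for g, w in zip(sig.genes, sig.weights) if w == 1)

    def test_membership_matches_brute_force_filter(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.normal(0, 0.8, (300, 7)),
                            index=[f"P{i}" for i in range(300)],
                            columns=[1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0])
        sig = sg.build_signature(prof, fold_cutoff=2.0)
        expected = {pid for pid, row in prof.iterrows()
                    if 2 ** np.abs(row).max() >= 2.0}
        assert set(sig.genes) == expected

    def test_no_responders_is_an_error(self):
        prof = self._profiles(0, 0, 100)
        with pytest.raises(ValueError, match="empty signature"):
            sg.build_signature(prof)


class TestScorePatients:
    def test_zero_expression_scores_zero(self):
        sig = _sig()
        expr = pd.DataFrame(np.zeros((10, 4)), index=sig.genes,
                            columns=[f"pt{i}" for i in range(4)])
        scores = sg.score_patients(expr, sig, normalize="none")
        assert (scores == 0).all()

    def test_expression_equal_to_coefficients_scores_length(self):
        sig = _sig()
        expr = pd.DataFrame(np.tile(sig.weights[:, None], (1, 3)), index=sig.genes,
                            columns=list("abc"))
        scores = sg.score_patients(expr, sig, normalize="none")
        assert (scores == len(sig)).all()

    def test_matches_explicit_summation_loop(self):
        rng = np.random.default_rng(1)
        sig = _sig(7, 6)
        expr = pd.DataFrame(rng.normal(size=(13, 20)), index=sig.genes,
                            columns=[f"pt{i}" for i in range(20)])
        scores = sg.score_patients(expr, sig)
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0), axis=0)
        for pt in expr.columns:
            manual = sum(w * z.loc[g, pt] for g, w in zip(sig.genes, sig.weights))
            assert scores[pt] == pytest.approx(manual)

    def test_linearity_in_expression(self):
        rng = np.random.default_rng(2)
        sig = _sig()
        a = pd.DataFrame(rng.normal(size=(10, 8)), index=sig.genes)
        b = pd.DataFrame(rng.normal(size=(10, 8)), index=sig.genes)
        s = sg.score_patients
        total = s(a + b, sig, normalize="none")
        assert np.allclose(total, s(a, sig, normalize="none") + s(b, sig, normalize="none"))

    def test_negating_coefficients_and_expression_is_invariant(self):
        rng = np.random.default_rng(3)
        sig = _sig()
        flipped = sg.SignedSignature(genes=sig.genes, weights=-sig.weights)
        expr = pd.DataFrame(rng.normal(size=(10, 8)), index=sig.genes)
        s1 = sg.score_patients(expr, sig, normalize="none")
        s2 = sg.score_patients(-expr, flipped, normalize="none")
        assert np.allclose(s1, s2)

    def test_too_many_missing_genes_rejected(self):
        sig = _sig(10, 10)
        expr = pd.DataFrame(np.zeros((5, 3)), index=sig.genes[:5])
        with pytest.raises(ValueError, match="missing"):
            sg.score_patients(expr, sig)


class TestStratify:
    def test_ten_distinct_scores_give_two_per_tail(self):
        scores = pd.Series(np.arange(10.0), index=[f"pt{i}" for i in range(10)])
        cohorts = sg.stratify(scores, 0.20)
        assert (cohorts == "top").sum() == 2 and (cohorts == "bottom").sum() == 2

    def test_negating_coefficients_swaps_cohorts(self):
        rng = np.random.default_rng(4)
        sig = _sig()
        expr = pd.DataFrame(rng.normal(size=(10, 50)), index=sig.genes,
                            columns=[f"pt{i}" for i in range(50)])
        flipped = sg.SignedSignature(genes=sig.genes, weights=-sig.weights)
        c1 = sg.stratify(sg.score_patients(expr, sig), 0.2)
        c2 = sg.stratify(sg.score_patients(expr, flipped), 0.2)
        assert set(c1[c1 == "top"].index) == set(c2[c2 == "bottom"].index)

    def test_degenerate_scores_warn_and_split_by_order(self):
        scores = pd.Series(np.ones(10), index=[f"pt{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="degenerate"):
            cohorts = sg.stratify(scores, 0.2)
        assert (cohorts == "top").sum() == 2 and (cohorts == "bottom").sum() == 2

    def test_cohort_sizes_match_percentile_oracle(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=1000), index=[f"pt{i}" for i in range(1000)])
        cohorts = sg.stratify(scores, 0.2)
        lo, hi = np.quantile(scores, [0.2, 0.8])
        assert (cohorts == "top").sum() == (scores >= hi).sum()
        assert (cohorts == "bottom").sum() == (scores <= lo).sum()

    def test_invalid_quantile_rejected(self):
        scores = pd.Series(np.arange(20.0))
        with pytest.raises(ValueError):
            sg.stratify(scores, 0.6)


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        res = sg.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (res.table["survival"].iloc[1:] == 1.0).all()
        assert np.isnan(res.median)

    def test_three_events_product_limit_by_hand(self):
        # S(1)=2/3, S(2)=1/3, S(3)=0; median = first t with S<=0.5 -> 2
        res = sg.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        tab = res.table.set_index("time")["survival"]
        assert tab[1.0] == pytest.approx(2 / 3)
        assert tab[2.0] == pytest.approx(1 / 3)
        assert tab[3.0] == pytest.approx(0.0)
        assert res.median == 2.0

    def test_curve_invariant_to_censoring_time_within_interval(self):
        # a censored subject contributes only through risk-set membership, so
        # moving its censoring time between two adjacent event times cannot
        # change the product-limit curve
        a = sg.km_estimate([1.0, 2.5, 3.0, 5.0], [1, 0, 1, 1])
        b = sg.km_estimate([1.0, 2.9, 3.0, 5.0], [1, 0, 1, 1])
        at = a.table[a.table["time"].isin([1.0, 3.0, 5.0])]["survival"].to_numpy()
        bt = b.table[b.table["time"].isin([1.0, 3.0, 5.0])]["survival"].to_numpy()
        assert np.allclose(at, bt)
        assert a.median == b.median

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            sg.km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_cohorts_give_null_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        stat, p = sg.logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_computed_oracle(self):
        # groups A={1,3,5}, B={2,4,6}, all events; O_A - E_A = 0.76667,
        # Var = 1.21222 -> chi2 = 0.48488 (hand product over risk sets)
        stat, p = sg.logrank([1, 3, 5], [1, 1, 1], [2, 4, 6], [1, 1, 1])
        assert stat == pytest.approx(0.48488, abs=1e-4)

    def test_swapping_groups_preserves_statistic(self):
        s1, _ = sg.logrank([1, 3, 5], [1, 1, 1], [2, 4, 8], [1, 0, 1])
        s2, _ = sg.logrank([2, 4, 8], [1, 0, 1], [1, 3, 5], [1, 1, 1])
        assert s1 == pytest.approx(s2)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            sg.logrank([1.0], [0], [2.0], [0])


class TestSignatureFDR:
    def test_null_signature_fdr_is_not_extreme(self):
        # effect_size=0: the target signature is no better than a random one,
        # so decoy ratios scatter around the target's and the empirical FDR
        # lands in the body of [0, 1] rather than at the floor
        sig = _sig(10, 10)
        fdrs = []
        for s in range(8):
            expr, surv = syn.gen_cohort(150, sig, effect_size=0.0,
                                        censor_rate=0.0, seed=100 + s)
            res = sg.signature_fdr(expr, surv, sig, n_boot=40, seed=s)
            fdrs.append(res.fdr)
        assert 0.15 < np.mean(fdrs) < 0.85
        assert max(fdrs) - min(fdrs) > 0.1

    def test_strong_signature_never_beaten_by_decoys(self):
        sig = _sig(15, 15)
        expr, surv = syn.gen_cohort(400, sig, effect_size=1.5, censor_rate=0.1, seed=9)
        fdr = sg.signature_fdr(expr, surv, sig, n_boot=100, seed=10)
        assert fdr.n_beat == 0
        assert fdr.label == "< 0.01"

    def test_insufficient_decoy_pool_rejected(self):
        sig = _sig(10, 10)
        expr, surv = syn.gen_cohort(50, sig, 0.5, 0.0, seed=11, n_extra_genes=5)
        with pytest.raises(ValueError, match="non-signature"):
            sg.signature_fdr(expr, surv, sig, n_boot=10, seed=12)
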