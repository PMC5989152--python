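"""Synthetic-data generator: construction constraints and determinism."""

import numpy as np
import pandas as pd
import pytest

from turnoverkit.config import ConfigError, SimConfig
from turnoverkit import synthetic as syn
from turnoverkit.signature import SignedSignature
from turnoverkit.signature import logrank, stratify, score_patients

LN2 = np.log(2.0)


class TestGenProteome:
    def test_histone_abundance_share_matches_config(self):
        cfg = SimConfig(n_proteins=5000, histone_fraction=0.05, seed=1)
        quant, _ = syn.gen_proteome(cfg)
        share = quant.loc[quant["is_histone"], "intensity"].sum() / quant["intensity"].sum()
        assert 0.049 <= share <= 0.051

    def test_same_seed_reproduces_identical_tables(self):
        cfg = SimConfig(n_proteins=500, seed=7)
        q1, t1 = syn.gen_proteome(cfg)
        q2, t2 = syn.gen_proteome(cfg)
        pd.testing.assert_frame_equal(q1, q2)
        pd.testing.assert_frame_equal(t1.proteins, t2.proteins)

    def test_copy_number_dynamic_range_spans_eight_decades(self):
        # sigma 1.15 targets a max/min copy ratio of ~1e8 at n=5000
        cfg = SimConfig(n_proteins=5000, abundance_sigma=1.15, seed=2)
        _, truth = syn.gen_proteome(cfg)
        copies = truth.proteins.loc[~truth.proteins["is_histone"], "copy_number"]
        span = np.log10(copies.max() / copies.min())
        assert 7.0 <= span <= 9.0  # within 10x of 1e8

    def test_more_histones_than_proteins_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_proteins=5, n_histones=10)


class TestGenPulseSilac:
    def test_noise_free_decay_hits_half_at_half_life(self):
        # A=1, C=0, tau=10 -> D(10*ln2) = 0.5
        cfg = SimConfig(n_proteins=1, timepoints=(10 * LN2,), seed=0,
                        ratio_noise_sd=0.0, responsive_fraction=0.0, n_histones=1)
        _, truth = syn.gen_proteome(cfg)
        truth.proteins.loc[:, ["A_CTRL", "C_CTRL", "tau_CTRL"]] = [1.0, 0.0, 10.0]
        pep = syn.gen_pulse_silac(truth, cfg, "CTRL")
        ml = pep[pep["channel"] == "M/L"]["ratio"]
        assert np.allclose(ml, 0.5)

    def test_synthesis_plus_degradation_conserves_total(self):
        cfg = SimConfig(n_proteins=20, ratio_noise_sd=0.0, seed=3, n_histones=2)
        _, truth = syn.gen_proteome(cfg)
        pep = syn.gen_pulse_silac(truth, cfg, "CTRL")
        wide = pep.pivot_table(index=["peptide_id", "replicate", "time_h"],
                               columns="channel", values="ratio")
        total = wide["M/L"] + wide["H/L"]
        expected = (truth.proteins.set_index("protein_id")["A_CTRL"]
                    + truth.proteins.set_index("protein_id")["C_CTRL"])
        prot_of_pep = pep.drop_duplicates("peptide_id").set_index("peptide_id")["protein_id"]
        for (pid, _, _), tot in total.items():
            assert tot == pytest.approx(expected[prot_of_pep[pid]])

    def test_noisy_peptide_mean_tracks_true_curve(self):
        cfg = SimConfig(n_proteins=1, ratio_noise_sd=0.05, seed=4, n_histones=1,
                        responsive_fraction=0.0)
        _, truth = syn.gen_proteome(cfg)
        truth.proteins.loc[:, "n_peptides"] = 20
        A, tau, C = truth.proteins.loc[0, ["A_CTRL", "tau_CTRL", "C_CTRL"]]
        pep = syn.gen_pulse_silac(truth, cfg, "CTRL")
        ml = pep[pep["channel"] == "M/L"]
        for tp, grp in ml.groupby("time_h"):
            true_d = C + A * np.exp(-tp / tau)
            # log-normal noise: E[obs] = true * exp(sd^2/2)
            mean_exp = true_d * np.exp(0.05**2 / 2)
            se = grp["ratio"].std(ddof=1) / np.sqrt(len(grp))
            assert abs(grp["ratio"].mean() - mean_exp) < 3 * se + 1e-12

    def test_negative_noise_sd_rejected(self):
        cfg = SimConfig(n_proteins=5, seed=0, n_histones=1)
        _, truth = syn.gen_proteome(cfg)
        with pytest.raises(ValueError):
            syn.gen_pulse_silac(truth, cfg, "CTRL", noise_sd=-0.1)


class TestGenTimecourse:
    def test_no_responders_means_flat_truth(self):
        cfg = SimConfig(n_proteins=200, responsive_fraction=0.0, seed=5)
        _, truth = syn.gen_proteome(cfg)
        assert (truth.profiles.to_numpy() == 0).all()

    def test_responsive_count_is_rounded_fraction(self):
        cfg = SimConfig(n_proteins=6890, responsive_fraction=0.03, seed=6)
        _, truth = syn.gen_proteome(cfg)
        n_resp = (truth.proteins["archetype"] != "NC").sum()
        assert n_resp == round(0.03 * 6890)

    def test_early_up_templates_reach_threefold(self):
        tps = (1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0)
        curve = syn.archetype_template("EU", tps)
        assert 2.0 ** np.abs(curve).max() >= 3.0

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError):
            syn.archetype_template("XX", (1.0, 3.0))

    def test_planted_missingness_recoverable(self):
        cfg = SimConfig(n_proteins=100, seed=7)
        _, truth = syn.gen_proteome(cfg)
        tc = syn.gen_timecourse(truth, cfg, missing_fraction=0.1)
        full = 100 * cfg.n_replicates * len(cfg.timepoints)
        assert len(tc) < full
        # brute-force recount of complete profiles
        counts = tc.groupby("protein_id").size()
        expected_complete = (counts == cfg.n_replicates * len(cfg.timepoints)).sum()
        from turnoverkit.clustering import select_complete
        wide = select_complete(tc, cfg.timepoints, cfg.n_replicates)
        assert len(wide) == expected_complete


class TestGenComplexes:
    def test_zero_coherence_gives_identical_member_half_lives(self):
        cfg = SimConfig(n_proteins=300, seed=8)
        _, truth = syn.gen_proteome(cfg)
        cat, truth = syn.gen_complexes(truth, 20, [3, 4], coherence=0.0, seed=1)
        hl = truth.half_lives()
        for _, members in cat.groupby("complex_id")["protein_id"]:
            assert hl[members].std(ddof=1) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_size_catalog_row_count(self):
        cfg = SimConfig(n_proteins=300, seed=9)
        _, truth = syn.gen_proteome(cfg)
        cat, _ = syn.gen_complexes(truth, 50, [4], coherence=1.0, seed=2)
        assert len(cat) == 200
        assert cat.groupby("complex_id").size().eq(4).all()

    def test_size_below_two_rejected(self):
        cfg = SimConfig(n_proteins=50, seed=0)
        _, truth = syn.gen_proteome(cfg)
        with pytest.raises(ValueError):
            syn.gen_complexes(truth, 5, [1, 3], coherence=0.0, seed=1)

    def test_uncoupled_complexes_match_decoy_spread(self):
        # coherence=inf leaves member half-lives at their global draws, so
        # complex SDs should be indistinguishable from random groups
        from scipy.stats import ks_2samp
        from turnoverkit.complexes import complex_halflife_sd, decoy_catalog
        cfg = SimConfig(n_proteins=2000, seed=10)
        _, truth = syn.gen_proteome(cfg)
        cat, truth = syn.gen_complexes(truth, 200, [4], coherence=np.inf, seed=3)
        hl = truth.half_lives()
        target = complex_halflife_sd(cat, hl)
        decoy = complex_halflife_sd(decoy_catalog(cat, list(hl.index), seed=4), hl)
        assert ks_2samp(target, decoy).pvalue > 0.05


class TestGenCohort:
    @staticmethod
    def _sig(n=40):
        w = np.ones(n)
        w[n // 2:] = -1
        return SignedSignature(genes=[f"G{i}" for i in range(n)], weights=w)

    def test_no_censoring_means_all_events(self):
        _, surv = syn.gen_cohort(100, self._sig(), 0.5, censor_rate=0.0, seed=1)
        assert (surv["event"] == 1).all()

    def test_bad_censor_rate_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_cohort(50, self._sig(), 0.5, censor_rate=1.0, seed=1)

    def test_empty_signature_rejected(self):
        empty = SignedSignature(genes=[], weights=np.array([]))
        with pytest.raises(ValueError):
            syn.gen_cohort(50, empty, 0.5, censor_rate=0.1, seed=1)

    def test_positive_effect_shortens_top_cohort_survival(self):
        sig = self._sig()
        expr, surv = syn.gen_cohort(500, sig, effect_size=1.0, censor_rate=0.0, seed=2)
        scores = score_patients(expr, sig)
        cohorts = stratify(scores)
        si = surv.set_index("patient_id").loc[scores.index]
        top = si.loc[(cohorts == "top").to_numpy(), "time_years"]
        bottom = si.loc[(cohorts == "bottom").to_numpy(), "time_years"]
        assert top.median() < bottom.median()

    def test_null_effect_logrank_is_calibrated(self):
        # effect_size=0: reject-at-0.05 rate over repeated cohorts ~5%
        sig = self._sig(20)
        rejects = 0
        n_sim = 200
        for s in range(n_sim):
            expr, surv = syn.gen_cohort(60, sig, 0.0, censor_rate=0.1, seed=s,
                                        n_extra_genes=0)
            scores = score_patients(expr, sig)
            cohorts = stratify(scores)
            si = surv.set_index("patient_id").loc[scores.index]
            t_m = (cohorts == "top").to_numpy()
            b_m = (cohorts == "bottom").to_numpy()
            _, p = logrank(si["time_years"][t_m], si["event"][t_m],
                           si["time_years"][b_m], si["event"][b_m])
            rejects += p < 0.05
        assert abs(rejects / n_sim - 0.05) < 0.035
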