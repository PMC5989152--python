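"""Self-validation benchmarks: recovery, calibration and smoke checks.

Each function runs one end-to-end statistical check of the pipeline on
synthetic data generated under the study conditions (7 time points, 3
replicates, multiplicative ratio noise) and returns the measured quantities.
They power both the acceptance script and the acceptance test suite; every
source of randomness is derived from the ``seed`` argument.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import abundance as ab
from . import clustering as cl
from . import complexes as cx
from . import differential as de
from . import enrichment as en
from . import signature as sg
from . import synthetic as syn
from . import turnover as tv
from .config import RunConfig, SimConfig

LN2 = float(np.log(2.0))


def _seed(base: int, k: int) -> int:
    return int((base * 1000 + k) % (2**31 - 1))


def tau_ceiling_half_life() -> dict:
    """Half-life implied by the 300 h tau ceiling."""
    return {"half_life_at_tau_ceiling_h": float(tv.half_life_from_tau(300.0)), "n": 1}


def tau_recovery(seed: int, n_proteins: int = 1000) -> dict:
    """Median relative tau error over simulated proteins.

    tau ~ log-uniform [2, 48] h, 5 peptides, 3 replicates, ln-scale ratio
    noise SD 0.05 on the 7-point grid.
    """
    cfg = SimConfig(n_proteins=n_proteins, seed=_seed(seed, 1), ratio_noise_sd=0.05,
                    responsive_fraction=0.0)
    _, truth = syn.gen_proteome(cfg)
    rng = np.random.default_rng(_seed(seed, 2))
    truth.proteins["tau_CTRL"] = np.exp(rng.uniform(np.log(2.0), np.log(48.0),
                                                    n_proteins))
    truth.proteins["n_peptides"] = 5
    pep = syn.gen_pulse_silac(truth, cfg, "CTRL")
    fits, _ = tv.fit_all_proteins(pep, "CTRL", replicate_sigma=False)
    merged = fits.set_index("protein_id").join(
        truth.proteins.set_index("protein_id")["tau_CTRL"])
    ok = merged[~merged["degenerate"].astype(bool)]
    rel_err = np.abs(ok["tau"] - ok["tau_CTRL"]) / ok["tau_CTRL"]
    return {"median_rel_tau_error": float(rel_err.median()), "n": len(ok)}


def ttest_null_calibration(seed: int, n_proteins: int = 10000) -> dict:
    """Rejection rate of the shrink-variance t-test at p<0.01 under the null."""
    rng = np.random.default_rng(_seed(seed, 3))
    x = rng.normal(0.0, 0.3, size=(n_proteins, 3))
    *_, p, _ = de._moderated_onesample(x)
    return {
        "rejection_rate_p01": float((p < 0.01).mean()),
        "ks_uniform_p": float(stats.kstest(p, "uniform").pvalue),
        "n": n_proteins,
    }


def delta_halflife_null_calibration(seed: int, n_proteins: int = 2500) -> dict:
    """|z|>1.96 rate of the half-life z-test when both conditions share the
    same kinetics (full pipeline: simulate, fit, filter, test)."""
    cfg = SimConfig(n_proteins=n_proteins, seed=_seed(seed, 4), ratio_noise_sd=0.05,
                    responsive_fraction=0.0, tau_shift_fraction=0.0,
                    tau_median_h=14.0, tau_log10_sd=0.25)
    _, truth = syn.gen_proteome(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits_c, _ = tv.fit_all_proteins(syn.gen_pulse_silac(truth, cfg, "CTRL"),
                                        "CTRL", replicate_sigma=False)
        fits_o, _ = tv.fit_all_proteins(syn.gen_pulse_silac(truth, cfg, "4OHT"),
                                        "4OHT", replicate_sigma=False)
        paired = tv.filter_paired_fits(fits_c, fits_o)
        res = de.delta_halflife_ztest(paired)
    return {
        "z_gt_196_rate": float((np.abs(res["z"]) > 1.96).mean()),
        "n": len(res),
    }


def weighted_median_checks(seed: int, n_instances: int = 500) -> dict:
    """Agreement of weighted_median with the cumulative-scan oracle, and with
    the unweighted median under uniform weights (odd n)."""
    rng = np.random.default_rng(_seed(seed, 5))
    agree = unif = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, 50))
        v = rng.lognormal(2.5, 0.6, n)
        w = rng.uniform(0.01, 10.0, n)
        order = np.argsort(v, kind="stable")
        cum = np.cumsum(w[order])
        oracle = v[order][int(np.searchsorted(cum, w.sum() / 2.0))]
        agree += ab.weighted_median(v, w) == oracle
        n_odd = n if n % 2 == 1 else n + 1
        v_odd = rng.lognormal(2.5, 0.6, n_odd)
        unif += ab.weighted_median(v_odd, np.ones(n_odd)) == float(np.median(v_odd))
    return {
        "oracle_agreement_rate": agree / n_instances,
        "uniform_weight_median_agreement_rate": unif / n_instances,
        "n": n_instances,
    }


def clustering_recovery(seed: int, n_proteins: int = 1500) -> dict:
    """Fraction of responsive proteins recovering their planted kinetic class
    at log2 replicate noise 0.25 (k-means k=30 + rule agglomeration)."""
    cfg = SimConfig(n_proteins=n_proteins, seed=_seed(seed, 6),
                    responsive_fraction=0.05, timecourse_noise_sd=0.25)
    _, truth = syn.gen_proteome(cfg)
    tc = syn.gen_timecourse(truth, cfg)
    wide = cl.select_complete(tc, cfg.timepoints, cfg.n_replicates)
    km = cl.kmeans_profiles(wide, k=30, seed=_seed(seed, 7), n_init=20)
    classes = cl.assign_classes(km)
    truth_lab = truth.proteins.set_index("protein_id")["archetype"]
    resp = truth_lab[truth_lab != "NC"]
    recovery = float((classes.loc[resp.index, "kinetic_class"] == resp).mean())
    return {"responsive_class_recovery": recovery, "n": len(resp)}


def pscore_calibration(seed: int, n_terms: int = 500, n_background: int = 1000,
                       n_perm: int = 10000) -> dict:
    """Uniformity of null-term Pscores and the call on a planted term made of
    the globally shortest-lived proteins."""
    rng = np.random.default_rng(_seed(seed, 8))
    hl = pd.Series(rng.lognormal(2.5, 0.6, n_background),
                   index=[f"P{i:05d}" for i in range(n_background)])
    terms = {
        f"T{i:04d}": set(rng.choice(hl.index, int(rng.integers(5, 31)),
                                    replace=False))
        for i in range(n_terms)
    }
    res = en.pscore(terms, hl, n_perm=n_perm, seed=_seed(seed, 9))
    ks_p = float(stats.kstest(res.table["pscore"], "uniform").pvalue)
    planted = {"PLANTED": set(hl.nsmallest(20).index)}
    res_p = en.pscore(planted, hl, n_perm=n_perm, seed=_seed(seed, 10))
    return {
        "null_ks_uniform_p": ks_p,
        "planted_short_term_pscore": float(res_p.table["pscore"].iloc[0]),
        "planted_short_term_called": res_p.table["call"].iloc[0] == "short-lived",
        "n": n_terms,
    }


def complex_coherence_floor(seed: int) -> dict:
    """Empirical p at its floor for perfectly coherent planted complexes."""
    cfg = SimConfig(n_proteins=400, seed=_seed(seed, 11))
    _, truth = syn.gen_proteome(cfg)
    cat, truth = syn.gen_complexes(truth, 40, [3, 4, 5], coherence=0.0,
                                   seed=_seed(seed, 12))
    res = cx.compare_target_decoys(cat, truth.half_lives(), n_iter=1000,
                                   seed=_seed(seed, 13))
    return {"coherent_empirical_p": float(res.empirical_p), "n": res.n_iter}


def complex_null_calibration(seed: int, n_runs: int = 200) -> dict:
    """Reject-at-0.05 rate of the decoy bootstrap when complex membership is
    uncoupled from half-life (coherence = inf)."""
    rejects = 0
    for r in range(n_runs):
        cfg = SimConfig(n_proteins=400, seed=_seed(seed, 100 + r))
        _, truth = syn.gen_proteome(cfg)
        cat, truth = syn.gen_complexes(truth, 40, [3, 4, 5], coherence=np.inf,
                                       seed=_seed(seed, 500 + r))
        res = cx.compare_target_decoys(cat, truth.half_lives(), n_iter=1000,
                                       seed=_seed(seed, 900 + r))
        rejects += res.empirical_p <= 0.05
    return {"null_reject_rate_005": rejects / n_runs, "n": n_runs}


def survival_power(seed: int, n_sims: int = 100) -> dict:
    """Power of the top-vs-bottom log-rank test on cohorts whose hazard rises
    with the planted signature score (effect 1.0 per unit z, n=500)."""
    w = np.ones(40)
    w[20:] = -1.0
    sig = sg.SignedSignature(genes=[f"G{i}" for i in range(40)], weights=w)
    hits = 0
    for s in range(n_sims):
        expr, surv = syn.gen_cohort(500, sig, effect_size=1.0, censor_rate=0.2,
                                    seed=_seed(seed, 2000 + s), n_extra_genes=0)
        scores = sg.score_patients(expr, sig)
        cohorts = sg.stratify(scores)
        si = surv.set_index("patient_id").loc[scores.index]
        t_m = (cohorts == "top").to_numpy()
        b_m = (cohorts == "bottom").to_numpy()
        _, p = sg.logrank(si["time_years"][t_m], si["event"][t_m],
                          si["time_years"][b_m], si["event"][b_m])
        hits += p < 0.01
    return {"logrank_power_p01": hits / n_sims, "n": n_sims}


def signature_fdr_floor(seed: int, n_boot: int = 1000) -> dict:
    """Bootstrap FDR of a strongly prognostic signature (expect the floor)."""
    w = np.ones(30)
    w[15:] = -1.0
    sig = sg.SignedSignature(genes=[f"G{i}" for i in range(30)], weights=w)
    expr, surv = syn.gen_cohort(400, sig, effect_size=1.5, censor_rate=0.1,
                                seed=_seed(seed, 14))
    res = sg.signature_fdr(expr, surv, sig, n_boot=n_boot, seed=_seed(seed, 15))
    return {
        "n_decoys_beating_target": res.n_beat,
        "fdr_bound": 1.0 / n_boot if res.n_beat == 0 else res.fdr,
        "fdr_label": res.label,
        "n": n_boot,
    }


def pipeline_determinism(seed: int, workdir: str | Path,
                         n_proteins: int = 500) -> dict:
    """Run the full pipeline twice with one seed; outputs must be identical."""
    sim = SimConfig(n_proteins=n_proteins, seed=_seed(seed, 16), n_complexes=40,
                    n_patients=300)
    rc = RunConfig(pscore_n_perm=2000, complex_n_iter=300, n_boot_signature=200,
                   kmeans_n_init=10, complex_min_testable=10, seed=_seed(seed, 17))
    workdir = Path(workdir)
    from .pipeline import run_pipeline
    d1 = run_pipeline(sim, rc, workdir / "run1")
    d2 = run_pipeline(sim, rc, workdir / "run2")
    names = sorted(p.name for p in d1.iterdir())
    identical = all((d1 / n).read_bytes() == (d2 / n).read_bytes() for n in names)
    return {
        "identical_rerun": bool(identical),
        "n_output_files": len(names),
        "n": n_proteins,
    }
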