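"""Stage orchestration: simulate a study bundle and run every analysis stage.

Each stage reads its TSV inputs from the bundle directory, writes its TSV
outputs next to them, and is independently callable (the CLI exposes one
subcommand per stage). ``run_pipeline`` chains all stages and writes a
machine-readable manifest (versions, seeds, thresholds, outputs); any stage
error aborts the run with the stage name attached.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import abundance as ab
from . import clustering as cl
from . import complexes as cx
from . import differential as de
from . import enrichment as en
from . import signature as sg
from . import synthetic as syn
from . import turnover as tv
from .config import CONDITIONS, RunConfig, SimConfig, dump_config
from .io import (read_expression_matrix, read_peptide_table, read_survival,
                 read_table, read_two_column_map, write_table)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _cond_key(condition: str) -> str:
    return condition.replace("/", "_")


def stage_simulate(sim: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Generate the full synthetic input bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    quant, truth = syn.gen_proteome(sim)
    catalog, truth = syn.gen_complexes(
        truth, sim.n_complexes, sim.complex_sizes, sim.complex_coherence_h,
        seed=sim.seed + 1001,
    )
    files: dict[str, str] = {}
    for cond in CONDITIONS:
        pep = syn.gen_pulse_silac(truth, sim, cond)
        f = out / f"peptides_{_cond_key(cond)}.tsv"
        write_table(pep, f)
        files[f"peptides_{cond}"] = f.name
    write_table(quant, out / "quant.tsv")
    tc = syn.gen_timecourse(truth, sim)
    write_table(tc, out / "timecourse.tsv")
    write_table(catalog, out / "complexes.tsv")
    terms = syn.gen_annotations(
        truth.proteins["protein_id"], sim.n_terms, sim.term_size_range,
        seed=sim.seed + 1002,
    )
    ann_rows = [(t, p) for t in sorted(terms) for p in sorted(terms[t])]
    write_table(pd.DataFrame(ann_rows, columns=["term", "protein_id"]),
                out / "annotation.tsv")
    # the truth table itself, for recovery checks against pipeline output
    write_table(truth.proteins, out / "truth_proteins.tsv")
    prof = truth.profiles.reset_index()
    write_table(prof, out / "truth_profiles.tsv")
    files.update(
        quant="quant.tsv", timecourse="timecourse.tsv", complexes="complexes.tsv",
        annotation="annotation.tsv", truth="truth_proteins.tsv",
    )
    return files


def stage_fit_turnover(bundle: str | Path, rc: RunConfig) -> None:
    out = Path(bundle)
    for cond in CONDITIONS:
        pep = read_peptide_table(out / f"peptides_{_cond_key(cond)}.tsv")
        fits, pep_fits = tv.fit_all_proteins(
            pep, weighting=rc.peptide_weighting, tau_ceiling=rc.tau_ceiling_h,
            peptide_fits=rc.peptide_level_fits,
        )
        write_table(fits, out / f"fits_{_cond_key(cond)}.tsv")
        if rc.peptide_level_fits:
            write_table(pep_fits, out / f"peptide_fits_{_cond_key(cond)}.tsv")


def stage_copy_number(bundle: str | Path, rc: RunConfig) -> None:
    out = Path(bundle)
    quant = read_table(out / "quant.tsv").set_index("protein_id")
    quant["copy_number"] = ab.proteome_ruler(quant, rc.dna_mass_pg)
    cum = ab.cumulative_abundance(quant["copy_number"])
    fits = read_table(out / "fits_CTRL.tsv").set_index("protein_id")
    ok = fits[~fits["degenerate"].astype(bool)]
    joined = ok.join(quant["copy_number"], how="inner")
    hl = joined["half_life"].to_numpy()
    w = joined["copy_number"].to_numpy()
    summary = pd.DataFrame(
        [
            {
                "n_proteins": len(joined),
                "median_half_life_h": float(np.median(hl)),
                "weighted_median_half_life_h": ab.weighted_median(hl, w),
                "mean_half_life_h": float(np.mean(hl)),
                "weighted_mean_half_life_h": ab.weighted_mean(hl, w),
                "n50": cum.n50,
                "n90": cum.n90,
            }
        ]
    )
    cn = quant.reset_index()[["protein_id", "copy_number"]].copy()
    cn["copy_number"] = cn["copy_number"].map("{:.6e}".format)
    write_table(cn, out / "copy_numbers.tsv")
    write_table(cum.ranked, out / "cumulative_abundance.tsv")
    write_table(summary, out / "turnover_summary.tsv")


def stage_diff_abundance(bundle: str | Path, rc: RunConfig) -> None:
    out = Path(bundle)
    tc = read_table(out / "timecourse.tsv")
    res = de.shrink_var_ttest(tc)
    labelled, counts = de.classify_de(res.table, rc.fold_cutoff, rc.p_cutoff)
    write_table(labelled, out / "diff_abundance.tsv")
    write_table(counts, out / "de_counts.tsv")


def stage_diff_halflife(bundle: str | Path, rc: RunConfig) -> None:
    out = Path(bundle)
    basal = read_table(out / "fits_CTRL.tsv")
    transformed = read_table(out / "fits_4OHT.tsv")
    paired = tv.filter_paired_fits(
        basal, transformed, rc.tau_filter_max_h, rc.tau_error_max_h
    )
    result = de.delta_halflife_ztest(paired, rc.delta_halflife_alpha)
    write_table(result, out / "diff_halflife.tsv")


def stage_cluster(bundle: str | Path, rc: RunConfig, sim: SimConfig) -> None:
    out = Path(bundle)
    tc = read_table(out / "timecourse.tsv")
    complete = cl.select_complete(tc, sim.timepoints, sim.n_replicates)
    k = min(rc.kmeans_k, max(2, len(complete) // 5))
    km = cl.kmeans_profiles(complete, k=k, seed=rc.seed, n_init=rc.kmeans_n_init)
    classes = cl.assign_classes(
        km, rc.agglomerate_fold, rc.early_max_h, rc.ud_reversal_frac
    )
    write_table(classes.reset_index(), out / "clusters.tsv")
    write_table(km.cluster_means.reset_index(), out / "cluster_means.tsv")
    write_table(complete.reset_index(), out / "complete_profiles.tsv")


def stage_enrich(bundle: str | Path, rc: RunConfig) -> None:
    out = Path(bundle)
    fits = read_table(out / "fits_CTRL.tsv").set_index("protein_id")
    hl = fits.loc[~fits["degenerate"].astype(bool), "half_life"]
    terms = read_two_column_map(out / "annotation.tsv", "term", "protein_id")
    bins, bounds = en.decile_bins(hl, rc.n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enr = en.bin_term_enrichment(bins, terms, fdr=rc.enrichment_fdr)
    ps = en.pscore(terms, hl, n_perm=rc.pscore_n_perm, seed=rc.seed,
                   min_size=rc.pscore_min_term_size)
    write_table(bins.rename("bin").reset_index(), out / "halflife_bins.tsv")
    write_table(bounds, out / "bin_boundaries.tsv")
    write_table(enr, out / "bin_enrichment.tsv")
    write_table(ps.table, out / "pscore.tsv")


def stage_complexes(bundle: str | Path, rc: RunConfig) -> None:
    out = Path(bundle)
    fits = read_table(out / "fits_CTRL.tsv").set_index("protein_id")
    hl = fits.loc[~fits["degenerate"].astype(bool), "half_life"]
    catalog = read_table(out / "complexes.tsv")
    cmp_res = cx.compare_target_decoys(
        catalog, hl, n_iter=rc.complex_n_iter, seed=rc.seed,
        min_testable=rc.complex_min_testable,
    )
    write_table(cmp_res.target_sds.reset_index(), out / "complex_sds.tsv")
    write_table(
        pd.DataFrame({"decoy_median_sd": cmp_res.decoy_median_sds}),
        out / "decoy_median_sds.tsv",
    )
    write_table(
        pd.DataFrame(
            [{"target_median_sd": cmp_res.target_median_sd,
              "empirical_p": cmp_res.empirical_p, "n_iter": cmp_res.n_iter}]
        ),
        out / "complex_summary.tsv",
    )


def stage_signature(bundle: str | Path, rc: RunConfig, sim: SimConfig) -> None:
    out = Path(bundle)
    complete = read_table(out / "complete_profiles.tsv").set_index("protein_id")
    sig = sg.build_signature(complete, rc.signature_fold_cutoff)
    expr, surv = syn.gen_cohort(
        sim.n_patients, sig, sim.cohort_effect_size, sim.censor_rate,
        seed=sim.seed + 1003,
    )
    write_table(expr.reset_index(), out / "expression.tsv")
    write_table(surv, out / "survival.tsv")
    _signature_outputs(out, sig, expr, surv, rc)


def _signature_outputs(out: Path, sig, expr, surv, rc: RunConfig) -> None:
    scores = sg.score_patients(expr, sig)
    cohorts = sg.stratify(scores, rc.quantile)
    surv_i = surv.set_index("patient_id").loc[scores.index]
    km_tables, medians = {}, {}
    for name in ("top", "bottom"):
        mask = (cohorts == name).to_numpy()
        km = sg.km_estimate(surv_i["time_years"].to_numpy()[mask],
                            surv_i["event"].to_numpy()[mask])
        km_tables[name] = km.table
        medians[name] = km.median
    stat, p = sg.logrank(
        surv_i["time_years"][(cohorts == "top").to_numpy()],
        surv_i["event"][(cohorts == "top").to_numpy()],
        surv_i["time_years"][(cohorts == "bottom").to_numpy()],
        surv_i["event"][(cohorts == "bottom").to_numpy()],
    )
    fdr = sg.signature_fdr(expr, surv, sig, n_boot=rc.n_boot_signature, seed=rc.seed,
                           quantile=rc.quantile)
    write_table(pd.DataFrame({"gene": sig.genes, "weight": sig.weights}),
                out / "signature.tsv")
    write_table(
        pd.DataFrame({"patient_id": scores.index, "score": scores.to_numpy(),
                      "cohort": cohorts.to_numpy()}),
        out / "patient_scores.tsv",
    )
    write_table(km_tables["top"], out / "km_top.tsv")
    write_table(km_tables["bottom"], out / "km_bottom.tsv")
    write_table(
        pd.DataFrame(
            [{
                "n_signature": len(sig),
                "median_survival_top": medians["top"],
                "median_survival_bottom": medians["bottom"],
                "median_ratio": fdr.target_ratio,
                "logrank_chi2": stat,
                "logrank_p": p,
                "fdr": fdr.fdr,
                "fdr_label": fdr.label,
                "n_decoys_beat": fdr.n_beat,
                "n_decoys_excluded": fdr.n_excluded,
            }]
        ),
        out / "survival_summary.tsv",
    )


STAGES = (
    "simulate", "fit-turnover", "copy-number", "diff-abundance",
    "diff-halflife", "cluster", "enrich", "complexes", "signature",
)


def run_pipeline(sim: SimConfig, rc: RunConfig, outdir: str | Path) -> Path:
    """Run every stage on a fresh synthetic bundle; returns the bundle path.

    Writes ``manifest.json`` recording versions, configs and stage outputs.
    Raises :class:`StageError` naming the first failing stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    steps = [
        ("simulate", lambda: stage_simulate(sim, out)),
        ("fit-turnover", lambda: stage_fit_turnover(out, rc)),
        ("copy-number", lambda: stage_copy_number(out, rc)),
        ("diff-abundance", lambda: stage_diff_abundance(out, rc)),
        ("diff-halflife", lambda: stage_diff_halflife(out, rc)),
        ("cluster", lambda: stage_cluster(out, rc, sim)),
        ("enrich", lambda: stage_enrich(out, rc)),
        ("complexes", lambda: stage_complexes(out, rc)),
        ("signature", lambda: stage_signature(out, rc, sim)),
    ]
    completed = []
    for name, fn in steps:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fn()
        except Exception as exc:  # noqa: BLE001 - stage name must reach the log
            raise StageError(name, exc) from exc
        completed.append(name)
    manifest = {
        "turnoverkit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "sim_config": _plain(asdict(sim)),
        "run_config": _plain(asdict(rc)),
        "stages": completed,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    dump_config(sim, out / "sim_config.yaml")
    dump_config(rc, out / "run_config.yaml")
    return out


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    return obj
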