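"""Differential abundance and differential half-life testing.

Abundance: a one-sample moderated t-test of the per-replicate log2
(transformed/control) ratios against zero, per protein per time point. The
per-protein sample variances are shrunk toward a common target with an
analytic optimal shrinkage intensity:

    lambda* = clip( sum_k Var^(v_k) / sum_k (v_k - v_target)^2 , 0, 1 )
    v*_k    = lambda* * v_target + (1 - lambda*) * v_k

where ``Var^(v_k) = 2 v_k^2/(n+1)`` is the normal-theory unbiased estimate
of the sampling variance of each protein's variance (the distribution-free
plug-in is badly biased low at triplicate scale and would under-shrink).
The target is the median raw variance rescaled by (n-1)/median(chi2_{n-1}),
which makes it unbiased on the variance scale under normal sampling; the
reference distribution for p-values is Student t with an effective
``df = (n-1)/(1-lambda*)``, which reduces to the classical t_{n-1} when no
shrinkage is applied and to the normal as lambda* -> 1. Proteins whose
abundance changes at least ``fold_cutoff``-fold with p below ``p_cutoff``
are classified up/down.

Half-life: for proteins passing the paired-fit filters, the change
``delta = t1/2(transformed) - t1/2(control)`` is standardised by the
propagated fit errors, ``z = delta / sqrt(sigma_ctrl^2 + sigma_oht^2)``, with
a two-sided normal p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ShrinkTTestResult:
    table: pd.DataFrame  # protein_id, time_h, mean_log2, var_raw, var_shrunk, t, p, q
    shrinkage: dict[float, float]  # time point -> lambda*


def _moderated_onesample(x: np.ndarray, force_lambda: float | None = None):
    """Vectorised moderated one-sample t vs 0 on an (n_items, n_rep) array."""
    n_items, n = x.shape
    if n < 2:
        raise ValueError("need >= 2 replicates")
    mean = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)

    if force_lambda is None:
        # unbiased-scale median target under chi-square sampling
        target = np.median(v) * (n - 1) / stats.chi2.median(n - 1)
        # normal-theory unbiased estimate of Var(s^2): 2*s^4/(n+1)
        var_of_v = 2.0 * v**2 / (n + 1)
        denom = ((v - target) ** 2).sum()
        lam = 1.0 if denom == 0 else float(np.clip(var_of_v.sum() / denom, 0.0, 1.0))
    else:
        target = np.median(v)
        lam = float(np.clip(force_lambda, 0.0, 1.0))

    v_shrunk = lam * target + (1.0 - lam) * v
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(v_shrunk / n)
        t = np.where(v_shrunk == 0,
                     np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)

    if lam >= 1.0 - 1e-12:
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        df_eff = (n - 1) / (1.0 - lam)
        p = 2.0 * stats.t.sf(np.abs(t), df=df_eff)
    p = np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0)
    return mean, v, v_shrunk, t, p, lam


def shrink_var_ttest(
    ratios: pd.DataFrame, force_lambda: float | None = None
) -> ShrinkTTestResult:
    """Moderated one-sample t-test per protein per time point.

    ``ratios`` is a long table (protein_id, time_h, replicate, log2_ratio);
    shrinkage is estimated across proteins within each time point. Proteins
    with a single replicate at a time point are skipped with a warning.
    ``force_lambda`` pins the shrinkage intensity (0 gives the classical t).
    Benjamini-Hochberg q-values are appended per time point.
    """
    rows = []
    shrinkage: dict[float, float] = {}
    for tp, grp in ratios.groupby("time_h", sort=True):
        wide = grp.pivot_table(
            index="protein_id", columns="replicate", values="log2_ratio", aggfunc="mean"
        )
        complete = wide.dropna()
        n_skipped = len(wide) - len(complete)
        singles = (wide.notna().sum(axis=1) < 2).sum()
        if singles:
            warnings.warn(
                f"time {tp}: {int(singles)} protein(s) with <2 replicates skipped",
                stacklevel=2,
            )
        complete = wide.dropna()
        if complete.empty:
            continue
        mean, v, vs, t, p, lam = _moderated_onesample(
            complete.to_numpy(float), force_lambda
        )
        shrinkage[float(tp)] = lam
        q = multipletests(p, method="fdr_bh")[1]
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": complete.index,
                    "time_h": float(tp),
                    "mean_log2": mean,
                    "var_raw": v,
                    "var_shrunk": vs,
                    "t": t,
                    "p": p,
                    "q": q,
                }
            )
        )
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["protein_id", "time_h", "mean_log2", "var_raw", "var_shrunk", "t", "p", "q"]
        )
    )
    return ShrinkTTestResult(table=table, shrinkage=shrinkage)


def classify_de(
    results: pd.DataFrame, fold_cutoff: float = 2.0, p_cutoff: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label proteins up/down/nc at each time point.

    ``up`` requires mean log2 ratio >= log2(fold_cutoff) and p < p_cutoff;
    ``down`` is symmetric. Returns the labelled table and per-time-point
    counts of each class.
    """
    if fold_cutoff <= 0 or p_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    out = results.copy()
    thr = np.log2(fold_cutoff)
    sig = out["p"] < p_cutoff
    out["de_class"] = np.select(
        [sig & (out["mean_log2"] >= thr), sig & (out["mean_log2"] <= -thr)],
        ["up", "down"],
        default="nc",
    )
    counts = (
        out.groupby(["time_h", "de_class"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down", "nc"], fill_value=0)
        .reset_index()
    )
    return out, counts


def delta_halflife_ztest(
    paired: pd.DataFrame, alpha: float = 0.01, sigma_source: str = "fit"
) -> pd.DataFrame:
    """z-test on the half-life change between conditions.

    ``paired`` is the output of the paired-fit filter (columns
    half_life_ctrl/_oht, sigma_tau_ctrl/_oht, delta_half_life).
    ``sigma_source`` selects the half-life error: "fit" propagates the fit
    covariance tau error (sigma_t1/2 = sigma_tau * ln 2); "replicate" uses the
    replicate-spread tau error instead. Proteins with zero combined error are
    skipped with a warning. The ``significant`` flag applies the two-sided
    ``alpha``; ``direction`` records shorter/longer-lived after activation.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    col = {"fit": "sigma_tau", "replicate": "sigma_tau_rep"}.get(sigma_source)
    if col is None:
        raise ValueError("sigma_source must be 'fit' or 'replicate'")
    ln2 = np.log(2.0)
    s_ctrl = paired[f"{col}_ctrl"].to_numpy(float) * ln2
    s_oht = paired[f"{col}_oht"].to_numpy(float) * ln2
    combined = np.sqrt(s_ctrl**2 + s_oht**2)
    keep = np.isfinite(combined) & (combined > 0)
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} protein(s) with zero/undefined combined "
                      "sigma skipped", stacklevel=2)
    out = paired.loc[keep, ["protein_id", "half_life_ctrl", "half_life_oht",
                            "delta_half_life"]].copy()
    out["sigma_ctrl"] = s_ctrl[keep]
    out["sigma_oht"] = s_oht[keep]
    delta = out["delta_half_life"].to_numpy(float)
    z = delta / np.sqrt(out["sigma_ctrl"] ** 2 + out["sigma_oht"] ** 2)
    out["z"] = z
    out["p"] = np.where(delta == 0, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out["significant"] = out["p"] < alpha
    out["direction"] = np.select(
        [out["delta_half_life"] < 0, out["delta_half_life"] > 0],
        ["shorter-lived", "longer-lived"],
        default="unchanged",
    )
    return out.reset_index(drop=True)
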