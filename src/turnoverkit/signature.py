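"""Signed response signature, patient scoring, and survival stratification.

The transformation response defines a signed signature: every protein with a
complete temporal profile whose abundance changes at least 2-fold gets a
coefficient of +1 (up-regulated) or -1 (down-regulated) from the direction of
its extreme change. A patient's score is the dot product of that coefficient
vector with their per-gene z-scored expression; cohorts are the top and
bottom 20% score quantiles, compared by Kaplan-Meier estimators and the
log-rank test. Significance of the survival separation is assessed against
random signed signatures of the same length and coefficient balance: the
empirical FDR is the fraction of decoys whose top/bottom median-survival
ratio is at most the target's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class SignedSignature:
    """Gene list with +/-1 coefficients (direction of the response)."""

    genes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if not np.all(np.isin(self.weights, (-1.0, 1.0))):
            raise ValueError("weights must be +1 or -1")

    def __len__(self) -> int:
        return len(self.genes)


def build_signature(
    profiles: pd.DataFrame, fold_cutoff: float = 2.0
) -> SignedSignature:
    """Signature from complete replicate-averaged log2 profiles.

    Genes whose maximum absolute fold change reaches ``fold_cutoff`` enter
    the signature with the sign of their extreme change.
    """
    x = profiles.to_numpy(float)
    peak_idx = np.argmax(np.abs(x), axis=1)
    peak = x[np.arange(len(x)), peak_idx]
    keep = 2.0 ** np.abs(peak) >= fold_cutoff
    if not keep.any():
        raise ValueError("empty signature: no gene meets the fold-change cutoff")
    genes = list(profiles.index[keep])
    weights = np.sign(peak[keep])
    return SignedSignature(genes=genes, weights=weights)


def score_patients(
    expression: pd.DataFrame,
    signature: SignedSignature,
    normalize: str = "zscore",
    max_missing_frac: float = 0.2,
) -> pd.Series:
    """Signed-signature score per patient.

    ``expression`` is genes x patients. Each signature gene is z-scored
    across patients (``normalize='none'`` uses values as supplied) and the
    score is the coefficient-weighted sum. Signature genes absent from the
    matrix are dropped with a warning; more than ``max_missing_frac`` missing
    is an error.
    """
    if normalize not in ("zscore", "none"):
        raise ValueError("normalize must be 'zscore' or 'none'")
    present = [g in expression.index for g in signature.genes]
    n_missing = len(signature) - sum(present)
    if n_missing > max_missing_frac * len(signature):
        raise ValueError(
            f"{n_missing}/{len(signature)} signature genes missing from expression"
        )
    if n_missing:
        warnings.warn(f"{n_missing} signature gene(s) missing; dropped", stacklevel=2)
    genes = [g for g, ok in zip(signature.genes, present) if ok]
    w = signature.weights[np.asarray(present)]
    x = expression.loc[genes].to_numpy(float)
    if normalize == "zscore":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    return pd.Series(w @ x, index=expression.columns, name="score")


def stratify(scores: pd.Series, quantile: float = 0.20) -> pd.Series:
    """Label patients top / bottom / middle by score quantile.

    Top is score >= the (1-quantile) percentile, bottom is score <= the
    quantile percentile. If every score is identical the split degenerates;
    a warning is issued and the tie is broken by stable patient order.
    """
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    if len(scores) < 10:
        raise ValueError("need >= 10 patients to stratify")
    s = scores.to_numpy(float)
    lo, hi = np.quantile(s, [quantile, 1.0 - quantile])
    if lo == hi:
        warnings.warn("degenerate scores: quantile split by stable patient order",
                      stacklevel=2)
        n_q = int(np.floor(quantile * len(s)))
        labels = np.array(["middle"] * len(s), dtype=object)
        labels[:n_q] = "bottom"
        labels[len(s) - n_q :] = "top"
        return pd.Series(labels, index=scores.index, name="cohort")
    labels = np.where(s >= hi, "top", np.where(s <= lo, "bottom", "middle"))
    return pd.Series(labels, index=scores.index, name="cohort")


@dataclass
class KMResult:
    table: pd.DataFrame  # time, survival
    median: float  # earliest time with S(t) <= 0.5; nan if never reached


def km_estimate(times, events) -> KMResult:
    """Product-limit (Kaplan-Meier) survival curve and median survival."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty cohort")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame({"time": surv.index.to_numpy(), "survival": surv.to_numpy()})
    below = table[table["survival"] <= 0.5]
    median = float(below["time"].iloc[0]) if len(below) else float("nan")
    return KMResult(table=table, median=median)


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-squared statistic, p)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both cohorts must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SignatureFDR:
    fdr: float
    label: str  # e.g. "< 0.001" when no decoy beats the target
    target_ratio: float
    n_beat: int
    n_excluded: int
    n_boot: int
    decoy_ratios: np.ndarray


def _cohort_median_ratio(
    scores: pd.Series, survival: pd.DataFrame, quantile: float
) -> float:
    cohorts = stratify(scores, quantile)
    surv = survival.set_index("patient_id").loc[scores.index]
    ratios = {}
    for name in ("top", "bottom"):
        mask = (cohorts == name).to_numpy()
        km = km_estimate(surv["time_years"].to_numpy()[mask],
                         surv["event"].to_numpy()[mask])
        ratios[name] = km.median
    return ratios["top"] / ratios["bottom"]


def signature_fdr(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    signature: SignedSignature,
    n_boot: int = 1000,
    seed: int = 0,
    quantile: float = 0.20,
    normalize: str = "zscore",
) -> SignatureFDR:
    """Empirical FDR of the signature's survival separation.

    Each bootstrap draws a random gene set of the same length from the
    expression matrix, assigns it the target's coefficient multiset in random
    order, and recomputes the top/bottom median-survival ratio. The FDR is
    ``#{decoy ratio <= target ratio} / n_boot``; iterations whose cohorts
    never reach 50% survival have no median and are excluded (counted in
    ``n_excluded``). Reported as "< 1/n_boot" when no decoy beats the target.
    """
    n_non_sig = len(set(expression.index) - set(signature.genes))
    if n_non_sig < len(signature):
        raise ValueError("expression must contain >= |signature| non-signature genes")
    target_ratio = _cohort_median_ratio(
        score_patients(expression, signature, normalize), survival, quantile
    )
    if not np.isfinite(target_ratio):
        raise ValueError("target median-survival ratio is not determined")

    rng = np.random.default_rng(seed)
    genes_all = np.asarray(expression.index)
    ratios = np.full(n_boot, np.nan)
    for i in range(n_boot):
        decoy_genes = rng.choice(genes_all, size=len(signature), replace=False)
        decoy_w = rng.permutation(signature.weights)
        decoy = SignedSignature(genes=list(decoy_genes), weights=decoy_w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratios[i] = _cohort_median_ratio(
                score_patients(expression, decoy, normalize), survival, quantile
            )
    determined = np.isfinite(ratios)
    n_excluded = int((~determined).sum())
    n_beat = int(np.sum(ratios[determined] <= target_ratio))
    fdr = n_beat / n_boot
    label = f"< {1.0 / n_boot:g}" if n_beat == 0 else f"{fdr:g}"
    return SignatureFDR(
        fdr=fdr, label=label, target_ratio=float(target_ratio), n_beat=n_beat,
        n_excluded=n_excluded, n_boot=n_boot, decoy_ratios=ratios,
    )
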