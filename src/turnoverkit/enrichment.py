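"""Half-life decile binning, per-bin term enrichment, and the permutation
Pscore for short-/long-lived functional classes.

Deciles are equal-count bins of the half-life order (ties resolved by protein
id). Per-bin enrichment is a hypergeometric upper-tail test of each
annotation term against the measured background with Benjamini-Hochberg FDR.

The Pscore compares a term's mean half-life with the means of random
same-size protein sets drawn without replacement from the background: it is
the fraction of permutation means below the observed mean, with permutation
means equal to it (within floating tolerance) counted half — the midpoint
rule keeps the score symmetric, so a term coextensive with the background
scores exactly 0.5 and negating the half-life ranks maps a score to its
complement. Terms with Pscore < 0.001 are called short-lived and > 0.999
long-lived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

SHORT_THRESHOLD = 0.001
LONG_THRESHOLD = 0.999


def decile_bins(half_lives: pd.Series, n_bins: int = 10) -> tuple[pd.Series, pd.DataFrame]:
    """Equal-count bins of the half-life distribution.

    Returns a per-protein bin id (1 = shortest-lived decile) and a table of
    bin boundaries (min/max half-life and count per bin). Bin counts differ
    by at most one; ties across a boundary are resolved by protein id.
    """
    if len(half_lives) < n_bins:
        raise ValueError(f"need >= {n_bins} proteins for {n_bins} bins")
    df = half_lives.rename("half_life").rename_axis("protein_id").reset_index()
    df = df.sort_values(["half_life", "protein_id"], kind="stable").reset_index(drop=True)
    base, extra = divmod(len(df), n_bins)
    sizes = [base + (1 if i < extra else 0) for i in range(n_bins)]
    ids = np.repeat(np.arange(1, n_bins + 1), sizes)
    df["bin"] = ids
    bounds = (
        df.groupby("bin")["half_life"].agg(["min", "max", "count"]).reset_index()
    )
    assignment = df.set_index("protein_id")["bin"].loc[half_lives.index]
    return assignment, bounds


def bin_term_enrichment(
    bins: pd.Series,
    annotation: dict[str, set[str]],
    background: set[str] | None = None,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each term in each half-life bin.

    ``bins`` maps protein id -> bin id; the background defaults to all binned
    proteins. Terms with no member in the background are skipped with a
    warning. Returns one row per (bin, term) with the upper-tail p, BH
    q-value (across all tests) and a significance flag at ``fdr``.
    """
    bg = set(bins.index) if background is None else set(background)
    if not set(bins.index) <= bg:
        raise ValueError("background must contain every binned protein")
    n_bg = len(bg)
    rows = []
    for term, members in annotation.items():
        members_bg = members & bg
        if not members_bg:
            warnings.warn(f"term {term} absent from background; skipped", stacklevel=2)
            continue
        for bin_id, bin_proteins in bins.groupby(bins):
            bin_set = set(bin_proteins.index)
            k = len(members_bg & bin_set)
            p = float(hypergeom.sf(k - 1, n_bg, len(members_bg), len(bin_set)))
            rows.append(
                {"bin": bin_id, "term": term, "n_term": len(members_bg),
                 "n_bin": len(bin_set), "overlap": k, "p": p}
            )
    out = pd.DataFrame(rows, columns=["bin", "term", "n_term", "n_bin", "overlap", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] <= fdr
    else:
        out["q"] = []
        out["significant"] = []
    return out


@dataclass
class PscoreResult:
    table: pd.DataFrame  # term, n, mean_half_life, pscore, call
    n_perm: int


def _perm_means(
    hl: np.ndarray, size: int, n_perm: int, rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Means of ``n_perm`` random size-``size`` subsets drawn without
    replacement (random-key top-k selection, chunked to bound memory)."""
    n = len(hl)
    out = np.empty(n_perm)
    pos = 0
    while pos < n_perm:
        m = min(chunk, n_perm - pos)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        out[pos : pos + m] = hl[idx].mean(axis=1)
        pos += m
    return out


def pscore(
    annotation: dict[str, set[str]],
    half_lives: pd.Series,
    n_perm: int = 10000,
    seed: int = 0,
    min_size: int = 5,
) -> PscoreResult:
    """Permutation percentile of each term's mean half-life.

    The background is every protein with a measured half-life. Terms smaller
    than ``min_size`` (after intersection with the background) are reported
    as ``ns`` with a flag. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    hl = half_lives.to_numpy(float)
    index = {pid: i for i, pid in enumerate(half_lives.index)}
    rows = []
    for term in sorted(annotation):
        members = [index[p] for p in annotation[term] if p in index]
        n = len(members)
        if n < min_size:
            rows.append(
                {"term": term, "n": n, "mean_half_life": np.nan, "pscore": np.nan,
                 "call": "ns", "too_small": True}
            )
            continue
        obs = hl[members].mean()
        null = _perm_means(hl, n, n_perm, rng)
        tol = 1e-9 * max(abs(obs), 1.0)
        n_less = np.sum(null < obs - tol)
        n_tied = np.sum(np.abs(null - obs) <= tol)
        score = float((n_less + 0.5 * n_tied) / n_perm)
        call = "short-lived" if score < SHORT_THRESHOLD else (
            "long-lived" if score > LONG_THRESHOLD else "ns"
        )
        rows.append(
            {"term": term, "n": n, "mean_half_life": float(obs), "pscore": score,
             "call": call, "too_small": False}
        )
    table = pd.DataFrame(
        rows, columns=["term", "n", "mean_half_life", "pscore", "call", "too_small"]
    )
    return PscoreResult(table=table, n_perm=n_perm)
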