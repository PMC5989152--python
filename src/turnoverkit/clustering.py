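"""Response-kinetics clustering of temporal expression profiles.

Complete profiles (all replicates at all time points) are grouped by k-means
(Euclidean distance on replicate-averaged log2 profiles, k=30 by default,
chosen where the within-group sum of squares becomes asymptotic), and cluster
mean profiles are then agglomerated into six kinetic classes by explicit
rules:

* NC  — maximum absolute fold change below the 3-fold threshold;
* UD  — an up response that reverses by at least 25% of its peak;
* EU / ED — half-maximal change reached at or before 12 h (up / down);
* MU / MD — half-maximal change reached after 12 h (up / down).

The agglomeration rules replace an unrecorded manual grouping step, so the
boundaries (3-fold, 12 h, 25% reversal) are explicit and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

KINETIC_CLASSES = ("EU", "MU", "ED", "MD", "UD", "NC")


def select_complete(
    timecourse: pd.DataFrame,
    timepoints,
    n_replicates: int,
) -> pd.DataFrame:
    """Keep proteins observed in every replicate at every time point.

    Input is the long time-course table (protein_id, replicate, time_h,
    log2_ratio); returns a wide replicate-averaged matrix (proteins x time
    points) restricted to complete profiles.
    """
    tps = [float(t) for t in timepoints]
    expected = len(tps) * n_replicates
    cells = timecourse.groupby(["protein_id", "time_h", "replicate"]).size()
    per_protein = cells.groupby("protein_id").size()
    complete_ids = per_protein.index[per_protein == expected]
    sub = timecourse[timecourse["protein_id"].isin(complete_ids)]
    wide = (
        sub.groupby(["protein_id", "time_h"])["log2_ratio"].mean().unstack()
    )
    return wide.reindex(columns=tps)


@dataclass
class KMeansResult:
    assignments: pd.Series  # protein_id -> cluster id (0..k-1)
    cluster_means: pd.DataFrame  # cluster x time point
    inertia: float
    wss_sweep: dict[int, float] = field(default_factory=dict)


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int = 30,
    seed: int = 0,
    n_init: int = 50,
    sweep_k: list[int] | None = None,
) -> KMeansResult:
    """k-means on complete log2 profiles; deterministic given the seed.

    Profiles are clustered unstandardised (all columns share log2 units).
    ``sweep_k`` optionally reports the within-group sum of squares over
    candidate k for elbow inspection.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(profiles) < k:
        raise ValueError(f"need >= {k} profiles, got {len(profiles)}")
    x = profiles.to_numpy(float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    assignments = pd.Series(km.labels_, index=profiles.index, name="cluster")
    means = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
    means.index.name = "cluster"
    sweep = {}
    if sweep_k:
        for kk in sweep_k:
            if 1 <= kk <= len(profiles):
                sweep[kk] = float(
                    KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
                    .fit(x)
                    .inertia_
                )
    return KMeansResult(
        assignments=assignments, cluster_means=means, inertia=float(km.inertia_),
        wss_sweep=sweep,
    )


def _half_crossing_time(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """First time |y| crosses `level`, linearly interpolated; inf if never."""
    a = np.abs(y)
    for i in range(len(t)):
        if a[i] >= level:
            if i == 0 or a[i] == a[i - 1]:
                return float(t[i])
            frac = (level - a[i - 1]) / (a[i] - a[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return float("inf")


def classify_mean_profile(
    times,
    profile,
    threshold_fold: float = 3.0,
    early_max_h: float = 12.0,
    ud_reversal_frac: float = 0.25,
) -> str:
    """Assign one kinetic class to a mean log2 profile (see module rules)."""
    t = np.asarray(times, dtype=float)
    m = np.asarray(profile, dtype=float)
    if m.size == 0:
        raise ValueError("empty cluster mean profile")
    peak_idx = int(np.argmax(np.abs(m)))
    peak = m[peak_idx]
    if 2.0 ** abs(peak) < threshold_fold:
        return "NC"
    if peak > 0:
        reversal = peak - m[peak_idx:].min()
        if reversal >= ud_reversal_frac * peak:
            return "UD"
    t_half = _half_crossing_time(t, m, abs(peak) / 2.0)
    early = t_half <= early_max_h
    if peak > 0:
        return "EU" if early else "MU"
    return "ED" if early else "MD"


def agglomerate_clusters(
    cluster_means: pd.DataFrame,
    threshold_fold: float = 3.0,
    early_max_h: float = 12.0,
    ud_reversal_frac: float = 0.25,
) -> pd.Series:
    """Class label per cluster from its mean profile."""
    times = [float(c) for c in cluster_means.columns]
    labels = {
        c: classify_mean_profile(
            times, cluster_means.loc[c], threshold_fold, early_max_h, ud_reversal_frac
        )
        for c in cluster_means.index
    }
    return pd.Series(labels, name="kinetic_class").rename_axis("cluster")


def assign_classes(
    km: KMeansResult,
    threshold_fold: float = 3.0,
    early_max_h: float = 12.0,
    ud_reversal_frac: float = 0.25,
) -> pd.DataFrame:
    """Protein-level table: cluster id and agglomerated kinetic class."""
    cluster_class = agglomerate_clusters(
        km.cluster_means, threshold_fold, early_max_h, ud_reversal_frac
    )
    out = km.assignments.to_frame()
    out["kinetic_class"] = cluster_class.loc[out["cluster"]].to_numpy()
    return out
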