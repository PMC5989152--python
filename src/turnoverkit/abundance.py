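"""Proteome-ruler copy numbers and abundance-weighted turnover statistics.

The proteome ruler anchors MS intensities to the summed histone intensity:
histone protein mass per cell tracks DNA mass (~6.5 pg for a diploid human
cell), so ``mass_i = I_i * dna_mass / sum(histone I)`` and
``copies_i = mass_i * N_A / MW_i``. Abundance weighting then re-expresses
proteome turnover per molecule rather than per gene: the weighted median
half-life is the half-life at which the cumulative copy number (proteins
sorted by half-life) reaches 50% of total copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro


def proteome_ruler(quant: pd.DataFrame, dna_mass_pg: float = 6.5) -> pd.Series:
    """Copies per cell from intensities, molecular weights and histone flags.

    ``quant`` needs columns intensity, mw_da, is_histone. Scale-invariant in
    the intensities and linear in ``dna_mass_pg``.
    """
    if dna_mass_pg <= 0:
        raise ValueError("dna_mass_pg must be positive")
    hist = quant.loc[quant["is_histone"].astype(bool), "intensity"]
    if hist.empty or hist.sum() <= 0:
        raise ValueError("proteome ruler needs >= 1 histone with positive intensity")
    mass_g = quant["intensity"] * (dna_mass_pg * 1e-12) / hist.sum()
    copies = mass_g * Avogadro / quant["mw_da"]
    return copies.rename("copy_number")


@dataclass
class CumulativeAbundance:
    """Ranked cumulative-abundance curve and the counts reaching 50%/90%."""

    ranked: pd.DataFrame  # protein_id, copy_number, rank, cumulative_fraction
    n50: int
    n90: int


def cumulative_abundance(copy_numbers: pd.Series) -> CumulativeAbundance:
    """Sort proteins by abundance and report the cumulative-fraction curve.

    ``n50``/``n90`` are the smallest numbers of top-ranked proteins whose
    summed abundance reaches 50% / 90% of the total.
    """
    if copy_numbers.empty:
        raise ValueError("empty abundance table")
    total = float(copy_numbers.sum())
    if total <= 0:
        raise ValueError("cumulative abundance undefined for all-zero abundances")
    ranked = copy_numbers.sort_values(ascending=False, kind="stable")
    frac = ranked.cumsum() / total
    out = pd.DataFrame(
        {
            "protein_id": ranked.index,
            "copy_number": ranked.to_numpy(),
            "rank": np.arange(1, len(ranked) + 1),
            "cumulative_fraction": frac.to_numpy(),
        }
    )
    n50 = int(np.searchsorted(out["cumulative_fraction"].to_numpy(), 0.5) + 1)
    n90 = int(np.searchsorted(out["cumulative_fraction"].to_numpy(), 0.9) + 1)
    return CumulativeAbundance(ranked=out, n50=n50, n90=n90)


def weighted_median(values, weights) -> float:
    """Abundance-weighted median: sort by value ascending and return the
    first value at which the cumulative weight reaches half the total.

    No interpolation — the boundary rule is taken literally, so with uniform
    weights this matches the lower-middle convention for even counts.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_median of empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(v[order][idx])


def weighted_mean(values, weights) -> float:
    """Abundance-weighted mean sum(w*v)/sum(w)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_mean of empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return float(np.sum(w * v) / total)
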