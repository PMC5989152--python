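"""Configuration objects for the simulator and the analysis pipeline.

Two dataclasses carry every tunable: :class:`SimConfig` for the synthetic-data
generator and :class:`RunConfig` for the analysis stages. Both validate their
fields eagerly so a bad threshold fails before any stage runs, and both can be
loaded from a YAML mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

DEFAULT_TIMEPOINTS_H: tuple[float, ...] = (1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0)

CONDITIONS = ("CTRL", "4OHT")


class ConfigError(ValueError):
    """A configuration field is outside its documented legal range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    The defaults encode the study design being emulated: a 7-point pulse
    time course (1, 3, 6, 12, 24, 48, 72 h) in biological triplicate, a
    log-normal copy-number distribution spanning ~8 orders of magnitude with
    histones holding ~5% of total abundance, 1-50 peptides per protein, and
    ~3% of proteins responding to kinase activation.
    """

    n_proteins: int = 5000
    histone_fraction: float = 0.05
    n_histones: int = 10
    abundance_sigma: float = 1.15  # log10 SD of copy numbers
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    n_replicates: int = 3
    # peptides per protein: round(10**N(log10(median), sd)) clipped to [1, max]
    peptides_median: float = 5.0
    peptides_log10_sd: float = 0.35
    peptides_max: int = 50
    ratio_noise_sd: float = 0.05  # SD of ln-scale multiplicative ratio noise
    responsive_fraction: float = 0.03
    timecourse_noise_sd: float = 0.25  # log2 replicate noise on expression profiles
    # true turnover kinetics
    tau_median_h: float = 16.0
    tau_log10_sd: float = 0.35
    offset_range: tuple[float, float] = (0.02, 0.15)
    # optional perturbation of the transformed condition's turnover
    tau_shift_fraction: float = 0.0
    tau_shift_factor: float = 0.7
    # planted structure consumed by the downstream stages
    n_complexes: int = 50
    complex_sizes: tuple[int, ...] = (3, 4, 5, 6)
    complex_coherence_h: float = 1.0
    n_terms: int = 100
    term_size_range: tuple[int, int] = (5, 30)
    n_patients: int = 500
    cohort_effect_size: float = 1.0
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_proteins >= 1, "n_proteins must be >= 1")
        _check(0.0 <= self.histone_fraction < 1.0, "histone_fraction must be in [0, 1)")
        _check(self.n_histones >= 1, "n_histones must be >= 1")
        _check(
            self.n_proteins >= self.n_histones,
            f"n_proteins ({self.n_proteins}) < requested histones ({self.n_histones})",
        )
        _check(self.abundance_sigma > 0, "abundance_sigma must be positive")
        tp = tuple(float(t) for t in self.timepoints)
        _check(len(tp) >= 1 and all(t > 0 for t in tp), "timepoints must be positive")
        _check(all(b > a for a, b in zip(tp, tp[1:])), "timepoints must be strictly increasing")
        self.timepoints = tp
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")
        _check(self.peptides_median >= 1, "peptides_median must be >= 1")
        _check(1 <= self.peptides_max, "peptides_max must be >= 1")
        _check(self.ratio_noise_sd >= 0, "ratio_noise_sd must be non-negative")
        _check(0.0 <= self.responsive_fraction <= 1.0, "responsive_fraction must be in [0, 1]")
        _check(self.timecourse_noise_sd >= 0, "timecourse_noise_sd must be non-negative")
        _check(self.tau_median_h > 0, "tau_median_h must be positive")
        lo, hi = self.offset_range
        _check(0 <= lo <= hi, "offset_range must be ordered and non-negative")
        _check(0.0 <= self.tau_shift_fraction <= 1.0, "tau_shift_fraction must be in [0, 1]")
        _check(self.tau_shift_factor > 0, "tau_shift_factor must be positive")
        _check(self.n_complexes >= 0, "n_complexes must be non-negative")
        sizes = tuple(int(s) for s in self.complex_sizes)
        _check(all(s >= 2 for s in sizes), "complex_sizes must all be >= 2")
        self.complex_sizes = sizes
        _check(self.complex_coherence_h >= 0, "complex_coherence_h must be non-negative")
        _check(self.n_terms >= 0, "n_terms must be non-negative")
        lo_t, hi_t = self.term_size_range
        _check(1 <= lo_t <= hi_t, "term_size_range must be ordered and >= 1")
        self.term_size_range = (int(lo_t), int(hi_t))
        _check(self.n_patients >= 10, "n_patients must be >= 10")
        _check(0.0 <= self.censor_rate < 1.0, "censor_rate must be in [0, 1)")


@dataclass
class RunConfig:
    """Thresholds, iteration counts, and seeds for the analysis stages."""

    # turnover fitting
    tau_ceiling_h: float = 300.0
    tau_filter_max_h: float = 72.0
    tau_error_max_h: float = 12.0
    peptide_weighting: str = "intensity"  # intensity | uniform
    peptide_level_fits: bool = True
    # proteome ruler
    dna_mass_pg: float = 6.5
    # differential abundance
    fold_cutoff: float = 2.0
    p_cutoff: float = 0.01
    # differential half-life
    delta_halflife_alpha: float = 0.01
    # clustering
    kmeans_k: int = 30
    kmeans_n_init: int = 50
    agglomerate_fold: float = 3.0
    early_max_h: float = 12.0
    ud_reversal_frac: float = 0.25
    # enrichment
    n_bins: int = 10
    enrichment_fdr: float = 0.01
    pscore_n_perm: int = 10000
    pscore_min_term_size: int = 5
    # complexes
    complex_n_iter: int = 1000
    complex_min_testable: int = 20
    # signature / survival
    signature_fold_cutoff: float = 2.0
    quantile: float = 0.20
    n_boot_signature: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.tau_ceiling_h > 0, "tau_ceiling_h must be positive")
        _check(0 < self.tau_filter_max_h <= self.tau_ceiling_h, "tau_filter_max_h out of range")
        _check(self.tau_error_max_h > 0, "tau_error_max_h must be positive")
        _check(self.peptide_weighting in ("intensity", "uniform"), "peptide_weighting invalid")
        _check(self.dna_mass_pg > 0, "dna_mass_pg must be positive")
        _check(self.fold_cutoff > 0, "fold_cutoff must be positive")
        _check(0 < self.p_cutoff <= 1, "p_cutoff must be in (0, 1]")
        _check(0 < self.delta_halflife_alpha <= 1, "delta_halflife_alpha must be in (0, 1]")
        _check(self.kmeans_k >= 2, "kmeans_k must be >= 2")
        _check(self.kmeans_n_init >= 1, "kmeans_n_init must be >= 1")
        _check(self.agglomerate_fold > 1, "agglomerate_fold must exceed 1")
        _check(self.early_max_h > 0, "early_max_h must be positive")
        _check(0 < self.ud_reversal_frac < 1, "ud_reversal_frac must be in (0, 1)")
        _check(self.n_bins >= 2, "n_bins must be >= 2")
        _check(0 < self.enrichment_fdr <= 1, "enrichment_fdr must be in (0, 1]")
        _check(self.pscore_n_perm >= 1, "pscore_n_perm must be >= 1")
        _check(self.pscore_min_term_size >= 2, "pscore_min_term_size must be >= 2")
        _check(self.complex_n_iter >= 1, "complex_n_iter must be >= 1")
        _check(self.signature_fold_cutoff > 0, "signature_fold_cutoff must be positive")
        _check(0 < self.quantile < 0.5, "quantile must be in (0, 0.5)")
        _check(self.n_boot_signature >= 1, "n_boot_signature must be >= 1")


def _from_mapping(cls, mapping: dict):
    fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(mapping) - fields
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("timepoints", "offset_range", "complex_sizes", "term_size_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: str | Path, cls=RunConfig):
    """Load a SimConfig or RunConfig from a YAML mapping file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a YAML mapping")
    return _from_mapping(cls, data)


def dump_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(asdict(cfg)), fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    return obj
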