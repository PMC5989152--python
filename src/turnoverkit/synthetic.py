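"""Synthetic study generator.

Emulates the data structure of an inducible-kinase transformation study in an
epithelial cell line: a pulse-SILAC turnover experiment (label switch at t=0,
seven chase time points in biological triplicate) and an abundance time course
over the same grid, plus protein complexes with coherent half-lives, functional
annotation terms, and a patient cohort whose survival hazard depends on a
planted signed expression signature.

Every generator is a deterministic function of its parameters and a seed; each
consumes an independent random stream derived from ``SimConfig.seed`` so the
call order of the generators does not change their output.

Forward kinetic model (steady state, single precursor pool): for a protein
with amplitude ``A``, time constant ``tau`` and offset ``C``, the pre-existing
(medium-label) material decays as ``D(t) = C + A*exp(-t/tau)`` while newly
synthesised (heavy-label) material accumulates as the complement
``S(t) = (C + A) - D(t) = A*(1 - exp(-t/tau))``, so the labelled total
``S + D = C + A`` is conserved at every time point; both are ratios to a
spiked-in light reference channel. Amino-acid recycling is absorbed into the
offset ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CONDITIONS, SimConfig

LN2 = float(np.log(2.0))

ARCHETYPES = ("EU", "MU", "ED", "MD", "UD", "NC")
RESPONSIVE_ARCHETYPES = ("EU", "MU", "ED", "MD", "UD")

#: log2 amplitude of the archetype templates (4-fold at the extreme).
TEMPLATE_AMPLITUDE = 2.0

# Piecewise-linear log2 templates, (time h, log2 ratio) breakpoints. Values
# before the first / after the last breakpoint are held constant.
_A = TEMPLATE_AMPLITUDE
_TEMPLATES: dict[str, tuple[tuple[float, float], ...]] = {
    "EU": ((0.0, 0.0), (6.0, _A)),
    "MU": ((6.0, 0.0), (24.0, _A)),
    "ED": ((0.0, 0.0), (6.0, -_A)),
    "MD": ((6.0, 0.0), (24.0, -_A)),
    "UD": ((0.0, 0.0), (8.0, _A), (12.0, _A), (72.0, 0.25 * _A)),
    "NC": ((0.0, 0.0),),
}


def archetype_template(archetype: str, timepoints: Sequence[float]) -> np.ndarray:
    """True log2(4-OHT/CTRL) trajectory of an archetype at the given times."""
    if archetype not in _TEMPLATES:
        raise ValueError(f"unknown archetype label: {archetype!r}")
    pts = _TEMPLATES[archetype]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return np.interp(np.asarray(timepoints, dtype=float), xs, ys)


@dataclass
class Truth:
    """Ground truth behind a simulated study, for recovery tests.

    ``proteins`` holds one row per protein: abundance (copies/cell), molecular
    weight, histone flag, per-condition kinetic parameters, archetype label,
    peptide count and complex membership. ``profiles`` holds the noise-free
    log2 abundance fold change per protein per time point.
    """

    proteins: pd.DataFrame
    profiles: pd.DataFrame  # index protein_id, columns = time points (h)
    timepoints: tuple[float, ...]

    def half_lives(self, condition: str = "CTRL") -> pd.Series:
        tau = self.proteins.set_index("protein_id")[f"tau_{condition}"]
        return (tau * LN2).rename("half_life_h")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def gen_proteome(config: SimConfig) -> tuple[pd.DataFrame, Truth]:
    """Draw a proteome: abundances, molecular weights, kinetics, archetypes.

    Copy numbers are log-normal (log10 SD ``abundance_sigma``); a designated
    histone subset is rescaled so its summed intensity share equals
    ``histone_fraction`` exactly. Intensities follow the proteome-ruler
    proportionality I = copies x MW (arbitrary units). Returns the protein
    quantification table and the ground truth.
    """
    rng = _rng(config, 1)
    n = config.n_proteins
    ids = np.array([f"P{i:05d}" for i in range(n)])

    log10_copies = rng.normal(4.5, config.abundance_sigma, size=n)
    copies = 10.0 ** log10_copies

    is_histone = np.zeros(n, dtype=bool)
    histone_idx = rng.choice(n, size=config.n_histones, replace=False)
    is_histone[histone_idx] = True

    mw = 10.0 ** rng.normal(np.log10(4.0e4), 0.25, size=n)
    mw[is_histone] = 10.0 ** rng.normal(np.log10(1.4e4), 0.05, size=int(is_histone.sum()))

    # rescale histone copies so the histone intensity share is exact
    intensity = copies * mw
    h_sum = intensity[is_histone].sum()
    r_sum = intensity[~is_histone].sum()
    if config.histone_fraction > 0:
        f = config.histone_fraction * r_sum / ((1.0 - config.histone_fraction) * h_sum)
        copies[is_histone] *= f
        intensity = copies * mw

    tau_ctrl = 10.0 ** rng.normal(np.log10(config.tau_median_h), config.tau_log10_sd, size=n)
    tau_ctrl = np.clip(tau_ctrl, 0.5, 300.0)
    c_ctrl = rng.uniform(*config.offset_range, size=n)
    a_ctrl = 1.0 - c_ctrl

    tau_oht = tau_ctrl.copy()
    n_shift = int(round(config.tau_shift_fraction * n))
    if n_shift:
        shift_idx = rng.choice(n, size=n_shift, replace=False)
        tau_oht[shift_idx] = np.clip(tau_oht[shift_idx] * config.tau_shift_factor, 0.5, 300.0)

    archetype = np.array(["NC"] * n, dtype=object)
    n_resp = int(round(config.responsive_fraction * n))
    if n_resp:
        resp_idx = rng.choice(n, size=n_resp, replace=False)
        labels = [RESPONSIVE_ARCHETYPES[i % len(RESPONSIVE_ARCHETYPES)] for i in range(n_resp)]
        archetype[resp_idx] = labels

    n_pep = np.rint(
        10.0 ** rng.normal(np.log10(config.peptides_median), config.peptides_log10_sd, size=n)
    ).astype(int)
    n_pep = np.clip(n_pep, 1, config.peptides_max)

    proteins = pd.DataFrame(
        {
            "protein_id": ids,
            "is_histone": is_histone,
            "copy_number": copies,
            "mw_da": mw,
            "intensity": intensity,
            "tau_CTRL": tau_ctrl,
            "A_CTRL": a_ctrl,
            "C_CTRL": c_ctrl,
            "tau_4OHT": tau_oht,
            "A_4OHT": a_ctrl,
            "C_4OHT": c_ctrl,
            "archetype": archetype,
            "n_peptides": n_pep,
            "complex_id": pd.array([pd.NA] * n, dtype="string"),
        }
    )

    profiles = pd.DataFrame(
        np.vstack([archetype_template(a, config.timepoints) for a in archetype]),
        index=pd.Index(ids, name="protein_id"),
        columns=list(config.timepoints),
    )

    quant = proteins[["protein_id", "intensity", "mw_da", "is_histone"]].copy()
    truth = Truth(proteins=proteins, profiles=profiles, timepoints=config.timepoints)
    return quant, truth


def _kinetic_curves(
    A: np.ndarray, tau: np.ndarray, C: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    decay = np.exp(-t[None, :] / tau[:, None])
    d = C[:, None] + A[:, None] * decay
    s = A[:, None] * (1.0 - decay)
    return d, s


def gen_pulse_silac(
    truth: Truth,
    config: SimConfig,
    condition: str,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Simulate per-peptide pulse-SILAC ratio series for one condition.

    The pre-existing channel (M/L) follows ``D(t)`` and the newly synthesised
    channel (H/L) follows ``S(t) = (C+A) - D(t)``; every measurement is multiplied by
    independent log-normal noise of ln-scale SD ``ratio_noise_sd``. Peptide
    intensities track protein copy number with per-peptide ionisation factors.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    sd = config.ratio_noise_sd if noise_sd is None else float(noise_sd)
    if sd < 0:
        raise ValueError("ratio noise SD must be non-negative")
    rng = _rng(config, 2 if condition == "CTRL" else 3)

    prot = truth.proteins
    t = np.asarray(config.timepoints, dtype=float)
    n_tp, n_rep = len(t), config.n_replicates
    n_pep = prot["n_peptides"].to_numpy()
    total_pep = int(n_pep.sum())

    pep_protein = np.repeat(np.arange(len(prot)), n_pep)
    pep_rank = np.concatenate([np.arange(k) for k in n_pep])
    pep_ids = np.array(
        [f"{prot['protein_id'].iat[p]}_pep{r:02d}" for p, r in zip(pep_protein, pep_rank)]
    )
    pep_intensity = (
        prot["copy_number"].to_numpy()[pep_protein] * rng.lognormal(0.0, 0.5, size=total_pep)
    )

    d, s = _kinetic_curves(
        prot[f"A_{condition}"].to_numpy(),
        prot[f"tau_{condition}"].to_numpy(),
        prot[f"C_{condition}"].to_numpy(),
        t,
    )
    # expand to (peptide, replicate, time, channel)
    true_vals = np.stack([d[pep_protein], s[pep_protein]], axis=-1)  # (pep, tp, 2)
    true_vals = np.broadcast_to(true_vals[:, None, :, :], (total_pep, n_rep, n_tp, 2))
    noise = np.exp(rng.normal(0.0, sd, size=true_vals.shape)) if sd > 0 else 1.0
    obs = (true_vals * noise).ravel()

    reps = np.tile(np.repeat(np.arange(1, n_rep + 1), n_tp * 2), total_pep)
    times = np.tile(np.repeat(t, 2), total_pep * n_rep)
    channels = np.tile(np.array(["M/L", "H/L"]), total_pep * n_rep * n_tp)
    rows_per_pep = n_rep * n_tp * 2
    return pd.DataFrame(
        {
            "peptide_id": np.repeat(pep_ids, rows_per_pep),
            "protein_id": prot["protein_id"].to_numpy()[np.repeat(pep_protein, rows_per_pep)],
            "condition": condition,
            "replicate": reps,
            "time_h": times,
            "channel": channels,
            "ratio": obs,
            "intensity": np.repeat(pep_intensity, rows_per_pep),
        }
    )


def gen_timecourse(
    truth: Truth, config: SimConfig, missing_fraction: float = 0.0
) -> pd.DataFrame:
    """Simulate the abundance time course: log2(4-OHT/CTRL) per replicate.

    Each protein follows its archetype template plus Gaussian replicate noise
    (log2-scale SD ``timecourse_noise_sd``). ``missing_fraction`` drops that
    fraction of (protein, replicate, time) observations at random, emulating
    incomplete MS coverage.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = _rng(config, 4)
    ids = truth.proteins["protein_id"].to_numpy()
    t = np.asarray(config.timepoints, dtype=float)
    n, n_tp, n_rep = len(ids), len(t), config.n_replicates

    base = truth.profiles.to_numpy()  # (n, n_tp)
    vals = base[:, None, :] + rng.normal(0.0, config.timecourse_noise_sd, size=(n, n_rep, n_tp))
    df = pd.DataFrame(
        {
            "protein_id": np.repeat(ids, n_rep * n_tp),
            "replicate": np.tile(np.repeat(np.arange(1, n_rep + 1), n_tp), n),
            "time_h": np.tile(t, n * n_rep),
            "log2_ratio": vals.ravel(),
        }
    )
    if missing_fraction > 0:
        keep = rng.random(len(df)) >= missing_fraction
        df = df.loc[keep].reset_index(drop=True)
    return df


def gen_complexes(
    truth: Truth,
    n_complexes: int,
    size_dist: Sequence[int],
    coherence: float,
    seed: int | None = None,
) -> tuple[pd.DataFrame, Truth]:
    """Plant protein complexes with coherent member half-lives.

    Complex sizes are drawn uniformly from ``size_dist``; members are sampled
    from proteins not yet in a complex. Each complex draws a mean half-life
    from the global distribution and member half-lives are that mean plus
    Gaussian noise of SD ``coherence`` (hours); ``coherence=inf`` leaves the
    members' own globally drawn half-lives untouched (uncoupled control).
    Returns the membership catalog and the updated truth.
    """
    sizes_pool = np.asarray(list(size_dist), dtype=int)
    if (sizes_pool < 2).any():
        raise ValueError("size_dist must not allow complexes smaller than 2")
    if coherence < 0:
        raise ValueError("coherence must be non-negative")
    rng = np.random.default_rng(seed if seed is not None else 5)

    proteins = truth.proteins.copy()
    unassigned = proteins.index[proteins["complex_id"].isna()].to_numpy()
    sizes = rng.choice(sizes_pool, size=n_complexes, replace=True)
    if sizes.sum() > len(unassigned):
        raise ValueError("not enough unassigned proteins for the requested complexes")
    members_flat = rng.choice(unassigned, size=int(sizes.sum()), replace=False)

    rows = []
    pos = 0
    tau_all = proteins["tau_CTRL"].to_numpy()
    for ci, size in enumerate(sizes):
        cid = f"CPX{ci:04d}"
        idx = members_flat[pos : pos + size]
        pos += size
        if np.isfinite(coherence):
            mean_hl = float(rng.choice(tau_all)) * LN2
            member_hl = np.maximum(mean_hl + rng.normal(0.0, coherence, size=size), 0.5)
            proteins.loc[idx, "tau_CTRL"] = member_hl / LN2
            proteins.loc[idx, "tau_4OHT"] = member_hl / LN2
        proteins.loc[idx, "complex_id"] = cid
        rows.extend((cid, proteins.loc[i, "protein_id"]) for i in idx)

    catalog = pd.DataFrame(rows, columns=["complex_id", "protein_id"])
    return catalog, Truth(proteins=proteins, profiles=truth.profiles, timepoints=truth.timepoints)


def gen_annotations(
    protein_ids: Sequence[str],
    n_terms: int,
    size_range: tuple[int, int] = (5, 30),
    seed: int | None = None,
) -> dict[str, set[str]]:
    """Random functional annotation terms over a protein background (null map)."""
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size_range")
    rng = np.random.default_rng(seed if seed is not None else 6)
    ids = np.asarray(protein_ids)
    out: dict[str, set[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        out[f"TERM{i:04d}"] = set(rng.choice(ids, size=min(size, len(ids)), replace=False))
    return out


def gen_cohort(
    n_patients: int,
    signature,
    effect_size: float,
    censor_rate: float,
    seed: int,
    n_extra_genes: int | None = None,
    baseline_hazard: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a patient cohort whose hazard depends on the signature score.

    Expression is standard normal per gene per patient (signature genes plus
    ``n_extra_genes`` background genes, default 2x the signature length).
    Survival times are exponential with hazard
    ``baseline_hazard * exp(effect_size * z)`` where ``z`` is the cohort
    z-scored signed-signature score, so ``effect_size`` is the log hazard per
    unit score. Censoring is independent: each patient is censored with
    probability ``censor_rate`` at a uniform time before their event.

    Returns ``(expression, survival)``: a genes x patients matrix and a table
    of (patient_id, time_years, event).
    """
    if len(signature.genes) == 0:
        raise ValueError("signature must be non-empty")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    sig_genes = list(signature.genes)
    n_extra = 2 * len(sig_genes) if n_extra_genes is None else int(n_extra_genes)
    genes = sig_genes + [f"BG{i:05d}" for i in range(n_extra)]
    patients = [f"PT{i:04d}" for i in range(n_patients)]

    x = rng.normal(size=(len(genes), n_patients))
    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=patients)

    w = np.asarray(signature.weights, dtype=float)
    score = w @ x[: len(sig_genes), :]
    z = (score - score.mean()) / score.std(ddof=0)
    hazard = baseline_hazard * np.exp(effect_size * z)
    times = rng.exponential(1.0 / hazard)

    event = np.ones(n_patients, dtype=int)
    if censor_rate > 0:
        censored = rng.random(n_patients) < censor_rate
        times = np.where(censored, times * rng.random(n_patients), times)
        event[censored] = 0
    times = np.maximum(times, 1e-9)

    surv = pd.DataFrame({"patient_id": patients, "time_years": times, "event": event})
    return expr, surv
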