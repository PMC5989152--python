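import numpy as np
import pandas as pd

from turnoverkit import turnover as tv

STUDY_TIMEPOINTS = np.array([1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0])


def forward_series(A, tau, C, timepoints=STUDY_TIMEPOINTS, reps=1):
    """Noise-free joint D/S ratio series on the standard time grid."""
    t = np.asarray(timepoints, float)
    d = C + A * np.exp(-t / tau)
    s = A * (1.0 - np.exp(-t / tau))
    tt = np.tile(np.concatenate([t, t]), reps)
    yy = np.tile(np.concatenate([d, s]), reps)
    ch = np.tile(np.array([0] * len(t) + [1] * len(t)), reps)
    return tv.RatioSeries(t=tt, y=yy, channel=ch)


def peptide_frame(A, tau, C, n_peptides=1, n_reps=3, noise_sd=0.0, seed=0,
                  condition="CTRL", protein_id="P1", intensities=None):
    """Long peptide table for one protein on the standard time grid."""
    rng = np.random.default_rng(seed)
    t = STUDY_TIMEPOINTS
    d = C + A * np.exp(-t / tau)
    s = A * (1.0 - np.exp(-t / tau))
    rows = []
    for p in range(n_peptides):
        inten = intensities[p] if intensities is not None else 1.0
        for r in range(1, n_reps + 1):
            for ti, tp in enumerate(t):
                for ch, val in (("M/L", d[ti]), ("H/L", s[ti])):
                    noise = np.exp(rng.normal(0, noise_sd)) if noise_sd > 0 else 1.0
                    rows.append((f"pep{p}", protein_id, condition, r, tp, ch,
                                 val * noise, inten))
    return pd.DataFrame(rows, columns=["peptide_id", "protein_id", "condition",
                                       "replicate", "time_h", "channel", "ratio",
                                       "intensity"])
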