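# turnoverkit

Quantitative analysis of proteome remodelling during inducible oncogenic
transformation, built around pulse-SILAC protein turnover kinetics. The
package implements, as a tested and reusable pipeline, the statistics used
to characterise how an activated Src kinase reshapes an epithelial
proteome — which proteins change in abundance, which change in half-life,
how turnover distributes across the proteome per molecule rather than per
gene, whether complex subunits turn over coherently, and whether the
response signature stratifies patient survival — together with a
synthetic-data generator that emulates the study design (seven chase time
points at 1, 3, 6, 12, 24, 48 and 72 h, biological triplicate, 1–50
peptides per protein, a log-normal copy-number distribution spanning ~8
orders of magnitude).

## The models

**Turnover kinetics.** After the pulse label switch, the pre-existing
protein pool measured against a spiked-in light reference decays as

    D(t) = C + A·e^(−t/τ)

and newly synthesised protein accumulates as the complement
S(t) = (C + A) − D(t) = A·(1 − e^(−t/τ)), with half-life t½ = τ·ln 2. The
offset C absorbs amino-acid recycling. Both curves are fitted jointly by
bounded nonlinear least squares with shared (A, τ, C); τ is capped at
300 h (a 208 h half-life). Proteins are fitted on the intensity-weighted
per-time-point mean of their peptide ratios.

**Downstream statistics.** Proteome-ruler copy numbers (histone intensity
sum anchored to the DNA mass per cell); abundance-weighted median/mean
half-life; a shrink-variance one-sample t-test on log2 ratios with 2-fold /
p<0.01 classification; a z-test on Δt½ between conditions using propagated
fit errors; k-means (k=30) of complete temporal profiles agglomerated into
six kinetic classes (EU, MU, ED, MD, UD, NC); decile binning with
hypergeometric term enrichment and a permutation Pscore for short-/long-
lived functional classes; a decoy pseudo-complex bootstrap for half-life
coherence; and a ±1 signed-signature score with 20%-quantile cohorts,
Kaplan–Meier / log-rank comparison and a 1000-decoy bootstrap FDR.

## Worked example

```python
import numpy as np
from turnoverkit import turnover as tv

t = np.array([1, 3, 6, 12, 24, 48, 72], dtype=float)
A, tau, C = 0.9, 14.43, 0.05
d = C + A * np.exp(-t / tau)          # decay (M/L) ratios
s = A * (1 - np.exp(-t / tau))        # synthesis (H/L) ratios
series = tv.RatioSeries(
    t=np.concatenate([t, t]),
    y=np.concatenate([d, s]),
    channel=np.array([0] * 7 + [1] * 7),
)
fit = tv.fit_turnover(series)
print(f"A={fit.A:.3f} tau={fit.tau:.2f} h C={fit.C:.3f} "
      f"t1/2={fit.half_life:.2f} h")
```

prints

```
A=0.900 tau=14.43 h C=0.050 t1/2=10.00 h
```

i.e. the fitter recovers the generating parameters exactly on noise-free
data, and a 14.43 h time constant corresponds to a 10.0 h half-life
(τ·ln 2). The same machinery run through the whole pipeline:

```sh
turnoverkit run-all bundle/ --seed 42 --n-proteins 500
```

simulates a 500-protein study and writes every stage output
(`fits_CTRL.tsv`, `turnover_summary.tsv`, `diff_halflife.tsv`,
`clusters.tsv`, `pscore.tsv`, `complex_summary.tsv`,
`survival_summary.tsv`, …) plus a `manifest.json` with versions, seeds and
thresholds. On this bundle `turnover_summary.tsv` reports an unweighted
median half-life of 11.7 h against an abundance-weighted median of 7.6 h —
with only 500 proteins the weighted statistic is dominated by the handful
of most-abundant proteins (the top 5 already hold 50% of all copies,
column `n50`) — and `survival_summary.tsv` shows the planted 15-gene
signature separating the simulated patient cohorts at log-rank
p ≈ 1.2e-32 with a bootstrap FDR below 0.001 (0 of 1000 decoy signatures
matched it).

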