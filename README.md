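# respchaos

Tools for studying how chaotic activity in brainstem respiratory pacemakers
shapes the complexity of human breathing.

The human respiratory rhythm is generated by two coupled groups of
pacemaker-like neurons in the ventrolateral brainstem: the pre-Bötzinger
complex (rostral VL medulla, inspiration) and the parafacial respiratory
group (caudal VL pons, active expiration).  Airflow recorded at the mouth is
chaotic, resting-state fMRI shows different relative activity of the two
centers in health (medulla-dominant) and in chronic obstructive pulmonary
disease (COPD, pons reactivated) — and a minimal dynamical model can connect
the two observations.  `respchaos` implements that computational chain:

* **`respchaos.cpg`** — a two-unit map-based central pattern generator.
  Each unit is a discrete FitzHugh–Nagumo-type (Courbage–Nekorkin) map

      x[n+1] = x[n] + F(x[n]) − y[n] − β·H(x[n] − d) + I_T[n] + I_syn[n]
      y[n+1] = y[n] + ε·(x[n] − J)

  with a piecewise-linear cubic `F`, excitability `J`, a low-threshold
  calcium current `I_T` producing post-inhibitory rebound bursts, and
  rectangular-pulse chemical synapses `I_syn`.  Shipped presets reproduce
  four synchronization regimes: no handshake (parafacial silent), dominant
  pre-Bötzinger with occasional parafacial activity, full handshake
  (parafacial triggers inspiration, is inhibited, rebounds to switch it
  off), and half handshake (the delayed rebound re-triggers inspiration).
* **`respchaos.airflow`** — breath-by-breath segmentation of flow
  recordings (default 400 Hz) into inspiratory/expiratory durations,
  volumes and mean flows (Vt/Ti, Vt/Te), plus the coefficient of variation
  and lag-one-breath autocorrelation.
* **`respchaos.nonlinear`** — the chaos pipeline for short physiological
  series: Volterra–Wiener noise titration (the noise limit NL, in percent of
  signal power, is positive iff nonlinear determinism survives the noise
  floor), Rosenstein's largest Lyapunov exponent λ_L, Grassberger–Procaccia
  correlation dimension D_corr, autocorrelation/false-nearest-neighbor
  embedding selection, phase-randomized surrogates and the paired Wilcoxon
  signed-rank test.
* **`respchaos.bold`** — a hemodynamic forward model: simulated neural
  states are convolved with a double-gamma HRF (response/undershoot delays
  6/16 s, dispersions 1 s, ratio 6, kernel 32 s), sampled at TR = 2 s with
  Gaussian noise (SD 0.25), and summarized as the amplitude of low-frequency
  oscillations (AlFO: mean root power spectral density over 0.01–0.08 Hz,
  normalized to the cross-region mean).  Real ROI series can be analyzed the
  same way after regressing out physiological covariates.
* **`respchaos.fixtures`** — seeded generators (logistic and Hénon maps,
  linear AR nulls, sinusoidal flow, CPG-driven breath series, covariates)
  so the whole pipeline is testable without recordings.

## Worked example

Detect chaos in a logistic-map series, then reproduce the healthy-vs-COPD
fMRI contrast from the model:

```bash
$ respchaos generate --kind logistic --n 250 --out logistic.csv
$ respchaos titrate --input logistic.csv --seed 1 --out titration.json
NL = 34.60% (chaotic)
```

The noise limit of 34.6% means nonlinear determinism in this 250-point
series survives until added white noise reaches about a third of the signal
power — strong chaos.  A linear AR series gives NL = 0.

```bash
$ respchaos simulate --scheme C --steps 30000 --seed 1 --out trace.tsv
regime: full_handshake
```

The trace file holds per-step `x, y, k` for both pacemakers; the JSON
sidecar records spikes, bursts and the classified regime.

```bash
$ respchaos boldsim --scheme B --runs 5 --n-ap 250 --seed 1 --out alfo_B.json
{"medulla": 1.4254168541877674, "pons": 0.5745831458122327}
$ respchaos boldsim --scheme C --runs 5 --n-ap 250 --seed 1 --out alfo_C.json
{"medulla": 0.77090098821996, "pons": 1.2290990117800402}
```

Under the healthy scheme (B, pre-Bötzinger dominant) the simulated medullary
channel carries the larger normalized AlFO (1.43 vs 0.57); under the COPD
scheme (C, parafacial-driven full handshake) the pontine channel is elevated
(1.23) above the healthy pons — the direction observed in resting-state
fMRI of controls and patients.

The same operations are available as a library:

```python
from respchaos import cpg, nonlinear

trace = cpg.simulate(cpg.load_preset("regime_C", seed=1))
x = trace.x["pfrg"][trace.n_transient:]
lle = nonlinear.lle_rosenstein(x, nonlinear.EmbeddingSpec(tau_embed=3, m=3))
print(trace.regime, lle.lambda_L)   # full_handshake ~0.17 per step
```

## Documentation

`docs/methods.md` describes the model equations, the numerical choices in
the chaos pipeline, the preset search, and known limitations.
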