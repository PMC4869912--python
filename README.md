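# coopgate

Analysis toolkit for **cooperative gating of clustered voltage-gated Ca²⁺
channels**, built for electrophysiologists and imaging labs studying
CaV1-family channels (the motivating system is the CaV1.3 short/long
splice-variant pair in tsA-201 cells and hippocampal neurons).

The question the toolkit addresses: do the channels in a membrane cluster
open independently, or cooperatively? The core machinery is a **binary
coupled Markov-chain model** of a site with N two-state channels, whose
occupancy kernel mixes an independent-channels kernel with an all-or-none
"super-channel" kernel,

    T = (1 − κ) · T_ind + κ · T_coh,     κ ∈ [0, 1],

and a maximum-likelihood estimator of the **coupling coefficient κ** from a
single optical or electrical record (hidden-Markov forward algorithm with
Gaussian emissions around the quantal levels). κ = 0 means purely
independent gating, κ = 1 fully coupled gating; sites with κ > 0.1 are
classified as coupled.

Around this core the package implements the full supporting pipeline:

* `coopgate.coupling` — the gating model, likelihood, κ estimator.
* `coopgate.singlechannel` — all-points amplitude histograms, the
  multi-Gaussian quantal fit N(i) = Σⱼ aⱼ·exp[−(i−jq)²/(2jb)], sweep
  idealization, ensemble averages, NPo = |I|/|i| arithmetic.
* `coopgate.sparklets` — Ca²⁺ sparklet event detection, nPs activity
  scoring, event-amplitude quantal fits, site density, fluorescence→nM
  calibration.
* `coopgate.wholecell` — G–V transform, Boltzmann fits, CDI metrics
  (r300, f300, % inactivation), activation τ, F/F0–voltage curves.
* `coopgate.photobleach` — TIRF stack preprocessing, spot ROIs, automated
  photobleaching step counting, channels-per-cluster summaries.
* `coopgate.superres` — DLR/√N localization precision, 2-D Gaussian spot
  fitting, localization rendering, binary-mask cluster areas and density.
* `coopgate.synthetic` — generators for every input class, with ground
  truth, anchored to named presets (unitary currents, 38 nM sparklet
  quantum, coupling presets κ = 0.21/0.08/0, activation constants).
* `coopgate.pipeline` / `coopgate` CLI — validated JSON configs, staged
  runs, deterministic outputs, summary statistics.

## Worked example

Simulate one sparklet site at the coupled (short-isoform) preset and ask
whether the channels gate cooperatively:

```python
from coopgate.presets import get_gating_preset, get_signal_preset
from coopgate.synthetic import make_sparklet_trace
from coopgate.coupling import estimate_kappa
from coopgate.sparklets import site_nps

gating = get_gating_preset("cav13s_sparklet")    # 2 channels, kappa = 0.21
signal = get_signal_preset("sparklet_default")   # q = 38 nM, noise 8 nM, 100 Hz
trace, truth = make_sparklet_trace(gating, signal, n_frames=2000, seed=42)

site = site_nps(trace, q=38.0, baseline="auto")
fit = estimate_kappa(trace, n_channels=2, q=38.0, baseline=100.0, noise_sd=8.0)
print(f"events detected : {len(site.events)}")
print(f"nPs             : {site.nps:.3f}")
print(f"kappa_hat       : {fit.kappa_hat:.3f}")
print(f"coupled (>0.1)  : {fit.coupled}")
```

Output:

```
events detected : 104
nPs             : 0.316
kappa_hat       : 0.229
coupled (>0.1)  : True
```

The site produced 104 supra-threshold Ca²⁺ influx events; its
time-averaged activity (nPs, the optical NPo analog) is 0.32 open channels
per frame; and the ML estimate κ̂ = 0.23 correctly recovers the preset's
κ = 0.21 and classifies the site as coupled. (With 8 nM noise on a 38 nM
quantum, an occasional frame can round one quantal level above the true
occupancy; levels are floored at zero.)

The same analyses run from the shell, e.g.:

```bash
coopgate kappa --trace site.txt --n-channels 2 --q 38 --noise-sd 8
coopgate quantal-fit --sweeps sweeps.txt --n-components 2 --bin-width 0.02
coopgate bleach --stack movie.tif --min-step auto
```

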