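# sagloc

Modelling of human sound localization in sagittal planes, for auditory
researchers and spatial-audio engineers who want to ask *which frequency
regions of the pinna's spectral cues drive localization behaviour*.

Within a sagittal plane (front–up–back at a fixed lateral angle ϕ), listeners
localize broadband sounds from monaural spectral cues imprinted by the pinna.
`sagloc` implements a template-matching model of this process and a
model-comparison analysis over **spectral weighting schemes** — hypotheses
about how much each frequency band contributes to the cue evaluation.

## The model

For a target sound and a listener's directional transfer functions (DTFs),
spectral magnitude profiles ξ are computed in 28 auditory bands spaced one
ERB apart between 700 Hz and 18 kHz, and reduced to positive spectral
gradient (PSG) profiles ξ̃[b] = max(ξ[b] − ξ[b−1], 0). The target profile is
compared to the listener's internal templates ξ̃ᵣ at every polar angle θ via
a weighted distance

    d[θ] = Σ_b |ξ̃ᵣ[θ, b] − ξ̃ₜ[b]| · w[b],

mapped to a similarity index by the sigmoid ς[θ] = 1 − (1 + e^{−Γ(d[θ]−S)})⁻¹
(Γ: degree of selectivity; S: sensitivity), combined across ears with a
lateral-angle-dependent binaural weight, smeared by a wrapped Gaussian of SD
ε (sensorimotor scatter), and normalized to a probability mass vector (PMV)
over response polar angles.

Five weighting schemes w[b] are compared: **Flat** (uniform), **NR** (notch
region, emphasis near 8 kHz), **DT** (discrimination task, near 6 kHz),
**SV** (per-band spatial variance of the listener's own templates, subject-
or group-level), and **LP** (low-pass, exponentially decaying). Each variant
is refitted per listener by maximizing the response likelihood over
{Γ, S, ε} within bounds (0.1–100, ±20, 3–50°), and variants are compared at
the group level by random-effects Bayesian model selection: BIC evidence per
subject, protected exceedance probabilities (PXP) and the Bayesian omnibus
risk (BOR). Goodness of fit is Nagelkerke's likelihood R̄² against a
uniform-response null. Localization performance is summarized by the
quadrant error rate (QE, % of responses with |polar error| > 90°) and the
local polar error (PE, RMS error of the remaining responses).

A parametric synthetic-listener generator produces DTF sets with a main
spectral notch migrating upward with polar angle, pinna peaks, front–back
asymmetries and directional ripple, plus response sets sampled from the
model's own PMVs — so the full pipeline (fit → select → evaluate) can be
validated against known ground truth without any external data.

## Worked example

```python
from sagloc import (erb_band_centers, make_dtf_set, SyntheticListenerSpec,
                    ModelParams, nr_scheme, simulate_responses, predict_pmv,
                    fit_subject, qe_pe)

grid = erb_band_centers()                      # 28 bands, 700 Hz - 18 kHz
templates, dtfs = make_dtf_set(SyntheticListenerSpec(rng_seed=1), grid=grid)

scheme = nr_scheme(grid)                       # emphasis around 8 kHz
true = ModelParams(gamma=6.0, s=0.7, epsilon=12.79)

pmv = predict_pmv(templates, (0.0, 0.0), true, scheme)
print(f"PMV mode at {pmv.mode():.0f} deg, entropy {pmv.entropy():.2f} nats")

responses = simulate_responses(templates, scheme, true, n_per_target=14, seed=2)
m = qe_pe(responses)
print(f"simulated {m.n_total} trials: QE = {m.qe:.1f}%, PE = {m.pe:.1f} deg")

fit = fit_subject(responses, templates, scheme, seed=3)
p = fit.params
print(f"fitted gamma = {p.gamma:.2f}, S = {p.s:.2f}, epsilon = {p.epsilon:.2f} deg "
      f"(logL = {fit.log_likelihood:.1f})")
```

prints

```
PMV mode at 0 deg, entropy 3.59 nats
simulated 1008 trials: QE = 24.9%, PE = 35.6 deg
fitted gamma = 7.06, S = 0.79, epsilon = 11.99 deg (logL = -3462.7)
```

The PMV peaks at the target direction (a flat-spectrum target filtered by
the listener's own DTF matches its template best there); the fitted
parameters recover the generating values to within the resolution ~1000
trials affords.

The same pipeline is available from the shell:

```sh
sagloc simulate --subjects 17 --trials 300 --scheme NR --seed 1 --dir run
sagloc fit      --dir run --seed 1
sagloc select   --dir run --seed 1        # PXP/BOR report -> run/selection.json
sagloc evaluate --dir run                 # per-subject QE/PE
sagloc report   --dir run --scheme NR     # Markdown + PMV heat map
```

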