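# Methods

## Model overview and assumptions

`sagloc` predicts the distribution of a listener's polar-angle responses to a
broadband, flat-spectrum sound within a sagittal plane. The model assumes
that (i) localization in sagittal planes rests on comparing the positive
spectral gradient (PSG) profile of the incoming sound to internally stored
templates derived from the listener's own DTFs; (ii) the mapping from
spectral distance to perceptual similarity is a two-parameter sigmoid; (iii)
the two ears contribute a convex combination weighted toward the ipsilateral
ear; and (iv) motor/pointing noise adds an independent circular-Gaussian
scatter to the perceived direction. The model predicts a probability mass
vector (PMV), not single responses — likelihood-based fitting uses the PMV
directly.

Polar angle θ is circular on [−90°, 270°) (front-below → up → rear-below);
lateral angle ϕ is positive toward the listener's left. This sign convention
is declared here and in the I/O layer; the spatial-variance scheme is
symmetric in ±ϕ, so group analyses do not depend on it.

## Peripheral stage

Band profiles are computed in the frequency domain: per band, the dB level
of the stimulus-weighted mean squared DTF magnitude inside a rectangular
window of 1 ERB centred on the band's centre frequency. Centres are spaced
one ERB-number unit apart on the Glasberg–Moore scale
E(f) = 21.4·log10(0.00437·f + 1), anchored at 700 Hz; 28 bands reach
16.7 kHz (the next would exceed 18 kHz). For long stationary flat-spectrum
noise this equals the expected output of a time-domain gammatone front end
without stimulus-realization noise; users preferring a filterbank front end
can supply precomputed band profiles to the template containers directly.
Cochlear nonlinearities, temporal integration and level dependence are out
of scope.

## Weighting schemes

All five schemes are non-negative and normalized to unit sum over the 27
gradient bands, so the weight scale cannot trade off against Γ and S (every
variant is refitted anyway; normalization just makes fitted parameters
comparable). The NR and DT schemes are log-frequency Gaussian bumps (centres
8 and 6 kHz, width 1 octave, floor 0.05) — parametric stand-ins for
empirically drawn curves whose exact numbers are not published; both the
centres and shapes are configurable. LP decays by a factor 0.5 per octave
above 700 Hz (configurable), giving a clearly complementary low-frequency
emphasis. SV computes the population variance of the PSG templates across
the polar dimension per band and ear (population, not sample: the template
grid is a census of directions, not a draw), combines ears and mirrored
planes with the signed binaural weight α(ϕ) so that ν(+ϕ) = ν(−ϕ) holds
bit-exactly, and normalizes by the band sum; the group-level scheme is the
arithmetic mean of subject-level weights.

## Binaural combination and response stage

The binaural weight is logistic in lateral angle with scale Φ = 13°
(left-ear weight 1/(1+e^{−ϕ/Φ})), exactly 0.5 on the median plane and
> 0.95 ipsilateral beyond ~40°. Similarity is computed per ear and combined
afterwards. Sensorimotor scatter is a circular convolution (period 360°)
with a wrapped Gaussian of SD ε on the regular 5° response grid; the kernel
is normalized so probability mass is conserved. Smearing is applied once,
after binaural combination (a single motor stage); analyses comparing
against implementations that smear per ear before combination should note
this choice. Templates on irregular polar grids are interpolated linearly
per band (circularly in θ) to the 5° grid before prediction.

Degenerate numerical corners are defined, not left to chance: extreme
{Γ, S} that underflow every similarity to zero yield a uniform PMV (the
informationless limit); PMV probabilities are floored at 1e-9 before logs so
a single outlying response cannot veto a fit; responses are assigned to
polar bins by circular nearest-centre distance with ties broken toward the
lower bin.

## Fitting

{Γ, S, ε} are fitted per subject by maximizing the summed log PMV
probability of the observed responses, restricted to the median plane
(−10° < ϕ < 10°). Bounds: Γ ∈ (0.1, 100), S ∈ (−20, 20), ε ∈ (3°, 50°).
The optimizer is seeded differential evolution (Sobol initialization,
population 16, up to 80 generations) with a local polish, searching Γ in
log10 space because its plausible range spans three decades; the spectral
distance stage is precomputed once per subject × scheme, so a full fit costs
about a second. A fit is flagged as not converged within bounds when a
parameter lands within 1% of the bound range of either edge (the tolerance
is a declared convention); subjects with any flagged variant are excluded
from model comparison. Lateral planes are evaluated with median-plane
parameters; hierarchical (group-level) parameter estimation is a non-goal.

## Model selection and goodness of fit

Evidence per subject × variant is BIC = ρ·ln N − 2·logL with ρ = 3.
Per-subject posteriors use the standard transform ∝ exp(−BIC/2); a
`printed_ratio` mode (BIC_k/Σ BIC_m) is shipped for compatibility with
analyses that used that normalization, but it assigns higher posterior to
the *worse* model and is nearly uniform for large BIC, so it is not the
default. Group inference is the variational random-effects scheme: Dirichlet
prior α₀ = 1 per variant, fixed-point updates to tolerance 1e-6, exceedance
probabilities from 10⁶ seeded Dirichlet samples, BOR from the free-energy
Bayes factor against the equal-frequency null, and
PXP_k = EP_k·(1−BOR) + BOR/M. For two variants the EP has a closed
Beta-tail form, kept as an independent cross-check of the sampler.
Goodness of fit is Nagelkerke's R² computed from log-likelihoods against the
uniform-response null, with the discrete-model correction R̄² that reaches
exactly 1 for a perfect predictor.

## Synthetic listeners

The generator emulates the acoustic structure the analysis relies on — not
physical pinna acoustics. Each listener's dB spectra contain: a main notch
(default −25 dB deep, 0.3 octaves wide) whose centre starts at 6 kHz for
θ = −30° and rises 0.75 octaves per 90° (so the front trajectory spans
roughly 4.2–12 kHz, concentrating spatial variance in the upper bands); a
secondary notch at 1.8× the main-notch frequency; a broad 6 dB peak at
4 kHz; rear spectra mirroring the front trajectory offset by 0.3 octaves
(controllable front–back similarity, hence tunable quadrant-error rates);
a lateral-angle-dependent interaural tilt (2 dB scale); and a smooth random
ripple field (2 dB SD, ≲1.5 cycles/octave, correlation ≈ 20° in θ) that
gives each direction an idiosyncratic fine structure. The ripple is what
makes {Γ, S, ε} jointly identifiable: without it, neighbouring directions
are spectrally near-identical and the sensorimotor scatter trades off
against the sigmoid slope. Cohorts jitter these parameters per subject
around the defaults; all randomness flows through one seeded generator, and
the ground-truth ledger stores the complete acoustic spec so any listener
can be reconstructed bit-exactly.

Simulated responses are drawn i.i.d. from the model's own PMVs at the 5°
bin centres. What passing tests therefore show is internal consistency —
that fitting and selection recover the generating scheme and parameters
under the model's own assumptions at realistic trial counts. They do not
show that real listeners' response biases (e.g. horizontal-plane attraction)
or real HRTF acoustics are captured; analyses of measured data should read
DTFs from SOFA files via the I/O layer.

## Default problem sizes

Chosen as the package's standard validation conditions: parameter recovery
uses one listener × ~1000 median-plane trials × 10 seeds at
(Γ, S, ε) = (6, 0.7, 12.79°) — ε being a typical group-average scatter,
Γ and S mid-range values producing realistic PMV sharpness; scheme recovery
uses 17 listeners (the analyzed pool size of comparable studies) × 300
trials under the NR scheme, all five variants refitted, with median recovery
errors of ~0.5° in ε and PXP(NR) > 0.99. QE/PE of the default cohort
(median QE ≈ 24%, PE ≈ 33°) sit at the upper end of the ranges reported for
normal-hearing adults (QE up to ~23%, PE 24–41°).

## Known limitations

- No interaural time/level cues and no lateral-angle response prediction;
  the model works within sagittal planes.
- The NR/DT bump shapes are parametric approximations; users with digitized
  empirical weighting curves can load them via the two-column table format.
- The SOFA layer reads/writes SimpleFreeFieldHRIR at the HDF5 level; exotic
  conventions or netCDF-specific decorations are not interpreted.
- Response biases and decision stages are not modelled; the PMV is the
  final output.
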