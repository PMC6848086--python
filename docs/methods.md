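# Methods

## The two-state photocycle model

A bacteriophytochrome population is described by the Pfr fraction
`f ∈ [0, 1]` (with `f_Pr = 1 − f` by conservation, enforced to 1e-9
throughout). Under a set of light sources j with irradiance `E_j`
(µmol photons m⁻² s⁻¹) at wavelength `λ_j`, the per-molecule excitation rate
of a pure state is

    k_state,j = ln(10)·1e-7 · ε_state(λ_j) · E_j    [s⁻¹]

The constant folds the decadic absorption cross-section
(`σ = 1000·ln(10)·ε/N_A` cm² for ε in M⁻¹ cm⁻¹) together with the photon
flux conversion (1 µmol m⁻² s⁻¹ = 1e-6·N_A·1e-4 photons cm⁻² s⁻¹);
Avogadro's number cancels, leaving ln(10)·1e-7 ≈ 2.3026e-7. A sanity point:
ε = 80 000 M⁻¹ cm⁻¹ at 60 µmol m⁻² s⁻¹ gives k ≈ 1.1 s⁻¹.

Total photoconversion rates are `A_fwd = Φ_fwd Σ_j k_Pr,j` (Pr→Pfr) and
`A_rev = Φ_rev Σ_j k_Pfr,j`. Thermal reversion drives the photoproduct back
to the ground state with one or more exponential components
`(a_i, k_i)`, `Σ a_i = 1`; its amplitude-weighted mean rate is `K = Σ a_i k_i`.
The population ODE is linear with constant coefficients within each protocol
segment:

    df/dt = A_fwd·(1 − f) − A_rev·f  ±  dark terms

so each illuminated segment relaxes mono-exponentially with rate
`λ = A_fwd + A_rev + K` toward the stationary value

    f_ss = A_fwd / λ              (Pr ground)
    f_ss = (A_fwd + K) / λ        (Pfr ground)

With dark reversion off (`K = 0`) this is the strong-light photostationary
state; the quantum-yield deduction `ratio = [f_prod/(1−f_prod)]·σ`, with
`σ = ε_photoproduct/ε_ground` at the excitation wavelength, is its exact
inverse, and the two functions round-trip to 1e-9 over a wide ratio×σ grid
(a property test).

**Multiphasic reversion.** Multiple dark components are modeled as parallel
subpopulations with fixed amplitude fractions, re-equilibrated at the start
of each dark segment: the non-ground fraction decays as
`f₀·Σ a_i exp(−k_i t)`. This reproduces multiphasic reversion without
inventing microscopic sub-states the data do not constrain. During
illuminated segments the multiphasic terms are collapsed to the mean rate
`K`; illumination rates dominate there by one to two orders of magnitude in
every fixture, and the strong-light deductions neglect reversion entirely.

**Integration.** The default path is the per-segment closed form (exact for
this model). `method="ode"` integrates the same piecewise equations with
SciPy's Radau solver at rtol 1e-10 / atol 1e-12 as an independent numerical
cross-check; the two agree to better than 1e-6 on all fixture protocols
(tested). Default output sampling is 1/1000 of each segment duration; a
user-supplied `dt` must be ≤ 1/10 of the shortest segment.

## Spectral operations

Spectra live on a common 250–850 nm grid at 1 nm (linear interpolation
between grid points and onto foreign grids). Peak location refines the
discrete maximum by 3-point parabolic interpolation, resolving sub-nanometer
positions from 1-nm data — the printed band maxima are 1-nm quantities, so
the generator targets and the finder both work at that precision. Isosbestic
points are sign changes of `ε_Pr − ε_Pfr`, bracketed on the grid and refined
linearly; when a window holds several crossings the one nearest the window
center is returned with the total count.

Unmixing solves `A(λ) = a_Pr ε_Pr + a_Pfr ε_Pfr` by non-negative least
squares (fractions are physical populations), reporting fractions
`a_i/Σa`, the fitted concentration-pathlength product `Σa`, the residual
norm, and a collinearity flag (condition number > 1e8). The default window
is 600–850 nm: the Soret band (~400 nm) is state-insensitive in these
proteins and carries no mixture information.

## Synthetic fixtures and their calibration

Nothing is deposited for these proteins; the quantitative record is a set of
printed constants. The generator turns them into fully specified objects and
**fails loudly** if any constraint is not met after calibration:

| constraint | value | origin |
|---|---|---|
| Pr-ground protein: Pr peak | 708 nm | printed |
| Pr-ground protein: Pfr band center | 740 nm (broad) | printed |
| Pfr-ground protein: Pfr / Pr peaks | 755 / 690 nm | printed |
| Pfr/Pr peak-extinction ratio | 2.5 | printed |
| Q-band isosbestic | 660 ± 5 nm | printed |
| ε_Pfr/ε_Pr at 780 nm (Pr-ground) | 13 | implied by ⅓ Pfr at yield ratio 6.5 |
| mixed 780+660 nm stationary Pfr | 0.90 | observed level, used as calibration |
| reversion half-time (Pfr ground) | 3 min, mono | printed |
| reversion (Pr ground) | biphasic, >90 min to complete | printed qualitatively |
| LED irradiance | 65 µmol m⁻² s⁻¹ | printed range 60–70 |

Bases are sums of Gaussians. Main Q-bands use 35 nm FWHM, the broad
740-nm photoproduct band 60 nm, secondary shoulders 55 nm, the shared Soret
band 50 nm — band shapes are not printed anywhere and are fixture choices.
A fixed-point loop then solves, per recipe: shoulder/tail amplitudes against
point-extinction targets, main-band centers against composite peak
positions (a shoulder shifts a composite peak by ~1 nm, so centers cannot
simply be set to the targets), and the Pr main amplitude against the peak
ratio. Calibration residuals are verified to 0.1 nm / 0.1% before a basis
is returned.

Two calibrations deserve comment. First, the 780-nm extinction ratio of 13
is not printed; it is the unique value consistent with the printed pair
(⅓ Pfr under far-red light, yield ratio 6.5) through the stationary
balance, and the generator enforces it by solving the Pr far-red tail
amplitude. Second, the 660-nm extinction of the Pfr-ground protein is set to
25% of its peak (via shoulders on both states crossing at 660 nm): large
enough that photoconversion at the printed irradiance outruns the 3-minute
reversion, as it plainly did in the observed kinetics. A narrow 690-nm
Gaussian alone would leave essentially no 660-nm absorbance and would
contradict the observed two-thirds bleaching.

Absolute scales are also fixture choices: ground-state Q-band peak
ε = 90 000 M⁻¹ cm⁻¹ (typical for biliverdin phytochromes) and quantum
yields Φ = 0.13/0.02 (Pr ground, ratio 6.5) and 0.15/0.30 (Pfr ground,
ratio 2). Only the ratios are observable in the data the package emulates;
the absolute values set realistic timescales (tens of seconds to minutes at
60–70 µmol m⁻² s⁻¹). The biphasic reversion components of the Pr-ground
fixture (half-times 8 and 35 min, equal amplitudes) are likewise
assumptions, chosen so 99% completion takes ~3 h, i.e. well beyond 90 min.

**What the fixtures do not emulate:** instrument response and baseline
drift, photothermal effects, intensity saturation or photobleaching, inner
filter/screening gradients in the cuvette, and true band shapes (real
phytochrome bands are asymmetric with vibronic structure). Tests passing on
these fixtures validate the algebra, the integrators and the estimators —
not the spectroscopy of any real sample.

**Noise model.** Additive Gaussian noise, standard deviation expressed as a
fraction of the peak absolute signal per channel, generated from a seeded
`numpy` Generator; identical seeds reproduce identical noisy objects.

## Inference choices

*Decay fitting.* Models with 1..n exponentials plus a free baseline are
fitted by bounded trust-region least squares, initialized from a log-linear
regression of the relaxing tail (rate spread ×3/÷3 for the 2-component
start). Model selection uses AICc with a Δ ≥ 2 preference threshold for the
more complex model; an ill-conditioned richer fit (mixed-sign amplitudes,
indistinct rates) falls back to the simpler one with a warning. Relaxations
toward higher or lower baselines are both handled; the reported half-time is
ln 2 / rate of the dominant-amplitude component, in the input time units.
At least 20 samples are required.

*Parameter recovery.* From a protocol trajectory the recovery extracts, per
illuminated segment, the stationary level (tail mean over the last 10% of
samples) and the mono-exponential approach rate, plus a directly fitted
reversion rate from any dark segment. `(Φ_fwd, Φ_rev, K)` are then fitted
jointly (yields bounded to (0, 1], 5-start multistart with a fixed seed) to
the level and log-rate residuals. Two distinct wavelengths with known
extinction ratios make the absolute yields identifiable; a single
wavelength pins only the ratio, which is flagged in the result. Noiseless
two-wavelength round trips recover the generating yields to better than
0.1%; with 1% trace noise the median recovered ratio over 50 seeded
replicates stays within 5%.

## The division-logic model

The repression hypothesis is a total Boolean function of genotype and light:
phytochromes are photoactive iff the chromophore pathway is intact
(heme oxygenase present) and the light contains red/far-red (the white
regime includes it); a non-photoactive phytochrome is phosphorylated;
repression of rod–rod division requires both phytochromes, the hybrid
kinase, and phosphorylation. Repressed + water → cyst–cyst division,
unrepressed + water → rod–rod; blue-containing light (blue, white)
inhibits growth outright through a separate, unmodeled pathway, and absent
water no division occurs. The rare dark cyst–rod–cyst differentiation cycle
is carried as an annotation on the cyst–cyst outcome, not a fourth mode.

The response regulator does not gate repression by default — its knockout
could not be constructed, so no observation constrains it; `strict_brr=True`
adds the gate as an explicitly untested variant. The heterodimer and
shared-regulator mechanisms produce identical truth tables over every
observable condition, so the variant flag is provenance, and the scorer
cannot (and should not) separate them on the observed 10-row table — both
score 10/10. Totality and monotonicity (removing any repressor component
never preserves cyst division) are verified over the full 2⁵ × 5 × 2
enumeration.

## Problem sizes and determinism

Default trajectory sampling is 1000 points per segment; the acceptance
computation fits a 200-sample, 30-minute decay trace and reads 601-point
spectra, and the statistical checks use 50–100 seeded replicates — sizes at
which every estimator's sampling error is far below its tolerance. All
stochastic tests fix their seeds (Hypothesis runs derandomized), so the
suite is fully reproducible.

## Known limitations

- The two-state model has no spectroscopic intermediates (Lumi/Meta); it
  cannot describe microsecond-to-millisecond photocycle kinetics.
- Extinction scales are relative unless the user supplies a calibration;
  only ratio-based conclusions transfer to real samples.
- The mean-rate treatment of multiphasic reversion under illumination is an
  approximation, adequate when light rates dominate (all fixtures) but not
  near the dark limit of very weak illumination.
- The photostationary deduction assumes a single effective wavelength and
  uncorrected strong light, mirroring the assumptions of the published
  analysis it implements.
- The logic model is qualitative by construction: it predicts division
  *mode*, not rates or colony morphology, and encodes no mechanism for the
  blue-light growth inhibition.
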