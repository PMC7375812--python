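# Methods

This note documents the models, the numerical choices, and the synthetic
data that the test suite and the acceptance script rely on.

## Kinetic model of nuclear accumulation

Nuclear cargo fluorescence is modelled as a saturating mono-exponential

    I(t) = A + I_max · (1 − e^(−τ·t))

* `A` (intensity units) — offset absorbing the ~2 min dead time between
  adding the transport mix and the first frame, plus sample-specific
  background. Fitted freely per trace; it is not expected to be constant
  across samples.
* `I_max` (intensity units) — plateau amplitude, constrained ≥ 0.
* `τ` — rate constant in the reciprocal of the trace's native time unit.
  Traces here are sampled in minutes (frames every 2 min over 80 min), so
  fitted rates are per minute and treated as unit-agnostic fit outputs.

The quantity carried forward is the **initial flux** `J = I_max·τ`, the
slope at t = 0. It is insensitive to late-time effects (receptor recycling,
cargo back-leakage, pore crowding) that the mono-exponential makes no
attempt to capture; a bi-exponential fit with AIC comparison is provided
only as a model-selection check. Fitting is unweighted nonlinear least
squares (`scipy.optimize.curve_fit`) with initialisation A ← first point,
I_max ← last − first, τ ← 3/span — robust for saturating traces — and
bounds τ ≥ 0, I_max ≥ 0, A free. Optional 1/σ² weighting by the across-FOV
dispersion is available but off by default, since nothing indicates the
original fits were weighted. Non-convergence is reported via a flag and
message, never silently. When replicate fits are averaged per sample, each
parameter and J are averaged independently, so the averaged J̄ generally
differs from Ī_max·τ̄.

## Segmentation

The two reference channels are blurred (Gaussian, σ = 1 px by default),
thresholded (Otsu per frame; parameter-free and standard — the exact rule
used originally is not documented, so it is configurable), and
size-filtered (64 px² minimum). The nuclear mask is eroded with a 3×3
full-connectivity square, 3 iterations; the envelope mask is the eroded-away
rim; the cytoplasm mask is the thresholded cytoplasm channel minus the
pre-erosion nuclear mask. The three masks are pairwise disjoint by
construction. Masks are recomputed per frame by default (cells drift); a
static mode reuses frame 0. With zero erosions the envelope is empty — a
valid degenerate configuration, which is why emptiness of the envelope is
not a hard container invariant. Cargo background is estimated as the mean
intensity outside all masks; subtraction happens in the kinetics module
(`correct_trace`: (raw − background)/#dyes), keeping raw extraction pure.

## Flux normalization and free-energy inversion

Initial fluxes are normalized by `C = a_Ran·J*`, where `J*` is the largest
replicate-level flux that does not exceed the 95% t-confidence upper bound
of its own sample mean. This makes the model's saturation level `1/a_Ran`
attainable, with equality only for the normalizing replicate. Normalized
fluxes at or above `1/a_Ran` cannot be inverted (ΔG → −∞) and are excluded
with a warning, never clamped. The packaged per-sample table carries ΔG
values as printed, because the replicate-level raw fluxes behind the
original normalization constant are not published; those ΔG are treated as
authoritative inputs.

`ΔG = ln(1/ĵ − a_Ran)` and `P_tr = 1/(a_Ran + e^ΔG)` are exact inverses.
Both functions preserve the floating dtype of their input: in double
precision the round trip is exact to ~1e-6 k_BT at ΔG = −20 (the flux is
then within 2×10⁻⁹ of saturation, and inverting amplifies representation
error by ≈ a_Ran·e^(−ΔG)); extended-precision inputs recover 1e-9. The
default is `a_Ran = 2` (no RanGTP waiting at the exit); `a_Ran = 1` changes
F(R) by less than ln 2 and is available via configuration.

The ΔG-vs-N line is unweighted ordinary least squares
(`scipy.stats.linregress`); F(R) is the intercept, ε the negated slope, and
standard errors come from the fit covariance. A negative fitted ε is
flagged, not rejected. `ε₀ = ε/φ` uses φ = 0.01 (≈3000 FG motifs in the
pore volume). Energies are k_BT throughout; 1 k_BT ≈ 0.6 kcal/mol is a
display-only conversion.

## Vestibule (heterogeneous FG density) model

Regions along the pore axis carry `G_i = f_i − ε₀·φ_i·N`. The default
profile — cytoplasmic vestibule 20% of the axis at φ = 0.002 with zero
insertion cost, two 15% transition regions at φ = 0.005, a 50% central
barrier at φ = 0.01 — is a declared placeholder exposed in configuration;
in-pore insertion costs scale as `f_i = (φ_i/φ_barrier)·f_barrier`, and
`f_barrier` is fitted per capsid rather than imposing an `R^α` law, since
the form of the size dependence is not established for cargoes this large.
Flux through the in-pore regions uses the resistor-like steady-state
1D-diffusion sum

    ĵ = 1 / (a_Ran + Σ_i w_i·e^(G_i)),

with w_i the in-pore length fractions renormalized to 1. This functional
form is this package's modelling choice for diffusion across a piecewise
potential; it is isolated behind `profile_flux` and reduces exactly to the
minimal model for a single barrier region. Envelope enrichment is the
Boltzmann weight `e^(−G_vestibule)` against a cytoplasmic G = 0 reference:
a multivalent cargo can accumulate at the envelope (G_vestibule < 0) while
a high barrier still blocks bulk import. The joint fit shares one ε₀
across all capsid datasets (multi-start `scipy.optimize.least_squares`,
ε₀ starts at 2, 5, 8, 12, 15 k_BT) and reports the residual alongside
independent per-capsid fits; on the packaged datasets it lands at
ε₀ ≈ 7.4 k_BT with the default profile.

## Synthetic data: what it emulates, and what it does not

Trace generation draws `n_fov` (default 12) independent fields of view with
additive Gaussian noise per time point; image generation renders elliptical
nuclei with a rim of declared thickness, a cytoplasm beyond a small margin,
reference stains confined to their compartments, and a cargo channel
following each compartment's kinetics, with optional Poisson + Gaussian
pixel noise. No noise magnitude is documented for the original
acquisitions, so the defaults are placeholders chosen for testability, not
inferred values. Synthetic flux datasets apply mean-preserving
multiplicative log-normal noise of chosen CV to the minimal-model flux. The
default #NLS levels for synthetic runs are each capsid's measured values
(0–54, 0–44, 0–98): they keep simulated fluxes out of deep saturation, the
regime the assay itself never reached, where ΔG inversion of noisy fluxes
degenerates. Identical seeds give bit-identical traces and stacks.

Deliberately not simulated: photobleaching, stage drift, cell motion,
mitosis, 3D geometry, single-NPC transport events, and multi-particle pore
occupancy (jamming). Passing round-trip tests therefore demonstrates the
correctness of the analysis chain, not robustness to these real-data
effects.

## Problem sizes and determinism

Tests run on 128×128 px stacks with 40 frames, 200-seed Monte-Carlo
batches for recovery statistics, and a brute-force grid-search oracle
(coarse lattice + 1e-3 refinement) for short-trace fits — sizes chosen so
the whole suite completes in well under a minute. The acceptance script
reruns the fixture fits, the joint vestibule fit, a noiseless image
round-trip and a 200-seed recovery batch from scratch; all randomness
derives from its `--seed`.

## Known limitations

* The exact blur σ and threshold rule of the original analysis script are
  not extractable from the text; defaults here are declared choices.
* The printed τ column's stated unit (1/s) is inconsistent with 2-min
  sampling over 80 min; values are treated as unit-agnostic fixtures.
* The vestibule flux formula and region geometry are this package's
  parameterisation; its quantitative outputs beyond the reduction identity,
  round-trip recovery and the ε₀ band should not be over-interpreted.
* For the largest capsid the ΔG-vs-N trend is nearly flat, so its fit
  leans heavily on the N = 0 point and excluding that point moves F(R)
  beyond one standard error — unlike the two smaller capsids.
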