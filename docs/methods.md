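# Methods

This note records the models the package implements, the estimation
protocol, the synthetic-data conditions used for validation, and the
numerical and design choices a user should know before trusting results on
real data.

## Units and constants

Energies in meV, momentum transfer Q in Å⁻¹, lengths in Å, times in ps.
Rates expressed in inverse time convert to linewidths through
ħ = 0.6582119569 meV·ps; diffusion coefficients convert as
1×10⁻⁵ cm²/s = 0.1 Å²/ps.  Reported D_T values use the conventional
10⁻⁵ cm²/s scale.

## Spectral model

A spectrum at one Q is an elastic line plus Lorentzian quasi-elastic
components on a linear background, damped by the Debye–Waller factor and
convolved with the instrumental resolution:

S(Q,ω) = e^(−⟨u²⟩Q²/3)[A₀(Q)δ(ω) + Σᵢ Aᵢ(Q)L(Γᵢ,ω)] + b₀ + b₁ω,
S_exp = S ⊗ S_res.

- The delta function is realized as the measured resolution lineshape
  itself (the vanadium spectrum, unit-normalized) — the standard numerical
  treatment, since anything narrower than the resolution is
  indistinguishable from it.
- Convolution is discrete linear convolution on the uniform ω grid,
  truncated to the data support; generator and fitter use the identical
  operator, so discretization cancels in round trips.
- Backgrounds (linear term, flat empty-cell level) are *not* convolved:
  they model detector/cell contributions added after the scattering
  process.  The generator follows the same convention.

Motion models:

- translational jump diffusion, Γ_N(Q) = ħD_TQ²/(1 + D_TQ²τ₀), saturating
  at ħ/τ₀;
- rotation confined to a sphere, kept at its first multipole: one
  Q-independent Lorentzian of width Γ_R = 2D_R (higher multipole weights
  are not separable at these statistics and are out of scope);
- elastic fraction A₀(Q) = p + (1−p)[3j₁(QR)/QR]², where p is the fraction
  of protons whose motion is unresolved within the instrument's time
  window and R the confinement radius.

## Elastic-scan reduction

⟨u²⟩ at each temperature is −3× the slope of ln S_el against Q², by
weighted linear regression (weights 1/σ² of ln S).  The Gaussian
approximation degrades beyond ⟨u²⟩Q² ≈ 1, so the fit runs twice: all
usable points first, then only points with u²_fit·Q² ≤ `max_u2q2`
(default 1.0).  If that mask would leave fewer than three points, the
three lowest-Q points are kept and the result flagged
(`window_fallback`) — a hard error is reserved for scans with fewer than
three usable points overall.  Temperatures are fitted independently; the
estimate is invariant under overall intensity rescaling.

## QENS fitting protocol

Per condition: (optional empty-cell handling) → vanadium normalization →
buffer fit → constrained sample fit → EISF → transport parameters.

**Empty cell.**  By default the flat empty-cell level is absorbed by each
fit's background term rather than subtracted bin-by-bin: at realistic
counting statistics the level is comparable to the wing signal, and
subtraction clips a large fraction of wing bins at zero, which biases
weighted fits.  `analyze_condition(subtract_empty=True)` restores the
subtraction path; `subtract_background_spectra` itself propagates errors
in quadrature and logs clipped bins.

**Vanadium.**  Each Q's counts are divided by the vanadium integral at
that Q (relative detector efficiency); the unit-normalized vanadium
lineshape becomes S_res(Q,ω).

**Buffer.**  Two resolution-convolved Lorentzians plus a flat background
per Q, located by a coarse grid scan over the two widths (the model is
linear in the amplitudes at fixed widths, so each grid point is a bounded
linear least-squares solve) and polished with Levenberg–Marquardt from
jittered starts.  The narrow widths are then fitted globally with the
jump-diffusion law — excluding a configurable Q² window (default
2.0–3.0 Å⁻²) around the coherent de Gennes dip of D₂O — and the broad
width is reduced to an error-weighted Q-average.

**Sample.**  Model per Q: frozen buffer pair (per-Q narrow width,
Q-averaged broad width, per-Q fitted intensities) times one solvent
scale, a resolution-shaped elastic line, two free sample Lorentzians and
a linear background.  Fitting proceeds in passes:

1. free per-Q fits (grid scan + polish), giving a first broad-width set;
2. the broad width is frozen at its robust (median) global value — the
   rotational model is Q-independent — and the per-Q fits rerun; these
   supply the reported per-Q narrow widths and their errors;
3. a global variable-projection fit ties the widths together across all
   Q: for trial (D_T, τ₀, Γ_broad, solvent scale) the per-Q amplitudes
   are projected out by bounded linear least squares, so only a handful
   of nonlinear parameters are constrained by every spectrum at once;
4. with all widths and the solvent scale frozen at the global estimates,
   a final amplitude-only pass makes the elastic/quasi-elastic split — the
   EISF — a well-conditioned linear problem at every Q.

Identifiability safeguards, each of which proved necessary on synthetic
data: the sample's narrow width is kept above a quarter of the resolution
width (anything narrower is elastic by definition of the time window);
fits whose widths collapse within 20% of each other, pin at bounds, or
zero out the elastic line are flagged and excluded from EISF/transport
estimation; D_T ≤ 10 Å²/ps and τ₀ ≤ 100 ps stop the degenerate runaway
when noisy widths are Q-flat; the width-law fit uses a soft-L1 loss so a
wrong-basin width cannot dominate.

**Solvent scale.**  Spectra carry a monitor factor, so sample and buffer
share one absolute intensity scale and the buffer component's coefficient
in the sample fit is the physical solvent fill fraction (sample solvent
relative to the neat buffer cell).  When buffer and sample relaxation
rates overlap — the no-sucrose condition here — the spectra carry almost
no information on that coefficient (the profiled χ² changes by well under
one unit across the physically plausible range), while every other
parameter is recovered correctly *conditional* on it.  The pipeline
therefore accepts the composition-derived fill
(`analyze_condition(solvent_fill=...)` — the same knowledge a buffer
subtraction presumes) and pins the scale; when no composition is given
the scale is fitted inside the plausibility window 0.6–1.1 (a hydrated
sample holds neither zero solvent nor more than the neat buffer).

**EISF and geometry.**  A₀(Q) = elastic/(elastic + narrow + broad sample
amplitudes); the buffer and background are excluded (solvent and
instrument, not sample).  Errors propagate through the fitted amplitude
covariance.  The sphere model with immobile fraction is fitted by
weighted least squares with p ∈ [0,1], R ∈ (0.1, 20) Å, starting from a
radius grid because the (p,R) surface can hold two local minima;
bound-pinned or R-unidentifiable solutions (p → 1) are flagged.

**Transport.**  D_T and τ₀ are reported from the joint width fit when it
ran (the per-Q width curve is noisier and its jump-diffusion fit can
degenerate when widths come out Q-flat; a D_T pinned at its bound falls
back to the per-Q route); D_R is half the broad width.  The per-Q widths
remain in `SampleFit` for the classical Γ(Q²) presentation.

## Synthetic data: what it emulates, what it does not

`gen_qens_dataset` composes exactly the spectral model above — which is
the point: the generator/fit pair makes every injected parameter
recoverable in the noise-free limit (verified to machine precision), so
failures under noise isolate estimation problems rather than model
mismatch.  Conditions emulate an aqueous enzyme titrated with sucrose at
310 K on a 20 ps cold time-of-flight instrument:

- instrument: ω ∈ [−5, 5] meV in 0.01 meV steps; Gaussian resolution of
  HWHM ħ/Δt (0.0329 meV for the 20 ps window); 12 detectors at
  Q = 0.4–2.0 Å⁻¹;
- buffer: D_T falling from 0.117 to 0.061 Å²/ps and τ₀ rising from 3.3 to
  5.5 ps with sucrose; rotational width 0.4 meV at half the narrow line's
  intensity;
- protein: jump-diffusion narrow line (e.g. 0.29 Å²/ps, 5.5 ps at 0 wt%),
  broad line 2D_R, elastic fraction from the sphere model (p = 0.726,
  R = 2.11 Å at 0 wt%), ⟨u²⟩ = 0.3 Å², solvent at 20% of the protein
  intensity with fill fraction 0.9, flat empty level at 1% of peak;
- noise: Poisson counts at 10⁴ expected peak counts per spectrum (each
  measurement counted to its own peak, as beam time would be allocated),
  reported uncertainties √(expected) — basing σ on observed counts
  overweights downward fluctuations at low counts and demonstrably biases
  weighted fits.

What passing recovery tests does **not** show about real data: no
absorption or multiple-scattering effects, no detector-to-detector
efficiency structure beyond a scalar, a Gaussian (not measured) resolution
shape, no coherent-scattering dip in the generated widths (the exclusion
window is exercised but cannot be validated against a real dip), and a
solvent whose spectral form is exactly the fit model's.  Real reductions
should treat the recovered uncertainties as lower bounds.

Trajectory generators: free walks (Gaussian steps, variance 2D·dt per
axis), spherical confinement via a *reflecting* wall — rejection
resampling biases the stationary density inward at finite step size,
missing the uniform-sphere plateau 1.2R² — and an alternating
rest/diffusion jump walk with exponential waiting times.

## MD observables

Lag-time MSD averages the squared displacement over all overlapping time
origins and selected atoms.  Per-residue RMSF is computed after iterated
least-squares superposition onto the mean structure, so rigid-body motion
does not count.  Hydrogen bonds use donor–acceptor distance ≤ 3.2 Å and a
D–H⋯A deviation from linearity ≤ 40° (the cutoff applies at the hydrogen);
donors lacking a covalent hydrogen within 1.25 Å are skipped with a
warning.  Contacts count cross-group pairs within the cutoff (default
2 Å, hydrogens included) via a KD-tree, validated against brute force.

## Problem sizes

Validation runs use 12 Q × 1001 ω spectra, 6–20 noise replicates per
condition, trajectories of a few hundred atoms × a few thousand frames,
and 100–300 Monte-Carlo repeats for the linear-regression estimators;
these sizes put every reported mean within a small fraction of its
replicate scatter while keeping the full suite inexpensive on one CPU.

## Known limitations

- At conditions where solvent and protein relaxation rates coincide, the
  solvent/protein attribution is unidentifiable from spectra alone;
  composition knowledge is required (see above), exactly as in a real
  buffer subtraction.
- D_T is weakly identified whenever the narrow width is flat across the
  Q window (saturated jump diffusion); the bound at 10 Å²/ps makes the
  failure explicit rather than silent.
- The EISF's p is tied to the instrument's time window; values from
  different resolutions are not comparable.
- Multipole structure of the rotational line (l ≥ 2) is not modelled.
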