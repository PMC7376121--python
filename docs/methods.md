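# Methods

## DEER forward model and inversion

A 4-pulse DEER measurement of an oligomer with n equivalent nitroxide labels
is modelled as

    V(t) = B(t) · [ (1 − λ) + λ ∫ K(t, r) P(r) dr ] + ε(t),

with modulation depth λ ∈ [0, 1], additive Gaussian noise ε, and an
intermolecular background B(t) = exp(−k t^(d/3)) from a homogeneous spin
bath of dimensionality d (default 3; configurable because membrane-mimetic
samples can deviate). The powder-averaged dipolar kernel

    K(t, r) = ∫₀¹ cos[ (2πD/r³)(1 − 3x²) t ] dx ,
    D = (μ₀/4π) g² μ_B² / h ≈ 52.04 MHz·nm³  (free-electron g),

is evaluated by its Fresnel-integral closed form,
K = √(π/6φ)·[cos φ·C(z) + sin φ·S(z)] with φ = 2πD t/r³ and z = √(6φ/π);
phases below 1e−9 return the exact limit 1. The closed form agrees with a
10⁴-point trapezoid quadrature to better than 1e−6 (tested).

**Background correction.** B is fitted to the trace tail (from a fit-start
fraction of the trace length onward, ≥ 5 points) as s·exp(−k t^(d/3)),
initialised by log-linearisation and refined by nonlinear least squares.
The fitted scale absorbs the (1 − λ) plateau of the form factor, so the
division uses the fitted decay *shape* anchored at the zero-time amplitude
(a quadratic fit through the first points): the resulting form factor decays
from 1 toward 1 − λ, retaining the modulation-depth information. Fits with
negative k (a continuously rising background, i.e. negative apparent
concentration) can genuinely minimise the residual when the dipolar
oscillation is incompletely sampled; they are permitted when
`allow_unphysical` is set and always flagged. The default single-trace
analysis scans the fit start over the same 16-step 5–80 % grid used by the
validation protocol and keeps the start with the lowest full-trace fit RMSD;
a regression test checks that fixing the start at one third of the trace
gives an essentially identical distribution on clean data.

**Tikhonov inversion.** P(r) is the minimiser of
‖(1−λ) + λKP − F‖² + α²‖L₂P‖² subject to P ≥ 0, with L₂ the second-difference
operator. Rather than nesting a 1-D λ search around the solver, the problem
is solved once in the unnormalised variable Q = λP, in which it is a single
stacked non-negative least-squares system

    min ‖ [ (K−1)Δr ; αL₂ ] Q − [ F−1 ; 0 ] ‖²,  Q ≥ 0,

solved with `scipy.optimize.nnls`; λ is the integral of Q and P = Q/λ is
returned with unit trapezoid integral. The solution matches an independent
bounded-variable least-squares oracle (`scipy.optimize.lsq_linear`) to
< 1e−6 per bin on 30-bin instances (tested). The default distance grid is
1.5–8.0 nm in 0.05 nm steps; time is in µs from 0.

**α selection.** α is chosen at the corner (maximum curvature) of the
log-residual vs log-penalty L-curve over a 24-point grid spanning 1e−4–10.
Two degenerate cases fall back to the median α with a warning: a residual
that is flat over the whole grid (pure noise — regularisation costs nothing)
and a curve with no positive-curvature interior point (noiseless data — the
L has no corner). Both fallbacks err on the side of more smoothing.

**Validation ensemble.** Robustness of P(r) is quantified by re-running the
background fit + inversion for 16 equally spaced fit-start fractions in
[0.05, 0.80], 50 trials each (800 total), each trial adding Gaussian noise
with sd equal to 0.5× the trace's estimated noise sd (from the residuals of
a Savitzky–Golay smoothness fit; "50 % random noise" is interpreted relative
to the noise level, not the signal amplitude — a config switch records the
alternative). α is selected once on the unperturbed trace and held fixed.
Trials with fit RMSD more than 15 % above the best are discarded (ties at
exactly 1.15× are kept; the best trial is always kept, so the kept set is
never empty), and the kept trials define pointwise mean ± 2σ bands (lower
band clipped at 0). Solver failures are counted and reported, never silently
dropped.

**Multispin suppression.** For n > 2 coupled spins the measured form factor
is approximately the product of pair form factors, which creates spurious
sum-combination peaks below D1. Power scaling replaces F by F^(1/(n−1))
(identity for pairs; exponent 0.25 for a pentamer) after flooring
non-positive values at 1e−3 with a warning. On a synthetic 5-spin product
trace the integrated P(r) mass outside the true modes drops to zero after
scaling (tested).

**Reliability ranges.** Given a trace of length t_max (µs), the longest
distances for which the shape, width and mean of P(r) are trusted are
4.0, 5.0 and 6.0 nm × t_max^(1/3) respectively — fixed rule-of-thumb
constants encoding the r³ scaling of the dipolar period.

## 3pESEEM accessibility

The echo envelope of the π/2–τ–π/2–T–π/2 sequence is modelled per weakly
coupled nucleus (degenerate-frequency limit) as

    E_i(T) = 1 − (k_i/2)(1 − cos ω_i τ)(1 − cos ω_i(τ + T)),

multiplied over nuclei and by a stretched-exponential decay
A·exp(−(T/τ_d)^β). The same I = 1/2-style expression is used for ¹H and an
effective ²H line, the I = 1 deuterium enhancement being absorbed into the
amplitude k — only relative accessibility is quantified, so the spin-physics
prefactor cancels. At τ = 2/ν (an integer number of 2π in ωτ) a nucleus's
modulation vanishes identically: the proton blind spot, ≈ 138.8 ns at
9.5 GHz and g = 2.006 (set as "≈ 140 ns" in practice), suppresses the ¹H
line by many orders of magnitude while leaving ²H modulations near maximal.

**Decay normalisation.** The stretched exponential is fitted to the real
trace (log-log linearised initialisation, bounded β ∈ [0.05, 2]). Deep
coherent modulation biases a plain decay fit — the early-time modulation dip
masquerades as slower decay — so if the fit residual carries a dominant
spectral tone the decay is refit jointly with a single cosine and only the
decay part is kept; this recovers τ_d within 10 % under 40 %-deep modulation
(tested) and reduces to the plain fit when no tone is present. Undecaying
traces (tail ≥ 99 % of the initial level) are unidentifiable in β and return
a flat model flagged `at_bound` with a warning. The trace is then normalised
as (V − f)/f, which retains modulation depth and is exactly independent of
the overall amplitude A.

**Spectrum and readout.** The normalised modulation is apodised with the
descending half of a Hamming window — the trace is a one-sided decaying
signal, and the tail, where division by the decayed envelope has amplified
the noise, is de-weighted — zero-filled to 2× the next power of two, and
Fourier transformed (frequency axis in MHz for the 12 ns default sampling).
A single zero-order phase, found in closed form, minimises the squared
imaginary amplitude over 0.5–8 MHz. The accessibility is the maximum of
|spectrum| within one frequency bin of the deuterium Larmor frequency
computed from the acquisition metadata (ν = γ_²H·hν_e/(g μ_B), CODATA
constants) — the one-bin window tolerates small field-calibration offsets
between the computed and the apparent line position. The error is the RMSD
of the imaginary part over the signal-free 3.5–8 MHz band (a time-domain
residual estimate is available as a config switch). Percent changes between
conditions use first-order error propagation.

Note that the readout is mildly superlinear in the modulation amplitude:
the spectral intensity scales as k/(1 − c·k) because the decay fit absorbs
the k-dependent DC factor of the modulation, so a +30 % programmed amplitude
difference at k ≈ 0.1 reads out as ≈ +32 %. Both conditions of a comparison
carry the same mapping, so relative ordering is preserved; recovery tests
use the small-k regime where the distortion is within the stated tolerance.

## Accessible-volume label model

Label positions are modelled as midpoints sampled uniformly in a spherical
shell of 0.4–1.0 nm around the attachment residue's Cβ (Cα + 0.15 nm along
N→Cα for glycine), in a local frame built from the residue's own atoms so
that clouds transform equivariantly under rigid motions of the model.
Candidates closer than a clash cutoff to any retained heavy atom (the
labelled residue excluded) are rejected; "tight" van-der-Waals restraints
map to 0.25 nm and "loose" to 0.20 nm — documented constants approximating
a rotamer-library search by its midpoint statistics, which is the quantity
that feeds distance distributions. This is a deliberate fidelity limit: no
rotamer scoring, no induced fit. Oligomer predictions label every chain
carrying the site, order the clouds around the ring by angle, and pool
nearest-neighbour and next-nearest histograms (5 + 5 pairs for a pentamer).

Peak analysis reports local maxima above 10 % prominence of the global
maximum (merged within 2 grid steps), splits weights at inter-peak minima,
and flags a distribution pentamer-consistent when D2/D1 ∈ [1.55, 1.70]
(window around 2cos 36° = 1.618).

## Synthetic data: what it does and does not emulate

The simulators reproduce the statistical structure the analysis assumes:
C5 geometries with per-site Gaussian jitter, exponential backgrounds,
modulation depths ~0.1–0.5, additive Gaussian noise (independent on the
real and imaginary ESEEM channels), proton blind-spotting, and 12 ns ESEEM
sampling. Defaults where no study condition dictates a value: DEER λ = 0.3,
noise 1 % of V(0), traces of 2.5–3 µs at ~150–250 points; ESEEM decay
(A = 1, τ_d = 1500 ns, β = 0.8) with a 4.8 µs window — typical of nitroxide
echo decays at cryogenic temperatures. Not emulated: orientation selection,
excitation-bandwidth effects, full ESEEM spin Hamiltonians (quadrupole,
combination lines), phase noise, and baseline drifts beyond what the
stretched-exponential correction leaves behind. Passing tests therefore
demonstrate correctness of the analysis chain under its own model
assumptions, not robustness to every experimental artifact.

Problem sizes used in tests and in `scripts/acceptance.py` (150–250-point
traces, 30–130-bin distance grids, 800-trial ensembles, 10–20 ESEEM seed
pairs) keep the full suite in the tens of seconds while leaving every
statistical check comfortably resolved.

## Numerical choices and edge cases

- All seeds are explicit arguments; no global RNG state. Fixed seeds make
  every simulator bit-reproducible.
- Trace axes must be strictly increasing and uniform (1e−6 relative
  tolerance); NaNs are rejected with line numbers on read.
- Distributions are renormalised on write; on read, drift > 1e−3 triggers a
  warning and renormalisation; negative densities are rejected.
- λ = 0 inversions (no dipolar signal) return a flat distribution with zero
  depth rather than failing.
- The RMSD filter keeps ties at exactly the 1.15× cut.
- PDB coordinates are converted Å → nm on read; altlocs keep the highest
  occupancy; waters, heteroatoms and hydrogens are excluded; 1-based residue
  numbering is preserved.
- CLI runs write a manifest (config snapshot with provenance, seeds, input
  SHA-256 hashes, package version); exit codes are 0 (success), 2 (input or
  validation errors), 64 (unknown flags).

## Known limitations

- The accessible-volume model ignores rotamer energetics; predicted widths
  are upper bounds on real label flexibility.
- The L-curve corner is a heuristic; strongly correlated noise can shift the
  selected α. The validation ensemble, not the single inversion, is the
  instrument for judging which features of P(r) are robust.
- ESEEM percent changes inherit the k/(1 − c·k) mapping discussed above;
  comparisons between conditions with very different absolute modulation
  depths should be interpreted with that in mind.
- Power scaling assumes equivalent spins and full pump efficiency; partial
  excitation leaves residual ghost mass.
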