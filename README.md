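# pentaspin

Pulse-EPR analysis of oligomeric spin-labelled membrane proteins — built for
studies of pentameric mechanosensitive channels (MscL-type) in lipid
nanodisks, but applicable to any Cn-symmetric nitroxide-labelled complex.

The package implements two measurement chains end to end, together with
forward simulators that make every stage testable without experimental data:

**DEER/PELDOR distance recovery.** A 4-pulse DEER trace
V(t) = B(t)·[(1−λ) + λ∫K(t,r)P(r)dr] is inverted to the inter-label distance
distribution P(r): the intermolecular background B(t) = exp(−k·t^(d/3)) is
fitted to the trace tail and divided out, and the form factor is inverted
with non-negative Tikhonov regularisation (second-derivative penalty,
L-curve-selected α, powder-averaged dipolar kernel
K(t,r) = ∫₀¹cos[(2πD/r³)(1−3x²)t]dx with D ≈ 52.04 MHz·nm³). Robustness is
assessed with a validation ensemble: the background fit start is scanned
over 5–80 % of the trace in 16 steps with 50 noise-perturbed re-inversions
each (800 trials), trials more than 15 % above the best RMSD are discarded,
and the kept trials define mean ± 2σ confidence bands. Multispin ghost peaks
of a pentamer are suppressed by power scaling, F → F^(1/(n−1)). For a
symmetric pentamer the two recovered distances must satisfy
D2/D1 = 2cos(36°) ≈ 1.62 — the geometric fingerprint the analysis tests for.

**3pESEEM deuterium accessibility.** A three-pulse ESEEM trace recorded at
the proton blind spot (τ = 2/ν_H ≈ 140 ns at X-band) is normalised by a
fitted stretched-exponential echo decay (subtract, then divide — retaining
modulation depth), Hamming-apodised, zero-filled and Fourier transformed;
the solvent (²H) accessibility is the absolute spectral amplitude at the
deuterium Larmor frequency, with an error from the imaginary-part RMSD of
the phase-corrected spectrum. Accessibilities of two conditions (e.g.
detergent vs nanodisk) are compared as a signed percent change with
propagated errors.

A third module predicts inter-label distance distributions from PDB
structures with a simplified accessible-volume label model (shell sampling
around Cβ with clash rejection), for comparing recovered distributions
against structural expectations.

## Worked example

Simulate a pentamer DEER measurement and invert it:

```python
import numpy as np
import pentaspin as ps

geom = ps.make_cn_geometry(5, 2.2)          # C5 ring, radius 2.2 nm
pr = ps.geometry_to_distribution(geom, ps.deer.default_r_grid(), width_sd=0.08)
params = ps.DeerParameters(mod_depth=0.3, bg_rate=0.15, noise_sd=0.01,
                           time_axis=np.arange(0.0, 3.0, 0.012))
trace = ps.simulate_deer(pr, params, seed=1)

res = ps.DeerModel(trace).fit()
print(res.summary())
```

```
DEER distance-distribution fit
==============================================
trace length             2.988 µs (250 pts)
r grid                1.50-8.00 nm, step 0.050
background rate k       0.1167 /µs
background fit start     0.650 of trace
modulation depth        0.3656
regularization alpha    0.3008
fit RMSD               0.01127
reliability (nm)      shape<5.76 width<7.20 mean<8.64
peaks (nm)            2.60, 4.20, 7.35
D2/D1 ratio              1.615  (pentamer-consistent: True)
```

The ground-truth distances of this geometry are D1 = 2.586 nm and
D2 = 4.185 nm: both peaks are recovered to within one grid step, and their
ratio 1.615 sits at the pentagon value 2cos 36° ≈ 1.62, flagging the
distribution as consistent with a symmetric pentamer (the 7.35 nm bump is a
noise artifact outside the reliable shape range). `res.validate(seed=1)`
runs the 800-trial ensemble and returns the ± 2σ confidence bands shown by
`res.plot(ensemble=...)`.

The ESEEM chain works the same way: `ps.EseemModel(trace).fit()` returns the
fitted decay, the phase-corrected spectrum and the ²H peak intensity, and
`nd_result.compare(detergent_result)` gives the percent accessibility change
± propagated error. With a programmed +30 % amplitude difference at 1 %
noise, ten simulated condition pairs give a mean recovered change of
+31.2 % (sd 7.9).

A CLI exposes the same operations as reproducible, manifest-writing runs:

```sh
pentaspin simulate-deer --seed 1 --out-dir run1
pentaspin invert run1/deer_trace.txt --out-dir run1_inv
pentaspin validate run1/deer_trace.txt --out-dir run1_val
```

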