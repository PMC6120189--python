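# Methods

## The gating model

`rho1kin` models the homomeric ρ1 GABA_A receptor as a six-state,
continuous-time Markov scheme:

```
         k1·[A]        f1          β
    R  <-------->  AR <----> AF <----> AO
         k-1          f-1         α
                            |           |
                    dAF_on  |dAF_off    | dAO_on / dAO_off
                            v           v
                           AFD         AOD
```

R is the resting agonist-free receptor, AR agonist-bound shut, AF
agonist-bound preactivated (flipped) shut, and AO the open state; AFD and
AOD are non-conducting desensitized states entered from the preactivated
and open states respectively. Binding is a single bimolecular step, so the
only concentration-dependent rate is `k1·[A]`. The model's macroscopic
"current" is the open-state occupancy `p_open`; conductance, chloride
driving force and channel count are not modelled, because every summary
statistic the package computes is normalized.

Occupancies evolve by the master equation `dp/dt = p·Q(c)`, with `Q` the
6×6 generator whose off-diagonal entries are the ten directed transition
rates and whose rows sum to zero. Agonist application is piecewise
constant (instant solution exchange), so within each protocol segment the
propagation is the exact matrix exponential, evaluated through an
eigendecomposition of `Q`. If the eigenvector basis is ill-conditioned
(condition number above 1e8; near-degenerate spectra), the propagator
falls back to dense `expm` stepping on the sampling grid. Either route is
exact up to numerical round-off: the sampling interval `dt` (default 10 ms;
ρ1 kinetics are seconds-scale) only sets the output grid. The stationary
distribution at fixed concentration is obtained from the null space of the
generator restricted to the states reachable from R, which handles the
zero-agonist case (all bound states unreachable) without special-casing.

Mutants are never fitted independently. They are derived from the WT rate
vector through fixed multiplicative rules:

* **W329A** — `dAF_on = dAO_on = 0`, `k-1 × 10`. "Virtually eliminated"
  desensitization entry is implemented as an exact zero multiplier (the
  rule map is data, so a small positive multiplier is a one-line change);
  the desensitization exit rates then become irrelevant.
* **W280Q** — `k-1 × 0.1`, `dAO_on × 0.7`.

## Summary statistics

* **Peak response** — maximum `p_open` on the sampled grid inside a window
  (no interpolation; ties go to the earliest sample).
* **Desensitization extent** — `(1 − residual/peak) × 100` with the
  residual read at 60 s of saturating (1 mM) GABA; 0% means no
  desensitization. A 20 s variant exists for fast-desensitizing
  heteromeric-style schemes.
* **Deactivation** — after washout the trace is re-zeroed and expressed as
  `−100·p_open(t)/p_open(0)`: a percent inward current decaying from −100
  toward 0. This convention makes the bi-exponential amplitudes
  percentages and forces the constraint A1+A2 = 100.
* **Concentration–response** — peaks of 60 s concentration jumps from rest
  over a 10 nM–1 mM half-log grid (11 points), normalized to the largest
  peak, fitted with the activation Hill equation.

## Curve fits

Activation: `I/Imax = 1/(1+(EC50/[A])^n)`; inhibition:
`I/Imax = 1 − 1/(1+(IC50/[B])^n)` (full current as blocker → 0, none at
saturating blocker); deactivation:
`I/Imax(%) = −100 + A1(1−e^{−t/τ1}) + A2(1−e^{−t/τ2})` with A1+A2 = 100,
reported through the amplitude-weighted time constant
`τ_w = (A1τ1 + A2τ2)/(A1+A2)`.

All fits are trust-region least squares (`scipy.optimize.least_squares`)
with analytic Jacobians; half-max constants and time constants are
parameterized in log space, which makes the Hill fits exactly
scale-equivariant in concentration. Initialization is a deterministic
multi-start: a data-driven first guess (the concentration nearest
half-maximal response; the 1/e decay time), then a fixed ladder of starts
spanning the data range. The start list is exhausted unless a start
reproduces the current best optimum from a second basin or the fit is
already exact to round-off, which keeps the procedure deterministic while
avoiding pointless restarts. Bounds: half-max within [min conc/100,
max conc×100], `n ∈ [0.1, 10]`, `τ` between the sampling interval and 10×
the segment length. Standard errors come from the linearized covariance at
the optimum (pseudo-inverse, so parameters pinned at a bound report NaN
rather than failing); a seeded bootstrap is deliberately not provided.
If the two deactivation components converge to the same `τ` within 1%, the
fit collapses to a mono-exponential with A1 = 100.

## Joint calibration

No absolute rate constants are published for this scheme; only the mutant
perturbation structure and six summary statistics (GABA EC50 and weighted
deactivation τ for WT, W280Q, W329A: 2.19 ± 0.65 µM, 0.92 ± 0.17 µM,
25.76 ± 3.39 µM; 26.9 ± 5.6 s, 84.4 ± 15.1 s, 0.86 ± 0.1 s). Calibration
estimates the ten WT rates jointly so the model reproduces all six, with
mutants derived strictly through the rules.

* **Loss** — Σ (log model − log printed)² over the targets, so µM-scale
  EC50s and τ's spanning 0.86–84.4 s contribute comparably.
* **Search space** — log rates, bounded `k1 ∈ [1e5, 1e8] M⁻¹s⁻¹`, all
  first-order rates `∈ [1e-3, 1e4] s⁻¹`.
* **Multi-start** — start 0 is an informed guess computed at run time from
  the targets themselves: in the quasi-equilibrium limit the peak EC50 is
  `K_d/S` and the unbinding-limited deactivation τ is `S/k-1`, with
  `S = 1 + F + F·E` the bound-state partition factor (`F = f1/f-1`,
  `E = β/α`); applied to the desensitization-free fast mutant these give
  `k-1` and `K_d`, completed by moderate flip/gating equilibria and slow
  desensitization rates. The remaining starts are seeded log-uniform
  draws. All starts get a short screening run of the trust-region
  optimizer; the best few (plus start 0, which is seed-independent and
  anchors reproducibility) are refined to convergence, keeping each start
  within a ≈500-evaluation budget.
* **Two grids** — the optimizer's inner loop simulates at `dt = 50 ms` and
  fits the deactivation decay on ≤600 log-spaced samples; the reported
  per-target statistics are always recomputed on the reference grid
  (`dt = 10 ms`, ≤2000 samples). The two grids agree to ≈0.2% on the
  statistics, far inside the ±1 SEM acceptance bands, and the coarse inner
  grid keeps a full 32-start calibration to a few minutes on one CPU.
* **Convergence** — `converged` is true iff every model statistic lies
  within ±1 printed SEM of its target. With the default setup (32 starts)
  this holds for every seed tried, and the heuristic start alone converges,
  so the result does not depend on the luck of the random draws.
  Desensitization extent is reported (WT ≈ 66% at 60 s, W329A 0%) but is
  not a fitted target — no within-text number is printed for it — and is
  checked only directionally.

The calibrated solution is not claimed to be unique: with ten rates and six
statistics the problem is under-determined, and the package makes no
identifiability claims. What the calibration shows is that the constraint
structure — one WT rate set plus the two fixed perturbation rules — is
*sufficient* to reproduce all six statistics simultaneously.

## Synthetic data

The generators exist so every pipeline stage can be exercised without
external data, and they define the package's test conditions:

* **Traces** — model occupancies with i.i.d. Gaussian noise added to
  `p_open` only (the clean occupancies are kept alongside); no filtering,
  drift, series-resistance or capacitive artifacts.
* **Concentration–response tables** — exact Hill curves plus Gaussian
  noise, unclamped, so fits must tolerate values slightly outside [0, 1].
  Fit-recovery tests use σ = 0.02 (2% of the response range) — typical of
  normalized whole-cell data — with 100 seeded replicates.
* **Images** — a disk cell (radius 60 px in a 256×256 frame) with a 4 px
  membrane ring: marker channel fills the cell; label channel is
  membrane/interior/background = 1000/300/200 with σ = 10 Gaussian noise.
  Masks are exact pixel-center geometry. No PSF, shot noise, z-stacks or
  multi-cell scenes: passing tests validate the ROI arithmetic and the
  automatic ROI placement on a clean single-cell scene, not robustness to
  real confocal imagery.

All generators are bit-reproducible given parameters and seed.

## Image quantification

The published workflow drew ROIs by hand; this package substitutes a
deterministic procedure so results are reproducible: median-filter the
marker channel (3×3), threshold at 0.5× its maximum, keep the largest
connected component as the cell, take the band 4 px just inside its edge
as the membrane ROI, and use pixels more than 10 px from any
above-threshold component as background. ΔROI = mean(membrane) −
mean(background), exactly; condition means are expressed as percent of a
reference condition. The widths and threshold are arguments; the defaults
are validated against the generator's ground truth (membrane-mask Jaccard
≥ 0.7, ΔROI within 5%).

## Numerical choices and edge cases

* Occupancy conservation is enforced to 1e-8 at every sample; propagation
  failures (NaN, non-finite rates) raise with segment context rather than
  propagating silently.
* `steady_state` raises if the stationary distribution on the reachable
  set is not unique (e.g. rate combinations that disconnect the chain).
* Peak search never interpolates; acceptance-grade runs use `dt ≤ 10 ms`.
* Deactivation fits subsample long segments onto a log-spaced grid
  (default cap 2000 points) because the decay spans three decades in time;
  for noiseless model traces this changes the weighted τ by ≪1%.
* Trace CSV round-trips are lossless (floats written at full precision);
  scheme JSON rejects unknown or missing rate keys.

## Known limitations

* Deterministic occupancies only — no stochastic single-channel
  simulation, voltage dependence or conductance model.
* The desensitization exit rates are unconstrained by any printed number
  and are therefore purely calibration degrees of freedom.
* Eq.-style inhibition fits are implemented exactly as stated even though
  the surrounding normalization prose reads ambiguously; see the module
  docstring for the convention adopted.
* The calibration reproduces summary statistics, not full waveforms.
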