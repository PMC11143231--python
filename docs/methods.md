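# Methods

`genosc` implements a family of deterministic models of a single-gene
autoinhibitory circuit — a gene whose protein product (a transcription
factor, TF) represses its own transcription — together with the analyses
that expose how the model's level of mechanistic detail, and the assumed
cooperative-binding mechanism, change the predicted phenotype.

## The model family

All variants share the same biology: transcription at rate αm gated by a
monotone-decreasing regulatory function R(c), translation at rate α per
transcript, and first-order degradation (γm for mRNA, γ for protein).  All
rates are per minute; concentrations are molecule counts.

* **Model I** (2 ODEs): transcription and translation are instantaneous.
  m' = αm·R(c) − γm·m, c' = α·m − γ·c.  By the Bendixson–Dulac criterion
  (divergence −γm − γ < 0 everywhere) this planar system can never
  oscillate, whatever the nonlinearity of R.
* **Model II** (4 ODEs): the open-DNA state m0 and the translation
  initiation complex c0 are resolved, with effective elongation rates
  β1, β2.
* **Chain model** (N+M+4 ODEs): elongation resolved step by step, N
  transcript and M peptide stages, each a first-order step with rate r1 or
  r2.
* **Model III** (4 ODEs + 2 discrete lags): the elongation chains replaced
  by discrete delays τ_N = N/r1 and τ_M = M/r2, the limit of the chain as
  the number of stages grows at fixed mean delay.
* **Models IV/IV_full/QSS** (explicit promoter): a cis-regulatory system
  (CRS) of three identical TF binding sites evolves by mass action; the
  gene transcribes only from the empty state a0.  IV_full keeps the TF
  molecules sequestered by binding (conserving a0+a1+a2+a3 = 1); IV drops
  that flux (valid when TF copies ≫ 3); QSS equilibrates the promoter,
  leaving c' = α·R_adair(c) − γ·c.
* **Model V** (5 ODEs): promoter kinetics plus separate transcription and
  translation.
* **Delayed-CRS model** (4 ODEs + kernel): model V reduced by the linear
  chain trick.  With m′ = (α/γ)m, the protein the promoter sees is the
  delayed/filtered D[m′]; the exact reduction gives the weak (shape-1
  Erlang, rate γ) kernel.  Strong (shape-2) and discrete kernels stand in
  for further lumped downstream processes.

All variants share one scalar fixed-point equation, γγm·c = ααm·R(c)
(or γc = αR(c) for IV/QSS); what differs is the *stability* of that point.

## Cooperative binding: recruitment vs stabilization

The six CRS rates derive from three parameters: binding rate p, unbinding
rate q, cooperativity intensity ε ≥ 1.  Recruitment (RM) multiplies binding
rates by ε^i; stabilization (SM) divides unbinding rates by ε^i.  The two
mechanisms share every equilibrium constant K_i, hence the same Adair
regulatory function R(c) = (1 + cK1 + c²K1K2 + c³K1K2K3)⁻¹ and the same
fixed point — but not the same dynamics.  The phenomenological map reports
Kd (the half-repression root of R = 1/2, by bracketed bisection, absolute
tolerance 1e-10) and nH (the Hill-plot slope −d log[R/(1−R)]/d log c at
Kd, evaluated analytically).  For a true Hill curve that slope is constant
and the map is the identity; for any 3-site Adair curve 1 ≤ nH ≤ 3.

## Numerics

* **Integrator**: fixed-step explicit RK4; discrete delays by the method of
  steps, reading the past through cubic Hermite interpolation of the stored
  solution (matching the scheme's 4th order; the cos-DDE oracle reproduces
  the analytic solution to ~1e-14 at step 1e-3).  Erlang delays are
  chain-expanded exactly before integration, never approximated.  The
  integrator does not clip negative states; a non-finite state aborts with
  a timestamp.  An LSODA fallback is available for stiff delay-free runs.
* **Default step 0.005 min.**  Scenarios with fast promoter kinetics
  override it (0.001 for the γ = 4.6 kernel comparison; 5e-4 for the
  f = 1.5 regime, where the RM binding rate ε²p·c reaches ~2×10³/min on the
  limit cycle and explicit stability demands h ≲ 1e-3).
* **Characteristic roots**: delay-free systems use the Jacobian eigenvalues
  (the analytic Jacobians are validated against central finite differences);
  discrete-delay systems use damped-Newton iterations on
  χ(λ) = det(λI − A − Σ B_j e^(−λτ_j)) from a seed grid (default
  Re ∈ [−20, 5], Im ∈ [0, 60] min⁻¹, 40×40 seeds, dedupe 1e-6, conjugates
  by symmetry).  Newton steps are damped to magnitude ≤ 5 to keep iterates
  in range.
* **Classification tolerances**: |Im λ| > 1e-8 separates spiral from node;
  |Re λ| < 1e-7 is marginal and defers to the simulation cross-check.  A
  root-vs-simulation conflict is reported as "inconclusive", never
  silently resolved.
* **Oscillation summaries**: first 50% of the span discarded (40% for the
  long-lag f = 1.5 scenario, whose period is ~18 min), at least 4 peaks
  required, peaks refined by local parabola.  The decay ratio is the
  geometric mean of consecutive peak heights *measured from the window
  mean* — raw values hover near the fixed point (~130 molecules in the
  f-scan), so raw ratios would read ~1 even for a strongly damped spiral.
  "Sustained" means decay ratio within 1 ± 0.02 and relative excursion
  above 1e-5; the latter floor rejects numerical ripple on converged
  trajectories (it would also reject a genuinely microscopic limit cycle
  very close to a Hopf point, an accepted trade-off).
* **Hopf scans** bisect the sign of the leading root's real part; if the
  sign does not change over the interval the result says so explicitly.

## Scenario registry and assumed values

Every registry entry tags each numeric field with its provenance; fields
not fixed by the published regimes are marked "assumed" and are ordinary
config values:

* the Fig.-2-style regime uses αm = 33, γm = γ = 0.23, α = 4.5, Kd = 40,
  nH = 2, with lumped delays τ_N = 20.8, τ_M = 2.8 min and single-step
  elongation rates r1 = r2 = 2.0/min (the effective rates β_i = 1/τ_i do
  not depend on the r's).  The phenotype triple — model I converges, model
  II is a damped spiral, model III sustains ~70-min oscillations — is
  robust to the r choice; only the number of peaks inside a fixed window
  changes, so that scenario runs 1000 min.
* the kernel-comparison scenario (p = 0.246, q = 30, ε = 10, γ = 4.6) is
  run with weak, strong and discrete kernels from a far start (empty
  promoter).  The strong kernel preserves the weak kernel's *mean*
  (rate 2γ) by default; a rate-preserving option exists.  The discrete lag
  for this scenario is not fixed by the source regime and is set to the
  assumed τ = 3.5 min; with it the discrete-kernel system is a weakly
  damped spiral (leading root Re ≈ −0.03), so this scenario demonstrates
  kernel-order dependence of the transient rather than a Hopf crossing.
* the f-scan (ε = 8.5, p = f·0.1, q = f·43, τ = 3.5 min) uses γ = 0.23
  (not printed for that regime; matching the Fig.-2 regime), with a
  γ = 4.6 sensitivity variant registered alongside.  Initial histories are
  likewise unprinted; scenarios start from a constant history at the fixed
  point with the TF coordinate scaled by 1.2 and the promoter at detailed
  balance for that level.  A far-from-equilibrium start (empty promoter,
  zero protein) sends the TF transiently to ~2800 molecules, which makes
  the RM binding term ε²p·c stiff beyond any practical explicit step at
  f = 1.5; the perturbed-equilibrium start stays in the physiological range
  and lands on the same attractor (verified: limit-cycle amplitude is
  start-independent to 2%).

## What the synthetic fixtures emulate — and what they do not

The "data" of this analysis are parameter regimes, not measurements.  The
fixture sampler draws residence times q⁻¹ log-uniformly over 2–100 s (the
range single-molecule tracking reports for specific regulatory sites),
p ∈ [0.001, 1]/min, ε ∈ [1, 20], and synthesis/degradation rates around
segmentation-clock magnitudes, using numpy's PCG64 generator with explicit
seeds.  These batches exercise both mechanisms and all variants, but they
are idealized: real promoters have non-identical sites, extrinsic and
intrinsic noise, and cell-to-cell parameter variation, none of which is
modelled.  Passing tests therefore certify the deterministic mathematics
of the model family, not agreement with any experimental time series.

## Design choices where the design was open

* nH is defined as the Hill-plot slope at half-occupancy (constant and
  equal to nH for a true Hill curve); a functional estimator
  (`phenomenological_fit`) provides an independent numerical route used for
  cross-validation.
* ε < 1 (anti-cooperativity) is rejected rather than extrapolated.
* The Erlang kernel is implemented in normalized form
  r^k τ^(k−1) e^(−rτ)/(k−1)! with mean k/r (the form consistent with the
  chain-trick derivation and the stated mean n/r).
* Symbolic stability proofs for the promoter models are replaced by numeric
  verification: eigenvalue checks over a 10⁴-point seeded Latin hypercube
  of (p, q, ε, α, γ) find no unstable point for model IV.
* State ordering is fixed per variant (m0, m, c0, c; a0, a1, a2, [a3],
  m′) so trajectory CSV columns are stable.

## Known limitations

* Fixed-step explicit integration: stiff regimes need a manually reduced
  step (the registry encodes suitable values); there is no adaptive DDE
  error control with discontinuity tracking — unnecessary at these problem
  sizes but a limitation for very long lags or extreme rate ratios.
* The rightmost-root search is a seeded local method; roots far outside the
  search box are invisible (irrelevant here, where oscillation frequencies
  are below 1/min).
* Mechanism comparisons are ordering-based (RM faster than SM, differences
  shrinking with faster CRS kinetics); no absolute frequencies are claimed
  beyond what the simulations compute.
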