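# Methods

This note documents the models and estimators implemented in
`crowdtransport`, the assumptions behind the synthetic data used to
validate them, and the numerical choices that are not obvious from the
code.

## Unit system and constants

All quantities are carried internally in Å / ns / cP / K / bar / g/L /
mM. The only physical constant entering any formula is
k_B = 1.380649×10⁻²³ J/K; every conversion between this unit system and
SI is centralized in `units.py`, including the number-density
conversion 1 Å⁻³ = 1.66054×10⁶ mM used for dissociation constants.
Boxes are restricted to cubic, because every finite-size correction
implemented here is derived for cubic periodicity; per-frame box edges
(NPT production) are reduced to their mean L before corrections are
applied.

## Green-Kubo viscosity

The zero-shear viscosity is the τ→∞ limit of the running integral
η(τ) = V/(k_B T) ∫₀^τ ⟨P_αβ(t)P_αβ(0)⟩ dt. The estimator follows the
many-short-trajectories protocol:

1. The autocorrelation is computed per trajectory by FFT with the
   unbiased (N−k) normalization and averaged over all nine tensor
   components with equal weight, without imposing symmetry. The mean
   removed from each component is the **ensemble-pooled** mean, not the
   per-series sample mean: subtracting a series' own mean constrains
   its autocorrelation to sum to zero over the record, which biases the
   running integral downward by an amount comparable to the integral
   itself once τ reaches a few percent of the series length. Pooling
   over n trajectories reduces that bias by 1/n.
2. η_i(τ) is integrated per trajectory (cumulative trapezoid — second
   order, adequate for 4 fs sampling); the ensemble mean η(τ) and
   standard deviation σ(τ) follow.
3. σ(τ) is fit to a power law Aτ^b on log-log axes.
4. The mean η(τ) up to τ_max is fit, with weights ∝ 1/σ(τ), to the
   time-integrated double-exponential
   η(τ) = A[ατ₁(1−e^(−τ/τ₁)) + (1−α)τ₂(1−e^(−τ/τ₂))], whose plateau
   A[ατ₁ + (1−α)τ₂] is the viscosity estimate. The functional form is
   recorded in the estimate's metadata. The fit is multi-start (nine
   log-spaced (τ₁,τ₂) starts including a sub-grid pair that represents
   an already-plateaued curve), uses an analytic Jacobian, and caps the
   time constants at 3τ_max — components slower than the fit window are
   unconstrained by the data and destabilize the extrapolation.
5. τ_max is chosen as the smallest candidate whose estimate differs
   from the next candidate's by less than the cross-trajectory standard
   error at that lag; a monotonically drifting estimate raises an error
   advising longer series.

The reported uncertainty is σ(τ_max)/√n_traj. Ratios of viscosities
carry extreme-ratio bounds (η∓u)/(η_ref±u_ref).

## Translational diffusion

D_t is the slope/6 of a linear least-squares fit to the center-of-mass
MSD over a lag window (default 2–10 ns, avoiding short-time anomalous
behavior and long-time noise); the intercept is free, so an anomalous
offset does not bias the slope. The MSD uses all sliding time origins
(FFT evaluation) averaged over molecules; per-molecule curves are kept
so a standard error across molecules can be formed. The periodic
correction D_t = D_t,PBC + k_B T ξ/(6πηL) uses
ξ = 2.837297 − 4πR_p²/(3L²); R_p defaults to 0 and should be set to the
radius of the sphere with the molecule's volume — the same size
convention as the colloid analysis — when the molecule is an
appreciable fraction of the box. The optional water-model rescaling
multiplies by η_model/η_experiment (default 0.334/0.890 cP, the
simulated-to-experimental water viscosity ratio at 298 K).

## Rotational diffusion

Each frame's Cα sites are superposed on the first frame by unweighted
least squares with the proper-rotation constraint (SVD sign
correction); the resulting rotation is applied to a fixed set of random
unit vectors, and C(Δt) = ⟨P₂(u(t)·u(t+Δt))⟩ is averaged over vectors
and origins. The P₂ correlation is evaluated exactly through the
identity P₂(a·b) = (3/2)Tr[(aaᵀ)(bbᵀ)] − 1/2, which reduces it to nine
ordinary autocorrelations per vector and allows FFT evaluation in
chunks. C(Δt) is fit over 0–20 ns to w e^(−Δt/τ₁) + (1−w) e^(−Δt/τ₂);
the overall relaxation time is the amplitude-weighted mean *rate*,
τ = (w/τ₁ + (1−w)/τ₂)⁻¹, with the fitted amplitudes used directly, and
D_r = 1/(6τ). Time constants are bounded below by the lag spacing: a
component faster than one frame is indistinguishable from a point
offset at Δt = 0 and would otherwise let w/τ₁ — and hence D_r — blow up
on noise. For anisotropic tensors obtained externally, the closed-form
relaxation time
τ = (1/15)[Σᵢ 1/(D̄+Dᵢ) + (ΣDᵢ)/(D₁D₂+D₂D₃+D₃D₁)], D̄ = ΣDᵢ/3,
is provided; estimating the tensor itself is out of scope. The
rotational finite-size correction is D_r,PBC + k_B T/(6ηL³), followed
by the same water-model rescaling.

Apparent hydrodynamic radii come from inverting
D_t = k_B T/(6πηR_h) and D_r = k_B T/(8πηR_h³); the generalized
Stokes-Einstein deviation is (D_c/D_0)/(η_0/η_c), with values below 1
indicating slow-down beyond viscosity (effective particle growth).

## Contacts, clusters, kinetics, convergence

A molecular contact is a minimum heavy-atom distance **strictly below**
5 Å between two molecules under the minimum-image convention (boundary
frames differ between ≤ and < conventions, so the choice is fixed and
documented). Neighbor search uses a periodic k-d tree with a distance
re-check, guaranteed identical to the O(N²) double loop. Per-residue
crowder contact density counts crowder heavy atoms strictly within 7 Å
of each Cα. The contact graph's connected components give, for a probe
molecule, its direct partners (graph neighbors) and in-cluster partners
(component co-members).

Contact survival uses the intermittent autocorrelation
P(Δt) = ⟨δᵢ(t)δᵢ(t+Δt)⟩ over all pairs — including never-in-contact
pairs — and sliding origins, normalized by P(0) so fitted weights are
interpretable; the normalization is recorded in the curve metadata.
The triple-exponential fit keeps weights on the simplex by a nested
parameterization, reports time constants in increasing order, is
multi-start with fixed sub-seeds, and flags solutions with effectively
duplicated constants (ratio < 1.05) as degenerate. An optional plateau
term, P(Δt) = (1−b)Σwᵢe^(−Δt/τᵢ) + b, is available (default off):
contacts that re-form decay to the stationary occupancy rather than
zero, and ignoring that plateau inflates the slowest time constant.

The equilibration Z-score compares, for each start time t, the average
over [t, t+400 ns] with the average over [t, t_end], divided by the sum
of their standard errors; SEMs use block averaging with five blocks per
interval, the standard choice for autocorrelated series. Z ≲ 1 is read
as equilibrated.

## Colloid theory and concentration models

B2 = 2π∫₀^rmax (1−g(r))r²dr is integrated by trapezoid from a
center-of-mass RDF normalized by the periodic ideal-gas shell
expectation; the unsampled hard-core region below the first bin center
r₀ contributes analytically as 2πr₀³/3 (omitting it would bias B2
positive by the core volume). The integration limit rmax is
caller-supplied per pair; no automatic peak detection is attempted.
Hard-sphere volumes are (4/3)πa³ (homotypic) and (2π/12)(a₁+a₂)³
(heterotypic), the latter reducing exactly to the former at a₁ = a₂.
τ_B = V_HS/(4V_HS − B2) requires B2 < 4V_HS (an error otherwise: no
attractive stickiness). K_D = τ_B/V_ref in mM, with V_ref = V_HS for
homotypic pairs and the probe's own sphere volume for probe-crowder
pairs, the convention that makes probe binding comparable across
crowders. Note that 4V_HS − B2 is a near-cancellation for weakly
attractive pairs, so percent-level rounding in V_HS can amplify
several-fold in τ_B.

Relative viscosities follow the Einstein (1 + 2.5φ), quadratic
(1 + 2.5φ + bφ²) and Mooney (e^{Sφ/(1−Kφ)}) laws; concentration converts
to volume fraction via c[g/L] = 1430φ (a fixed configuration constant,
not refit). The quadratic coefficient maps to stickiness through
b = 5.931 + 1.899/τ_B. Cluster-corrected diffusion fits
D(φ) = D₀/(η_r(φ)(1+ςφ)^k) with k = 1/3 (translation) or 1 (rotation)
and ς ≥ 0 bounded; 1+ςφ is reported per φ as an effective cluster size.
The Mooney fit keeps Kφ < 1 during optimization. A caution on
identifiability: with multiplicative noise at the few-percent level, K
is determined only by the curvature of log η_r at high φ; its
Cramér-Rao bound at 3% noise is ~21% even for 25 points reaching
φ = 0.34. Recovery tests therefore average fits over noise replicates
rather than asserting a single draw.

## Synthetic data: what it emulates and what it does not

Every generator is seeded, derives independent sub-streams per particle
block (so enlarging a system does not reshuffle existing particles),
and attaches a `GroundTruth` record.

* `gen_brownian`: independent Gaussian steps of variance 2D·dt per
  dimension in a periodic box; wrapped and unwrapped records retained.
  Defaults: 200 particles, D = 100 Å²/ns, 100 ns at 10 ps frames.
* `gen_rotational`: a rigid site template rotated by composing
  per-step random rotation vectors with N(0, 2D_r·dt) components;
  C₂(t) = e^(−6D_r t) by construction (the finite-step correction to
  the decay rate is < 0.02% at the defaults).
* `gen_ou_pressure`: each tensor component an independent
  Ornstein-Uhlenbeck process with autocovariance C₀e^(−t/τ_c), diagonal
  components offset by a constant mean; the analytic viscosity is
  (V/k_B T)·C₀τ_c. Defaults (C₀ = 7×10³ bar², τ_c = 0.2 ps,
  V = 10⁵ Å³, 4 fs sampling, 0.2 ns per series, 150 series) put the
  fluctuation magnitude, relaxation time and resulting η ≈ 0.34 cP in
  the range of a small aqueous simulation box.
* `gen_telegraph_contacts`: independent two-state Markov chains in
  discrete time with per-step flip probabilities k·dt (first-order
  accurate; the ground truth records the exact discrete-chain
  relaxation times, ACF amplitudes and plateau). Defaults: 500 pairs,
  three unbinding time scales (0.1, 3, 60 ns) with weights
  (0.4, 0.3, 0.3), rebinding at 5% stationary occupancy per component,
  2 µs records. The rebinding rate is proportional to unbinding so all
  components carry ACF amplitude proportional to their weight — with a
  shared rebinding rate the fast components' amplitudes would be
  smaller by the ratio of unbinding rates (~600×) and unrecoverable —
  and the slow component's weight gives it ≈ 500·0.3·0.05·2000/60 ≈ 250
  on-events, enough for a sub-10% standard error on its time constant.
* `gen_concentration_series`: η_r from a chosen law, D_t and D_r from
  the cluster-corrected relations, independent multiplicative Gaussian
  noise per observable. The default grid is 50 volume fractions over
  0–0.34 — the density of a pooled experimental concentration series —
  because the Mooney K is otherwise unidentifiable (see above);
  sparser, simulation-like grids can be passed explicitly.

None of the generators include interacting-particle dynamics, realistic
protein geometry, hydrodynamic interactions, or force-field artifacts.
Passing recovery tests therefore demonstrates that the estimators are
correct and calibrated on processes satisfying their assumptions; it
does not validate those assumptions for real crowded solutions.

## Numerical choices and degenerate inputs

* FFT-based correlations use zero-padding to at least twice the record
  (no circular wrap-around) and unbiased per-lag counts; long
  pair/vector sets are processed in chunks to bound memory.
* Strict `<` everywhere a distance cutoff is compared.
* Unwrapping uses minimum-image continuation and errors on apparent
  jumps at L/2 (undersampled trajectories cannot be unwrapped).
* All nonlinear fits are multi-start with fixed sub-seeds and report
  the lowest-residual solution; non-convergence from every start is an
  error carrying the context, never a silent fallback.
* Degenerate cases have defined behavior: a constant η(τ) plateau is
  extrapolated to itself exactly; a single-exponential survival decay
  is reported with duplicated time constants and a degeneracy flag;
  a zero-variance ensemble rejects the σ power-law fit.

## Known limitations

* Only cubic boxes; only the mean-L reduction of NPT box fluctuations.
* The anisotropic rotational-diffusion tensor is consumed, not
  estimated.
* Cluster *size distributions* are not computed (the per-probe direct
  and in-cluster counts are); small crowder counts make distributions
  unreliable anyway.
* The Green-Kubo estimator assumes the ensemble members are
  statistically equivalent (same V, T, spacing) and stationary.
* Telegraph contact chains are first-order discretizations; rates
  within ~10× of 1/dt are rejected rather than corrected.
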