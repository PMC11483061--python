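# crowdtransport

Transport coefficients and interaction thermodynamics of crowded protein
solutions, computed from molecular-dynamics trajectories.

In a cell-like solution at hundreds of g/L of protein, translational and
rotational diffusion slow down more than the rise in solution viscosity
alone can explain. Disentangling the two contributions — bulk viscosity
versus transient protein clusters that enlarge the effective diffusing
particle — requires estimating viscosity and diffusion *independently*
from the same simulations and then confronting them through the
Stokes-Einstein relations. This package implements that analysis chain
for computational biophysicists:

* **Zero-shear viscosity** by the Green-Kubo relation
  η = V/(k_B T) ∫₀^∞ ⟨P_αβ(t) P_αβ(0)⟩ dt from ensembles of short
  pressure-tensor trajectories, with the multi-trajectory σ(τ) = Aτ^b
  weighting and double-exponential τ→∞ extrapolation protocol.
* **Translational diffusion** D_t from linear fits to center-of-mass
  mean-square displacements, corrected for periodic finite-size
  artifacts, D_t = D_t,PBC + k_B T ξ/(6πηL) with
  ξ = 2.837297 − 4πR_p²/(3L²), and rescaled by the water-model
  viscosity ratio.
* **Rotational diffusion** D_r = 1/(6τ) from the second-Legendre
  autocorrelation of body-fixed probe vectors fitted to a
  double-exponential, with the analogous correction
  D_r = D_r,PBC + k_B T/(6ηL³); the anisotropic-tensor route
  τ(D₁,D₂,D₃) is provided for externally fitted tensors.
* **Contact and cluster kinetics**: heavy-atom contact detection (5 Å),
  per-residue crowder contact densities (7 Å around each Cα), connected-
  component cluster decomposition, triple-exponential contact-survival
  fits P(Δt) ≈ Σᵢ wᵢ e^(−Δt/τᵢ), and a windowed Z-score equilibration
  diagnostic.
* **Colloid theory**: second virial coefficients
  B2 = 2π∫(1−g(r))r²dr from center-of-mass RDFs, the Baxter
  sticky-hard-sphere parameter τ_B = V_HS/(4V_HS − B2), dissociation
  constants K_D = τ_B/V_ref, the viscosity-stickiness bridge
  b = 5.931 + 1.899/τ_B, and the Mooney (η_r = e^{Sφ/(1−Kφ)}),
  quadratic (η_r = 1 + 2.5φ + bφ²) and cluster-corrected diffusion
  (D = D₀/(η_r(1+ςφ)^k)) concentration models.

Estimator pipelines follow the statsmodels convention: a model object is
built from data and `fit()` returns a results object with estimates,
uncertainties, `summary()` and plotting. Closed-form operations are
plain functions. A seeded synthetic-data module generates every input
class with known ground truth — Brownian walkers, rigid-body tumbling,
Ornstein-Uhlenbeck pressure tensors, telegraph contact processes and
concentration series — so each estimator is validated by parameter
recovery.

## Worked example

```python
import crowdtransport as ct
from crowdtransport import synthetic

# Sticky-sphere thermodynamics of a probe-crowder pair from its
# hard-sphere radii and measured second virial coefficient:
rec = ct.colloid_record("SH3-GB1", a1=12.07, a2=11.70, B2=-18403)
print(f"VHS = {rec.VHS:.0f} A^3, tau_B = {rec.tau_B:.3f}, KD = {rec.KD:.1f} mM")

# Green-Kubo viscosity from an ensemble of pressure-tensor series with
# a known analytic answer:
series, truth = synthetic.gen_ou_pressure(n_traj=50, n_steps=50_000, seed=42)
res = ct.GreenKuboViscosity(series, max_lag=0.1).fit(tau_max=0.1)
print(res.summary())
print(f"ground truth: {truth.params['eta_true']:.4g} cP")
```

prints

```
VHS = 7032 A^3, tau_B = 0.151, KD = 34.1 mM

Green-Kubo viscosity estimate
=============================
trajectories          : 50
tau_max               : 100 ps
eta (extrapolated)    : 0.3402 +/- 0.035 cP
sigma power law       : A=0.9021, b=0.625
double-exp plateau fit: alpha=0.0263, tau1=0.114 ps, tau2=0.202 ps
ground truth: 0.3403 cP
```

The first line says the pair's negative B2 (net attraction) maps onto a
stickiness τ_B = 0.151 — well below the ideal-gas value of 0.25 — and
an effective dissociation constant of 34 mM, i.e. weak but significant
transient binding. The viscosity block shows the extrapolated plateau
of the running Green-Kubo integral recovering the analytic value of the
synthetic ensemble to a fraction of its cross-trajectory uncertainty.

A `crowdtransport` command-line tool exposes the same pipelines
(`simulate-*`, `viscosity`, `msd`, `rotacf`, `contacts`, `rdf`,
`colloid`, `fit`); see `crowdtransport --help`.

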