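"""Seeded synthetic-data generators with recorded ground truth.

Each generator stands in for one class of observable the MD study
produced, at parameters for which the estimated quantity is known in
closed form:

* free Brownian translation at a known D in a periodic box,
* isotropic rigid-body rotational diffusion at a known Dr,
* stationary Gaussian (Ornstein-Uhlenbeck) pressure-tensor fluctuations
  whose Green-Kubo viscosity integral is analytic,
* two-state telegraph contact processes with known on/off rates,
* concentration series from the quadratic/Mooney viscosity laws with the
  cluster-corrected diffusion relations.

Random streams are derived per generator and per particle block from the
master seed, so enlarging a system does not reshuffle existing particles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.transform import Rotation

from . import units
from .config import write_toml
from .pressure import PressureSeries
from .trajectory import Trajectory

__all__ = [
    "GroundTruth", "BrownianSample", "RotationalSample",
    "gen_brownian", "gen_rotational", "gen_ou_pressure",
    "gen_telegraph_contacts", "gen_concentration_series",
]

# Sub-stream tags keeping the per-generator streams disjoint.
_TAGS = {"brownian": 1, "rotational": 2, "ou_pressure": 3,
         "telegraph": 4, "series": 5}


@dataclass
class GroundTruth:
    """Name, seed and true parameters behind a generated artifact."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_toml(self, path) -> None:
        flat = {k: v for k, v in self.params.items()
                if not isinstance(v, np.ndarray)}
        write_toml(path, {"generator": self.generator, "seed": self.seed,
                          "params": flat})


def _rng(seed: int, tag: str, *block: int) -> np.random.Generator:
    return np.random.default_rng([seed, _TAGS[tag], *block])


# ---------------------------------------------------------------------------
# Brownian translation
# ---------------------------------------------------------------------------

@dataclass
class BrownianSample:
    wrapped: Trajectory
    unwrapped: Trajectory
    ground_truth: GroundTruth


def gen_brownian(n_particles: int = 200, D_true: float = 100.0,
                 L: float = 200.0, dt: float = 0.01, n_steps: int = 10_000,
                 seed: int = 0) -> BrownianSample:
    """Independent Brownian walkers in a cubic periodic box.

    Steps per dimension are Gaussian with variance 2·D_true·dt (Å²); both
    the wrapped and the ground-truth unwrapped coordinate records are
    returned so unwrapping can be verified exactly.
    """
    if D_true < 0:
        raise ValueError("D_true must be >= 0")
    step_sd = np.sqrt(2.0 * D_true * dt)
    if step_sd >= L / 4:
        raise ValueError(
            f"rms step {step_sd:.3g} Å violates the wrap precondition L/4")
    coords = np.empty((n_steps, n_particles, 3))
    for i in range(n_particles):
        rng = _rng(seed, "brownian", i)
        start = rng.uniform(0.0, L, size=3)
        steps = rng.normal(0.0, step_sd, size=(n_steps - 1, 3))
        coords[0, i] = start
        coords[1:, i] = start + np.cumsum(steps, axis=0)
    times = np.arange(n_steps) * dt
    box = np.full(n_steps, float(L))
    labels = dict(
        mol_ids=np.arange(n_particles), residue_ids=np.arange(n_particles),
        atom_class=np.full(n_particles, "heavy", dtype="U8"),
        masses=np.ones(n_particles))
    gt = GroundTruth("brownian", seed, dict(
        D_true=float(D_true), L=float(L), dt=float(dt),
        n_particles=n_particles, n_steps=n_steps))
    unwrapped = Trajectory(times, coords, box, wrapped=False,
                           ground_truth=gt, **labels)
    wrapped = Trajectory(times, np.mod(coords, L), box, wrapped=True,
                         ground_truth=gt, **labels)
    return BrownianSample(wrapped, unwrapped, gt)


# ---------------------------------------------------------------------------
# Rigid-body rotational diffusion
# ---------------------------------------------------------------------------

@dataclass
class RotationalSample:
    trajectory: Trajectory
    rotations: np.ndarray        # quaternions (n_frames, 4), scalar-last
    ground_truth: GroundTruth


def _rigid_template(n_sites: int, rng: np.random.Generator,
                    radius: float = 10.0) -> np.ndarray:
    """A centered, well-conditioned (non-collinear) rigid site template."""
    sites = rng.normal(size=(n_sites, 3))
    sites -= sites.mean(axis=0)
    # guard against accidental near-collinearity
    while np.linalg.matrix_rank(sites, tol=1e-6) < 3:
        sites = rng.normal(size=(n_sites, 3))
        sites -= sites.mean(axis=0)
    sites *= radius / np.abs(sites).max()
    return sites


def gen_rotational(Dr_true: float = 0.05, dt: float = 0.02,
                   n_steps: int = 4000, n_sites: int = 10,
                   seed: int = 0, L: float = 200.0) -> RotationalSample:
    """Isotropic rotational diffusion of a rigid body of labeled Cα sites.

    Orientation evolves by composing per-step random rotations whose
    rotation vector has independent N(0, 2·Dr_true·dt) components; the
    P2 orientational autocorrelation is then exp(−6·Dr_true·t).
    """
    if Dr_true < 0:
        raise ValueError("Dr_true must be >= 0")
    step_sd = np.sqrt(2.0 * Dr_true * dt)
    if step_sd * np.sqrt(3.0) > 0.5:
        raise ValueError("per-step rotation too large for small-rotation "
                         "composition; reduce dt")
    rng = _rng(seed, "rotational", 0)
    template = _rigid_template(n_sites, rng)
    rotvecs = rng.normal(0.0, step_sd, size=(n_steps - 1, 3))
    quats = np.empty((n_steps, 4))
    current = Rotation.identity()
    quats[0] = current.as_quat()
    for f in range(1, n_steps):
        current = Rotation.from_rotvec(rotvecs[f - 1]) * current
        quats[f] = current.as_quat()
    mats = Rotation.from_quat(quats).as_matrix()
    coords = np.einsum("fij,sj->fsi", mats, template) + L / 2.0
    times = np.arange(n_steps) * dt
    gt = GroundTruth("rotational", seed, dict(
        Dr_true=float(Dr_true), dt=float(dt), n_steps=n_steps,
        n_sites=n_sites, tau_true=np.inf if Dr_true == 0
        else 1.0 / (6.0 * Dr_true)))
    traj = Trajectory(times, coords, np.full(n_steps, float(L)),
                      mol_ids=np.zeros(n_sites, dtype=int),
                      residue_ids=np.arange(n_sites),
                      atom_class=np.full(n_sites, "calpha", dtype="U8"),
                      masses=np.ones(n_sites), wrapped=False,
                      ground_truth=gt)
    return RotationalSample(traj, quats, gt)


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck pressure tensors
# ---------------------------------------------------------------------------

def gen_ou_pressure(C0: float = 7.0e3, tau_c: float = 2.0e-4,
                    V: float = 1.0e5, T: float = units.T_DEFAULT,
                    dt: float = 4.0e-6, n_steps: int = 50_000,
                    n_traj: int = 150, seed: int = 0,
                    diag_mean: float = 1.0) -> tuple[list[PressureSeries],
                                                     GroundTruth]:
    """Stationary Gaussian pressure-tensor series with exponential ACF.

    Every tensor component is an independent Ornstein-Uhlenbeck process
    with autocovariance C0·exp(−t/tau_c) (C0 in bar², tau_c in ns); the
    three diagonal components additionally carry a constant mean
    ``diag_mean`` bar, exercising the per-component mean removal of the
    estimator.  The analytic Green-Kubo viscosity
    η_true = (V/kB T)·C0·tau_c (unit-converted to cP) is recorded.

    Defaults emulate the production protocol for a small aqueous box:
    4 fs sampling (0.004 ps), 0.2 ns per trajectory, 150 trajectories,
    with C0·tau_c sized to put η_true near the 0.3 cP of the simulation
    water model.
    """
    if C0 < 0 or tau_c <= 0:
        raise ValueError("C0 must be >= 0 and tau_c > 0")
    if tau_c <= dt:
        raise ValueError("tau_c must exceed the sampling interval dt")
    if n_traj < 2:
        raise ValueError("need at least two trajectories")
    a = np.exp(-dt / tau_c)
    innov_sd = np.sqrt(C0 * (1.0 - a * a))
    times = np.arange(n_steps) * dt
    mean = np.zeros(9)
    mean[[0, 4, 8]] = diag_mean
    eta_true = units.green_kubo_prefactor(V, T) * C0 * tau_c
    gt = GroundTruth("ou_pressure", seed, dict(
        C0=float(C0), tau_c=float(tau_c), V=float(V), T=float(T),
        dt=float(dt), n_steps=n_steps, n_traj=n_traj,
        eta_true=float(eta_true)))
    out = []
    for j in range(n_traj):
        rng = _rng(seed, "ou_pressure", j)
        x0 = rng.normal(0.0, np.sqrt(C0), size=9) if C0 > 0 else np.zeros(9)
        w = rng.normal(0.0, innov_sd, size=(n_steps, 9))
        w[0] = x0
        # OU recursion x[n] = a x[n-1] + w[n] as an IIR filter
        x = signal.lfilter([1.0], [1.0, -a], w, axis=0)
        out.append(PressureSeries(times, x + mean, V, T, ground_truth=gt))
    return out, gt


# ---------------------------------------------------------------------------
# Telegraph contact processes
# ---------------------------------------------------------------------------

def gen_telegraph_contacts(n_pairs: int = 500,
                           rate_components: Sequence[tuple[float, float]] = (
                               (0.4, 10.0), (0.3, 1.0 / 3.0), (0.3, 1.0 / 60.0)),
                           k_on: "float | Sequence[float] | None" = None,
                           dt: float = 0.01, n_steps: int = 200_000,
                           seed: int = 0):
    """Independent two-state (contact on/off) Markov chains.

    ``rate_components`` is a list of (weight, k_off) pairs; every pair is
    assigned to one component and evolves in discrete time with per-step
    flip probabilities k·dt (first-order accurate).  The defaults realize
    the three contact time scales seen for protein crowders:
    sub-nanosecond, few-nanosecond and ~60 ns unbinding, over a 2 µs
    record (production-trajectory length).  The component weights give
    the slow component enough sampling mass for its time constant to be
    estimable: with weight w, occupancy p and record T, the number of
    distinct slow on-periods is ≈ n_pairs·w·p·T/τ_off, and w = 0.3
    yields a few hundred events at the defaults (a relative standard
    error below ~10%).

    ``k_on`` may be a scalar shared by all components, a per-component
    sequence, or None, in which case k_on ≈ 0.0526·k_off per component.
    The default keeps the stationary contact occupancy equal (5%) across
    components, so the survival ACF amplitudes follow the component
    weights; a shared rebinding rate would make the fast components'
    amplitudes smaller by the ratio of their unbinding rates and hence
    unresolvable.

    The exact ACF of the discrete chain is recorded in the ground truth:
    for a component with stationary occupancy p the normalized survival
    correlation is p + (1−p)·λ^(Δt/dt) with λ = 1 − (k_on + k_off)·dt,
    i.e. an exponential with time constant −dt/ln λ.
    """
    from .contacts import ContactTimeline

    weights = np.array([w for w, _ in rate_components], dtype=float)
    k_offs = np.array([k for _, k in rate_components], dtype=float)
    if np.any(weights <= 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("component weights must be positive and sum to 1")
    if k_on is None:
        k_ons = (0.05 / 0.95) * k_offs    # 5% stationary occupancy
    else:
        k_ons = np.broadcast_to(np.asarray(k_on, dtype=float),
                                k_offs.shape).copy()
    if np.any(k_offs < 0) or np.any(k_ons < 0):
        raise ValueError("rates must be non-negative")
    rates = np.concatenate([k_offs, k_ons])
    if dt * rates.max() > 0.1:
        raise ValueError("dt * max(rate) > 0.1: discretization too coarse")

    # largest-remainder apportionment of pairs to components
    ideal = weights * n_pairs
    counts = np.floor(ideal).astype(int)
    remainder = n_pairs - counts.sum()
    order = np.argsort(-(ideal - counts))
    counts[order[:remainder]] += 1

    states = np.empty((n_pairs, n_steps), dtype=bool)
    start = 0
    comp_of_pair = np.empty(n_pairs, dtype=int)
    for c, (n_c, k_off, kon_c) in enumerate(zip(counts, k_offs, k_ons)):
        if n_c == 0:
            continue
        rng = _rng(seed, "telegraph", c)
        p_on_step = kon_c * dt
        p_off_step = k_off * dt
        denom = p_on_step + p_off_step
        p_stat = p_on_step / denom if denom > 0 else 1.0
        s = rng.random(n_c) < p_stat
        block = np.empty((n_c, n_steps), dtype=bool)
        block[:, 0] = s
        for t in range(1, n_steps):
            u = rng.random(n_c)
            flip = np.where(s, u < p_off_step, u < p_on_step)
            s = s ^ flip
            block[:, t] = s
        states[start:start + n_c] = block
        comp_of_pair[start:start + n_c] = c
        start += n_c

    lam = 1.0 - (k_ons + k_offs) * dt
    p_stat = np.where(k_ons + k_offs > 0,
                      k_ons / (k_ons + k_offs), 1.0)
    with np.errstate(divide="ignore"):
        tau_exact = np.where(lam > 0, -dt / np.log(lam), np.nan)
    frac = counts / n_pairs
    p0 = float(np.sum(frac * p_stat))
    amps = frac * p_stat * (1.0 - p_stat) / p0 if p0 > 0 else frac * 0
    baseline = float(np.sum(frac * p_stat ** 2) / p0) if p0 > 0 else 0.0
    gt = GroundTruth("telegraph", seed, dict(
        k_ons=k_ons, k_offs=k_offs, weights=weights, dt=float(dt),
        n_steps=n_steps, n_pairs=n_pairs, counts=counts,
        tau_exact=tau_exact, acf_amplitudes=amps, acf_baseline=baseline))
    times = np.arange(n_steps) * dt
    pair_ids = [(i, n_pairs + i) for i in range(n_pairs)]
    timeline = ContactTimeline(pair_ids, times, states, ground_truth=gt)
    return timeline, gt


# ---------------------------------------------------------------------------
# Concentration series
# ---------------------------------------------------------------------------

def relative_viscosity_model(phi: np.ndarray, model: str,
                             params: dict) -> np.ndarray:
    """Evaluate ηr(φ) for the einstein/quadratic/Mooney laws."""
    phi = np.asarray(phi, dtype=float)
    if model == "einstein":
        return 1.0 + 2.5 * phi
    if model == "quadratic":
        return 1.0 + 2.5 * phi + params["b"] * phi ** 2
    if model == "mooney":
        S, K = params["S"], params["K"]
        if np.any(K * phi >= 1.0):
            raise ValueError("Mooney pole K*phi >= 1 inside the grid")
        return np.exp(S * phi / (1.0 - K * phi))
    raise ValueError(f"unknown viscosity model {model!r}")


def gen_concentration_series(model: str = "mooney",
                             params: dict | None = None,
                             D0: float = 1.0, cluster_factor: float = 20.0,
                             phi_grid: Sequence[float] | None = None,
                             noise_sd: float = 0.03, seed: int = 0,
                             conc_per_phi: float = 1430.0
                             ) -> tuple[pd.DataFrame, GroundTruth]:
    """Concentration series of (ηr, Dt, Dr) with multiplicative noise.

    Dt = D0 / (ηr·(1+ςφ)^{1/3}) and Dr = D0 / (ηr·(1+ςφ)) where ς
    (``cluster_factor``) sets the effective cluster size 1+ςφ.  The
    Mooney defaults are lysozyme-like.  The default φ grid is 50 points
    spanning 0–0.34 (0 to ~490 g/L), the density of a pooled
    experimental concentration series: the Mooney self-crowding factor
    K is identified by the curvature of log ηr at high φ and needs both
    reach in φ and many points to be estimable (its Cramér-Rao bound at
    3% noise on a sparse 5-point simulation-style grid is ~80% of K).
    Pass an explicit sparse grid to emulate simulation conditions.
    """
    params = dict(params) if params else {"S": 2.8, "K": 0.53}
    if phi_grid is None:
        phi_grid = np.linspace(0.0, 0.34, 50)
    phi = np.asarray(phi_grid, dtype=float)
    if np.any(phi < 0) or np.any(phi > 0.35):
        raise ValueError("phi_grid must lie within [0, 0.35]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if cluster_factor < 0:
        raise ValueError("cluster_factor must be >= 0")
    eta_r = relative_viscosity_model(phi, model, params)
    cluster = 1.0 + cluster_factor * phi
    d_t = D0 / (eta_r * cluster ** (1.0 / 3.0))
    d_r = D0 / (eta_r * cluster)
    rng = _rng(seed, "series", 0)
    if noise_sd > 0:
        eta_r = eta_r * (1.0 + rng.normal(0.0, noise_sd, phi.shape))
        d_t = d_t * (1.0 + rng.normal(0.0, noise_sd, phi.shape))
        d_r = d_r * (1.0 + rng.normal(0.0, noise_sd, phi.shape))
    table = pd.DataFrame({
        "phi": phi, "conc": conc_per_phi * phi,
        "eta_r": eta_r, "D_t": d_t, "D_r": d_r})
    gt = GroundTruth("series", seed, dict(
        model=model, D0=float(D0), cluster_factor=float(cluster_factor),
        noise_sd=float(noise_sd), conc_per_phi=float(conc_per_phi), **params))
    return table, gt
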