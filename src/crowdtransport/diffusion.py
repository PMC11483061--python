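"""Translational and rotational diffusion estimators.

Translational diffusion comes from linear fits to center-of-mass
mean-square displacements, Dt = MSD(τ)/(6τ); rotational diffusion from
the second-Legendre autocorrelation of body-fixed probe vectors fitted
to a double-exponential, Dr = 1/(6τ).  Both raw estimates are corrected
for periodic finite-size artifacts,

    Dt = Dt,PBC + kB·T·ξ/(6π·η·L),   ξ = 2.837297 − 4π·Rp²/(3L²)
    Dr = Dr,PBC + kB·T/(6·η·L³)

and optionally rescaled by the ratio of the simulated to the
experimental water viscosity.  Stokes-Einstein inversion gives apparent
hydrodynamic radii; the generalized relation D(c)/D0 = η0/η(c) is used
to quantify crowding-induced deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.fft import irfft, next_fast_len, rfft
from scipy.spatial.transform import Rotation

from . import units
from .config import AnalysisConfig
from .curves import CorrelationCurve
from .trajectory import Trajectory

__all__ = [
    "MSDCurve", "TransportEstimate", "RotationalFit", "HydrodynamicRadius",
    "compute_msd", "fit_diffusion", "xi_factor", "pbc_correct_translational",
    "rescale_by_viscosity_ratio", "rot_acf", "fit_rotational",
    "tau_from_tensor", "pbc_correct_rotational", "hydrodynamic_radii",
    "stokes_einstein_ratio",
    "TranslationalDiffusion", "RotationalDiffusion",
]

#: Leading constant of the cubic-box translational finite-size correction.
XI_CUBIC = 2.837297


@dataclass
class MSDCurve:
    """Mean-square displacement vs lag, averaged over molecules/origins."""

    lags: np.ndarray          # ns
    msd: np.ndarray           # Å²
    counts: np.ndarray        # time-origin pairs per lag (summed over mols)
    selection: str = ""
    replicas: np.ndarray | None = None   # per-molecule curves


@dataclass
class TransportEstimate:
    """A diffusion coefficient with its corrected/rescaled variants."""

    raw: float                 # PBC-affected value (Å²/ns or ns⁻¹)
    pbc_corrected: float
    rescaled: float | None
    se: float
    inputs: dict = field(default_factory=dict)


@dataclass
class RotationalFit:
    """Double-exponential fit of the P2 orientational ACF."""

    w: float
    tau1: float                # ns
    tau2: float                # ns
    tau: float                 # overall relaxation time, ns
    Dr: float                  # ns⁻¹
    method: str = "acf"
    residual: float = np.nan


@dataclass
class HydrodynamicRadius:
    Rh_translational: float    # Å
    Rh_rotational: float       # Å
    inputs: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mean-square displacement
# ---------------------------------------------------------------------------

def _msd_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Origin-averaged MSD of one 3D path (T, 3) via the FFT identity."""
    T = x.shape[0]
    nfft = next_fast_len(2 * T)
    f = rfft(x, nfft, axis=0)
    s2 = irfft(f * np.conj(f), nfft, axis=0)[:n_lags + 1].sum(axis=1)
    d = (x * x).sum(axis=1)
    # S1(k) = sum_{t=0}^{T-k-1} [D(t) + D(t+k)] by prefix sums
    csum = np.concatenate([[0.0], np.cumsum(d)])
    k = np.arange(n_lags + 1)
    s1 = (csum[T - k] - csum[0]) + (csum[T] - csum[k])
    return (s1 - 2.0 * s2) / (T - k)


def compute_msd(traj: Trajectory, selection=None,
                max_lag: float | None = None) -> MSDCurve:
    """Center-of-mass MSD averaged over molecules and sliding origins.

    ``selection`` is an iterable of molecule ids (default: all).  The
    trajectory must be unwrapped.
    """
    if traj.wrapped:
        raise ValueError("MSD requires unwrapped coordinates; call unwrap()")
    mols = list(selection) if selection is not None else list(traj.molecules)
    if not mols:
        raise ValueError("selection resolves to no molecules")
    dt = traj.dt
    n_lags = (traj.n_frames - 1 if max_lag is None
              else min(int(round(max_lag / dt)), traj.n_frames - 1))
    per_mol = np.empty((len(mols), n_lags + 1))
    for i, mol in enumerate(mols):
        per_mol[i] = _msd_fft(traj.center_of_mass(mol), n_lags)
    counts = (traj.n_frames - np.arange(n_lags + 1)) * len(mols)
    return MSDCurve(np.arange(n_lags + 1) * dt, per_mol.mean(axis=0),
                    counts.astype(float),
                    selection=f"{len(mols)} molecules", replicas=per_mol)


def fit_diffusion(msd: MSDCurve, window: tuple[float, float] = (2.0, 10.0)
                  ) -> float:
    """Slope-only linear fit of MSD over the lag window; returns slope/6.

    Insensitive to an anomalous intercept at short times.
    """
    mask = (msd.lags >= window[0]) & (msd.lags <= window[1])
    if mask.sum() < 3:
        raise ValueError("fewer than 3 MSD points inside the fit window")
    slope, _ = np.polyfit(msd.lags[mask], msd.msd[mask], 1)
    return float(slope) / 6.0


# ---------------------------------------------------------------------------
# Finite-size and water-model corrections
# ---------------------------------------------------------------------------

def xi_factor(Rp: float, L: float) -> float:
    """Self-interaction constant ξ = 2.837297 − 4π·Rp²/(3L²)."""
    if L <= 0:
        raise ValueError("box edge must be positive")
    if Rp < 0:
        raise ValueError("particle radius must be >= 0")
    return XI_CUBIC - 4.0 * math.pi * Rp ** 2 / (3.0 * L ** 2)


def pbc_correct_translational(D_pbc: float, eta: float, L: float,
                              Rp: float = 0.0,
                              temperature: float = units.T_DEFAULT) -> float:
    """Add the hydrodynamic self-image correction kB·T·ξ/(6π·η·L), Å²/ns."""
    if eta <= 0 or L <= 0:
        raise ValueError("eta and L must be positive")
    return D_pbc + units.translational_pbc_term(
        xi_factor(Rp, L), eta, L, temperature)


def pbc_correct_rotational(Dr_pbc: float, eta: float, L: float,
                           temperature: float = units.T_DEFAULT) -> float:
    """Add the rotational finite-size correction kB·T/(6·η·L³), ns⁻¹."""
    if eta <= 0 or L <= 0:
        raise ValueError("eta and L must be positive")
    return Dr_pbc + units.rotational_pbc_term(eta, L, temperature)


def rescale_by_viscosity_ratio(D: float, eta_model: float,
                               eta_experiment: float) -> float:
    """Rescale D by η_model/η_experiment (water-model viscosity fix)."""
    if eta_model <= 0 or eta_experiment <= 0:
        raise ValueError("viscosities must be positive")
    return D * eta_model / eta_experiment


# ---------------------------------------------------------------------------
# Rotational autocorrelation
# ---------------------------------------------------------------------------

def _p2_autocorrelation(vecs: np.ndarray, n_lags: int,
                        chunk: int = 64) -> np.ndarray:
    """⟨P2(u(t)·u(t+k))⟩ over origins and vectors, exactly, via FFT.

    Uses P2(a·b) = (3/2)·Tr[(aaᵀ)(bbᵀ)] − 1/2: correlating the nine
    outer-product components reduces the quadratic form to ordinary
    autocorrelations.  ``vecs`` has shape (T, n_vec, 3).
    """
    T, n_vec, _ = vecs.shape
    nfft = next_fast_len(2 * T)
    counts = T - np.arange(n_lags + 1)
    acc = np.zeros(n_lags + 1)
    for lo in range(0, n_vec, chunk):
        v = vecs[:, lo:lo + chunk, :]
        outer = np.einsum("tvi,tvj->tvij", v, v).reshape(T, -1, 9)
        f = rfft(outer, nfft, axis=0)
        corr = irfft(f * np.conj(f), nfft, axis=0)[:n_lags + 1]
        acc += corr.sum(axis=(1, 2))
    tr = acc / (counts * n_vec)
    return 1.5 * tr - 0.5


def rot_acf(traj: Trajectory, molecule: int | None = None,
            n_vectors: int = 1000, window: float = 20.0,
            seed: int = 0) -> CorrelationCurve:
    """Second-Legendre rotational ACF of a molecule's rigid-body motion.

    Each frame's Cα sites are superposed onto the first frame by
    unweighted least squares (proper rotation enforced); the best-fit
    rotation is applied to ``n_vectors`` random unit vectors whose P2
    autocorrelation, averaged over vectors and origins, is returned.
    """
    if molecule is None:
        molecule = int(traj.molecules[0])
    idx = traj.atoms_of(molecule)
    idx = idx[traj.calpha_mask[idx]]
    if idx.size < 3:
        raise ValueError("molecule needs >= 3 Calpha sites")
    sites = traj.coords[:, idx, :]
    sites = sites - sites.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(sites[0], tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) Calpha geometry")
    ref = sites[0]
    T = traj.n_frames
    rots = np.empty((T, 4))
    for f in range(T):
        r, _ = Rotation.align_vectors(ref, sites[f])
        rots[f] = r.as_quat()
    rotations = Rotation.from_quat(rots)

    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_vectors, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    vecs = np.einsum("tij,vj->tvi", rotations.as_matrix(), u)

    dt = traj.dt
    n_lags = min(int(round(window / dt)), T - 1)
    c = _p2_autocorrelation(vecs, n_lags)
    counts = (T - np.arange(n_lags + 1)) * float(n_vectors)
    return CorrelationCurve(np.arange(n_lags + 1) * dt, c, counts=counts,
                            meta={"molecule": molecule,
                                  "n_vectors": n_vectors})


def fit_rotational(acf: CorrelationCurve,
                   window: tuple[float, float] = (0.0, 20.0)
                   ) -> RotationalFit:
    """Fit C(t) = w·e^(−t/τ1) + (1−w)·e^(−t/τ2) and derive τ and Dr.

    τ = (w/τ1 + (1−w)/τ2)⁻¹ (amplitude-weighted mean rate), Dr = 1/(6τ).
    """
    cut = acf.window(*window)
    if len(cut) < 4:
        raise ValueError("too few ACF points inside the fit window")
    t, c = cut.lags, cut.values

    def model(t, w, tau1, tau2):
        return w * np.exp(-t / tau1) + (1.0 - w) * np.exp(-t / tau2)

    span = max(t[-1], t[1] * 10)
    starts = [(0.5, g, min(10 * g, 50 * span))
              for g in np.geomspace(max(t[1], 1e-3), span, 5)]
    best = None
    # time constants shorter than the lag spacing are indistinguishable
    # from a point offset at t=0 and make the amplitude-weighted rate
    # (and hence Dr) blow up on noise, so the grid sets the lower bound
    tau_floor = t[1] if t[0] == 0 else t[0]
    for p0 in starts:
        p0 = (p0[0], max(p0[1], tau_floor), max(p0[2], tau_floor))
        try:
            popt, _ = optimize.curve_fit(
                model, t, c, p0=p0,
                bounds=([0.0, tau_floor, tau_floor],
                        [1.0, np.inf, np.inf]),
                maxfev=20000)
        except Exception:
            continue
        resid = float(np.sum((model(t, *popt) - c) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError("rotational double-exponential fit did not "
                           "converge")
    (w, tau1, tau2), resid = best
    if tau1 > tau2:   # canonical order: tau1 <= tau2
        tau1, tau2, w = tau2, tau1, 1.0 - w
    tau = 1.0 / (w / tau1 + (1.0 - w) / tau2)
    return RotationalFit(float(w), float(tau1), float(tau2), float(tau),
                         Dr=1.0 / (6.0 * tau), method="acf", residual=resid)


def tau_from_tensor(D1: float, D2: float, D3: float) -> float:
    """Overall relaxation time from an anisotropic diffusion tensor.

    τ = (1/15)·[1/(D+D1) + 1/(D+D2) + 1/(D+D3)
               + (D1+D2+D3)/(D1·D2 + D2·D3 + D3·D1)],  D = (D1+D2+D3)/3.

    Reduces to 1/(6D) in the isotropic limit.
    """
    if min(D1, D2, D3) <= 0:
        raise ValueError("all tensor eigenvalues must be positive")
    D = (D1 + D2 + D3) / 3.0
    return (1.0 / (D + D1) + 1.0 / (D + D2) + 1.0 / (D + D3)
            + (D1 + D2 + D3) / (D1 * D2 + D2 * D3 + D3 * D1)) / 15.0


# ---------------------------------------------------------------------------
# Stokes-Einstein analysis
# ---------------------------------------------------------------------------

def hydrodynamic_radii(Dt: float, Dr: float, eta: float,
                       temperature: float = units.T_DEFAULT
                       ) -> HydrodynamicRadius:
    """Apparent hydrodynamic radii from both Stokes-Einstein laws.

    Rh,t = kB·T/(6π·η·Dt)  and  Rh,r = [kB·T/(8π·η·Dr)]^(1/3).
    """
    if min(Dt, Dr, eta, temperature) <= 0:
        raise ValueError("all inputs must be positive")
    return HydrodynamicRadius(
        units.stokes_einstein_radius_t(Dt, eta, temperature),
        units.stokes_einstein_radius_r(Dr, eta, temperature),
        inputs={"Dt": Dt, "Dr": Dr, "eta": eta, "T": temperature})


def stokes_einstein_ratio(D_c: float, D_0: float, eta_c: float,
                          eta_0: float) -> tuple[float, float, float]:
    """(D_c/D_0, η_0/η_c, deviation) of the generalized Stokes-Einstein.

    A deviation of 1 means D(c)/D0 = η0/η(c) holds; < 1 means diffusion
    is slowed beyond the viscosity increase (effective size growth).
    """
    if min(D_c, D_0, eta_c, eta_0) <= 0:
        raise ValueError("all inputs must be positive")
    rel_d = D_c / D_0
    rel_fluidity = eta_0 / eta_c
    return rel_d, rel_fluidity, rel_d / rel_fluidity


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class TranslationalDiffusion:
    """MSD-based translational diffusion of molecular centers of mass."""

    def __init__(self, traj: Trajectory, selection=None,
                 config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        self.traj = traj.unwrap() if traj.wrapped else traj
        self.selection = selection

    def fit(self, window: tuple[float, float] | None = None,
            max_lag: float | None = None) -> "TranslationalDiffusionResults":
        window = window or self.config.msd_fit_window
        if max_lag is None:
            max_lag = min(2.0 * window[1],
                          self.traj.times[-1] - self.traj.times[0])
        msd = compute_msd(self.traj, self.selection, max_lag)
        d = fit_diffusion(msd, window)
        if msd.replicas is not None and msd.replicas.shape[0] > 1:
            per_mol = np.array([
                fit_diffusion(MSDCurve(msd.lags, row, msd.counts), window)
                for row in msd.replicas])
            se = float(per_mol.std(ddof=1) / np.sqrt(per_mol.size))
        else:
            se = float("nan")
        return TranslationalDiffusionResults(self, msd, d, se, window)


class TranslationalDiffusionResults:
    def __init__(self, model, msd: MSDCurve, d_pbc: float, se: float,
                 window):
        self.model = model
        self.msd = msd
        self.D_pbc = d_pbc
        self.se = se
        self.window = window

    def correct(self, eta: float, Rp: float = 0.0, L: float | None = None,
                rescale: bool = True) -> TransportEstimate:
        """Apply the finite-size and water-model corrections."""
        cfg = self.model.config
        if L is None:
            L = self.model.traj.mean_box()
        d_corr = pbc_correct_translational(self.D_pbc, eta, L, Rp,
                                           cfg.temperature)
        d_resc = (rescale_by_viscosity_ratio(d_corr, cfg.eta_model,
                                             cfg.eta_reference)
                  if rescale else None)
        return TransportEstimate(self.D_pbc, d_corr, d_resc, self.se,
                                 inputs={"eta": eta, "L": L, "Rp": Rp,
                                         "T": cfg.temperature})

    def summary(self) -> str:
        return (f"Translational diffusion (window {self.window[0]}-"
                f"{self.window[1]} ns, {self.msd.selection}):\n"
                f"  D_pbc = {self.D_pbc:.4g} +/- {self.se:.2g} A^2/ns")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.msd.lags, self.msd.msd, label="MSD")
        mask = (self.msd.lags >= self.window[0]) \
            & (self.msd.lags <= self.window[1])
        ax.plot(self.msd.lags[mask],
                6 * self.D_pbc * self.msd.lags[mask]
                + (self.msd.msd[mask] - 6 * self.D_pbc
                   * self.msd.lags[mask]).mean(),
                "--", label=f"fit: D={self.D_pbc:.3g} $\\AA^2$/ns")
        ax.set_xlabel("lag time (ns)")
        ax.set_ylabel("MSD ($\\AA^2$)")
        ax.legend()
        return ax


class RotationalDiffusion:
    """Rotational diffusion from the P2 vector autocorrelation."""

    def __init__(self, traj: Trajectory, molecule: int | None = None,
                 n_vectors: int = 1000, seed: int = 0,
                 config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        self.traj = traj
        self.molecule = molecule
        self.n_vectors = n_vectors
        self.seed = seed

    def fit(self, window: tuple[float, float] | None = None
            ) -> "RotationalDiffusionResults":
        window = window or self.config.rot_fit_window
        acf = rot_acf(self.traj, self.molecule, self.n_vectors,
                      window[1], self.seed)
        rfit = fit_rotational(acf, window)
        return RotationalDiffusionResults(self, acf, rfit)


class RotationalDiffusionResults:
    def __init__(self, model, acf: CorrelationCurve, rfit: RotationalFit):
        self.model = model
        self.acf = acf
        self.fit = rfit

    @property
    def Dr_pbc(self) -> float:
        return self.fit.Dr

    def correct(self, eta: float, L: float | None = None,
                rescale: bool = True) -> TransportEstimate:
        cfg = self.model.config
        if L is None:
            L = self.model.traj.mean_box()
        dr_corr = pbc_correct_rotational(self.Dr_pbc, eta, L,
                                         cfg.temperature)
        dr_resc = (rescale_by_viscosity_ratio(dr_corr, cfg.eta_model,
                                              cfg.eta_reference)
                   if rescale else None)
        return TransportEstimate(self.Dr_pbc, dr_corr, dr_resc,
                                 float("nan"),
                                 inputs={"eta": eta, "L": L,
                                         "T": cfg.temperature})

    def summary(self) -> str:
        f = self.fit
        return ("Rotational diffusion (P2 autocorrelation):\n"
                f"  w = {f.w:.3g}, tau1 = {f.tau1:.4g} ns, "
                f"tau2 = {f.tau2:.4g} ns\n"
                f"  tau = {f.tau:.4g} ns, Dr = {f.Dr:.4g} 1/ns")
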