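"""Sticky-sphere colloid analysis and concentration-dependence fits.

Radial distribution functions of molecular centers of mass give the
second virial coefficient

    B2 = 2π ∫ (1 − g(r)) r² dr

which maps onto Baxter's adhesive-hard-sphere stickiness parameter via
B2 = 4·VHS − VHS/τB and onto a dissociation constant KD = τB/V_ref
(converted from Å⁻³ number density to mM).  Relative viscosities follow
either the quadratic hard-sphere expansion ηr = 1 + 2.5φ + bφ² — whose b
relates back to stickiness through b = 5.931 + 1.899/τB — or Mooney's
law ηr = exp(Sφ/(1−Kφ)); diffusion-vs-concentration data are described
by D(φ) = D0/(ηr·(1+ςφ)^k) with k = 1/3 (translation) or 1 (rotation),
1+ςφ being an effective cluster size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import units
from .synthetic import relative_viscosity_model
from .trajectory import Trajectory

__all__ = [
    "RDFCurve", "ColloidRecord", "ModelFitResult",
    "compute_rdf", "b2_from_rdf", "hard_sphere_volume", "baxter_tau",
    "kd_from_tau", "tau_from_viscosity_b", "conc_to_phi",
    "fit_viscosity_model", "fit_cluster_diffusion",
    "characteristic_diffusion_length", "colloid_record",
    "ViscosityConcentrationModel", "ClusterDiffusionModel",
    "ModelFitResults",
]

#: Stickiness-viscosity bridge constants: b = B_OFFSET + B_SLOPE/τB.
B_OFFSET = 5.931
B_SLOPE = 1.899


@dataclass
class RDFCurve:
    r: np.ndarray              # bin centers, Å
    g: np.ndarray
    selection: str = ""
    n_frames: int = 0
    rmax: float = np.nan       # intended upper integration limit, Å


@dataclass
class ColloidRecord:
    """One interaction pair's sticky-sphere thermodynamics."""

    pair: str
    a1: float                  # Å
    a2: float | None           # Å, None for homotypic
    VHS: float                 # Å³
    B2: float                  # Å³
    rmax: float                # Å
    tau_B: float
    KD: float                  # mM
    reference_volume: float    # Å³, used for KD


@dataclass
class ModelFitResult:
    model: str
    params: dict
    uncertainties: dict
    residual: float


# ---------------------------------------------------------------------------
# Radial distribution function
# ---------------------------------------------------------------------------

def compute_rdf(traj: Trajectory, selection_a, selection_b=None,
                bin_width: float = 1.0,
                rmax: float | None = None) -> RDFCurve:
    """Center-of-mass RDF between two molecule groups.

    Normalized by the ideal-gas shell expectation 4π r² dr / V in the
    periodic box.  ``selection_a``/``selection_b`` are molecule-id lists;
    equal (or ``selection_b=None``) means the homotypic i<j pairing.
    """
    mols_a = list(selection_a)
    mols_b = list(selection_b) if selection_b is not None else mols_a
    same = sorted(mols_a) == sorted(mols_b)
    if (same and len(mols_a) < 2) or not mols_a or not mols_b:
        raise ValueError("selection resolves to no valid pair")
    L_min = float(traj.box.min())
    if rmax is None:
        rmax = 0.49 * L_min
    if rmax >= L_min / 2:
        raise ValueError("rmax must be below half the box edge")
    n_bins = int(np.ceil(rmax / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    hist = np.zeros(n_bins)
    com_a = np.stack([traj.center_of_mass(m) for m in mols_a], axis=1)
    com_b = (com_a if same
             else np.stack([traj.center_of_mass(m) for m in mols_b], axis=1))
    n_pairs = (len(mols_a) * (len(mols_a) - 1) // 2 if same
               else len(mols_a) * len(mols_b))
    for f in range(traj.n_frames):
        L = traj.box[f]
        if same:
            d = com_a[f][:, None, :] - com_a[f][None, :, :]
            iu = np.triu_indices(len(mols_a), k=1)
            delta = d[iu]
        else:
            delta = (com_a[f][:, None, :] - com_b[f][None, :, :]
                     ).reshape(-1, 3)
        delta = delta - L * np.round(delta / L)
        dist = np.sqrt((delta ** 2).sum(axis=1))
        hist += np.histogram(dist, bins=edges)[0]
    vol = traj.box.astype(float) ** 3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs * traj.n_frames * shell / vol.mean()
    g = np.divide(hist, ideal, out=np.zeros_like(hist), where=ideal > 0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFCurve(centers, g, selection=f"{len(mols_a)}x{len(mols_b)}",
                    n_frames=traj.n_frames, rmax=float(rmax))


def b2_from_rdf(rdf: RDFCurve, rmax: float | None = None) -> float:
    """Second virial coefficient 2π∫(1−g)r²dr up to rmax, in Å³.

    The unsampled hard-core region below the first bin center r₀
    contributes analytically as 2π·r₀³/3 (g = 0 there).
    """
    if rmax is None:
        rmax = rdf.rmax
    if rmax > rdf.r[-1] + 1e-9:
        raise ValueError("rmax beyond the sampled RDF grid")
    mask = rdf.r <= rmax
    r, g = rdf.r[mask], rdf.g[mask]
    core = 2.0 * math.pi * r[0] ** 3 / 3.0
    return core + 2.0 * math.pi * np.trapezoid((1.0 - g) * r ** 2, r)


# ---------------------------------------------------------------------------
# Baxter sticky-sphere mapping
# ---------------------------------------------------------------------------

def hard_sphere_volume(a1: float, a2: float | None = None) -> float:
    """Hard-sphere interaction volume, Å³.

    Homotypic: (4/3)π·a³.  Heterotypic: (2π/12)·(a1+a2)³, which reduces
    to the homotypic value when a1 = a2.
    """
    if a1 <= 0 or (a2 is not None and a2 <= 0):
        raise ValueError("radii must be positive")
    if a2 is None:
        return 4.0 / 3.0 * math.pi * a1 ** 3
    return 2.0 * math.pi / 12.0 * (a1 + a2) ** 3


def baxter_tau(B2: float, VHS: float) -> float:
    """Stickiness parameter τB = VHS/(4·VHS − B2).

    Defined only while B2 < 4·VHS; at the ideal-gas value B2 = 0 it is
    exactly 1/4, and more negative B2 (stronger attraction) gives
    smaller τB.
    """
    if VHS <= 0:
        raise ValueError("VHS must be positive")
    if B2 >= 4.0 * VHS:
        raise ValueError("B2 >= 4*VHS: no attractive stickiness; "
                         "tau_B undefined/infinite")
    return VHS / (4.0 * VHS - B2)


def kd_from_tau(tau_B: float, reference_volume: float) -> float:
    """Dissociation constant KD = τB / V_ref, converted to mM."""
    if tau_B <= 0 or reference_volume <= 0:
        raise ValueError("tau_B and reference volume must be positive")
    return tau_B / reference_volume * units.INV_ANGSTROM3_TO_MM


def tau_from_viscosity_b(b: float) -> float:
    """Invert the stickiness-viscosity bridge: τB = 1.899/(b − 5.931)."""
    if b <= B_OFFSET:
        raise ValueError("b <= 5.931: stickiness term non-positive")
    return B_SLOPE / (b - B_OFFSET)


def conc_to_phi(c: float, coefficient: float = 1430.0) -> float:
    """Mass concentration (g/L) to volume fraction via c = coefficient·φ."""
    if np.any(np.asarray(c) < 0):
        raise ValueError("concentration must be >= 0")
    return c / coefficient


def colloid_record(pair: str, a1: float, a2: float | None, B2: float,
                   rmax: float = np.nan,
                   reference: str = "auto") -> ColloidRecord:
    """Assemble the full sticky-sphere chain for one interaction pair.

    ``reference`` picks the KD reference volume: "pair" uses VHS,
    "probe" uses the sphere volume of radius a1 (the probe), and "auto"
    chooses probe for heterotypic pairs and VHS for homotypic ones —
    the convention used when comparing probe binding across crowders.
    """
    vhs = hard_sphere_volume(a1, a2)
    tau = baxter_tau(B2, vhs)
    if reference == "auto":
        reference = "pair" if a2 is None else "probe"
    if reference == "pair":
        v_ref = vhs
    elif reference == "probe":
        v_ref = hard_sphere_volume(a1)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return ColloidRecord(pair, a1, a2, vhs, B2, rmax, tau,
                         kd_from_tau(tau, v_ref), v_ref)


def characteristic_diffusion_length(D: float, tau: float) -> float:
    """Distance √(D·τ) explored over a contact survival time, Å."""
    if D < 0 or tau < 0:
        raise ValueError("D and tau must be >= 0")
    return math.sqrt(D * tau)


# ---------------------------------------------------------------------------
# Concentration-dependence fits
# ---------------------------------------------------------------------------

def fit_viscosity_model(phi, eta_r, model: str = "mooney",
                        weights=None) -> ModelFitResult:
    """Least-squares fit of ηr(φ) for the einstein/quadratic/Mooney laws.

    einstein has no free parameters (residual only); quadratic fits b;
    Mooney fits (S, K) with the pole constraint K·max(φ) < 1.
    """
    phi = np.asarray(phi, dtype=float)
    eta_r = np.asarray(eta_r, dtype=float)
    w = np.ones_like(phi) if weights is None else np.asarray(weights, float)
    if model == "einstein":
        resid = float(np.sum(w * (1.0 + 2.5 * phi - eta_r) ** 2))
        return ModelFitResult("einstein", {}, {}, resid)
    if phi.size < {"quadratic": 2, "mooney": 3}[model]:
        raise ValueError("too few data points for the model")
    if model == "quadratic":
        # linear problem: eta_r - 1 - 2.5 phi = b phi^2
        y = eta_r - 1.0 - 2.5 * phi
        x = phi ** 2
        denom = np.sum(w * x * x)
        if denom == 0:
            raise ValueError("quadratic fit needs a nonzero phi point")
        b = float(np.sum(w * x * y) / denom)
        resid = float(np.sum(w * (y - b * x) ** 2))
        dof = max(phi.size - 1, 1)
        b_se = float(np.sqrt(resid / dof / denom))
        return ModelFitResult("quadratic", {"b": b}, {"b": b_se}, resid)
    if model == "mooney":
        k_max = 0.999 / phi.max() if phi.max() > 0 else np.inf

        def f(phi, S, K):
            return np.exp(S * phi / (1.0 - K * phi))

        popt, pcov = optimize.curve_fit(
            f, phi, eta_r, p0=(2.5, 0.5), sigma=1.0 / np.sqrt(w),
            bounds=([0.0, 0.0], [50.0, k_max]), maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        perr = np.sqrt(np.diag(pcov))
        resid = float(np.sum(w * (f(phi, *popt) - eta_r) ** 2))
        return ModelFitResult("mooney",
                              {"S": float(popt[0]), "K": float(popt[1])},
                              {"S": float(perr[0]), "K": float(perr[1])},
                              resid)
    raise ValueError(f"unknown viscosity model {model!r}")


def fit_cluster_diffusion(phi, D, mode: str = "translational",
                          eta_r_model=None, D0: float | None = None
                          ) -> ModelFitResult:
    """Fit D(φ) = D0/(ηr(φ)·(1+ςφ)^k), k = 1/3 (transl.) or 1 (rot.).

    ``eta_r_model`` is a callable φ→ηr or a ModelFitResult from
    :func:`fit_viscosity_model`.  ``D0`` fixes the dilute-limit
    diffusion; when None it is co-fitted.  ς ≥ 0 is enforced as a bound
    (ς = 0 meaning no clustering).
    """
    phi = np.asarray(phi, dtype=float)
    D = np.asarray(D, dtype=float)
    expo = {"translational": 1.0 / 3.0, "rotational": 1.0}[mode]
    if isinstance(eta_r_model, ModelFitResult):
        m = eta_r_model

        def eta_r(x):
            return relative_viscosity_model(x, m.model, m.params)
    elif callable(eta_r_model):
        eta_r = eta_r_model
    else:
        raise ValueError("eta_r_model must be callable or a ModelFitResult")
    er = eta_r(phi)

    if D0 is None:
        def f(phi_, logD0, sigma):
            return np.exp(logD0) / (er * (1.0 + sigma * phi_) ** expo)
        p0 = (np.log(max(D[np.argmin(phi)], 1e-12)), 1.0)
        popt, pcov = optimize.curve_fit(
            f, phi, D, p0=p0, bounds=([-np.inf, 0.0], [np.inf, np.inf]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        d0_fit = float(np.exp(popt[0]))
        sigma_fit = float(popt[1])
        perr = np.sqrt(np.diag(pcov))
        unc = {"D0": d0_fit * float(perr[0]), "cluster_factor": float(perr[1])}
        params = {"D0": d0_fit, "cluster_factor": sigma_fit}
        resid = float(np.sum((f(phi, *popt) - D) ** 2))
    else:
        def f(phi_, sigma):
            return D0 / (er * (1.0 + sigma * phi_) ** expo)
        popt, pcov = optimize.curve_fit(
            f, phi, D, p0=(1.0,), bounds=(0.0, np.inf), maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        sigma_fit = float(popt[0])
        params = {"D0": float(D0), "cluster_factor": sigma_fit}
        unc = {"D0": 0.0,
               "cluster_factor": float(np.sqrt(np.diag(pcov))[0])}
        resid = float(np.sum((f(phi, *popt) - D) ** 2))
    params["cluster_sizes"] = list(1.0 + sigma_fit * phi)
    name = "cluster_t" if mode == "translational" else "cluster_r"
    return ModelFitResult(name, params, unc, resid)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class ViscosityConcentrationModel:
    """Relative viscosity vs volume fraction under a chosen law."""

    def __init__(self, phi, eta_r, model: str = "mooney", weights=None):
        self.phi = np.asarray(phi, dtype=float)
        self.eta_r = np.asarray(eta_r, dtype=float)
        self.model = model
        self.weights = weights

    def fit(self) -> "ModelFitResults":
        res = fit_viscosity_model(self.phi, self.eta_r, self.model,
                                  self.weights)
        return ModelFitResults(self, res)


class ClusterDiffusionModel:
    """Cluster-corrected diffusion vs volume fraction."""

    def __init__(self, phi, D, mode: str = "translational",
                 eta_r_model=None, D0: float | None = None):
        self.phi = np.asarray(phi, dtype=float)
        self.D = np.asarray(D, dtype=float)
        self.mode = mode
        self.eta_r_model = eta_r_model
        self.D0 = D0

    def fit(self) -> "ModelFitResults":
        res = fit_cluster_diffusion(self.phi, self.D, self.mode,
                                    self.eta_r_model, self.D0)
        return ModelFitResults(self, res)


class ModelFitResults:
    """Generic fitted-parameter results with a summary table."""

    def __init__(self, model, result: ModelFitResult):
        self.model = model
        self.result = result

    @property
    def params(self) -> dict:
        return self.result.params

    def summary(self) -> str:
        lines = [f"Model: {self.result.model}",
                 f"residual sum of squares: {self.result.residual:.4g}"]
        for k, v in self.result.params.items():
            if isinstance(v, list):
                continue
            u = self.result.uncertainties.get(k)
            tail = f" +/- {u:.3g}" if u is not None else ""
            lines.append(f"  {k} = {v:.5g}{tail}")
        return "\n".join(lines)
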