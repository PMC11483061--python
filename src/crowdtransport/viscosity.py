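"""Green-Kubo shear viscosity from ensembles of pressure-tensor series.

The shear viscosity is the infinite-time limit of the running integral

    η(τ) = V/(kB·T) ∫₀^τ ⟨Pαβ(t)·Pαβ(0)⟩ dt

estimated here from many short trajectories: the autocorrelation is
averaged over all nine tensor components (each with its own series mean
removed) and the cross-trajectory standard deviation σ(τ) of the running
integral is fit to a power law A·τ^b.  A double-exponential in
time-integrated form is then fit to the mean η(τ) with weights 1/σ(τ),
whose τ→∞ plateau is the viscosity estimate; τmax is raised until the
estimate is stable within the cross-trajectory uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize
from scipy.fft import irfft, next_fast_len, rfft

from . import units
from .curves import CorrelationCurve
from .pressure import PressureSeries

__all__ = [
    "ViscosityCurve", "ViscosityEstimate", "pressure_acf",
    "running_viscosity", "fit_sigma_power_law", "extrapolate_eta",
    "select_tau_max", "relative_viscosity",
    "GreenKuboViscosity", "GreenKuboViscosityResults",
]


@dataclass
class ViscosityCurve:
    """Running Green-Kubo integrals η_i(τ) across an ensemble.

    ``tau`` in ns, viscosities in cP.  ``eta_traj`` has shape
    (n_traj, n_lags); ``eta`` and ``sigma`` are the ensemble mean and
    standard deviation per lag.
    """

    tau: np.ndarray
    eta_traj: np.ndarray
    eta: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_traj(self) -> int:
        return self.eta_traj.shape[0]


@dataclass
class ViscosityEstimate:
    """Extrapolated plateau viscosity and the protocol's fit parameters."""

    eta: float                      # cP, τ→∞ plateau
    tau_max: float                  # ns
    power_law: tuple[float, float]  # (A, b) of σ(τ) = A·τ^b
    dexp_params: dict               # amplitude/weight/time constants
    uncertainty: float              # cross-trajectory SE at τmax, cP
    n_traj: int
    meta: dict = field(default_factory=dict)


def pressure_acf(series_list: list[PressureSeries],
                 max_lag: float | None = None) -> CorrelationCurve:
    """Component-averaged pressure-tensor autocorrelation per trajectory.

    All nine components enter with equal weight after removal of the
    component's ensemble mean (the diagonal components carry the
    pressure mean); no tensor symmetry is imposed.  The mean is pooled
    across trajectories rather than taken per series: removing each
    series' own sample mean forces its autocorrelation to sum to zero
    over the record and biases the running integral downward by an
    amount comparable to the integral itself once the lag reaches a few
    percent of the series length, while the pooled mean shrinks that
    bias by 1/n_traj.  ``max_lag`` is a lag time in ns (default: a
    quarter of the series length).
    """
    if not series_list:
        raise ValueError("need at least one pressure series")
    dt = series_list[0].dt
    v, t = series_list[0].volume, series_list[0].temperature
    for s in series_list[1:]:
        if not np.isclose(s.dt, dt, rtol=1e-6):
            raise ValueError("inconsistent sample spacing across series")
        if not (np.isclose(s.volume, v) and np.isclose(s.temperature, t)):
            raise ValueError("inconsistent volume/temperature across series")
    n = min(s.n_samples for s in series_list)
    if max_lag is None:
        n_lags = n // 4
    else:
        n_lags = int(round(max_lag / dt))
    if n_lags >= n:
        raise ValueError("max_lag must be shorter than the series")
    counts = n - np.arange(n_lags + 1)
    nfft = next_fast_len(2 * n)
    pooled_mean = np.mean([s.tensors[:n].mean(axis=0)
                           for s in series_list], axis=0)
    per_traj = np.empty((len(series_list), n_lags + 1))
    for i, s in enumerate(series_list):
        x = s.tensors[:n] - pooled_mean
        f = rfft(x, nfft, axis=0)
        acf = irfft(f * np.conj(f), nfft, axis=0)[:n_lags + 1]
        per_traj[i] = acf.mean(axis=1) / counts
    lags = np.arange(n_lags + 1) * dt
    return CorrelationCurve(
        lags, per_traj.mean(axis=0),
        spread=per_traj.std(axis=0, ddof=1) if len(series_list) > 1 else None,
        replicas=per_traj, counts=counts.astype(float),
        meta={"volume": v, "temperature": t, "dt": dt})


def running_viscosity(acf: CorrelationCurve, volume: float | None = None,
                      temperature: float | None = None) -> ViscosityCurve:
    """Cumulative trapezoid of the ACF scaled by V/(kB·T), in cP.

    Integrates each trajectory's curve separately, then summarizes.
    """
    v = volume if volume is not None else acf.meta.get("volume")
    t = temperature if temperature is not None else acf.meta.get("temperature")
    if v is None or t is None:
        raise ValueError("volume and temperature are required")
    pref = units.green_kubo_prefactor(v, t)
    reps = acf.replicas if acf.replicas is not None else acf.values[None, :]
    eta_traj = pref * integrate.cumulative_trapezoid(
        reps, acf.lags, axis=1, initial=0.0)
    return ViscosityCurve(
        acf.lags.copy(), eta_traj, eta_traj.mean(axis=0),
        eta_traj.std(axis=0, ddof=1) if eta_traj.shape[0] > 1
        else np.zeros_like(acf.lags),
        meta={"volume": v, "temperature": t})


def fit_sigma_power_law(curve: ViscosityCurve,
                        fit_range: tuple[float, float] | None = None
                        ) -> tuple[float, float]:
    """Least-squares fit of log σ vs log τ; returns (A, b)."""
    if curve.n_traj < 2:
        raise ValueError("power-law fit needs >= 2 trajectories")
    mask = curve.tau > 0
    if fit_range is not None:
        mask &= (curve.tau >= fit_range[0]) & (curve.tau <= fit_range[1])
    mask &= curve.sigma > 0
    if mask.sum() < 2:
        raise ValueError("sigma(tau) is degenerate (zero spread) on the "
                         "fit range")
    slope, intercept = np.polyfit(np.log(curve.tau[mask]),
                                  np.log(curve.sigma[mask]), 1)
    return float(np.exp(intercept)), float(slope)


def _dexp(tau, amp, alpha, tau1, tau2):
    return amp * (alpha * tau1 * (1.0 - np.exp(-tau / tau1))
                  + (1.0 - alpha) * tau2 * (1.0 - np.exp(-tau / tau2)))


def _dexp_jac(tau, amp, alpha, tau1, tau2):
    e1 = np.exp(-tau / tau1)
    e2 = np.exp(-tau / tau2)
    g1 = tau1 * (1.0 - e1)
    g2 = tau2 * (1.0 - e2)
    return np.stack([
        alpha * g1 + (1.0 - alpha) * g2,                 # d/d amp
        amp * (g1 - g2),                                 # d/d alpha
        amp * alpha * (1.0 - e1 - (tau / tau1) * e1),    # d/d tau1
        amp * (1.0 - alpha) * (1.0 - e2 - (tau / tau2) * e2),
    ], axis=1)


def extrapolate_eta(curve: ViscosityCurve,
                    sigma_fit: tuple[float, float] | None = None,
                    tau_max: float | None = None,
                    n_starts: int = 8) -> ViscosityEstimate:
    """Weighted double-exponential extrapolation of η(τ) to τ→∞.

    The running integral is fit, with weights ∝ 1/σ(τ) from the fitted
    power law, to the time-integrated double-exponential

        η(τ) = A·[α·τ1·(1−e^(−τ/τ1)) + (1−α)·τ2·(1−e^(−τ/τ2))]

    whose plateau A·[α·τ1 + (1−α)·τ2] is the viscosity estimate.
    Multi-start over log-spaced (τ1, τ2) pairs; ties broken by lowest
    weighted residual.
    """
    if tau_max is None:
        tau_max = float(curve.tau[-1])
    mask = (curve.tau > 0) & (curve.tau <= tau_max * (1 + 1e-9))
    if mask.sum() < 5:
        raise ValueError("too few points below tau_max for the fit")
    tau = curve.tau[mask]
    eta = curve.eta[mask]
    if tau.size > 400:    # decimate dense grids; the fit is smooth
        stride = tau.size // 400 + 1
        tau, eta = tau[::stride], eta[::stride]
    if sigma_fit is not None:
        a_pl, b_pl = sigma_fit
        sig = a_pl * tau ** b_pl
        sig = np.where(sig > 0, sig, np.nan)
        weights = np.where(np.isfinite(sig), sig, np.nanmax(sig))
    else:
        a_pl, b_pl = np.nan, np.nan
        weights = np.ones_like(tau)

    eta_scale = max(abs(eta[-1]), abs(eta).max(), 1e-30)
    taus_grid = np.geomspace(tau[0], tau_max, n_starts)
    # sub-grid time constants describe a curve already at its plateau
    t_tiny = tau[0] * 1e-2
    starts = [(eta_scale / t_tiny, 1.0, t_tiny, 3.0 * t_tiny)]
    for i in range(n_starts):
        t1 = taus_grid[i]
        t2 = min(t1 * 10.0, 2.9 * tau_max)
        starts.append((eta_scale / (0.5 * (t1 + t2)), 0.5, t1, t2))
    best = None
    # time constants capped at 3*tau_max: components slower than the fit
    # window are not constrained by the data and destabilize the plateau
    lo = np.array([0.0, 0.0, tau[0] * 1e-3, tau[0] * 1e-3])
    hi = np.array([np.inf, 1.0, 3.0 * tau_max, 3.0 * tau_max])

    def resid_fn(p):
        return (_dexp(tau, *p) - eta) / weights

    def jac_fn(p):
        return _dexp_jac(tau, *p) / weights[:, None]

    floor = 1e-24 * tau.size * eta_scale ** 2
    for p0 in starts:
        p0 = np.clip(p0, lo, np.where(np.isfinite(hi), hi, p0))
        try:
            sol = optimize.least_squares(resid_fn, p0, jac=jac_fn,
                                         bounds=(lo, hi), max_nfev=300)
        except Exception:
            continue
        resid = float(np.sum(sol.fun ** 2))
        if best is None or resid < best[1]:
            best = (sol.x, resid)
        if resid < floor:      # numerically exact fit; stop searching
            break
    if best is None:
        raise RuntimeError("double-exponential fit did not converge from "
                           "any start")
    (amp, alpha, tau1, tau2), resid = best
    eta_inf = float(amp * (alpha * tau1 + (1.0 - alpha) * tau2))
    i_max = int(np.searchsorted(curve.tau, tau_max * (1 + 1e-9)) - 1)
    unc = float(curve.sigma[i_max] / np.sqrt(curve.n_traj))
    return ViscosityEstimate(
        eta=eta_inf, tau_max=float(tau_max), power_law=(a_pl, b_pl),
        dexp_params={"amp": float(amp), "alpha": float(alpha),
                     "tau1": float(tau1), "tau2": float(tau2),
                     "weighted_residual": resid},
        uncertainty=unc, n_traj=curve.n_traj,
        meta={"functional_form":
              "A*[a*t1*(1-exp(-tau/t1)) + (1-a)*t2*(1-exp(-tau/t2))]"})


def select_tau_max(curve: ViscosityCurve,
                   sigma_fit: tuple[float, float] | None = None,
                   candidate_grid: np.ndarray | None = None) -> float:
    """Smallest τmax whose η estimate is stable within uncertainties.

    Evaluates the extrapolated η at increasing candidate τmax values and
    returns the first whose estimate differs from the next one by less
    than the cross-trajectory uncertainty at that τmax.
    """
    if candidate_grid is None:
        end = curve.tau[-1]
        candidate_grid = end * np.array([0.125, 0.25, 0.5, 1.0])
    candidates = np.asarray(candidate_grid, dtype=float)
    if np.any(np.diff(candidates) <= 0):
        raise ValueError("candidate grid must be strictly increasing")
    ests = []
    for c in candidates:
        sf = sigma_fit
        if sf is None and curve.n_traj > 1:
            try:
                sf = fit_sigma_power_law(curve, fit_range=(0, c))
            except ValueError:
                sf = None
        ests.append(extrapolate_eta(curve, sf, c))
    for i in range(len(candidates) - 1):
        unc = max(ests[i].uncertainty, ests[i + 1].uncertainty)
        if abs(ests[i].eta - ests[i + 1].eta) < unc:
            return float(candidates[i])
    raise RuntimeError(
        "viscosity estimate has not plateaued over the candidate tau_max "
        "grid; extend the pressure series or add trajectories")


def relative_viscosity(eta: float, eta_ref: float, u: float = 0.0,
                       u_ref: float = 0.0) -> tuple[float, tuple[float, float]]:
    """Ratio η/η_ref with extreme-ratio bounds (η∓u)/(η_ref±u_ref)."""
    if eta_ref <= 0:
        raise ValueError("reference viscosity must be positive")
    if eta_ref - u_ref <= 0:
        raise ValueError("reference uncertainty exceeds the reference value")
    ratio = eta / eta_ref
    lo = (eta - u) / (eta_ref + u_ref)
    hi = (eta + u) / (eta_ref - u_ref)
    return ratio, (lo, hi)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class GreenKuboViscosity:
    """Green-Kubo viscosity estimator over an ensemble of pressure series.

    Parameters
    ----------
    series : list of PressureSeries
        Independent trajectories sharing spacing, volume and temperature.
    max_lag : float, optional
        Longest autocorrelation lag retained, ns.
    """

    def __init__(self, series: list[PressureSeries],
                 max_lag: float | None = None):
        self.series = list(series)
        self.max_lag = max_lag
        self.acf = pressure_acf(self.series, max_lag)
        self.curve = running_viscosity(self.acf)

    def fit(self, tau_max: float | str = "auto",
            candidate_grid=None,
            sigma_fit_range: tuple[float, float] | None = None
            ) -> "GreenKuboViscosityResults":
        sigma_fit = None
        if self.curve.n_traj > 1:
            try:
                sigma_fit = fit_sigma_power_law(self.curve, sigma_fit_range)
            except ValueError:
                sigma_fit = None
        if tau_max == "auto":
            tau_max = select_tau_max(self.curve, sigma_fit, candidate_grid)
        est = extrapolate_eta(self.curve, sigma_fit, float(tau_max))
        return GreenKuboViscosityResults(self, est)


class GreenKuboViscosityResults:
    """Fitted plateau viscosity with protocol diagnostics."""

    def __init__(self, model: GreenKuboViscosity, estimate: ViscosityEstimate):
        self.model = model
        self.estimate = estimate

    @property
    def eta(self) -> float:
        return self.estimate.eta

    @property
    def uncertainty(self) -> float:
        return self.estimate.uncertainty

    def relative_to(self, eta_ref: float, u_ref: float = 0.0):
        return relative_viscosity(self.eta, eta_ref,
                                  self.estimate.uncertainty, u_ref)

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Green-Kubo viscosity estimate",
            "=============================",
            f"trajectories          : {e.n_traj}",
            f"tau_max               : {e.tau_max * 1e3:.3g} ps",
            f"eta (extrapolated)    : {e.eta:.4g} +/- {e.uncertainty:.2g} cP",
            f"sigma power law       : A={e.power_law[0]:.4g}, "
            f"b={e.power_law[1]:.3g}",
            f"double-exp plateau fit: alpha={e.dexp_params['alpha']:.3g}, "
            f"tau1={e.dexp_params['tau1'] * 1e3:.3g} ps, "
            f"tau2={e.dexp_params['tau2'] * 1e3:.3g} ps",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Running integral with the fitted extrapolation curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.tau * 1e3, c.eta, label="mean $\\eta(\\tau)$")
        ax.fill_between(c.tau * 1e3, c.eta - c.sigma, c.eta + c.sigma,
                        alpha=0.3, label="$\\pm\\sigma(\\tau)$")
        p = self.estimate.dexp_params
        fit = _dexp(c.tau, p["amp"], p["alpha"], p["tau1"], p["tau2"])
        ax.plot(c.tau * 1e3, fit, "--", label="double-exp fit")
        ax.axhline(self.eta, color="k", lw=0.8, label="plateau")
        ax.set_xlabel("lag time (ps)")
        ax.set_ylabel("viscosity (cP)")
        ax.legend()
        return ax
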