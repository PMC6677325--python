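"""Growth laws for the accumulation of hybrid incompatibilities.

Two phenomenological laws describe the replicate-averaged DMI count I(t)
versus divergence time t = mu*t:

* saturating power law (small populations, drift-dominated ancestors):

      I(t) = I0 * t/(T + t) * (1 - exp(-(t/tau)^(gamma-1)))

  which grows as t^gamma for t << tau, T and saturates at I0.  gamma near 2
  for the total count matches the combinatorial expectation for pairwise
  incompatibilities.

* sub-diffusive first-passage law (large populations, ancestors far from
  the inviability boundary):

      I(t) = A * erfc( K* / sqrt(4 (mu t)^beta) )

  the fraction of fractional-Brownian hybrid traits that have crossed a
  boundary K* effective substitutions away; beta = 1 is normal diffusion,
  beta < 1 sub-diffusion.

The models follow the statsmodels idiom: construct from a
:class:`~dsdrift.dmi.DMITimeSeries` (or raw arrays), call ``fit()``, get a
results object with estimates, standard errors, covariance and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .dmi import DMITimeSeries, decompose_timeseries

__all__ = [
    "DMITimeSeries",
    "aggregate",
    "power_law_curve",
    "subdiffusion_curve",
    "GrowthLawResults",
    "PowerLawGrowthModel",
    "SubdiffusionGrowthModel",
    "fit_power_law",
    "fit_subdiffusion",
    "model_select",
]


def aggregate(runs, grid=None) -> DMITimeSeries:
    """Replicate-averaged DMI time series on a common grid (mean +/- SE)."""
    return decompose_timeseries(runs, grid=grid)


def power_law_curve(t, I0, T, tau, gamma):
    """Saturating power law; ~ (I0/(T tau^(gamma-1))) t^gamma as t -> 0."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = I0 * t / (T + t) * -np.expm1(-((t / tau) ** (gamma - 1.0)))
    return np.where(t > 0, out, 0.0)


def subdiffusion_curve(t, A, K_star, beta, mu=1.0):
    """Fractional-diffusion first-passage curve; -> A as t -> inf."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = A * special.erfc(K_star / np.sqrt(4.0 * (mu * t) ** beta))
    return np.where(t > 0, out, 0.0)


@dataclass
class GrowthLawResults:
    """Estimates and diagnostics of one growth-law fit.

    ``params`` maps parameter names to point estimates; ``bse`` to standard
    errors (NaN if the Jacobian was degenerate).  ``success`` is False for a
    failed optimisation - the object is still returned so callers can
    inspect ``message``.
    """

    model: "GrowthLawModel"
    params: dict
    bse: dict
    cov: np.ndarray
    cost: float
    n_obs: int
    success: bool
    message: str

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def aicc(self) -> float:
        """Small-sample-corrected Akaike criterion on the fit residuals."""
        n, k = self.n_obs, self.k_params
        if n <= k + 1:
            return np.inf
        rss = 2.0 * self.cost
        return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    def predict(self, t) -> np.ndarray:
        return self.model.curve(t, *self.params.values())

    def summary(self) -> str:
        lines = [
            f"{self.model.name} growth-law fit",
            "=" * 46,
            f"{'parameter':<10}{'estimate':>14}{'std err':>14}",
            "-" * 46,
        ]
        for name in self.params:
            lines.append(
                f"{name:<10}{self.params[name]:>14.5g}{self.bse[name]:>14.3g}")
        lines += [
            "-" * 46,
            f"n_obs {self.n_obs}   cost {self.cost:.4g}   "
            f"AICc {self.aicc:.4g}   converged {self.success}",
        ]
        return "\n".join(lines)


class GrowthLawModel:
    """Base weighted nonlinear least squares on log-transformed counts.

    Only strictly positive ordinates enter the log-space objective; weights
    are relative standard errors from the replicate SEM, floored at 2% so a
    lucky zero-variance point cannot dominate.
    """

    name = "growth-law"
    param_names: tuple = ()
    bounds: tuple = ()

    def __init__(self, series, component: str = "total", t=None, y=None,
                 sem=None):
        if series is not None:
            t = np.asarray(series.mu_t, dtype=float)
            y = np.asarray(series.mean[component], dtype=float)
            sem = np.asarray(series.sem[component], dtype=float)
        else:
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
            sem = np.zeros_like(y) if sem is None else np.asarray(sem, float)
        keep = (t > 0) & (y > 0)
        self.t, self.y = t[keep], y[keep]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(self.y > 0, sem[keep] / self.y, np.inf)
        self.sigma_log = np.clip(rel, 0.02, np.inf)
        if self.t.size < len(self.param_names) + 2:
            raise ValueError(
                f"need at least {len(self.param_names) + 2} informative "
                f"(t > 0, I > 0) points, got {self.t.size}")

    def curve(self, t, *params):  # pragma: no cover - abstract
        raise NotImplementedError

    def _initial_guess(self) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _residuals(self, p: np.ndarray) -> np.ndarray:
        f = np.clip(self.curve(self.t, *p), 1e-300, None)
        return (np.log(self.y) - np.log(f)) / self.sigma_log

    def fit(self, n_starts: int = 8, seed: int = 0) -> GrowthLawResults:
        """Multi-start weighted least squares; returns the best converged fit.

        Starts are the moment-based guess plus ``n_starts - 1`` lognormally
        jittered copies (fixed ``seed``); non-convergence yields a results
        object with ``success=False`` rather than an exception.
        """
        rng = np.random.default_rng(seed)
        p0 = self._initial_guess()
        lo, hi = (np.array(b, dtype=float) for b in zip(*self.bounds))
        starts = [p0]
        for _ in range(n_starts - 1):
            starts.append(np.clip(p0 * rng.lognormal(0.0, 0.4, p0.size),
                                  lo * 1.0001, hi * 0.9999))
        best = None
        for s in starts:
            try:
                res = optimize.least_squares(
                    self._residuals, np.clip(s, lo * 1.0001, hi * 0.9999),
                    bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12,
                    gtol=1e-12, max_nfev=20000)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            nanp = {n: np.nan for n in self.param_names}
            return GrowthLawResults(self, nanp, dict(nanp),
                                    np.full((len(nanp),) * 2, np.nan),
                                    np.inf, self.t.size, False,
                                    "all optimiser starts failed")
        n, k = self.t.size, len(self.param_names)
        dof = max(n - k, 1)
        s2 = 2.0 * best.cost / dof
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.pinv(jtj)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
            bse = np.full(k, np.nan)
        return GrowthLawResults(
            model=self,
            params=dict(zip(self.param_names, best.x)),
            bse=dict(zip(self.param_names, bse)),
            cov=cov, cost=float(best.cost), n_obs=n,
            success=bool(best.success), message=str(best.message))


class PowerLawGrowthModel(GrowthLawModel):
    """I(t) = I0 t/(T+t) (1 - exp(-(t/tau)^(gamma-1)))."""

    name = "power-law"
    param_names = ("I0", "T", "tau", "gamma")
    bounds = ((1e-12, 1e6), (1e-9, 1e9), (1e-9, 1e9), (1.01, 8.0))

    def curve(self, t, I0, T, tau, gamma):
        return power_law_curve(t, I0, T, tau, gamma)

    def _initial_guess(self) -> np.ndarray:
        ymax = self.y.max()
        i = int(np.argmin(np.abs(self.y - ymax / 2.0)))
        T = max(self.t[i], self.t[0])
        return np.array([1.3 * ymax, T, T, 2.0])


class SubdiffusionGrowthModel(GrowthLawModel):
    """I(t) = A erfc(K*/sqrt(4 (mu t)^beta)); mu fixed, not estimated."""

    name = "sub-diffusion"
    param_names = ("A", "K_star", "beta")
    bounds = ((1e-12, 1e6), (1e-3, 1e3), (0.05, 3.0))

    def __init__(self, series, component: str = "total", mu: float = 1.0,
                 t=None, y=None, sem=None):
        super().__init__(series, component=component, t=t, y=y, sem=sem)
        if not mu > 0:
            raise ValueError("mu must be > 0")
        self.mu = float(mu)

    def curve(self, t, A, K_star, beta):
        return subdiffusion_curve(t, A, K_star, beta, mu=self.mu)

    def _initial_guess(self) -> np.ndarray:
        ymax = self.y.max()
        A = 1.1 * ymax
        i = int(np.argmin(np.abs(self.y - ymax / 2.0)))
        # erfc(u) = 1/2 at u ~ 0.4769
        t_half = max(self.mu * self.t[i], 1e-9)
        beta0 = 0.5
        K0 = 0.4769 * np.sqrt(4.0 * t_half ** beta0)
        return np.array([A, max(K0, 1e-2), beta0])


def fit_power_law(series, component: str = "total", **fit_kw) -> GrowthLawResults:
    """Fit the saturating power law to a DMI time series."""
    return PowerLawGrowthModel(series, component=component).fit(**fit_kw)


def fit_subdiffusion(series, mu: float = 1.0, component: str = "total",
                     **fit_kw) -> GrowthLawResults:
    """Fit the sub-diffusive erfc law to a DMI time series."""
    return SubdiffusionGrowthModel(series, component=component, mu=mu).fit(**fit_kw)


def model_select(series, component: str = "total", mu: float = 1.0,
                 tie_tol: float = 2.0):
    """Fit both growth laws and label the better one by AICc.

    Returns (label, power_fit, subdiff_fit); label is "power_law",
    "subdiffusion", or "ambiguous" when the AICc difference is below
    ``tie_tol``.  Raises only if both fits fail outright.
    """
    pl = fit_power_law(series, component=component)
    sd = fit_subdiffusion(series, mu=mu, component=component)
    if not (pl.success or sd.success):
        raise RuntimeError("both growth-law fits failed to converge")
    if not pl.success:
        return "subdiffusion", pl, sd
    if not sd.success:
        return "power_law", pl, sd
    diff = pl.aicc - sd.aicc
    if abs(diff) < tie_tol:
        label = "ambiguous"
    else:
        label = "power_law" if diff < 0 else "subdiffusion"
    return label, pl, sd
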