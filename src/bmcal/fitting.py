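"""Exponential time-constant regression of deflection traces.

A first-order (lumped-mass) system stepped at ``t = 0`` has the tip
displacement

    v(t) = v_inf - (v_inf - v0) exp(-t / tau),

and fitting this three-parameter model to a measured trace is the
calibration of the instrument: ``tau`` is the thermal time constant of
whatever is convectively cooling (beam alone, or beam + sample).  The model
is fit by unweighted nonlinear least squares in the (v_inf, v0, tau)
parameterisation, with standard errors from the Jacobian at the optimum.

The interface follows the statsmodels idiom: build an
:class:`ExponentialDecayModel` from data, call :meth:`~ExponentialDecayModel.fit`,
get an :class:`ExponentialFitResults` with ``params``, ``bse``,
``cov_params``, ``rsquared`` and ``summary()``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import DomainError
from .mechanics import DeflectionTrace

__all__ = [
    "ExponentialDecayModel",
    "ExponentialFitResults",
    "DegenerateTraceError",
    "fit_exponential",
    "initial_guess",
]

PARAM_NAMES = ("v_inf", "v0", "tau")


class DegenerateTraceError(ValueError):
    """The trace carries no usable exponential signal (e.g. constant)."""


def initial_guess(trace: DeflectionTrace,
                  rel_tol: float = 1e-12) -> tuple[float, float, float]:
    """Moment-style starting values ``(v_inf, v0, tau)``.

    ``v_inf`` is the mean of the last decile of the trace, ``v0`` the first
    point, and ``tau`` the interpolated time at which the trace first
    crosses ``v0 + (1 - 1/e)(v_inf - v0)``.  A trace whose total excursion
    is below ``rel_tol`` of its magnitude (or identically zero) is rejected
    as degenerate.
    """
    t, v = trace.times, trace.tip
    if t.size < 4:
        raise DomainError("need at least 4 points for a 3-parameter fit")
    n_tail = max(1, t.size // 10)
    v_inf = float(np.mean(v[-n_tail:]))
    v0 = float(v[0])
    scale = max(abs(v_inf), abs(v0), float(np.max(np.abs(v))))
    if abs(v_inf - v0) <= rel_tol * max(scale, 1e-300):
        raise DegenerateTraceError("flat trace: v_inf ~ v0, time constant "
                                   "unidentifiable")
    target = v0 + (1.0 - math.exp(-1.0)) * (v_inf - v0)
    # first crossing of the e-folding level, by linear interpolation
    sgn = np.sign(v_inf - v0)
    crossed = np.nonzero(sgn * (v - target) >= 0)[0]
    if crossed.size and crossed[0] > 0:
        i = crossed[0]
        f = (target - v[i - 1]) / (v[i] - v[i - 1])
        tau = float(t[i - 1] + f * (t[i] - t[i - 1]) - t[0])
    elif crossed.size:
        tau = float(t[1] - t[0])
    else:  # never reaches the e-folding level: use a third of the span
        tau = float((t[-1] - t[0]) / 3.0)
    tau = max(tau, float(t[1] - t[0]) * 1e-3)
    return v_inf, v0, tau


@dataclass
class ExponentialFitResults:
    """Fit output: parameters, covariance and diagnostics.

    ``params`` is ``(v_inf, v0, tau)`` in SI units (m, m, s);
    ``cov_params`` the 3x3 covariance from the Jacobian scaled by the
    residual variance.  ``summary()`` prints in the instrument's natural
    units (um, ms).
    """

    model: "ExponentialDecayModel"
    params: np.ndarray
    cov: np.ndarray
    rss: float
    converged: bool
    nfev: int
    message: str

    @property
    def v_inf(self) -> float:
        return float(self.params[0])

    @property
    def v0(self) -> float:
        return float(self.params[1])

    @property
    def tau(self) -> float:
        return float(self.params[2])

    @property
    def nobs(self) -> int:
        return self.model.times.size

    @property
    def df_resid(self) -> int:
        return self.nobs - 3

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (v_inf, v0, tau)."""
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def cov_params(self) -> np.ndarray:
        return self.cov

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.displacement - self.fittedvalues

    @property
    def rsquared(self) -> float:
        y = self.model.displacement
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0.0:
            return float("nan")
        return 1.0 - self.rss / tss

    def to_dict(self) -> dict:
        return {
            "v_inf_m": self.v_inf,
            "v0_m": self.v0,
            "tau_s": self.tau,
            "se_v_inf_m": float(self.bse[0]),
            "se_v0_m": float(self.bse[1]),
            "se_tau_s": float(self.bse[2]),
            "rss_m2": self.rss,
            "rsquared": self.rsquared,
            "nobs": self.nobs,
            "converged": self.converged,
            "meta": self.model.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        # trailing newline keeps the file friendly to text tools
        with open(path, "a") as fh:
            fh.write("\n")

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Exponential approach fit: v(t) = v_inf - (v_inf - v0) exp(-t/tau)",
            f"  n obs             : {self.nobs}",
            f"  v_inf             : {self.v_inf * 1e6:12.4f} um  "
            f"(se {se[0] * 1e6:.2e})",
            f"  v0                : {self.v0 * 1e6:12.4f} um  "
            f"(se {se[1] * 1e6:.2e})",
            f"  tau               : {self.tau * 1e3:12.4f} ms  "
            f"(se {se[2] * 1e3:.2e})",
            f"  RSS               : {self.rss:.6e} m^2",
            f"  R-squared         : {self.rsquared:.9f}",
            f"  converged         : {self.converged}",
        ]
        return "\n".join(lines)


class ExponentialDecayModel:
    """Three-parameter exponential-approach model of a deflection trace.

    Parameters
    ----------
    times, displacement : array-like
        Sampled trace; times strictly increasing, at least 4 points.
    meta : dict, optional
        Provenance carried through to the results.

    Examples
    --------
    >>> model = ExponentialDecayModel.from_trace(trace)   # doctest: +SKIP
    >>> res = model.fit()                                 # doctest: +SKIP
    >>> print(res.summary())                              # doctest: +SKIP
    """

    def __init__(self, times, displacement, meta: dict | None = None):
        self.times = np.asarray(times, dtype=float)
        self.displacement = np.asarray(displacement, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if self.displacement.shape != self.times.shape:
            raise DomainError("displacement/time length mismatch")
        if not np.all(np.isfinite(self.displacement)):
            raise DomainError("displacement must be finite")
        if self.times.size < 4:
            raise DomainError("need at least 4 points for a 3-parameter fit")
        self.meta = dict(meta or {})

    @classmethod
    def from_trace(cls, trace: DeflectionTrace) -> "ExponentialDecayModel":
        return cls(trace.times, trace.tip, meta=trace.meta)

    def as_trace(self) -> DeflectionTrace:
        return DeflectionTrace(self.times, self.displacement, self.meta)

    def predict(self, params) -> np.ndarray:
        v_inf, v0, tau = params
        return v_inf - (v_inf - v0) * np.exp(-self.times / tau)

    def _residuals(self, params) -> np.ndarray:
        return self.predict(params) - self.displacement

    def _jacobian(self, params) -> np.ndarray:
        v_inf, v0, tau = params
        e = np.exp(-self.times / tau)
        J = np.empty((self.times.size, 3))
        J[:, 0] = 1.0 - e
        J[:, 1] = e
        J[:, 2] = -(v_inf - v0) * e * self.times / tau ** 2
        return J

    def fit(self, start_params=None, xtol: float = 1e-14,
            loss: str = "linear") -> ExponentialFitResults:
        """Nonlinear least squares from the moment-based starting values.

        ``loss`` is passed to :func:`scipy.optimize.least_squares`
        (``"linear"`` = plain least squares, the default; ``"soft_l1"``
        etc. give robust variants).  Non-convergence is reported through
        the ``converged`` flag rather than an exception.
        """
        if start_params is None:
            start_params = initial_guess(self.as_trace())
        sol = least_squares(self._residuals, np.asarray(start_params, float),
                            jac=self._jacobian,
                            method="lm" if loss == "linear" else "trf",
                            xtol=xtol, ftol=xtol, loss=loss)
        rss = float(2.0 * sol.cost)
        dof = max(self.times.size - 3, 1)
        sigma2 = rss / dof
        JTJ = sol.jac.T @ sol.jac
        try:
            cov = sigma2 * np.linalg.inv(JTJ)
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
        converged = bool(sol.success and sol.x[2] > 0)
        return ExponentialFitResults(model=self, params=sol.x, cov=cov,
                                     rss=rss, converged=converged,
                                     nfev=sol.nfev, message=str(sol.message))


def fit_exponential(trace: DeflectionTrace, **kw) -> ExponentialFitResults:
    """Convenience wrapper: fit the exponential model to a trace."""
    return ExponentialDecayModel.from_trace(trace).fit(**kw)


def fit_report(results: ExponentialFitResults) -> str:
    """Human-readable fit summary (alias for ``results.summary()``)."""
    return results.summary()
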