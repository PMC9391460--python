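"""Dose-response fitting for microscale thermophoresis (MST) titrations.

Three model objects, each built from a :class:`DoseResponse` and fitted by
(weighted) nonlinear least squares via :mod:`lmfit`:

``QuadraticIsothermModel``
    The exact 1:1 binding isotherm at finite labelled-receptor
    concentration ``F`` (the "K_D fit"): the fraction bound is the
    physical root of the binding quadratic, so the model is valid when the
    titrant concentration is comparable to the receptor concentration.

``HillModel``
    The empirical sigmoidal dose-response
    ``f(c) = unbound + (bound - unbound) / (1 + (EC50/c)^n)``, used when
    the midpoint (EC50) rather than a true dissociation constant is the
    quantity of interest.

``TwoSiteModel``
    A symmetric receptor with two identical, independent ligand sites of
    intrinsic dissociation constant K; free ligand is solved exactly
    (ligand depletion included) and the signal is linear in the average
    site occupancy.  A one-parameter profile of the error surface over K
    provides the confidence interval (68.3% by default).

All models return a :class:`FitResult`; ``summary()`` gives a printable
parameter table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit

__all__ = [
    "DoseResponse",
    "FitResult",
    "QuadraticIsothermModel",
    "HillModel",
    "TwoSiteModel",
    "merge_replicates",
    "quadratic_isotherm",
    "hill_curve",
    "two_site_curve",
]


@dataclass
class DoseResponse:
    """One titration series: signal versus titrant concentration (uM).

    Concentrations must be strictly positive; the series is sorted by
    concentration on construction.  ``signal_err`` are per-point standard
    errors used as least-squares weights when present.
    """

    conc: np.ndarray
    signal: np.ndarray
    signal_err: np.ndarray | None = None
    replicate_id: str | None = None

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal_err is not None:
            self.signal_err = np.asarray(self.signal_err, dtype=float)
        if self.conc.shape != self.signal.shape:
            raise ValueError("conc and signal must have equal length")
        if self.signal_err is not None and self.signal_err.shape != self.conc.shape:
            raise ValueError("signal_err length mismatch")
        if np.any(~np.isfinite(self.conc)) or np.any(~np.isfinite(self.signal)):
            raise ValueError("conc/signal must be finite")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        order = np.argsort(self.conc)
        self.conc = self.conc[order]
        self.signal = self.signal[order]
        if self.signal_err is not None:
            self.signal_err = self.signal_err[order]
        if np.any(np.diff(self.conc) <= 0):
            raise ValueError("concentrations must be distinct")

    def __len__(self):
        return self.conc.size


@dataclass
class FitResult:
    """Fitted parameters with uncertainties for one dose-response model."""

    params: dict[str, float]
    param_sd: dict[str, float]
    rss: float
    converged: bool
    model_name: str
    ci: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    message: str = ""
    warnings: list[str] = field(default_factory=list)
    ndata: int = 0

    @property
    def kd_or_ec50(self) -> float:
        for key in ("kd", "ec50", "k"):
            if key in self.params:
                return self.params[key]
        raise KeyError("no affinity parameter in fit")  # pragma: no cover

    def summary(self) -> str:
        lines = [f"{self.model_name} fit  (n = {self.ndata}, rss = {self.rss:.4g}, "
                 f"converged = {self.converged})"]
        for name, value in self.params.items():
            sd = self.param_sd.get(name, float("nan"))
            line = f"  {name:>10s} = {value:12.6g} +/- {sd:.3g}"
            if name in self.ci:
                lo, hi, level = self.ci[name]
                hi_s = "inf" if math.isinf(hi) else f"{hi:.6g}"
                line += f"   {100 * level:.1f}% CI [{lo:.6g}, {hi_s}]"
            lines.append(line)
        lines.extend(f"  warning: {w}" for w in self.warnings)
        return "\n".join(lines)


# -- model functions -------------------------------------------------------

def quadratic_isotherm(c, unbound, bound, kd, fluo_conc):
    """Exact 1:1 isotherm at labelled concentration ``fluo_conc``.

    Bound fraction = (F + c + K - sqrt((F + c + K)^2 - 4 F c)) / (2 F);
    bounded by [unbound, bound] and monotone in c.
    """
    c = np.asarray(c, dtype=float)
    s = fluo_conc + c + kd
    frac = (s - np.sqrt(s * s - 4.0 * fluo_conc * c)) / (2.0 * fluo_conc)
    return unbound + (bound - unbound) * frac


def hill_curve(c, unbound, bound, ec50, n):
    c = np.asarray(c, dtype=float)
    return unbound + (bound - unbound) / (1.0 + (ec50 / c) ** n)


def two_site_curve(c, unbound, bound, k, receptor_conc):
    """Signal for a receptor with two identical independent sites.

    Free ligand L solves L + 2 R0 L/(L+K) = c exactly (positive root of
    L^2 + (K + 2 R0 - c) L - c K = 0); the signal follows the average site
    occupancy L/(L+K).
    """
    c = np.asarray(c, dtype=float)
    b = k + 2.0 * receptor_conc - c
    l_free = 0.5 * (-b + np.sqrt(b * b + 4.0 * c * k))
    occ = l_free / (l_free + k)
    return unbound + (bound - unbound) * occ


# -- fitting machinery -----------------------------------------------------

def _initial_levels(data: DoseResponse) -> tuple[float, float]:
    """unbound/bound starting values from the first/last deciles."""
    n = len(data)
    k = max(1, n // 10)
    return float(np.mean(data.signal[:k])), float(np.mean(data.signal[-k:]))


def _log_midpoint_starts(data: DoseResponse, n_starts: int = 5) -> np.ndarray:
    lo, hi = math.log(data.conc[0]), math.log(data.conc[-1])
    return np.exp(np.linspace(lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo),
                              n_starts))


class _LeastSquaresMixin:
    """Shared multi-start weighted least-squares driver."""

    affinity_name: str = "kd"
    model_name: str = "model"

    def __init__(self, data: DoseResponse):
        self.data = data
        self.weights = (1.0 / data.signal_err
                        if data.signal_err is not None and
                        np.all(data.signal_err > 0) else None)

    def _eval(self, params: lmfit.Parameters) -> np.ndarray:
        raise NotImplementedError

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        r = self._eval(params) - self.data.signal
        return r * self.weights if self.weights is not None else r

    def _make_params(self, affinity_start: float) -> lmfit.Parameters:
        raise NotImplementedError

    def fit(self) -> FitResult:
        best = None
        for start in _log_midpoint_starts(self.data):
            p0 = self._make_params(start)
            try:
                out = lmfit.minimize(self._residual, p0, method="leastsq")
            except Exception:  # pragma: no cover - pathological start
                continue
            if best is None or out.chisqr < best.chisqr:
                best = out
        if best is None:  # pragma: no cover
            return FitResult({}, {}, math.nan, False, self.model_name,
                             message="all starts failed", ndata=len(self.data))
        params = {k: float(v.value) for k, v in best.params.items()}
        sds = {k: (float(v.stderr) if v.stderr is not None else math.nan)
               for k, v in best.params.items() if v.vary}
        rss = float(np.sum((self._eval(best.params) - self.data.signal) ** 2))
        warnings_ = []
        aff = best.params[self.affinity_name]
        if aff.vary and (math.isclose(aff.value, aff.min, rel_tol=1e-3) or
                         (math.isfinite(aff.max) and
                          math.isclose(aff.value, aff.max, rel_tol=1e-3))):
            warnings_.append(f"{self.affinity_name} at parameter bound")
        converged = bool(best.success) and aff.value > 0
        result = FitResult(params=params, param_sd=sds, rss=rss,
                           converged=converged, model_name=self.model_name,
                           message=str(best.message), warnings=warnings_,
                           ndata=len(self.data))
        self._last_minimizer_result = best
        return result


class QuadraticIsothermModel(_LeastSquaresMixin):
    """1:1 binding isotherm at fixed labelled-receptor concentration."""

    affinity_name = "kd"
    model_name = "quadratic 1:1 isotherm"

    def __init__(self, data: DoseResponse, fluo_conc: float):
        if len(data) < 5:
            raise ValueError("need at least 5 points")
        if not fluo_conc > 0:
            raise ValueError("fluo_conc must be > 0")
        super().__init__(data)
        self.fluo_conc = float(fluo_conc)

    def _make_params(self, affinity_start):
        unb, bnd = _initial_levels(self.data)
        p = lmfit.Parameters()
        p.add("unbound", value=unb)
        p.add("bound", value=bnd)
        p.add("kd", value=affinity_start, min=1e-9, max=1e6)
        return p

    def _eval(self, params):
        return quadratic_isotherm(self.data.conc, params["unbound"].value,
                                  params["bound"].value, params["kd"].value,
                                  self.fluo_conc)


class HillModel(_LeastSquaresMixin):
    """Sigmoidal EC50 model with optionally fixed Hill coefficient."""

    affinity_name = "ec50"
    model_name = "Hill dose-response"

    def __init__(self, data: DoseResponse, fix_n: float | None = None):
        if len(data) < 5:
            raise ValueError("need at least 5 points")
        super().__init__(data)
        self.fix_n = fix_n

    def _make_params(self, affinity_start):
        unb, bnd = _initial_levels(self.data)
        p = lmfit.Parameters()
        p.add("unbound", value=unb)
        p.add("bound", value=bnd)
        p.add("ec50", value=affinity_start, min=1e-9, max=1e6)
        if self.fix_n is None:
            p.add("hill_n", value=1.0, min=0.3, max=4.0)
        else:
            p.add("hill_n", value=float(self.fix_n), vary=False)
        return p

    def _eval(self, params):
        return hill_curve(self.data.conc, params["unbound"].value,
                          params["bound"].value, params["ec50"].value,
                          params["hill_n"].value)


class TwoSiteModel(_LeastSquaresMixin):
    """Symmetric receptor with two identical independent sites.

    ``fit`` additionally profiles the error surface over the intrinsic K
    to produce a confidence interval at ``ci_level`` (68.3% default, the
    one-sigma level: delta-chi-square = 1 with the variance estimated from
    the residuals at the optimum).  An upper bound beyond the profiled
    range is reported as an open (infinite) interval.
    """

    affinity_name = "k"
    model_name = "symmetric two-site"

    def __init__(self, data: DoseResponse, receptor_conc: float,
                 ci_level: float = 0.683):
        if len(data) < 8:
            raise ValueError("need at least 8 points")
        if not receptor_conc > 0:
            raise ValueError("receptor_conc must be > 0")
        super().__init__(data)
        self.receptor_conc = float(receptor_conc)
        self.ci_level = float(ci_level)

    def _make_params(self, affinity_start):
        unb, bnd = _initial_levels(self.data)
        p = lmfit.Parameters()
        p.add("unbound", value=unb)
        p.add("bound", value=bnd)
        p.add("k", value=affinity_start, min=1e-9, max=1e6)
        return p

    def _eval(self, params):
        return two_site_curve(self.data.conc, params["unbound"].value,
                              params["bound"].value, params["k"].value,
                              self.receptor_conc)

    def _rss_at_fixed_k(self, k: float) -> float:
        p = self._make_params(k)
        p["k"].set(value=k, vary=False)
        out = lmfit.minimize(self._residual, p, method="leastsq")
        return float(np.sum((self._eval(out.params) - self.data.signal) ** 2))

    def fit(self) -> FitResult:
        result = super().fit()
        if not result.converged:
            return result
        k_hat = result.params["k"]
        n, npar = len(self.data), 3
        s2 = result.rss / max(n - npar, 1)
        # chi^2 profile threshold at the requested level for one parameter
        from scipy.stats import chi2
        from scipy.optimize import brentq
        thresh = result.rss + s2 * chi2.ppf(self.ci_level, df=1)

        def excess(k):
            return self._rss_at_fixed_k(k) - thresh

        # bracket each crossing on a log grid, then refine by root search
        lo_grid = k_hat * np.geomspace(1e-4, 1.0, 25)[:-1][::-1]
        lo = 0.0  # profile may stay below threshold down to k -> 0
        for k in lo_grid:
            if excess(k) > 0:
                lo = float(brentq(excess, k, k_hat, rtol=1e-6))
                break
        hi_grid = k_hat * np.geomspace(1.0, 1e4, 25)[1:]
        hi = math.inf
        for k in hi_grid:
            if excess(k) > 0:
                hi = float(brentq(excess, k_hat, k, rtol=1e-6))
                break
        if math.isinf(hi):
            result.warnings.append("upper profile CI unbounded in scanned range")
        result.ci["k"] = (lo, hi, self.ci_level)
        return result


def merge_replicates(replicates: Sequence[DoseResponse]) -> DoseResponse:
    """Average replicate titrations point-wise (standard error in the mean).

    All replicates must share an identical concentration grid.  A single
    replicate is returned unchanged with undefined errors.
    """
    if not replicates:
        raise ValueError("no replicates given")
    first = replicates[0]
    if len(replicates) == 1:
        return DoseResponse(first.conc.copy(), first.signal.copy(),
                            signal_err=None, replicate_id=first.replicate_id)
    for r in replicates[1:]:
        if not np.allclose(r.conc, first.conc, rtol=1e-12, atol=0):
            raise ValueError("replicate concentration grids differ")
    stack = np.vstack([r.signal for r in replicates])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / math.sqrt(stack.shape[0])
    return DoseResponse(first.conc.copy(), mean, signal_err=sem,
                        replicate_id="merged")
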