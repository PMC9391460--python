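"""Biphasic thermal-denaturation analysis (DSF fluorescence, CD ellipticity).

A protein population containing two oligomeric species that unfold
independently shows *biphasic* melting: two sigmoidal transitions at the
melting temperatures of the two species (here: a dimer near 48-55 degC and
a tetramer near 85-88 degC).  The model fitted is a sum of two logistic
transitions on a linear baseline::

    signal(T) = b0 + b1*T + decay + amp1*sigma((T-tm1)/w1) + amp2*sigma((T-tm2)/w2)

with ``sigma`` the logistic function.  For DSF data an exponential
low-temperature dye signal (maximal near the start of the ramp and decaying
with temperature) is included by default; CD curves omit it.  The logistic
shape is used rather than a two-state van't Hoff model because only the
transition midpoints (Tm), not unfolding enthalpies, are extracted.

``tm_by_derivative`` provides a model-free cross-check: smoothed
first-derivative extrema of the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import lmfit
from scipy.signal import savgol_filter, argrelextrema

__all__ = ["MeltCurve", "BiphasicFit", "BiphasicMeltModel", "fit_biphasic",
           "tm_by_derivative", "normalize_curves"]


@dataclass
class MeltCurve:
    """(temperature, signal) series from a thermal ramp (~1 degC steps)."""

    temperature: np.ndarray
    signal: np.ndarray
    modality: Literal["dsf", "cd"] = "dsf"

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if self.modality not in ("dsf", "cd"):
            raise ValueError(f"unknown modality {self.modality!r}")

    def __len__(self):
        return self.temperature.size


@dataclass
class BiphasicFit:
    """Two-transition melt fit: midpoints, widths, amplitudes, baseline."""

    tm1: float
    tm2: float
    slope1: float
    slope2: float
    amp1: float
    amp2: float
    baseline: tuple[float, float]
    rss: float
    lowT_decay: tuple[float, float] | None = None
    param_sd: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def tms(self) -> tuple[float, float]:
        return self.tm1, self.tm2

    def summary(self) -> str:
        lines = [f"biphasic melt fit (rss = {self.rss:.4g})",
                 f"  tm1 = {self.tm1:.2f} degC (width {self.slope1:.2f}, "
                 f"amp {self.amp1:.3g})",
                 f"  tm2 = {self.tm2:.2f} degC (width {self.slope2:.2f}, "
                 f"amp {self.amp2:.3g})"]
        lines.extend(f"  warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def _model(T, p, with_decay):
    sig1 = 1.0 / (1.0 + np.exp(-(T - p["tm1"]) / p["slope1"]))
    sig2 = 1.0 / (1.0 + np.exp(-(T - p["tm2"]) / p["slope2"]))
    out = (p["b0"] + p["b1"] * T + p["amp1"] * sig1 + p["amp2"] * sig2)
    if with_decay:
        out = out + p["dec_amp"] * np.exp(-p["dec_rate"] * (T - T[0]))
    return out


class BiphasicMeltModel:
    """Least-squares model for a two-transition melt curve."""

    def __init__(self, curve: MeltCurve, include_decay: bool | None = None):
        self.curve = curve
        # DSF dye release produces a strong decaying signal at low T
        self.include_decay = (curve.modality == "dsf"
                              if include_decay is None else include_decay)

    def fit(self, tm_guesses: tuple[float, float] | None = None) -> BiphasicFit:
        T, y = self.curve.temperature, self.curve.signal
        span = float(np.ptp(y)) or 1.0
        if tm_guesses is None:
            guesses = tm_by_derivative(self.curve)
            if len(guesses) >= 2:
                tm_guesses = (guesses[0], guesses[-1])
            else:
                lo, hi = T[0], T[-1]
                tm_guesses = (lo + 0.3 * (hi - lo), lo + 0.75 * (hi - lo))

        p = lmfit.Parameters()
        p.add("b0", value=float(y[0]))
        p.add("b1", value=0.0)
        p.add("tm1", value=tm_guesses[0], min=T[0], max=T[-1])
        p.add("tm2", value=tm_guesses[1], min=T[0], max=T[-1])
        p.add("slope1", value=1.5, min=0.05, max=20.0)
        p.add("slope2", value=1.5, min=0.05, max=20.0)
        p.add("amp1", value=0.4 * span)
        p.add("amp2", value=0.4 * span)
        if self.include_decay:
            p.add("dec_amp", value=0.3 * span, min=0.0)
            p.add("dec_rate", value=0.1, min=1e-3, max=2.0)

        def resid(params):
            vals = {k: params[k].value for k in params}
            return _model(T, vals, self.include_decay) - y

        out = lmfit.minimize(resid, p, method="leastsq")
        v = {k: float(out.params[k].value) for k in out.params}
        # enforce tm1 < tm2 labelling
        if v["tm1"] > v["tm2"]:
            for a, b in (("tm1", "tm2"), ("slope1", "slope2"),
                         ("amp1", "amp2")):
                v[a], v[b] = v[b], v[a]
        rss = float(np.sum(resid(out.params) ** 2))
        warnings_ = []
        if abs(v["amp2"]) < 1e-3 * span or abs(v["amp1"]) < 1e-3 * span:
            warnings_.append("one transition amplitude is pinned near zero; "
                             "data may be single-transition")
        sds = {k: (float(pv.stderr) if pv.stderr is not None else math.nan)
               for k, pv in out.params.items()}
        return BiphasicFit(
            tm1=v["tm1"], tm2=v["tm2"], slope1=v["slope1"], slope2=v["slope2"],
            amp1=v["amp1"], amp2=v["amp2"], baseline=(v["b0"], v["b1"]),
            rss=rss,
            lowT_decay=((v["dec_amp"], v["dec_rate"])
                        if self.include_decay else None),
            param_sd=sds, converged=bool(out.success), warnings=warnings_)


def fit_biphasic(curve: MeltCurve, **kwargs) -> BiphasicFit:
    return BiphasicMeltModel(curve, **kwargs).fit()


def tm_by_derivative(curve: MeltCurve, smooth_window: int = 7) -> list[float]:
    """Candidate melting temperatures from smoothed derivative extrema.

    The first derivative of the (Savitzky-Golay smoothed) curve is scanned
    for local maxima of its magnitude in the direction of the unfolding
    signal change; each extremum temperature is one candidate Tm.  Fewer
    extrema than expected yield a shorter list.
    """
    if len(curve) < 20:
        raise ValueError("need at least 20 points")
    window = min(smooth_window | 1, len(curve) - 1)
    if window % 2 == 0:
        window -= 1
    window = max(window, 5)
    dT = np.gradient(curve.temperature)
    smoothed = savgol_filter(curve.signal, window, polyorder=3)
    deriv = np.gradient(smoothed) / dT
    # unfolding direction: dominant sign of the derivative over the ramp
    sign = 1.0 if np.nanmax(deriv) >= -np.nanmin(deriv) else -1.0
    d = sign * deriv
    idx = argrelextrema(d, np.greater, order=3)[0]
    # keep clear extrema only: above 10% of the strongest
    if idx.size:
        idx = idx[d[idx] > 0.1 * d[idx].max()]
    return [float(curve.temperature[i]) for i in idx]


def normalize_curves(curves: Sequence[MeltCurve],
                     mode: Literal["shift", "max"] = "max",
                     anchor_temperature: float | None = None) -> list[MeltCurve]:
    """Normalize curves for overlay plots.

    mode="max": divide each curve by its maximum absolute signal.
    mode="shift": additively offset each curve so that all agree (value 0)
    at the anchor temperature (default: midpoint of the common range).
    Both modes are idempotent.
    """
    if not curves:
        raise ValueError("no curves given")
    out = []
    if mode == "max":
        for c in curves:
            m = float(np.max(np.abs(c.signal)))
            if m == 0:
                raise ValueError("cannot max-normalize an all-zero curve")
            out.append(MeltCurve(c.temperature.copy(), c.signal / m, c.modality))
    elif mode == "shift":
        if anchor_temperature is None:
            lo = max(c.temperature[0] for c in curves)
            hi = min(c.temperature[-1] for c in curves)
            anchor_temperature = 0.5 * (lo + hi)
        for c in curves:
            anchor_val = float(np.interp(anchor_temperature, c.temperature,
                                         c.signal))
            out.append(MeltCurve(c.temperature.copy(), c.signal - anchor_val,
                                 c.modality))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out
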