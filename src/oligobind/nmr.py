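"""NMR-derived quantities: pKa titrations, CSPs, and STD epitope mapping.

pKa determination
    The chemical shift of a reporter proton near a single titratable group
    is a population-weighted average of the protonated (acid) and
    deprotonated (base) limiting shifts.  With Henderson-Hasselbalch
    populations this gives

        delta(pH) = (delta_HA + delta_A * 10^(pH - pKa)) / (1 + 10^(pH - pKa))

    fitted by least squares over the titration; the plateau shifts can be
    floated (default) or fixed from the end-point spectra.

Chemical shift perturbation (CSP)
    Combined amide perturbation per residue,
    ``sqrt(dH^2 + (w_N * dN)^2)`` with the community-standard nitrogen
    weight ``w_N = 0.14`` for 1H-15N correlation spectra.

STD epitope
    Per-proton STD effect ``(I0 - Isat)/I0`` (the STD-spectrum intensity
    over the off-resonance reference); the largest effect is set to 100%
    and relative intensities map the ligand epitope.  The STD
    amplification factor scales the effect by the ligand molar excess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit
import pandas as pd

__all__ = ["ShiftTitration", "PeakPair", "StdSpectrumRow", "PkaFitResult",
           "PkaTitrationModel", "fit_pka", "csp", "std_epitope",
           "henderson_hasselbalch_shift"]


@dataclass
class ShiftTitration:
    """pH-dependent chemical shifts (ppm) of one reporter proton."""

    ph: np.ndarray
    shift: np.ndarray
    reporter: str = ""

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if self.ph.shape != self.shift.shape:
            raise ValueError("ph and shift must have equal length")
        if np.any((self.ph < 0) | (self.ph > 14)):
            raise ValueError("pH values must lie within [0, 14]")

    def __len__(self):
        return self.ph.size


@dataclass
class PeakPair:
    """Amide 1H/15N shift differences (apo vs complex) for one residue."""

    residue: str
    dH: float
    dN: float

    def __post_init__(self):
        if not (math.isfinite(self.dH) and math.isfinite(self.dN)):
            raise ValueError("shift differences must be finite")


@dataclass
class StdSpectrumRow:
    """Per-proton intensities: off-resonance reference and STD spectrum."""

    proton: str
    i_off: float
    i_std: float

    def __post_init__(self):
        if not self.i_off > 0:
            raise ValueError("off-resonance intensity must be > 0")
        if not 0 <= self.i_std <= self.i_off:
            raise ValueError("STD intensity must lie in [0, i_off]")


def henderson_hasselbalch_shift(ph, pka, delta_acid, delta_base):
    """Observed shift of a fast-exchange reporter over a single pKa."""
    ph = np.asarray(ph, dtype=float)
    r = np.power(10.0, ph - pka)
    return (delta_acid + delta_base * r) / (1.0 + r)


@dataclass
class PkaFitResult:
    pka: float
    delta_acid: float
    delta_base: float
    param_sd: dict[str, float]
    rss: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"Henderson-Hasselbalch fit (rss = {self.rss:.4g})",
                 f"  pKa        = {self.pka:.4f} +/- "
                 f"{self.param_sd.get('pka', float('nan')):.4f}",
                 f"  delta_acid = {self.delta_acid:.4f} ppm",
                 f"  delta_base = {self.delta_base:.4f} ppm"]
        lines.extend(f"  warning: {w}" for w in self.warnings)
        return "\n".join(lines)


class PkaTitrationModel:
    """Single-site Henderson-Hasselbalch model of a shift titration.

    ``fix_plateaus=True`` pins the limiting shifts to the lowest- and
    highest-pH points (the end-point-spectra convention); by default both
    plateaus are free parameters.
    """

    def __init__(self, titration: ShiftTitration, fix_plateaus: bool = False):
        if len(titration) < 5:
            raise ValueError("need at least 5 titration points")
        self.titration = titration
        self.fix_plateaus = fix_plateaus

    def fit(self) -> PkaFitResult:
        t = self.titration
        order = np.argsort(t.ph)
        ph, shift = t.ph[order], t.shift[order]
        p = lmfit.Parameters()
        # midpoint guess: pH at half shift change
        mid = 0.5 * (shift[0] + shift[-1])
        i_mid = int(np.argmin(np.abs(shift - mid)))
        p.add("pka", value=float(ph[i_mid]), min=0.0, max=14.0)
        p.add("delta_acid", value=float(shift[0]), vary=not self.fix_plateaus)
        p.add("delta_base", value=float(shift[-1]), vary=not self.fix_plateaus)

        def resid(params):
            return henderson_hasselbalch_shift(
                ph, params["pka"].value, params["delta_acid"].value,
                params["delta_base"].value) - shift

        out = lmfit.minimize(resid, p, method="leastsq")
        rss = float(np.sum(resid(out.params) ** 2))
        sds = {k: (float(v.stderr) if v.stderr is not None else math.nan)
               for k, v in out.params.items()}
        warnings_ = []
        pka = float(out.params["pka"].value)
        span = abs(float(out.params["delta_base"].value) -
                   float(out.params["delta_acid"].value))
        # plateau coverage check: titration should bracket the transition
        if pka - ph[0] < 1.0 or ph[-1] - pka < 1.0:
            warnings_.append("titration does not span both plateaus; "
                             "pKa poorly determined")
        if span == 0:
            warnings_.append("no shift change across titration")
        return PkaFitResult(
            pka=pka, delta_acid=float(out.params["delta_acid"].value),
            delta_base=float(out.params["delta_base"].value),
            param_sd=sds, rss=rss, converged=bool(out.success),
            warnings=warnings_)


def fit_pka(titration: ShiftTitration, fix_plateaus: bool = False) -> PkaFitResult:
    return PkaTitrationModel(titration, fix_plateaus).fit()


def csp(pairs: Sequence[PeakPair], nitrogen_weight: float = 0.14) -> pd.DataFrame:
    """Combined amide chemical-shift perturbation per residue (ppm)."""
    rows = [{"residue": p.residue,
             "csp": math.sqrt(p.dH ** 2 + (nitrogen_weight * p.dN) ** 2)}
            for p in pairs]
    return pd.DataFrame(rows, columns=["residue", "csp"])


def std_epitope(rows: Sequence[StdSpectrumRow],
                excess_ratio: float = 100.0) -> pd.DataFrame:
    """STD effects, epitope-normalized percentages, amplification factors.

    The proton with the largest STD effect defines 100%; ``a_std`` is the
    STD amplification factor (effect times ligand molar excess).
    """
    if not rows:
        raise ValueError("no STD rows given")
    effects = np.array([r.i_std / r.i_off for r in rows])
    if np.all(effects == 0):
        raise ValueError("all STD intensities are zero")
    rel = 100.0 * effects / effects.max()
    return pd.DataFrame({
        "proton": [r.proton for r in rows],
        "std_effect": effects,
        "relative_pct": rel,
        "a_std": effects * excess_ratio,
    })
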