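"""Coupled tetramer-dimer-ligand binding equilibrium.

A homotetramer T dissociates into two dimers D (dissociation constant
``K_tet = [D]^2/[T]``), and a small-molecule ligand L binds the dimer in two
successive steps::

    T  <=>  2 D,        K_tet = [D]^2 / [T]
    D + L  <=>  DL,     K_1
    DL + L <=>  DLL,    K_2

Under the default ``macroscopic_equal`` site model the two stepwise
(macroscopic) constants are identical, ``K_1 = K_2 = K_lig`` — appropriate
when the two binding sites on a C2-symmetric dimer are distant and
non-interacting and the experiment resolves only macroscopic steps.  The
``intrinsic_statistical`` alternative treats ``K_lig`` as the intrinsic
per-site constant and applies the statistical factors of two independent
identical sites (``K_1 = K_lig/2``, ``K_2 = 2*K_lig``).

Protein amounts are expressed throughout in *monomer-equivalent* units, so
mass balance reads ``4[T] + 2([D] + [DL] + [DLL]) = P_total``.

The observable modelled for a dose-response experiment is the fraction of
protein monomer units residing in ligand-bound dimeric species,
``f = 2([DL] + [DLL]) / P_total``, which rises from 0 to 1 with total
ligand; its half-saturation point is the model EC50.  Inverting the model
EC50 for ``K_lig`` at known ``K_tet`` and protein concentration converts a
measured dose-response midpoint into a ligand dissociation constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EquilibriumParams",
    "SpeciesState",
    "UncertainValue",
    "CoupledEquilibrium",
    "SolverError",
    "solve_species",
    "dimer_fraction",
    "bound_fraction_curve",
    "model_ec50",
    "klig_from_ec50",
    "propagate_klig_error",
]

SiteModel = Literal["macroscopic_equal", "intrinsic_statistical"]

#: bracket for all 1-D root searches on concentrations / constants, in uM
_BRACKET = (1e-12, 1e4)
_REL_TOL = 1e-10


class SolverError(RuntimeError):
    """Root search failed; carries the residual diagnostics."""

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


@dataclass(frozen=True)
class EquilibriumParams:
    """Equilibrium constants of the coupled scheme (uM units).

    k_tet : dissociation constant of T <=> 2D, defined as [D]^2/[T].
    k_lig : stepwise (``macroscopic_equal``) or intrinsic per-site
        (``intrinsic_statistical``) ligand dissociation constant.
    """

    k_tet: float
    k_lig: float = math.inf
    site_model: SiteModel = "macroscopic_equal"

    def __post_init__(self):
        if not self.k_tet > 0:
            raise ValueError(f"k_tet must be > 0, got {self.k_tet}")
        if not self.k_lig > 0:
            raise ValueError(f"k_lig must be > 0, got {self.k_lig}")
        if self.site_model not in ("macroscopic_equal", "intrinsic_statistical"):
            raise ValueError(f"unknown site_model {self.site_model!r}")

    @property
    def stepwise_constants(self) -> tuple[float, float]:
        """Macroscopic (K1, K2) implied by the site model."""
        if self.site_model == "macroscopic_equal":
            return self.k_lig, self.k_lig
        return self.k_lig / 2.0, 2.0 * self.k_lig


@dataclass(frozen=True)
class SpeciesState:
    """Solved species concentrations (uM) at one composition.

    Protein totals are monomer-equivalents: 4[T] + 2([D]+[DL]+[DLL]) = P.
    """

    conc_T: float
    conc_D: float
    conc_DL: float
    conc_DLL: float
    conc_L_free: float
    protein_total_monomer: float
    ligand_total: float

    @property
    def dimer_fraction(self) -> float:
        """Fraction of monomer units in free dimers."""
        return 2.0 * self.conc_D / self.protein_total_monomer

    @property
    def bound_fraction(self) -> float:
        """Fraction of monomer units in ligand-bound dimeric species."""
        return 2.0 * (self.conc_DL + self.conc_DLL) / self.protein_total_monomer

    @property
    def tetramer_fraction(self) -> float:
        return 4.0 * self.conc_T / self.protein_total_monomer

    def mass_balance_residuals(self) -> tuple[float, float]:
        """Relative residuals of the protein and ligand balances."""
        p = 4 * self.conc_T + 2 * (self.conc_D + self.conc_DL + self.conc_DLL)
        rp = (p - self.protein_total_monomer) / self.protein_total_monomer
        l = self.conc_L_free + self.conc_DL + 2 * self.conc_DLL
        rl = 0.0 if self.ligand_total == 0 else (l - self.ligand_total) / self.ligand_total
        return rp, rl


@dataclass
class UncertainValue:
    """A point estimate with a standard deviation and optional interval."""

    value: float
    sd: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: Literal["monte_carlo", "profile"] | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValueError("value must lie within [ci_low, ci_high]")

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.value:.4g} +/- {self.sd:.2g}"


class CoupledEquilibrium:
    """Model object for the coupled T <=> 2D <=> DL <=> DLL equilibrium.

    Parameters
    ----------
    k_tet, k_lig : float
        Dissociation constants in uM (see :class:`EquilibriumParams`).
    site_model : {"macroscopic_equal", "intrinsic_statistical"}
    """

    def __init__(self, k_tet: float, k_lig: float = math.inf,
                 site_model: SiteModel = "macroscopic_equal"):
        self.params = EquilibriumParams(k_tet, k_lig, site_model)

    # -- core solver -------------------------------------------------------

    def _dimer_at_free_ligand(self, protein_total: float, l_free: float) -> float:
        """[D] from the protein balance at a fixed free-ligand concentration.

        With beta = 1 + L/K1 + L^2/(K1*K2) the balance is the quadratic
        (4/k_tet) d^2 + 2*beta*d - P = 0; the numerically stable positive
        root 2P / (2*beta + sqrt(4*beta^2 + 16P/k_tet)) is used so that the
        strong-tetramer and no-tetramer (k_tet -> inf) limits are both exact.
        """
        k1, k2 = self.params.stepwise_constants
        beta = 1.0 + l_free / k1 + (l_free * l_free) / (k1 * k2)
        b = 2.0 * beta
        a4p = 16.0 * protein_total / self.params.k_tet
        return 2.0 * protein_total / (b + math.sqrt(b * b + a4p))

    def solve_species(self, protein_total_monomer: float,
                      ligand_total: float = 0.0) -> SpeciesState:
        """Solve the mass-balance system for one composition.

        Reduces the protein balance to a closed form in [D] at fixed free
        ligand, then locates the free-ligand concentration satisfying the
        ligand balance by bracketed root search (free ligand cannot exceed
        total ligand).
        """
        if not protein_total_monomer > 0:
            raise ValueError("protein_total_monomer must be > 0")
        if ligand_total < 0:
            raise ValueError("ligand_total must be >= 0")
        k1, k2 = self.params.stepwise_constants
        p = float(protein_total_monomer)
        lt = float(ligand_total)

        if lt == 0.0:
            l_free = 0.0
        else:
            def residual(l):
                d = self._dimer_at_free_ligand(p, l)
                bound = d * (l / k1 + 2.0 * l * l / (k1 * k2))
                return l + bound - lt

            try:
                l_free = brentq(residual, 0.0, lt, xtol=5e-324,
                                rtol=1e-15, maxiter=200)
            except (RuntimeError, ValueError) as exc:  # pragma: no cover
                raise SolverError(
                    "free-ligand balance did not converge",
                    {"residual_at_total": residual(lt)}) from exc

        d = self._dimer_at_free_ligand(p, l_free)
        state = SpeciesState(
            conc_T=d * d / self.params.k_tet,
            conc_D=d,
            conc_DL=d * l_free / k1,
            conc_DLL=d * l_free * l_free / (k1 * k2),
            conc_L_free=l_free,
            protein_total_monomer=p,
            ligand_total=lt,
        )
        rp, rl = state.mass_balance_residuals()
        if abs(rp) > 1e-9 or abs(rl) > 1e-9:  # pragma: no cover
            raise SolverError("mass balance violated after solve",
                              {"protein": rp, "ligand": rl})
        return state

    # -- derived observables ----------------------------------------------

    def dimer_fraction(self, protein_total_monomer: float) -> float:
        """Fraction of monomer units in dimers at zero ligand."""
        return self.solve_species(protein_total_monomer, 0.0).dimer_fraction

    def bound_fraction(self, protein_total_monomer: float,
                       ligand_total: float) -> float:
        return self.solve_species(protein_total_monomer,
                                  ligand_total).bound_fraction

    def bound_fraction_curve(self, protein_total_monomer: float,
                             ligand_grid: Sequence[float]) -> np.ndarray:
        """Bound-dimer fraction versus total ligand (monotone non-decreasing)."""
        grid = np.asarray(ligand_grid, dtype=float)
        if np.any(grid < 0):
            raise ValueError("ligand_grid must be non-negative")
        if np.any(np.diff(grid) < 0):
            raise ValueError("ligand_grid must be sorted ascending")
        return np.array([
            self.bound_fraction(protein_total_monomer, l) for l in grid
        ])

    def species_table(self, protein_total_monomer: float,
                      ligand_grid: Sequence[float]):
        """Species-distribution curves as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for lt in ligand_grid:
            s = self.solve_species(protein_total_monomer, lt)
            rows.append({
                "ligand_total_uM": lt, "T": s.conc_T, "D": s.conc_D,
                "DL": s.conc_DL, "DLL": s.conc_DLL, "L_free": s.conc_L_free,
                "bound_fraction": s.bound_fraction,
            })
        return pd.DataFrame(rows)

    def ec50(self, protein_total_monomer: float) -> float:
        """Total ligand at which the bound-dimer fraction is 1/2.

        Unique by monotonicity; bracketed search, expanded upward if the
        default bracket does not reach half-saturation.
        """
        if not math.isfinite(self.params.k_lig):
            raise ValueError("ec50 requires a finite k_lig")

        def g(lt):
            return self.bound_fraction(protein_total_monomer, lt) - 0.5

        lo, hi = _BRACKET
        while g(hi) < 0 and hi < 1e12:
            hi *= 10.0
        if g(hi) < 0:  # pragma: no cover
            raise SolverError("bound fraction never reaches 1/2",
                              {"f_at_hi": g(hi) + 0.5})
        return brentq(g, lo, hi, rtol=_REL_TOL, maxiter=200)

    # -- EC50 inversion ----------------------------------------------------

    @classmethod
    def from_ec50(cls, ec50: float, k_tet: float, protein_total_monomer: float,
                  site_model: SiteModel = "macroscopic_equal") -> "CoupledEquilibrium":
        """Construct the model whose EC50 matches a measured one.

        Finds the k_lig for which :meth:`ec50` returns the measured value
        (monotone 1-D root search over the bracket).  Round-trips with
        :meth:`ec50` to 1e-6 relative.
        """
        if not ec50 > 0:
            raise ValueError("ec50 must be > 0")

        def g(log_k):
            model = cls(k_tet, math.exp(log_k), site_model)
            return model.ec50(protein_total_monomer) - ec50

        lo, hi = math.log(_BRACKET[0]), math.log(_BRACKET[1])
        try:
            log_k = brentq(g, lo, hi, rtol=1e-12, maxiter=200)
        except ValueError as exc:
            raise SolverError(
                f"no k_lig in [{_BRACKET[0]:g}, {_BRACKET[1]:g}] uM "
                f"reproduces EC50 = {ec50:g} uM") from exc
        return cls(k_tet, math.exp(log_k), site_model)

    def propagate_klig_error(self, ec50: UncertainValue, k_tet: UncertainValue,
                             protein_total_monomer: float,
                             n_draws: int = 10_000, *,
                             seed: int) -> UncertainValue:
        """Monte-Carlo propagation of (EC50, K_tet) uncertainty into K_lig.

        Draws are independent Gaussians truncated at zero; each draw is
        mapped through the EC50 inversion.  Deterministic for a given seed.
        A warning is recorded on the result if more than 10% of draws fail
        to invert.
        """
        if n_draws < 1000:
            raise ValueError("n_draws must be >= 1000")
        rng = np.random.default_rng(seed)

        def truncated(mean, sd, n):
            if sd == 0:
                return np.full(n, mean)
            out = rng.normal(mean, sd, size=n)
            while True:
                bad = out <= 0
                if not bad.any():
                    return out
                out[bad] = rng.normal(mean, sd, size=int(bad.sum()))

        e_draws = truncated(ec50.value, ec50.sd, n_draws)
        k_draws = truncated(k_tet.value, k_tet.sd, n_draws)
        values = np.empty(n_draws)
        n_failed = 0
        for i in range(n_draws):
            try:
                values[i] = type(self).from_ec50(
                    e_draws[i], k_draws[i], protein_total_monomer,
                    self.params.site_model).params.k_lig
            except SolverError:
                values[i] = np.nan
                n_failed += 1
        ok = values[np.isfinite(values)]
        notes = []
        if n_failed > 0.10 * n_draws:
            notes.append(f"{n_failed}/{n_draws} Monte-Carlo draws failed to invert")
            warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
        lo, hi = (np.percentile(ok, [15.87, 84.13]) if ok.size else (np.nan, np.nan))
        mean = float(np.mean(ok))
        return UncertainValue(value=mean, sd=float(np.std(ok, ddof=1)),
                              ci_low=min(float(lo), mean),
                              ci_high=max(float(hi), mean),
                              method="monte_carlo", warnings=notes)


# -- functional façade (mirrors the assay-pipeline call sites) -------------

def solve_species(params: EquilibriumParams, protein_total_monomer: float,
                  ligand_total: float = 0.0) -> SpeciesState:
    m = CoupledEquilibrium(params.k_tet, params.k_lig, params.site_model)
    return m.solve_species(protein_total_monomer, ligand_total)


def dimer_fraction(params: EquilibriumParams, protein_total_monomer: float) -> float:
    return solve_species(params, protein_total_monomer, 0.0).dimer_fraction


def bound_fraction_curve(params: EquilibriumParams, protein_total_monomer: float,
                         ligand_grid: Sequence[float]) -> np.ndarray:
    m = CoupledEquilibrium(params.k_tet, params.k_lig, params.site_model)
    return m.bound_fraction_curve(protein_total_monomer, ligand_grid)


def model_ec50(params: EquilibriumParams, protein_total_monomer: float) -> float:
    m = CoupledEquilibrium(params.k_tet, params.k_lig, params.site_model)
    return m.ec50(protein_total_monomer)


def klig_from_ec50(ec50: float, k_tet: float, protein_total_monomer: float,
                   site_model: SiteModel = "macroscopic_equal") -> float:
    return CoupledEquilibrium.from_ec50(
        ec50, k_tet, protein_total_monomer, site_model).params.k_lig


def propagate_klig_error(ec50: UncertainValue, k_tet: UncertainValue,
                         protein_total_monomer: float, n_draws: int = 10_000,
                         *, seed: int,
                         site_model: SiteModel = "macroscopic_equal") -> UncertainValue:
    m = CoupledEquilibrium(k_tet.value, site_model=site_model)
    return m.propagate_klig_error(ec50, k_tet, protein_total_monomer,
                                  n_draws, seed=seed)
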