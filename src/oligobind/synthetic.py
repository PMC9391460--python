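"""Seeded synthetic-data generators for every analysis stage.

Each generator emulates the statistical structure of the corresponding
experiment at its canonical design and returns ``(data, truth)`` so that
recovery tests can assert against the planted ground truth.  All
generators are bit-reproducible given their seed; the seed is mandatory.

Canonical designs (the experimental conditions the generators default to):

* MST K_D titration: 16-point serial 1:1 (factor-2) dilution from 500 uM
  down to ~15 nM, labelled receptor 0.1 uM, Gaussian noise 1% of the
  signal span, technical triplicates.
* MST EC50 titration: 16-point factor-2 dilution from 4000 uM down to
  ~0.122 uM, Hill coefficient 1.2, noise 2% of span.
* Thermal melts: 25-95 degC ramp in 1 degC steps (71 points), dimer and
  tetramer transitions (CD: ~48/88 degC; DSF: ~55/85 degC plus a
  low-temperature dye-release decay maximal at the start of the ramp).
* pH titration: 23 points, pH 2-13 in 0.5 steps, Henderson-Hasselbalch
  shifts.
* Ligand-diffusion trajectory: toy 4-chain symmetric bundle (one heavy
  atom per residue, 61 residues per chain -> 244-bit fingerprints) with
  planted sticky epitopes.
* Permeability calibration: 9 compounds on a line with Gaussian residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .contacts import SymmetryMap
from .melting import MeltCurve
from .mst import DoseResponse, hill_curve, quadratic_isotherm
from .nmr import ShiftTitration, henderson_hasselbalch_shift
from .permeability import CalibrationPoint

__all__ = ["GeneratorSpec", "gen_mst", "gen_melt", "gen_ph_titration",
           "gen_contact_trajectory", "gen_calibration", "ToyTrajectory",
           "serial_dilution_grid"]


def serial_dilution_grid(c_max: float, n_points: int = 16,
                         ratio: float = 2.0) -> np.ndarray:
    """Concentration grid of a serial 1:ratio dilution, ascending."""
    return c_max / ratio ** np.arange(n_points - 1, -1, -1, dtype=float)


def gen_mst(kind: str = "kd", *, seed: int,
            k: float = 1.60, ec50: float = 2.5, hill_n: float = 1.2,
            fluo_conc: float = 0.1, c_max: float | None = None,
            n_points: int = 16, unbound: float = 900.0, bound: float = 820.0,
            noise_frac: float | None = None, n_replicates: int = 1
            ) -> tuple[list[DoseResponse], dict[str, Any]]:
    """Synthetic MST titration(s) from the 1:1 isotherm or the Hill model.

    ``noise_frac`` is the Gaussian noise sd as a fraction of the signal
    span (defaults: 1% for "kd", 2% for "hill").  Returns a list of
    replicate series plus the ground truth.
    """
    if kind not in ("kd", "hill"):
        raise ValueError(f"unknown MST generator kind {kind!r}")
    rng = np.random.default_rng(seed)
    if c_max is None:
        c_max = 500.0 if kind == "kd" else 4000.0
    if noise_frac is None:
        noise_frac = 0.01 if kind == "kd" else 0.02
    conc = serial_dilution_grid(c_max, n_points)
    if kind == "kd":
        clean = quadratic_isotherm(conc, unbound, bound, k, fluo_conc)
        truth = {"k": k, "fluo_conc": fluo_conc}
    else:
        clean = hill_curve(conc, unbound, bound, ec50, hill_n)
        truth = {"ec50": ec50, "hill_n": hill_n}
    span = abs(bound - unbound)
    sd = noise_frac * span
    reps = [DoseResponse(conc.copy(),
                         clean + rng.normal(0.0, sd, conc.size) if sd > 0
                         else clean.copy(),
                         replicate_id=f"rep{i + 1}")
            for i in range(n_replicates)]
    truth.update(unbound=unbound, bound=bound, noise_sd=sd, conc=conc,
                 clean_signal=clean)
    return reps, truth


def gen_melt(modality: str = "cd", *, seed: int,
             tm1: float | None = None, tm2: float | None = None,
             slope1: float = 1.5, slope2: float = 1.5,
             amp1: float = 0.45, amp2: float = 0.55,
             t_min: float = 25.0, t_max: float = 95.0, step: float = 1.0,
             noise_frac: float = 0.01,
             decay_amp: float = 0.6, decay_rate: float = 0.12
             ) -> tuple[MeltCurve, dict[str, Any]]:
    """Synthetic biphasic melt curve (CD default: Tm 48/88; DSF: 55/85).

    The DSF variant adds the exponential low-temperature dye signal that
    is maximal at the start of the ramp.
    """
    if modality not in ("cd", "dsf"):
        raise ValueError(f"unknown modality {modality!r}")
    if tm1 is None:
        tm1 = 48.0 if modality == "cd" else 55.0
    if tm2 is None:
        tm2 = 88.0 if modality == "cd" else 85.0
    rng = np.random.default_rng(seed)
    T = np.arange(t_min, t_max + 0.5 * step, step)
    sig = (amp1 / (1.0 + np.exp(-(T - tm1) / slope1))
           + amp2 / (1.0 + np.exp(-(T - tm2) / slope2)))
    if modality == "dsf":
        sig = sig + decay_amp * np.exp(-decay_rate * (T - T[0]))
    span = float(np.ptp(sig))
    noisy = sig + rng.normal(0.0, noise_frac * span, T.size) \
        if noise_frac > 0 else sig
    truth = {"tm1": tm1, "tm2": tm2, "slope1": slope1, "slope2": slope2,
             "amp1": amp1, "amp2": amp2, "noise_sd": noise_frac * span}
    return MeltCurve(T, noisy, modality), truth


def gen_ph_titration(*, seed: int, pka: float = 3.99,
                     delta_acid: float = 4.10, delta_base: float = 3.85,
                     ph_min: float = 2.0, ph_max: float = 13.0,
                     step: float = 0.5, noise_sd: float = 0.0,
                     reporter: str = "H2"
                     ) -> tuple[ShiftTitration, dict[str, Any]]:
    """Synthetic Henderson-Hasselbalch shift titration (23 points default)."""
    rng = np.random.default_rng(seed)
    ph = np.arange(ph_min, ph_max + 0.5 * step, step)
    clean = henderson_hasselbalch_shift(ph, pka, delta_acid, delta_base)
    shift = clean + rng.normal(0.0, noise_sd, ph.size) if noise_sd > 0 \
        else clean
    truth = {"pka": pka, "delta_acid": delta_acid, "delta_base": delta_base,
             "noise_sd": noise_sd}
    return ShiftTitration(ph, shift, reporter), truth


# -- toy ligand-diffusion trajectory ---------------------------------------

@dataclass
class ToyTrajectory:
    """Toy symmetric homotetramer plus a per-frame ligand trajectory.

    One heavy (pseudo-)atom per residue; chains stacked as a square
    four-helix bundle.  ``labels`` give the planted state per frame:
    -1 for unbound, otherwise the planted epitope index.
    """

    protein_coords_by_residue: list[np.ndarray]
    chain_of_residue: np.ndarray
    ligand_frames: list[np.ndarray]
    labels: np.ndarray
    epitope_residues: list[np.ndarray] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.protein_coords_by_residue)

    @property
    def n_frames(self) -> int:
        return len(self.ligand_frames)

    def symmetry_map(self) -> SymmetryMap:
        n_per_chain = self.n_residues // 4
        return SymmetryMap.dimer_of_dimers(n_per_chain)

    def reference_protein(self) -> np.ndarray:
        return np.concatenate(self.protein_coords_by_residue)


def _bundle_topology(n_per_chain: int, rise: float = 1.5,
                     half_side: float = 4.0) -> tuple[list[np.ndarray], np.ndarray]:
    """Four straight chains at the corners of a square, one atom/residue."""
    corners = np.array([[+half_side, +half_side],
                        [-half_side, +half_side],
                        [+half_side, -half_side],
                        [-half_side, -half_side]])
    coords, chain_ids = [], []
    z = (np.arange(n_per_chain) - (n_per_chain - 1) / 2.0) * rise
    for ci, (x, y) in enumerate(corners):
        for zz in z:
            coords.append(np.array([[x, y, zz]]))
            chain_ids.append(ci)
    return coords, np.array(chain_ids)


def gen_contact_trajectory(*, seed: int, n_frames: int = 200,
                           n_per_chain: int = 61, n_epitopes: int = 3,
                           stickiness: float = 0.8, bit_noise: float = 0.10,
                           ligand_atoms: int = 3
                           ) -> tuple[ToyTrajectory, dict[str, Any]]:
    """Toy free-diffusion trajectory with planted binding epitopes.

    ``stickiness`` is the probability that a frame is bound to one of the
    planted epitopes (uniformly chosen); unbound frames place the ligand
    far from the protein so that no residue is within the contact cutoff.
    Bound frames put the ligand atoms near a contiguous stretch of epitope
    residues; ``bit_noise`` jitters the ligand position along the chain so
    that ~that fraction of contact bits flips between frames of the same
    epitope.
    """
    if not 0 <= stickiness <= 1:
        raise ValueError("stickiness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    coords, chain_ids = _bundle_topology(n_per_chain)
    n_res = len(coords)

    # plant epitopes at distinct axial windows of chain 0 (symmetry then
    # yields the equivalent copies on the other chains)
    centers = np.linspace(8, n_per_chain - 9, n_epitopes).astype(int)
    epitopes = [np.arange(c - 3, c + 4) for c in centers]  # chain-0 indices

    frames, labels = [], []
    ref = np.concatenate(coords)
    for _ in range(n_frames):
        if rng.random() < stickiness:
            e = int(rng.integers(n_epitopes))
            chain = int(rng.integers(4))  # symmetric copy
            anchor = coords[chain * n_per_chain + centers[e]][0]
            # ligand sits just off the chain axis, within contact range
            direction = np.sign(anchor[:2])
            offset = np.array([direction[0] * 2.2, direction[1] * 2.2, 0.0])
            base = anchor + offset
            lig = base + np.array([[0.0, 0.0, dz]
                                   for dz in np.linspace(-2.2, 2.2,
                                                         ligand_atoms)])
            # positional jitter tuned so the marginal edge residues of the
            # ~7-residue footprint flip with probability ~ bit_noise each
            lig = lig + rng.normal(0.0, 3.0 * bit_noise, lig.shape)
            labels.append(e)
        else:
            far = rng.normal(0.0, 5.0, 3)
            far += np.sign(far) * 60.0  # well outside any contact cutoff
            lig = far + rng.normal(0.0, 1.0, (ligand_atoms, 3))
            labels.append(-1)
        frames.append(lig)

    traj = ToyTrajectory(protein_coords_by_residue=coords,
                         chain_of_residue=chain_ids,
                         ligand_frames=frames,
                         labels=np.array(labels),
                         epitope_residues=epitopes)
    truth = {"n_epitopes": n_epitopes, "centers": centers,
             "stickiness": stickiness, "labels": traj.labels,
             "reference_protein": ref}
    return traj, truth


def gen_calibration(*, seed: int, n_points: int = 9, slope: float = 0.269,
                    intercept: float = -5.31, noise_sd: float = 0.1,
                    x_min: float = -3.0, x_max: float = 2.0
                    ) -> tuple[list[CalibrationPoint], dict[str, Any]]:
    """Synthetic permeability calibration set (9 compounds on a line)."""
    rng = np.random.default_rng(seed)
    x = np.linspace(x_min, x_max, n_points)
    y = slope * x + intercept
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_points)
    points = [CalibrationPoint(f"cmpd{i + 1}", float(xi), float(yi))
              for i, (xi, yi) in enumerate(zip(x, y))]
    truth = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd}
    return points, truth


_KINDS = {
    "mst_kd": lambda params, seed: gen_mst("kd", seed=seed, **params),
    "mst_hill": lambda params, seed: gen_mst("hill", seed=seed, **params),
    "melt": lambda params, seed: gen_melt(params.pop("modality", "cd"),
                                          seed=seed, **params),
    "ph_titration": lambda params, seed: gen_ph_titration(seed=seed, **params),
    "contact_traj": lambda params, seed: gen_contact_trajectory(seed=seed,
                                                                **params),
    "calibration": lambda params, seed: gen_calibration(seed=seed, **params),
}


@dataclass
class GeneratorSpec:
    """Declarative generator request: kind, truth parameters, and seed."""

    kind: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; "
                             f"known: {sorted(_KINDS)}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def generate(self):
        return _KINDS[self.kind](dict(self.params), self.seed)
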