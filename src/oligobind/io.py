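"""Readers and writers for the pipeline's file formats.

Tabular data is CSV (comma separator, header row, '.' decimal); structures
are PDB, trajectories multi-frame PDB or XYZ (via MDAnalysis); occupancy
grids are OpenDX; sequences FASTA.  Every writer prepends a provenance
header (as '#' comment lines) recording the package version, inputs, seed
and parameters of the run; readers skip such comments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .contacts import FrameContacts
from .melting import MeltCurve
from .mst import DoseResponse
from .nmr import PeakPair, ShiftTitration, StdSpectrumRow
from .permeability import CalibrationPoint

logger = logging.getLogger(__name__)

__all__ = ["SchemaError", "read_table", "write_table", "read_dose_response",
           "read_melt_curve", "read_shift_titration", "read_peak_pairs",
           "read_std_rows", "read_calibration_points",
           "write_fingerprints", "read_fingerprints",
           "write_trajectory", "load_trajectory"]


class SchemaError(ValueError):
    """Input table does not match the stage schema."""


def read_table(path, required: list[str],
               optional: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV with header, validating columns against the stage schema.

    Missing required columns or non-numeric cells raise :class:`SchemaError`
    naming the offending column (and row); extra columns are preserved with
    a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise SchemaError(f"{path}: not a readable CSV ({exc})") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    known = set(required) | set(optional or [])
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"{path}: extra column(s) {extra} preserved but unused",
                      stacklevel=2)
    numeric = [c for c in required +
               [c for c in (optional or []) if c in df.columns]
               if c != "replicate"]  # replicate labels stay as strings
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = int(np.argmax(coerced.isna().to_numpy())) + 2  # 1-based + header
            raise SchemaError(f"{path}: non-numeric value in column "
                              f"{col!r} near line {row}")
        df[col] = coerced
    return df


def _provenance_header(seed=None, **params) -> str:
    items = [f"oligobind {_version}"]
    if seed is not None:
        items.append(f"seed={seed}")
    items.extend(f"{k}={v}" for k, v in params.items())
    return "# " + "; ".join(items)


def write_table(df: pd.DataFrame, path, seed=None, **params):
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(seed=seed, **params) + "\n")
        df.to_csv(fh, index=False)


# -- stage-specific readers ------------------------------------------------

def read_dose_response(path) -> list[DoseResponse]:
    """CSV columns: conc_uM, signal [, signal_err, replicate].

    Returns one DoseResponse per replicate label (single unlabeled series
    otherwise).
    """
    df = read_table(path, ["conc_uM", "signal"],
                    optional=["signal_err", "replicate"])
    groups = (df.groupby("replicate", sort=False)
              if "replicate" in df.columns else [(None, df)])
    out = []
    for rep, g in groups:
        err = g["signal_err"].to_numpy() if "signal_err" in g.columns else None
        out.append(DoseResponse(g["conc_uM"].to_numpy(),
                                g["signal"].to_numpy(), signal_err=err,
                                replicate_id=None if rep is None else str(rep)))
    return out


def read_melt_curve(path, modality: str = "dsf") -> MeltCurve:
    df = read_table(path, ["temperature_C", "signal"])
    return MeltCurve(df["temperature_C"].to_numpy(),
                     df["signal"].to_numpy(), modality)


def read_shift_titration(path, reporter: str = "") -> ShiftTitration:
    df = read_table(path, ["ph", "shift_ppm"])
    return ShiftTitration(df["ph"].to_numpy(), df["shift_ppm"].to_numpy(),
                          reporter)


def read_peak_pairs(path) -> list[PeakPair]:
    df = pd.read_csv(path, comment="#")
    for col in ("residue", "dH_ppm", "dN_ppm"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return [PeakPair(str(r.residue), float(r.dH_ppm), float(r.dN_ppm))
            for r in df.itertuples()]


def read_std_rows(path) -> list[StdSpectrumRow]:
    df = pd.read_csv(path, comment="#")
    for col in ("proton", "i_off", "i_std"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return [StdSpectrumRow(str(r.proton), float(r.i_off), float(r.i_std))
            for r in df.itertuples()]


def read_calibration_points(path) -> list[CalibrationPoint]:
    df = pd.read_csv(path, comment="#")
    for col in ("compound", "x_computed", "y_experimental"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return [CalibrationPoint(str(r.compound), float(r.x_computed),
                             float(r.y_experimental))
            for r in df.itertuples()]


# -- fingerprints ----------------------------------------------------------

def write_fingerprints(frames: list[FrameContacts], path, n_residues: int,
                       seed=None, **params):
    """Serialize fingerprints as 'frame_index TAB comma-separated indices'."""
    with open(Path(path), "w") as fh:
        fh.write(_provenance_header(seed=seed, n_residues=n_residues,
                                    **params) + "\n")
        for f in frames:
            idx = ",".join(map(str, f.residue_indices()))
            fh.write(f"{f.frame_index}\t{idx}\n")


def read_fingerprints(path, n_residues: int) -> list[FrameContacts]:
    frames = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                frame_s, idx_s = (line.split("\t") + [""])[:2]
                bits = np.zeros(n_residues, dtype=bool)
                if idx_s:
                    bits[[int(i) for i in idx_s.split(",")]] = True
                frames.append(FrameContacts(int(frame_s), bits))
            except (ValueError, IndexError) as exc:
                raise SchemaError(f"{path}:{lineno}: malformed fingerprint "
                                  f"line ({exc})") from exc
    return frames


# -- structures (MDAnalysis) -----------------------------------------------

def write_trajectory(traj, topology_path, trajectory_path):
    """Write a :class:`~oligobind.synthetic.ToyTrajectory` as PDB + XYZ.

    The topology PDB holds the protein (one pseudo-atom per residue, chain
    IDs A-D) plus the ligand atoms of frame 0; the XYZ file holds the
    ligand coordinates of every frame.
    """
    import MDAnalysis as mda

    n_res = traj.n_residues
    n_lig = traj.ligand_frames[0].shape[0]
    n_atoms = n_res + n_lig
    u = mda.Universe.empty(n_atoms, n_residues=n_res + 1,
                           atom_resindex=np.concatenate(
                               [np.arange(n_res), np.full(n_lig, n_res)]),
                           residue_segindex=np.concatenate(
                               [traj.chain_of_residue, [4]]),
                           n_segments=5, trajectory=True)
    u.add_TopologyAttr("name", ["CA"] * n_res + [f"C{i + 1}"
                                                 for i in range(n_lig)])
    u.add_TopologyAttr("resname", ["ALA"] * n_res + ["LIG"])
    u.add_TopologyAttr("resid", list(np.concatenate(
        [np.tile(np.arange(1, n_res // 4 + 1), 4), [1]])))
    u.add_TopologyAttr("chainIDs", np.array(
        ["ABCD"[c] for c in traj.chain_of_residue] + ["L"] * n_lig))
    u.add_TopologyAttr("segids", ["A", "B", "C", "D", "L"])
    u.atoms.positions = np.vstack([traj.reference_protein(),
                                   traj.ligand_frames[0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(topology_path))

    lig_u = mda.Universe.empty(n_lig, trajectory=True)
    lig_u.add_TopologyAttr("name", [f"C{i + 1}" for i in range(n_lig)])
    with mda.Writer(str(trajectory_path), n_lig) as w:
        for frame in traj.ligand_frames:
            lig_u.atoms.positions = np.asarray(frame, dtype=float)
            w.write(lig_u.atoms)


def load_trajectory(topology_path, trajectory_path=None,
                    ligand_resname: str = "LIG"):
    """Load a toy topology (+ optional ligand trajectory) via MDAnalysis.

    Returns (protein_coords_by_residue, chain_of_residue, ligand_frames).
    With no trajectory file, the single ligand pose in the topology is the
    only frame.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path))
        protein = u.select_atoms(f"not resname {ligand_resname}")
        ligand = u.select_atoms(f"resname {ligand_resname}")
        coords = [res.atoms.positions.astype(float).copy()
                  for res in protein.residues]
        chains = np.array([
            "ABCD".index(res.atoms.chainIDs[0]) if
            res.atoms.chainIDs[0] in "ABCD" else 0
            for res in protein.residues])
        if trajectory_path is None:
            frames = [ligand.positions.astype(float).copy()]
        else:
            lig_u = mda.Universe(str(trajectory_path))
            frames = [lig_u.atoms.positions.astype(float).copy()
                      for _ in lig_u.trajectory]
    return coords, chains, frames
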