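"""Ligand-contact analysis of free-diffusion trajectories.

A ligand diffusing around a symmetric homotetramer makes transient contacts
with protein residues.  Each trajectory frame is reduced to a binary
*contact fingerprint*: one bit per protein residue, set when any ligand
heavy atom lies within a distance cutoff (4 A default) of any heavy atom of
that residue.  Frames with too few contacts (< 5 residues by default) are
treated as unbound and discarded.  Because a dimer-of-dimers tetramer has
four symmetry-equivalent copies of every binding epitope, fingerprints are
*canonicalized* over the order-4 chain-permutation group before clustering;
agglomerative clustering of the Jaccard distances then groups frames into
binding epitopes, and a 3-D occupancy grid of ligand heavy atoms in contact
frames maps the epitopes in space.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = ["FrameContacts", "SymmetryMap", "OccupancyGrid",
           "contact_fingerprint", "filter_frames", "canonicalize",
           "cluster_epitopes", "ClusterResult", "occupancy_grid",
           "superpose_frames", "jaccard_distance_matrix"]


@dataclass
class FrameContacts:
    """Per-frame residue-contact bitvector (one bit per topology residue)."""

    frame_index: int
    contacts: np.ndarray
    ligand_id: str = "LIG"

    def __post_init__(self):
        self.contacts = np.asarray(self.contacts, dtype=bool)
        if self.contacts.ndim != 1:
            raise ValueError("contacts must be a 1-D bitvector")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def n_contacts(self) -> int:
        return int(self.contacts.sum())

    def residue_indices(self) -> np.ndarray:
        return np.flatnonzero(self.contacts)


class SymmetryMap:
    """Residue-index permutations of the tetramer's chain-swap symmetries.

    A dimer-of-dimers (chains A, B forming one dimer, C, D the other) has
    the Klein four-group of chain swaps: identity, the within-dimer swap
    (A<->B)(C<->D), the dimer swap (A<->C)(B<->D), and their product
    (A<->D)(B<->C).  Each element maps to a permutation of the
    concatenated residue index space.
    """

    def __init__(self, permutations: Sequence[np.ndarray]):
        self.permutations = [np.asarray(p, dtype=np.intp) for p in permutations]
        n = self.permutations[0].size
        for p in self.permutations:
            if p.size != n or not np.array_equal(np.sort(p), np.arange(n)):
                raise ValueError("each permutation must be a bijection on "
                                 "the residue index range")
        self._check_closure()

    def _check_closure(self):
        keys = {p.tobytes() for p in self.permutations}
        for p, q in itertools.product(self.permutations, repeat=2):
            if p[q].tobytes() not in keys:
                raise ValueError("permutation set is not closed under "
                                 "composition")

    @property
    def n_residues(self) -> int:
        return self.permutations[0].size

    @classmethod
    def dimer_of_dimers(cls, n_per_chain: int, n_chains: int = 4) -> "SymmetryMap":
        """Standard order-4 group for 4 chains of equal length."""
        if n_chains != 4:
            raise ValueError("dimer-of-dimers symmetry needs 4 chains")
        idx = np.arange(4 * n_per_chain).reshape(4, n_per_chain)
        A, B, C, D = idx

        def perm(order):
            return np.concatenate([idx[i] for i in order])

        return cls([perm((0, 1, 2, 3)),   # identity
                    perm((1, 0, 3, 2)),   # (AB)(CD)
                    perm((2, 3, 0, 1)),   # (AC)(BD)
                    perm((3, 2, 1, 0))])  # (AD)(BC)


def contact_fingerprint(ligand_coords: np.ndarray,
                        protein_coords_by_residue: Sequence[np.ndarray],
                        cutoff: float = 4.0,
                        frame_index: int = 0,
                        ligand_id: str = "LIG") -> FrameContacts:
    """Residue-contact bitvector for one frame (heavy atoms only).

    A residue bit is set iff any ligand-atom/residue-atom pair is closer
    than ``cutoff`` (A).
    """
    lig = np.asarray(ligand_coords, dtype=float)
    if lig.size == 0 or not protein_coords_by_residue:
        raise ValueError("empty coordinate set")
    n_res = len(protein_coords_by_residue)
    res_sizes = [np.asarray(r, dtype=float).reshape(-1, 3).shape[0]
                 for r in protein_coords_by_residue]
    if any(s == 0 for s in res_sizes):
        raise ValueError("empty residue coordinate set")
    prot = np.concatenate([np.asarray(r, dtype=float).reshape(-1, 3)
                           for r in protein_coords_by_residue])
    res_of_atom = np.repeat(np.arange(n_res), res_sizes)
    # min distance of each protein atom to any ligand atom
    diff = prot[:, None, :] - lig[None, :, :]
    dmin_atom = np.sqrt((diff ** 2).sum(-1)).min(axis=1)
    dmin_res = np.full(n_res, np.inf)
    np.minimum.at(dmin_res, res_of_atom, dmin_atom)
    return FrameContacts(frame_index=frame_index, ligand_id=ligand_id,
                         contacts=dmin_res < cutoff)


def filter_frames(frames: Sequence[FrameContacts],
                  min_residues: int = 5) -> list[FrameContacts]:
    """Keep frames where the ligand contacts at least ``min_residues``."""
    return [f for f in frames if f.n_contacts >= min_residues]


def _canonical_one(bits: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    # packbits is big-endian within bytes, so byte-string comparison equals
    # lexicographic comparison of the bit sequence
    best, best_key = None, None
    for p in sym.permutations:
        img = bits[p]
        key = np.packbits(img).tobytes()
        if best is None or key < best_key:
            best, best_key = img, key
    return best


def canonicalize(frames: Sequence[FrameContacts],
                 sym: SymmetryMap) -> list[FrameContacts]:
    """Replace each fingerprint by its lexicographically smallest symmetry
    image; idempotent, deterministic, and independent of frame order."""
    out = []
    for f in frames:
        if f.contacts.size != sym.n_residues:
            raise ValueError("fingerprint length does not match symmetry map")
        out.append(FrameContacts(f.frame_index, _canonical_one(f.contacts, sym),
                                 f.ligand_id))
    return out


def jaccard_distance_matrix(frames: Sequence[FrameContacts]) -> np.ndarray:
    """Pairwise Jaccard distances between frame fingerprints (square form)."""
    X = np.vstack([f.contacts for f in frames])
    return squareform(pdist(X, metric="jaccard"))


@dataclass
class ClusterResult:
    """Flat clustering of contact fingerprints into binding epitopes."""

    labels: np.ndarray
    sizes: dict[int, int]
    top_centroids: list[np.ndarray]
    distance_cutoff: float
    linkage: str

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def top_clusters(self, k: int = 3) -> list[int]:
        return sorted(self.sizes, key=self.sizes.get, reverse=True)[:k]


def cluster_epitopes(frames: Sequence[FrameContacts],
                     distance_cutoff: float = 0.3,
                     linkage: str = "average") -> ClusterResult:
    """Agglomerative Jaccard clustering of contact fingerprints.

    Flat clusters are cut at ``distance_cutoff``; clusters are ranked by
    population and the top three centroids (per-bit majority fingerprints)
    are reported.  ``linkage`` may be any scipy hierarchy method
    ("average" default; "centroid"-like behaviour via "complete"/"ward" is
    not meaningful for binary data).
    """
    if len(frames) == 0:
        raise ValueError("no frames to cluster")
    X = np.vstack([f.contacts for f in frames])
    if len(frames) == 1:
        return ClusterResult(labels=np.array([1]), sizes={1: 1},
                             top_centroids=[X[0].copy()],
                             distance_cutoff=distance_cutoff, linkage=linkage)
    d = pdist(X, metric="jaccard")
    Z = scipy_linkage(d, method=linkage)
    labels = fcluster(Z, t=distance_cutoff, criterion="distance")
    sizes = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    order = sorted(sizes, key=sizes.get, reverse=True)
    centroids = [X[labels == c].mean(axis=0) >= 0.5 for c in order[:3]]
    return ClusterResult(labels=labels, sizes=sizes, top_centroids=centroids,
                         distance_cutoff=distance_cutoff, linkage=linkage)


# -- occupancy grids -------------------------------------------------------

@dataclass
class OccupancyGrid:
    """3-D histogram of ligand heavy-atom positions over contact frames."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    n_contact_frames: int

    @property
    def edges(self) -> list[np.ndarray]:
        return [self.origin[i] + self.spacing * np.arange(self.counts.shape[i] + 1)
                for i in range(3)]

    def to_dx(self, path: str):
        """Write the grid in OpenDX format (gridDataFormats)."""
        from gridData import Grid
        g = Grid(self.counts.astype(float),
                 origin=self.origin + 0.5 * self.spacing,
                 delta=[self.spacing] * 3)
        g.export(str(path), file_format="dx")


def superpose_frames(mobile_protein: Sequence[np.ndarray],
                     mobile_ligand: Sequence[np.ndarray],
                     reference_protein: np.ndarray
                     ) -> list[np.ndarray]:
    """Least-squares superpose each frame's protein onto the reference and
    apply the same rigid transform to the ligand coordinates.

    Uses the Kabsch algorithm on protein heavy atoms.
    """
    ref = np.asarray(reference_protein, dtype=float)
    ref_c = ref - ref.mean(axis=0)
    out = []
    for prot, lig in zip(mobile_protein, mobile_ligand):
        prot = np.asarray(prot, dtype=float)
        lig = np.asarray(lig, dtype=float)
        mu = prot.mean(axis=0)
        H = (prot - mu).T @ ref_c
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(U @ Vt))
        R = (U @ np.diag([1.0, 1.0, d]) @ Vt)
        out.append((lig - mu) @ R + ref.mean(axis=0))
    return out


def occupancy_grid(ligand_frames: Sequence[np.ndarray],
                   reference_protein: np.ndarray,
                   spacing: float = 0.5,
                   pad: float = 5.0) -> OccupancyGrid:
    """Bin ligand heavy atoms of (already superposed) contact frames.

    The lattice covers the reference protein bounding box padded by
    ``pad`` A at ``spacing`` A resolution; it auto-expands (logged) when
    atoms fall outside, so the count-conservation invariant — total counts
    equal the number of binned (frame, atom) incidences — always holds.
    """
    ref = np.asarray(reference_protein, dtype=float)
    lo = ref.min(axis=0) - pad
    hi = ref.max(axis=0) + pad
    if ligand_frames:
        all_atoms = np.concatenate([np.asarray(f, float).reshape(-1, 3)
                                    for f in ligand_frames])
        out_lo = all_atoms.min(axis=0) < lo
        out_hi = all_atoms.max(axis=0) > hi
        if out_lo.any() or out_hi.any():
            logger.info("occupancy grid expanded to cover ligand atoms "
                        "outside the padded reference box")
            lo = np.minimum(lo, all_atoms.min(axis=0) - spacing)
            hi = np.maximum(hi, all_atoms.max(axis=0) + spacing)
    else:
        all_atoms = np.empty((0, 3))
    nbins = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    edges = [lo[i] + spacing * np.arange(nbins[i] + 1) for i in range(3)]
    counts, _ = np.histogramdd(all_atoms, bins=edges) if all_atoms.size else \
        (np.zeros(nbins, dtype=float), None)
    return OccupancyGrid(origin=lo, spacing=spacing,
                         counts=counts.astype(np.int64),
                         n_contact_frames=len(ligand_frames))
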