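"""Trajectory metrics: RMSD, radius of gyration, RMSF, H-bonds, distance maps.

Operates on multi-model PDB trajectories through a light in-memory container
(topology + a frames array). Internally all geometry is in Å; reported
series are in nm, the convention of MD analysis tooling. Superposition is a
weighted least-squares (Kabsch) fit returning a proper rotation.

Metrics
-------
* ``rmsd_series`` — each frame least-squares fitted to a reference frame on
  the selection, then RMSD over the selection.
* ``rg_series`` — mass-weighted (optionally unweighted) radius of gyration.
* ``rmsf_per_residue`` — fluctuation about the iteratively refitted
  time-average structure (two refinement passes).
* ``hbond_series`` — per-frame geometric H-bond counts plus per-pair
  occupancy fractions.
* ``mean_smallest_distance_matrix`` — residue-pair minimum heavy-atom
  distances, truncated, averaged over frames (contact-map style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .docking_post import AtomId, _DH_BOND_MAX
from .structio import ResidueId, Structure, read_pdb

A_PER_NM = 10.0

BACKBONE_ATOMS = {"N", "CA", "C", "O"}

#: Standard atomic masses (u) for elements common in proteins and small ligands.
ATOMIC_MASS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "NA": 22.990, "K": 39.098, "MN": 54.938, "CU": 63.546,
}


class FitError(ValueError):
    """Superposition is not defined (too few atoms or degenerate geometry)."""


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    frames: (n_frames, n_atoms, 3) array, Å. times: ps, strictly increasing.
    """

    topology: Structure
    frames: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology.atoms):
            raise ValueError("frame atom count does not match topology")
        if self.times is None:
            self.times = 2.0 * np.arange(self.n_frames)  # 2 ps recording interval
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.n_frames or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing, one per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def read_trajectory(source) -> Trajectory:
    """Read a multi-model PDB as a trajectory (2 ps frame spacing)."""
    models = read_pdb(source)
    topo = models[0]
    frames = np.stack([m.coords_array() for m in models])
    return Trajectory(topology=topo, frames=frames)


def resolve_selection(
    topology: Structure,
    selection: Union[str, Iterable[int], Iterable[AtomId]],
) -> np.ndarray:
    """Indices of selected polymer heavy atoms.

    ``"backbone"`` = N, CA, C, O; ``"calpha"`` = CA; otherwise an explicit
    iterable of atom indices or (chain, resnum, icode, name) identifiers.
    """
    if isinstance(selection, str):
        sel = selection.lower()
        if sel == "backbone":
            names: Optional[set] = BACKBONE_ATOMS
        elif sel in ("calpha", "ca"):
            names = {"CA"}
        elif sel == "heavy":
            names = None
        else:
            raise ValueError(f"unknown selection {selection!r}")
        idx = [
            i
            for i, a in enumerate(topology.atoms)
            if not a.is_hetero and not a.is_hydrogen and (names is None or a.atom_name in names)
        ]
    else:
        selection = list(selection)
        if selection and isinstance(selection[0], tuple):
            table = {
                (a.chain_id, a.res_seq, a.insertion_code, a.atom_name): i
                for i, a in enumerate(topology.atoms)
            }
            idx = [table[aid] for aid in selection]  # type: ignore[index]
        else:
            idx = [int(i) for i in selection]
    if not idx:
        raise ValueError("empty atom selection")
    return np.asarray(idx, dtype=int)


def kabsch_superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted least-squares superposition of ``mobile`` onto ``reference``.

    Returns (rotation 3x3 with det +1, translation, fitted mobile coords);
    fitted = mobile @ R.T + t minimizes the weighted squared deviation.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise FitError("reference and mobile must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise FitError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise FitError("weights must be non-negative with positive sum")
    ref_com = w @ ref / w.sum()
    mob_com = w @ mob / w.sum()
    ref_c = ref - ref_com
    mob_c = mob - mob_com
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise FitError("degenerate (collinear) reference geometry")
    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    rmat = rot.as_matrix()
    fitted = mob_c @ rmat.T + ref_com
    translation = ref_com - mob_com @ rmat.T
    return rmat, translation, fitted


def rmsd(reference: np.ndarray, coords: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    """Plain (already superposed) weighted RMSD in the input units."""
    ref = np.asarray(reference, dtype=float)
    xyz = np.asarray(coords, dtype=float)
    d2 = np.sum((xyz - ref) ** 2, axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt(w @ d2 / w.sum()))


def rmsd_series(
    traj: Trajectory,
    selection: Union[str, Iterable[int]] = "backbone",
    reference_frame: int = 0,
) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference frame after least-squares fitting."""
    idx = resolve_selection(traj.topology, selection)
    if not (0 <= reference_frame < traj.n_frames):
        raise IndexError(f"reference frame {reference_frame} out of range")
    ref = traj.frames[reference_frame][idx]
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        mob = traj.frames[t][idx]
        _, _, fitted = kabsch_superpose(ref, mob)
        out[t] = rmsd(ref, fitted)
    return out / A_PER_NM


def rg_series(
    traj: Trajectory,
    selection: Union[str, Iterable[int]] = "heavy",
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame radius of gyration (nm) of the selection."""
    idx = resolve_selection(traj.topology, selection)
    if mass_weighted:
        masses = []
        for i in idx:
            el = traj.topology.atoms[i].element.upper()
            if el not in ATOMIC_MASS:
                raise KeyError(f"no mass for element {el!r}")
            masses.append(ATOMIC_MASS[el])
        w = np.asarray(masses)
    else:
        w = np.ones(len(idx))
    if w.sum() <= 0:
        raise ValueError("zero total mass")
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        xyz = traj.frames[t][idx]
        com = w @ xyz / w.sum()
        out[t] = math.sqrt(w @ np.sum((xyz - com) ** 2, axis=1) / w.sum())
    return out / A_PER_NM


def _mean_structure(frames_sel: np.ndarray, passes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Iterated fit-to-mean. Returns (mean coords, fitted frames)."""
    fitted = frames_sel.copy()
    mean = fitted[0]
    for _ in range(passes):
        for t in range(fitted.shape[0]):
            _, _, fitted[t] = kabsch_superpose(mean, fitted[t])
        mean = fitted.mean(axis=0)
    return mean, fitted


def rmsf_per_residue(
    traj: Trajectory,
    selection: str = "backbone",
) -> tuple[list[ResidueId], np.ndarray]:
    """Per-residue RMSF (nm) about the refitted time-average structure.

    Returns (residue ids, rmsf array). Each frame is fitted to the running
    time average (two refinement passes); the residue RMSF averages the
    squared deviation over frames and the residue's selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = resolve_selection(traj.topology, selection)
    frames_sel = traj.frames[:, idx, :]
    mean, fitted = _mean_structure(frames_sel)
    for t in range(fitted.shape[0]):
        _, _, fitted[t] = kabsch_superpose(mean, fitted[t])
    dev2 = np.sum((fitted - mean) ** 2, axis=2)  # (frames, atoms)

    residues: list[ResidueId] = []
    positions: dict[ResidueId, list[int]] = {}
    for j, i in enumerate(idx):
        rid = traj.topology.atoms[i].residue_id
        if rid not in positions:
            positions[rid] = []
            residues.append(rid)
        positions[rid].append(j)
    out = np.array([math.sqrt(dev2[:, positions[rid]].mean()) for rid in residues])
    return residues, out / A_PER_NM


def hbond_series(
    traj: Trajectory,
    donors: Sequence[AtomId],
    acceptors: Sequence[AtomId],
    d_max: float = 3.5,
    angle_max: float = 30.0,
) -> tuple[np.ndarray, dict[tuple[AtomId, AtomId], float]]:
    """Per-frame H-bond count and per-pair occupancy over the trajectory.

    Same geometric criterion as :func:`pocketpipe.docking_post.detect_hbonds`
    (closed boundaries at ``d_max`` Å / ``angle_max`` degrees).
    """
    donors = list(donors)
    acceptors = list(acceptors)
    if not donors or not acceptors:
        raise ValueError("donor and acceptor sets must be non-empty")
    table = {
        (a.chain_id, a.res_seq, a.insertion_code, a.atom_name): i
        for i, a in enumerate(traj.topology.atoms)
    }
    d_idx = [table[d] for d in donors]
    a_idx = [table[a] for a in acceptors]
    # Hydrogens attached to each donor, from frame-0 geometry.
    hydro: dict[int, list[int]] = {}
    for di in d_idx:
        donor = traj.topology.atoms[di]
        hs = [
            i
            for i, a in enumerate(traj.topology.atoms)
            if a.is_hydrogen
            and (a.chain_id, a.res_seq, a.insertion_code) == donor.residue_id
            and np.linalg.norm(traj.frames[0][i] - traj.frames[0][di]) <= _DH_BOND_MAX
        ]
        hydro[di] = hs

    counts = np.zeros(traj.n_frames, dtype=int)
    hits: dict[tuple[AtomId, AtomId], int] = {}
    for t in range(traj.n_frames):
        xyz = traj.frames[t]
        for d_id, di in zip(donors, d_idx):
            for a_id, ai in zip(acceptors, a_idx):
                if di == ai:
                    continue
                dist = float(np.linalg.norm(xyz[ai] - xyz[di]))
                if dist > d_max or dist == 0.0:
                    continue
                ok = True
                if hydro[di]:
                    angles = []
                    for hi in hydro[di]:
                        v_h = xyz[hi] - xyz[di]
                        v_a = xyz[ai] - xyz[di]
                        c = float(
                            np.clip(v_h @ v_a / (np.linalg.norm(v_h) * np.linalg.norm(v_a)), -1, 1)
                        )
                        angles.append(math.degrees(math.acos(c)))
                    ok = min(angles) <= angle_max
                if ok:
                    counts[t] += 1
                    hits[(d_id, a_id)] = hits.get((d_id, a_id), 0) + 1
    occupancy = {pair: n / traj.n_frames for pair, n in hits.items()}
    return counts, occupancy


def mean_smallest_distance_matrix(
    traj: Trajectory,
    truncation: float = 1.5,
) -> tuple[list[ResidueId], np.ndarray, float, float]:
    """Mean smallest residue-pair heavy-atom distance matrix (nm).

    Per frame, entry (i, j) is the minimum heavy-atom distance between
    residues i and j, capped at ``truncation`` nm; the matrix averages these
    over frames. Returns (residues, matrix, mean of off-diagonal entries,
    sum of all entries).
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    residues = list(traj.topology.residue_index)
    groups = []
    for rid in residues:
        heavy = [i for i in traj.topology.residue_index[rid] if not traj.topology.atoms[i].is_hydrogen]
        if not heavy:
            raise KeyError(f"residue {rid} has no heavy atoms")
        groups.append(np.asarray(heavy))
    n = len(residues)
    cap = truncation * A_PER_NM  # work in Å
    acc = np.zeros((n, n))
    for t in range(traj.n_frames):
        xyz = traj.frames[t]
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = cdist(xyz[groups[i]], xyz[groups[j]]).min()
                mat[i, j] = mat[j, i] = min(d, cap)
        acc += mat
    acc /= traj.n_frames
    acc /= A_PER_NM  # nm
    off = acc[~np.eye(n, dtype=bool)]
    aggregate_mean = float(off.mean()) if n > 1 else 0.0
    aggregate_sum = float(acc.sum())
    return residues, acc, aggregate_mean, aggregate_sum
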