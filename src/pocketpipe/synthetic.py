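"""Synthetic inputs with known ground truth for every pipeline stage.

Generates, from a single integer seed:

* an ideal α-helical toy structure (backbone + CB heavy atoms, 3.8 Å
  consecutive Cα spacing) written/read as ordinary PDB;
* a reference/target homolog sequence pair with an exact per-position truth
  table (identical / conserved / mismatch), indel-free by default so that
  projecting conservation onto residues is exact bookkeeping;
* pocket-detector records from two mock methods scoring on deliberately
  different scales, with one true pocket implanted on conservation-enriched
  residues among background decoys;
* a trajectory = per-frame rigid-body motion of the structure plus isotropic
  Gaussian coordinate noise, whose post-fit RMSD/RMSF have closed-form
  expectations (σ√3 per atom as frames and atoms grow).

Frame 0 of a generated trajectory carries no coordinate noise: it is the
rigid-motion-only reference, so RMSD measured against frame 0 estimates the
noise amplitude itself rather than √2 times it.

At ``enrichment == 1`` all pockets (true and decoys) are drawn exchangeably,
giving an exact null for calibration runs; at enrichment > 1 the true pocket
receives a deterministic round(min(1, enrichment · background) · size)
conserved-residue count.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .conservation import COLUMN_CONSERVED, COLUMN_IDENTICAL, COLUMN_MISMATCH
from .pocket_consensus import PocketPrediction
from .structio import (
    AtomRecord,
    ProteinSequence,
    ResidueId,
    Structure,
    write_fasta,
    write_pdb,
)
from .traj_analysis import Trajectory

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class RigidMotion:
    """Smooth per-frame rotation + translation (degrees, Å, frames)."""

    rot_amplitude_deg: float = 10.0
    trans_amplitude: float = 3.0
    period: float = 50.0


@dataclass
class SyntheticSpec:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_residues: int = 100
    identity_fraction: float = 0.3
    conserved_fraction: float = 0.2
    n_pockets: int = 5
    pocket_size: int = 10
    enrichment: float = 2.0
    rank_noise: float = 0.0
    n_frames: int = 200
    noise_sigma: float = 0.1  # Å per coordinate
    rigid_motion: RigidMotion = field(default_factory=RigidMotion)

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_fraction <= 1.0 and 0.0 <= self.conserved_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.identity_fraction + self.conserved_fraction > 1.0:
            raise ValueError("identity_fraction + conserved_fraction must not exceed 1")
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        background = self.identity_fraction + self.conserved_fraction
        if self.enrichment * background > 1.0 + 1e-9:
            raise ValueError("enrichment * background conservation density exceeds 1")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # Independent deterministic stream per generator stage.
    return np.random.default_rng([spec.seed, stream])


def _substitution_partners() -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Per letter: different letters with positive / strictly negative score."""
    mat = substitution_matrices.load("BLOSUM62")
    positive: dict[str, list[str]] = {}
    negative: dict[str, list[str]] = {}
    for x in _AA20:
        positive[x] = [y for y in _AA20 if y != x and mat[x, y] > 0]
        negative[x] = [y for y in _AA20 if y != x and mat[x, y] < 0]
    return positive, negative


_POSITIVE_PARTNERS, _NEGATIVE_PARTNERS = _substitution_partners()
#: Letters usable at conserved positions (C has no positive BLOSUM62 partner).
_CONSERVABLE = [x for x in _AA20 if _POSITIVE_PARTNERS[x]]


def make_toy_structure(spec: SyntheticSpec, sequence: str | None = None, chain_id: str = "A") -> Structure:
    """Ideal α-helix with N, CA, C, O (+CB except Gly) heavy atoms.

    Helical parameters (rise 1.5 Å, radius 2.3 Å, 100°/residue) give
    consecutive Cα–Cα distances of ≈3.83 Å. Geometry is idealized, not
    physical; it only needs valid PDB bookkeeping and sane distances.
    """
    if spec.n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = _rng(spec, 1)
    if sequence is None:
        sequence = "".join(rng.choice(list(_AA20), size=spec.n_residues))
    if len(sequence) != spec.n_residues:
        raise ValueError("sequence length does not match n_residues")

    from Bio.SeqUtils import IUPACData

    one_to_three = {v: k.upper() for k, v in IUPACData.protein_letters_3to1.items()}
    atoms: list[AtomRecord] = []
    serial = 0
    rise, radius, twist = 1.5, 2.3, np.deg2rad(100.0)
    for i, letter in enumerate(sequence):
        theta = twist * i
        z = rise * i
        ca = np.array([radius * np.cos(theta), radius * np.sin(theta), z])
        n_pos = np.array([1.8 * np.cos(theta - 0.7), 1.8 * np.sin(theta - 0.7), z - 0.6])
        c_pos = np.array([1.9 * np.cos(theta + 0.7), 1.9 * np.sin(theta + 0.7), z + 0.6])
        o_pos = c_pos + np.array([0.95 * np.cos(theta + 0.7), 0.95 * np.sin(theta + 0.7), 0.4])
        res_name = one_to_three.get(letter, "UNK")
        placed = [("N", "N", n_pos), ("CA", "C", ca), ("C", "C", c_pos), ("O", "O", o_pos)]
        if letter != "G":
            cb = ca + np.array([1.3 * np.cos(theta), 1.3 * np.sin(theta), -0.5])
            placed.append(("CB", "C", cb))
        for name, element, pos in placed:
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial, atom_name=name, element=element, chain_id=chain_id,
                    res_name=res_name, res_seq=i + 1, coords=pos,
                )
            )
    return Structure(model_id=1, atoms=atoms)


def make_homolog_pair(
    spec: SyntheticSpec,
) -> tuple[ProteinSequence, ProteinSequence, list[str]]:
    """(reference, target, per-position truth) with exact class counts.

    The target has exactly round(identity_fraction·n) identical and
    round(conserved_fraction·n) conserved positions versus the reference;
    all other columns are strict mismatches (negative substitution score).
    Indel-free: both sequences have length n and align column-to-column.
    """
    n = spec.n_residues
    rng = _rng(spec, 2)
    n_ident = round(spec.identity_fraction * n)
    n_cons = round(spec.conserved_fraction * n)
    if n_ident + n_cons > n:
        raise ValueError("infeasible identity/conserved split")

    classes = np.array([COLUMN_MISMATCH] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_ident]] = COLUMN_IDENTICAL
    classes[order[n_ident : n_ident + n_cons]] = COLUMN_CONSERVED

    target_letters = []
    ref_letters = []
    for cls in classes:
        if cls == COLUMN_CONSERVED:
            t = rng.choice(_CONSERVABLE)
            r = rng.choice(_POSITIVE_PARTNERS[t])
        else:
            t = rng.choice(list(_AA20))
            r = t if cls == COLUMN_IDENTICAL else rng.choice(_NEGATIVE_PARTNERS[t])
        target_letters.append(t)
        ref_letters.append(r)
    reference = ProteinSequence(id="reference_lbd", residues="".join(ref_letters))
    target = ProteinSequence(id="target_receptor", residues="".join(target_letters))
    return reference, target, list(classes)


def conserved_residue_ids(truth: list[str], chain_id: str = "A") -> set[ResidueId]:
    """Truth classes → the structure residue ids that count as conserved."""
    return {
        (chain_id, i + 1, "")
        for i, cls in enumerate(truth)
        if cls in (COLUMN_IDENTICAL, COLUMN_CONSERVED)
    }


def make_pocket_fixture(
    spec: SyntheticSpec,
    structure: Structure,
    conserved: set[ResidueId],
) -> tuple[list[PocketPrediction], str]:
    """Two mock detectors' pocket records plus the implanted-pocket id.

    The true pocket sits on conservation-enriched residues, decoys on
    background; both methods score a shared latent pocket quality (true
    pocket = 1.0, decoys < 0.8) on different affine scales, perturbed by
    ``rank_noise``.
    """
    if spec.n_pockets < 2:
        raise ValueError("need at least 2 pockets")
    residues = list(structure.residue_index)
    if spec.pocket_size * spec.n_pockets > len(residues):
        raise ValueError("pockets do not fit in the structure")
    rng = _rng(spec, 3)

    pockets: list[list[ResidueId]]
    if spec.enrichment == 1.0:
        # Exact null: all pockets drawn exchangeably.
        perm = [residues[i] for i in rng.permutation(len(residues))]
        pockets = [
            perm[i * spec.pocket_size : (i + 1) * spec.pocket_size]
            for i in range(spec.n_pockets)
        ]
        true_index = int(rng.integers(spec.n_pockets))
    else:
        density = len(conserved) / len(residues)
        k_cons = round(min(1.0, spec.enrichment * density) * spec.pocket_size)
        cons_list = sorted(r for r in residues if r in conserved)
        back_list = sorted(r for r in residues if r not in conserved)
        if k_cons > len(cons_list) or spec.pocket_size - k_cons > len(back_list):
            raise ValueError("not enough residues to implant the true pocket")
        chosen_cons = [cons_list[i] for i in rng.choice(len(cons_list), size=k_cons, replace=False)]
        chosen_back = [
            back_list[i]
            for i in rng.choice(len(back_list), size=spec.pocket_size - k_cons, replace=False)
        ]
        true_pocket = chosen_cons + chosen_back
        remaining = [r for r in residues if r not in set(true_pocket)]
        perm = [remaining[i] for i in rng.permutation(len(remaining))]
        pockets = [true_pocket] + [
            perm[i * spec.pocket_size : (i + 1) * spec.pocket_size]
            for i in range(spec.n_pockets - 1)
        ]
        true_index = 0
        # Shuffle pocket order so the true pocket id is not always first.
        order = rng.permutation(spec.n_pockets)
        pockets = [pockets[i] for i in order]
        true_index = int(np.where(order == 0)[0][0])

    quality = rng.uniform(0.2, 0.8, size=spec.n_pockets)
    quality[true_index] = 1.0

    predictions: list[PocketPrediction] = []
    scales = {"castp": (150.0, 400.0), "activesite": (2.0, 18.0)}
    for method, (offset, gain) in scales.items():
        noise = rng.normal(0.0, spec.rank_noise, size=spec.n_pockets)
        for i, lining in enumerate(pockets):
            predictions.append(
                PocketPrediction(
                    method=method,
                    pocket_id=f"P{i + 1}",
                    raw_score=float(offset + gain * (quality[i] + noise[i])),
                    lining_residues=set(lining),
                )
            )
    return predictions, f"P{true_index + 1}"


def make_trajectory(spec: SyntheticSpec, structure: Structure) -> Trajectory:
    """Rigid-body motion + iid Gaussian coordinate noise (σ Å), 2 ps frames.

    Frame 0 is the unperturbed (noise-free, motion-free) structure; for
    t ≥ 1 the whole structure is rotated/translated smoothly and each
    coordinate perturbed by N(0, σ²). Expected post-fit RMSD versus frame 0
    approaches σ√3 for n_atoms ≫ fit degrees of freedom.
    """
    if spec.n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = _rng(spec, 4)
    base = structure.coords_array()
    com = base.mean(axis=0)
    motion = spec.rigid_motion
    frames = np.empty((spec.n_frames, base.shape[0], 3))
    frames[0] = base
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    for t in range(1, spec.n_frames):
        phase = 2.0 * np.pi * t / motion.period
        angle = np.deg2rad(motion.rot_amplitude_deg) * np.sin(phase)
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
        trans = motion.trans_amplitude * np.array(
            [np.sin(phase), np.cos(phase), 0.5 * np.sin(2 * phase)]
        )
        frames[t] = (base - com) @ rot.T + com + trans
        frames[t] += rng.normal(0.0, spec.noise_sigma, size=frames[t].shape)
    return Trajectory(topology=structure, frames=frames, times=2.0 * np.arange(spec.n_frames))


def pocket_predictions_to_json(predictions: list[PocketPrediction]) -> str:
    records = []
    for p in predictions:
        records.append(
            {
                "method": p.method,
                "pocket_id": p.pocket_id,
                "raw_score": p.raw_score,
                "residues": sorted(
                    f"{c}:{n}" + (f":{ic}" if ic else "") for c, n, ic in p.lining_residues
                ),
            }
        )
    return json.dumps(records, indent=2) + "\n"


def make_workspace(spec: SyntheticSpec, outdir: os.PathLike | str) -> dict[str, str]:
    """Materialize a complete demo workspace; returns the file map.

    Writes structure.pdb, reference.fasta, target.fasta, pockets.json,
    trajectory.pdb and truth.json (ground truth: true pocket id, conserved
    residues, per-position classes).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reference, target, truth = make_homolog_pair(spec)
    structure = make_toy_structure(spec, sequence=target.residues)
    conserved = conserved_residue_ids(truth)
    predictions, true_id = make_pocket_fixture(spec, structure, conserved)
    traj = make_trajectory(spec, structure)

    files = {
        "structure": str(out / "structure.pdb"),
        "reference": str(out / "reference.fasta"),
        "target": str(out / "target.fasta"),
        "pockets": str(out / "pockets.json"),
        "trajectory": str(out / "trajectory.pdb"),
        "truth": str(out / "truth.json"),
    }
    write_pdb(structure, files["structure"])
    write_fasta(reference, files["reference"])
    write_fasta(target, files["target"])
    with open(files["pockets"], "w") as fh:
        fh.write(pocket_predictions_to_json(predictions))
    models = [
        Structure(model_id=t + 1, atoms=[
            AtomRecord(
                serial=a.serial, atom_name=a.atom_name, element=a.element,
                chain_id=a.chain_id, res_name=a.res_name, res_seq=a.res_seq,
                insertion_code=a.insertion_code, coords=traj.frames[t][i],
                is_hetero=a.is_hetero,
            )
            for i, a in enumerate(structure.atoms)
        ])
        for t in range(traj.n_frames)
    ]
    write_pdb(models, files["trajectory"])
    with open(files["truth"], "w") as fh:
        json.dump(
            {
                "true_pocket_id": true_id,
                "conserved_residues": sorted(f"{c}:{n}" for c, n, _ in conserved),
                "position_classes": truth,
                "seed": spec.seed,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return files
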