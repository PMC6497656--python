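"""Docking-result interpretation: ΔG → Ki conversion and hydrogen-bond detection.

A docking engine reports a binding free energy ΔG (kcal/mol). The predicted
inhibition constant follows from ΔG = RT ln Ki:

    Ki = exp(ΔG / (R T)),  R = 1.987e-3 kcal/(mol K), T = 298.15 K by default

(the reporting convention of AutoDock-style engines). Hydrogen bonds in a
docked complex are detected geometrically: donor–acceptor distance within a
cutoff and, when an explicit hydrogen is present on the donor, the
hydrogen–donor–acceptor angle within an angular cutoff. Crystal structures
and docked poses frequently carry no hydrogens; those fall back to a
distance-only criterion, flagged per record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .structio import Structure

#: Gas constant, kcal mol^-1 K^-1 (CODATA).
R_KCAL = 1.98720425864083e-3
#: Standard reporting temperature, K.
T_STANDARD = 298.15

#: (chain_id, res_seq, insertion_code, atom_name) — same key as pocket_consensus.
AtomId = tuple[str, int, str, str]

#: Covalent D–H search radius, Å.
_DH_BOND_MAX = 1.25


def ki_from_energy(delta_g: float, temperature: float = T_STANDARD) -> float:
    """Inhibition constant (molar) from binding free energy (kcal/mol)."""
    if not math.isfinite(delta_g):
        raise ValueError("binding energy must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(delta_g / (R_KCAL * temperature))


def energy_from_ki(ki: float, temperature: float = T_STANDARD) -> float:
    """Binding free energy (kcal/mol) from inhibition constant (molar)."""
    if not (ki > 0) or not math.isfinite(ki):
        raise ValueError("ki must be positive and finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature * math.log(ki)


@dataclass
class HBond:
    donor_atom: AtomId
    acceptor_atom: AtomId
    distance: float  # Å, donor–acceptor
    angle: Optional[float]  # degrees, H–D–A; None in distance-only mode
    hydrogen: Optional[AtomId] = None
    distance_only: bool = False


@dataclass
class DockingSummary:
    """Binding energy, the derived Ki and any detected hydrogen bonds."""

    receptor_id: str
    ligand_id: str
    binding_energy: float  # kcal/mol
    temperature: float = T_STANDARD
    hbonds: list[HBond] | None = None

    @property
    def ki(self) -> float:
        return ki_from_energy(self.binding_energy, self.temperature)

    @property
    def ki_micromolar(self) -> float:
        return self.ki * 1e6


def _atom_lookup(s: Structure) -> dict[AtomId, int]:
    table: dict[AtomId, int] = {}
    for i, a in enumerate(s.atoms):
        table.setdefault((a.chain_id, a.res_seq, a.insertion_code, a.atom_name), i)
    return table


def _find_hydrogens(s: Structure, donor_idx: int) -> list[int]:
    """Hydrogens covalently bound to the donor: same residue, within 1.25 Å."""
    donor = s.atoms[donor_idx]
    out = []
    for i, a in enumerate(s.atoms):
        if not a.is_hydrogen:
            continue
        if (a.chain_id, a.res_seq, a.insertion_code) != donor.residue_id:
            continue
        if np.linalg.norm(a.coords - donor.coords) <= _DH_BOND_MAX:
            out.append(i)
    return out


def detect_hbonds(
    complex_structure: Structure,
    donors: Iterable[AtomId],
    acceptors: Iterable[AtomId],
    d_max: float = 3.5,
    angle_max: float = 30.0,
) -> list[HBond]:
    """Geometric hydrogen-bond detection between explicit donor/acceptor sets.

    A donor–acceptor pair is a hydrogen bond when the D–A distance is at most
    ``d_max`` Å (closed boundary) and, if the donor carries a hydrogen, the
    best H–D–A angle is at most ``angle_max`` degrees (0° = collinear
    D–H...A). Donors without hydrogens are evaluated on distance alone and
    the record flags ``distance_only``.
    """
    donors = list(donors)
    acceptors = list(acceptors)
    if not donors or not acceptors:
        raise ValueError("donor and acceptor sets must be non-empty")
    lookup = _atom_lookup(complex_structure)
    for aid in (*donors, *acceptors):
        if aid not in lookup:
            raise KeyError(f"atom {aid} not found in complex")

    bonds: list[HBond] = []
    for d_id in donors:
        di = lookup[d_id]
        d_xyz = complex_structure.atoms[di].coords
        hydrogens = _find_hydrogens(complex_structure, di)
        for a_id in acceptors:
            if a_id == d_id:
                continue
            ai = lookup[a_id]
            a_xyz = complex_structure.atoms[ai].coords
            dist = float(np.linalg.norm(a_xyz - d_xyz))
            if dist > d_max or dist == 0.0:
                continue
            if hydrogens:
                best_angle, best_h = None, None
                for hi in hydrogens:
                    h_xyz = complex_structure.atoms[hi].coords
                    v_h = h_xyz - d_xyz
                    v_a = a_xyz - d_xyz
                    cosang = float(
                        np.clip(
                            v_h @ v_a / (np.linalg.norm(v_h) * np.linalg.norm(v_a)),
                            -1.0,
                            1.0,
                        )
                    )
                    ang = math.degrees(math.acos(cosang))
                    if best_angle is None or ang < best_angle:
                        best_angle, best_h = ang, hi
                if best_angle is not None and best_angle <= angle_max:
                    h_atom = complex_structure.atoms[best_h]
                    bonds.append(
                        HBond(
                            donor_atom=d_id,
                            acceptor_atom=a_id,
                            distance=dist,
                            angle=best_angle,
                            hydrogen=(
                                h_atom.chain_id,
                                h_atom.res_seq,
                                h_atom.insertion_code,
                                h_atom.atom_name,
                            ),
                        )
                    )
            else:
                bonds.append(
                    HBond(
                        donor_atom=d_id,
                        acceptor_atom=a_id,
                        distance=dist,
                        angle=None,
                        distance_only=True,
                    )
                )
    return bonds


def read_donor_acceptor_file(path) -> tuple[list[AtomId], list[AtomId]]:
    """Read a two-column role file: role (donor|acceptor), atom token.

    Lines look like ``donor A:169:OG``; '#' starts a comment.
    """
    from .pocket_consensus import parse_atom_token

    donors: list[AtomId] = []
    acceptors: list[AtomId] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2 or parts[0] not in ("donor", "acceptor"):
                raise ValueError(f"line {lineno}: expected '<donor|acceptor> CHAIN:RESNUM:ATOM'")
            (donors if parts[0] == "donor" else acceptors).append(parse_atom_token(parts[1]))
    return donors, acceptors


def hbond_table(bonds: list[HBond]) -> pd.DataFrame:
    rows = [
        {
            "donor": ":".join(map(str, (b.donor_atom[0], b.donor_atom[1], b.donor_atom[3]))),
            "acceptor": ":".join(map(str, (b.acceptor_atom[0], b.acceptor_atom[1], b.acceptor_atom[3]))),
            "distance_A": b.distance,
            "angle_deg": b.angle,
            "distance_only": b.distance_only,
        }
        for b in bonds
    ]
    return pd.DataFrame(rows, columns=["donor", "acceptor", "distance_A", "angle_deg", "distance_only"])
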