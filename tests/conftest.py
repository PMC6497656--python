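"""Shared fixtures: small hand-written PDB texts and synthetic objects."""

from __future__ import annotations

import pytest

from pocketpipe.structio import read_pdb


def pdb_line(
    record: str,
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    occ: float = 1.00,
    altloc: str = " ",
) -> str:
    """Format one fixed-width PDB coordinate record."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{res_name:>3s} {chain}"
        f"{res_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


# Gly-Ala-Ser tripeptide: 4 + 5 + 6 = 15 heavy atoms.
GAS_ATOMS = [
    ("N", "GLY", 1, (11.104, 6.134, -6.504), "N"),
    ("CA", "GLY", 1, (11.639, 6.071, -5.147), "C"),
    ("C", "GLY", 1, (12.567, 7.169, -4.766), "C"),
    ("O", "GLY", 1, (13.162, 7.168, -3.688), "O"),
    ("N", "ALA", 2, (12.702, 8.167, -5.639), "N"),
    ("CA", "ALA", 2, (13.569, 9.300, -5.342), "C"),
    ("C", "ALA", 2, (14.993, 8.821, -5.089), "C"),
    ("O", "ALA", 2, (15.574, 8.037, -5.845), "O"),
    ("CB", "ALA", 2, (13.590, 10.273, -6.512), "C"),
    ("N", "SER", 3, (15.558, 9.298, -3.986), "N"),
    ("CA", "SER", 3, (16.919, 8.932, -3.608), "C"),
    ("C", "SER", 3, (17.917, 9.943, -4.147), "C"),
    ("O", "SER", 3, (17.577, 11.104, -4.374), "O"),
    ("CB", "SER", 3, (17.070, 8.813, -2.089), "C"),
    ("OG", "SER", 3, (16.180, 7.836, -1.571), "O"),
]


def gas_pdb_lines() -> list[str]:
    return [
        pdb_line("ATOM", i + 1, name, res, "A", seq, *xyz, el)
        for i, (name, res, seq, xyz, el) in enumerate(GAS_ATOMS)
    ]


@pytest.fixture
def gas_pdb_text() -> str:
    return "\n".join(gas_pdb_lines() + ["END", ""])


@pytest.fixture
def gas_structure(gas_pdb_text):
    return read_pdb(gas_pdb_text)[0]


@pytest.fixture
def two_model_pdb_text() -> str:
    lines = ["MODEL     1"] + gas_pdb_lines() + ["ENDMDL", "MODEL     2"]
    for i, (name, res, seq, xyz, el) in enumerate(GAS_ATOMS):
        x, y, z = xyz
        lines.append(pdb_line("ATOM", i + 1, name, res, "A", seq, x + 1.0, y, z, el))
    lines += ["ENDMDL", "END", ""]
    return "\n".join(lines)


@pytest.fixture
def tcdd_pdb_text() -> str:
    """Dibenzo-p-dioxin-like hetero compound, C12H4Cl4O2: 18 heavy atoms.

    Coordinates are schematic; only the element census matters here.
    """
    atoms = []
    k = 0
    for i in range(12):
        atoms.append(("C" + str(i + 1), "C", (float(i), 0.0, 0.0)))
    for i in range(2):
        atoms.append(("O" + str(i + 1), "O", (float(i), 1.4, 0.0)))
    for i in range(4):
        atoms.append(("CL" + str(i + 1), "CL", (float(i), -1.7, 0.0)))
    for i in range(4):
        atoms.append(("H" + str(i + 1), "H", (float(i) + 0.5, 0.0, 1.0)))
    lines = [
        pdb_line("HETATM", k + 1, name, "TCD", "L", 1, *xyz, el)
        for k, (name, el, xyz) in enumerate(atoms)
    ]
    return "\n".join(lines + ["END", ""])
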