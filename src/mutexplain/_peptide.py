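"""Internal-coordinate peptide backbone builder for synthetic test structures.

Builds poly-peptide backbones (N, CA, C, O) from ideal bond lengths and
angles with caller-supplied (phi, psi) torsions, using the standard
natural-extension-reference-frame placement.  Only used by the fixture
generator; real structures always come from PDB files.
"""

from __future__ import annotations

import numpy as np

# ideal backbone geometry (Engh-Huber style averages)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D given chain A-B-C, |CD|, angle(BCD) and torsion(ABCD)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict]:
    """Backbone coordinates for ``len(phi_psi)`` residues.

    Returns one dict per residue mapping atom name (N, CA, C, O) to a
    3-vector.  phi of the first residue is ignored (no preceding carbonyl).
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    res: list[dict] = []
    # seed frame: residue 1 in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        phi_i = phi_psi[i][0]
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: dihedral N-CA-C-O = psi + 180 (anti to the next N)
    for i in range(n_res):
        psi = phi_psi[i][1]
        r = res[i]
        r["O"] = place_atom(r["N"], r["CA"], r["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return res


def transform(residues: list[dict], rotation: np.ndarray, translation: np.ndarray) -> list[dict]:
    """Apply a rigid transform to every atom of a built backbone."""
    return [
        {name: rotation @ xyz + translation for name, xyz in r.items()}
        for r in residues
    ]
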