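"""Internal-coordinate geometry: torsions and ideal-geometry chain building.

Bond lengths and bond angles are held at ideal (Engh-Huber-like) values; the
peptide torsion is fixed trans (omega = 180 deg). Used by the coarse-grained
sampler and by the synthetic-structure builders.
"""

from __future__ import annotations

import numpy as np

# ideal backbone geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
# improper torsion N-C-CA-CB fixing L-chirality of the beta carbon
IMPROPER_N_C_CA_CB = 120.0
OMEGA_TRANS = 180.0


def torsion(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = p0 - p1
    v2 = p2 - p1
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d from the frame a-b-c with |c-d| = bond,
    angle(b,c,d) = angle and torsion(a,b,c,d) = dihedral (degrees).

    Natural extension reference frame construction; the returned position
    satisfies :func:`torsion` exactly.
    """
    ang = np.radians(angle)
    tor = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: np.ndarray, psi: np.ndarray, last_o_torsion: float = 0.0
) -> dict[str, np.ndarray]:
    """Build N/CA/C/O/CB coordinates for an n-residue chain from (phi, psi).

    ``phi[0]`` and ``psi[-1]`` may be NaN (undefined at the termini); phi of
    residue 1 has no effect on the build. O(i) is placed trans to N(i+1)
    (torsion psi(i) - 180 about CA-C); the last O, which has no successor,
    uses ``last_o_torsion`` (N-CA-C-O torsion, default 0 == psi 180).
    Returns arrays of shape (n, 3) keyed by atom name.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    # canonical frame for residue 1
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    ang = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        psi_prev = psi[i - 1]
        if not np.isfinite(psi_prev):
            raise ValueError(f"psi of residue {i} is undefined but needed")
        N[i] = nerf(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = nerf(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        phi_i = phi[i]
        if not np.isfinite(phi_i):
            raise ValueError(f"phi of residue {i + 1} is undefined but needed")
        C[i] = nerf(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi_i)
    O = np.zeros((n, 3))
    for i in range(n):
        if i < n - 1 and np.isfinite(psi[i]):
            tor = psi[i] - 180.0
        else:
            tor = last_o_torsion
        O[i] = nerf(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, tor)
    CB = np.zeros((n, 3))
    for i in range(n):
        CB[i] = nerf(N[i], C[i], CA[i], BOND_CA_CB, ANGLE_N_CA_CB,
                     IMPROPER_N_C_CA_CB)
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping ``mobile`` onto ``target``.

    Returns rotation R (3x3) and translation t with target ~= mobile @ R.T + t.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unsuperposed) RMSD between matched coordinate sets."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
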