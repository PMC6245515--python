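"""Ideal-geometry backbone construction in torsion space.

The coarse-grained chain is parameterized entirely by its backbone dihedrals
(phi, psi): bond lengths and bond angles are held at ideal trans-peptide
values, and Cartesian coordinates for N, CA, C are rebuilt from the torsions
by sequential natural-extension-reference-frame (NeRF) placement.  Carbonyl
O, amide H and the side-chain anchor CB are derived positions.

Hot functions are numba-compiled: the Metropolis sampler rebuilds the chain
at every trial move.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Ideal backbone geometry (Angstrom, degrees), trans peptide (omega = 180).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
BOND_C_O = 1.231
ANGLE_CA_C_O = 120.5
BOND_N_H = 1.020

_DEG = np.pi / 180.0


@njit(cache=True)
def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: position of atom d bonded to c, given chain a-b-c."""
    theta = angle_deg * _DEG
    chi = torsion_deg * _DEG
    bc = c - b
    bc /= np.sqrt(bc[0] ** 2 + bc[1] ** 2 + bc[2] ** 2)
    ab = b - a
    n = np.empty(3)
    n[0] = ab[1] * bc[2] - ab[2] * bc[1]
    n[1] = ab[2] * bc[0] - ab[0] * bc[2]
    n[2] = ab[0] * bc[1] - ab[1] * bc[0]
    n /= np.sqrt(n[0] ** 2 + n[1] ** 2 + n[2] ** 2)
    m = np.empty(3)
    m[0] = n[1] * bc[2] - n[2] * bc[1]
    m[1] = n[2] * bc[0] - n[0] * bc[2]
    m[2] = n[0] * bc[1] - n[1] * bc[0]
    d2 = np.empty(3)
    d2[0] = -bond * np.cos(theta)
    d2[1] = bond * np.sin(theta) * np.cos(chi)
    d2[2] = -bond * np.sin(theta) * np.sin(chi)  # sign fixes IUPAC dihedral convention
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


@njit(cache=True)
def build_chain(phi_deg, psi_deg):
    """Backbone N, CA, C coordinates from torsions; omega fixed at 180.

    ``phi_deg[0]`` and ``psi_deg[-1]`` are geometrically undefined for the
    termini and ignored.  Returns three (n, 3) arrays.
    """
    n_res = phi_deg.shape[0]
    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    # Seed frame for residue 0.
    N[0, 0], N[0, 1], N[0, 2] = 0.0, 0.0, 0.0
    CA[0, 0], CA[0, 1], CA[0, 2] = BOND_N_CA, 0.0, 0.0
    ang = ANGLE_N_CA_C * _DEG
    C[0, 0] = BOND_N_CA - BOND_CA_C * np.cos(ang)
    C[0, 1] = BOND_CA_C * np.sin(ang)
    C[0, 2] = 0.0
    for i in range(n_res - 1):
        N[i + 1] = _place(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi_deg[i])
        CA[i + 1] = _place(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, 180.0)
        C[i + 1] = _place(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C,
                          phi_deg[i + 1])
    return N, CA, C


@njit(cache=True)
def derive_atoms(N, CA, C, psi_deg):
    """Derived O, H, CB positions from the backbone trace.

    O is placed in the peptide plane anti to the next amide N (torsion
    psi + 180 about N-CA-C); H is placed on the bisector of the two N bonds
    in the amide plane; CB uses the standard ideal-geometry virtual-CB
    construction.  H of residue 0 is NaN (no preceding carbonyl).
    """
    n_res = N.shape[0]
    O = np.empty((n_res, 3))
    H = np.full((n_res, 3), np.nan)
    CB = np.empty((n_res, 3))
    for i in range(n_res):
        if i < n_res - 1:
            O[i] = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                          psi_deg[i] + 180.0)
        else:
            O[i] = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, 180.0)
        if i > 0:
            u = N[i] - C[i - 1]
            u /= np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
            v = N[i] - CA[i]
            v /= np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
            w = u + v
            w /= np.sqrt(w[0] ** 2 + w[1] ** 2 + w[2] ** 2)
            H[i] = N[i] + BOND_N_H * w
        b = CA[i] - N[i]
        c = C[i] - CA[i]
        a = np.empty(3)
        a[0] = b[1] * c[2] - b[2] * c[1]
        a[1] = b[2] * c[0] - b[0] * c[2]
        a[2] = b[0] * c[1] - b[1] * c[0]
        CB[i] = -0.58273431 * a + 0.56802827 * b - 0.54067466 * c + CA[i]
    return O, H, CB


@njit(cache=True)
def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.empty(3)
    n1[0] = b0[1] * b1[2] - b0[2] * b1[1]
    n1[1] = b0[2] * b1[0] - b0[0] * b1[2]
    n1[2] = b0[0] * b1[1] - b0[1] * b1[0]
    n2 = np.empty(3)
    n2[0] = b1[1] * b2[2] - b1[2] * b2[1]
    n2[1] = b1[2] * b2[0] - b1[0] * b2[2]
    n2[2] = b1[0] * b2[1] - b1[1] * b2[0]
    m1 = np.empty(3)
    nb1 = np.sqrt(b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2)
    m1[0] = (n1[1] * b1[2] - n1[2] * b1[1]) / nb1
    m1[1] = (n1[2] * b1[0] - n1[0] * b1[2]) / nb1
    m1[2] = (n1[0] * b1[1] - n1[1] * b1[0]) / nb1
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    y = m1[0] * n2[0] + m1[1] * n2[1] + m1[2] * n2[2]
    ang = np.arctan2(y, x) / _DEG
    if ang <= -180.0:
        ang += 360.0
    return ang


@njit(cache=True)
def measure_torsions(N, CA, C):
    """(phi, psi) in degrees from coordinates; NaN at the undefined termini."""
    n_res = N.shape[0]
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    for i in range(n_res):
        if i > 0:
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < n_res - 1:
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
    return phi, psi


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = ((-a + 180.0) % 360.0)
    out = 180.0 - out
    return out if out.ndim else float(out)


def circular_difference(a, b):
    """Minimal signed circular difference a - b in degrees, in (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def radius_of_gyration(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))
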