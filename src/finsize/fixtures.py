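"""Deterministic input generators for tests, examples and the CLI.

Everything the package is validated against is generated here from first
principles: a Born ion and a rock-salt lattice as analytic electrostatics
oracles, an ideal helical alanine octapeptide built from textbook backbone
geometry, Gaussian-mixture distance series emulating a two-state
conformational equilibrium, and orientation ensembles (isotropic or
box-face-locked).  All stochastic generators are reproducible under a
fixed seed.
"""

from __future__ import annotations

import itertools

import numpy as np

from .core import ChargeSystem

__all__ = [
    "born_ion",
    "rocksalt_cell",
    "ideal_helix_octapeptide",
    "two_state_distance_sampler",
    "orientation_sampler",
    "random_neutral_cloud",
]


def born_ion(q: float = 1.0, radius: float = 0.2, box_edge: float | None = None) -> ChargeSystem:
    """A single ion of charge ``q`` e and cavity radius ``radius`` nm.

    Placed at the box center when periodic, at the origin otherwise.  The
    nonperiodic solvation free energy has the Born closed form
    -f q^2 / (2 R) (1 - 1/eps_out), the primary analytic oracle for the
    Poisson machinery.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    center = (
        np.array([[box_edge / 2] * 3]) if box_edge is not None else np.zeros((1, 3))
    )
    return ChargeSystem(
        positions=center,
        charges=np.array([float(q)]),
        radii=np.array([float(radius)]),
        names=["ION"],
        box_edge=box_edge,
        group_tags=["solute"],
    )


def rocksalt_cell(a: float = 0.564, n_cells: int = 1) -> ChargeSystem:
    """Rock-salt (NaCl) lattice: alternating +-1 e charges, periodic.

    One conventional cell of edge ``a`` holds 8 ions on a simple cubic
    sublattice of spacing a/2; the box edge is ``n_cells * a``.  The Ewald
    energy per ion pair divided by f/d_nn (d_nn = a/2) is the Madelung
    constant -1.747565.
    """
    if not a > 0 or n_cells < 1:
        raise ValueError("need a > 0 and n_cells >= 1")
    half = a / 2.0
    n = 2 * n_cells
    positions, charges, names = [], [], []
    for i, j, k in itertools.product(range(n), repeat=3):
        positions.append((i * half, j * half, k * half))
        q = 1.0 if (i + j + k) % 2 == 0 else -1.0
        charges.append(q)
        names.append("NA" if q > 0 else "CL")
    return ChargeSystem(
        positions=np.array(positions),
        charges=np.array(charges),
        radii=np.full(len(charges), 0.15),
        names=names,
        box_edge=n_cells * a,
        group_tags=["solute"] * len(charges),
    )


# --- ideal alpha helix ----------------------------------------------------

# backbone internal coordinates (nm / degrees), textbook values
_B_N_CA = 0.1458
_B_CA_C = 0.1525
_B_C_N = 0.1329
_B_C_O = 0.1231
_B_N_H = 0.1010
_B_CA_CB = 0.1530
_A_C_N_CA = 121.7
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_CA_C_O = 120.8
_A_N_CA_CB = 110.4
_PHI_HELIX = -57.0
_PSI_HELIX = -47.0
_OMEGA = 180.0


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """Natural-extension (NeRF) placement of atom d bonded to c."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_helix_octapeptide() -> tuple[ChargeSystem, int, int]:
    """Ideal alpha-helical alanine octapeptide, zwitterionic termini.

    Backbone dihedrals are fixed at phi = -57, psi = -47, omega = 180 deg
    with standard bond lengths and angles (united-atom style: CB is a
    single methyl bead, only polar hydrogens are present).  The N-terminus
    is protonated (NH3+, charge +1 on the amine group) and the C-terminus
    deprotonated (COO-, charge -1 spread over the two oxygens).

    The molecule is oriented with its long (helix) axis along z and
    centered at the origin.

    Returns
    -------
    (system, n_index, c_index)
        The charge system plus the indices of the first-residue nitrogen
        and the last-residue carboxyl carbon, the end-to-end anchors.
    """
    n_res = 8
    atoms: list[tuple[str, np.ndarray, float, float]] = []  # name, xyz, q, r

    # seed the chain with three virtual-free positions for residue 1
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = n1 + np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c1 = ca1 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    backbone = [(n1, ca1, c1)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_new = _place(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, _PSI_HELIX)
        ca_new = _place(ca_prev, c_prev, n_new, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_new = _place(c_prev, n_new, ca_new, _B_CA_C, _A_N_CA_C, _PHI_HELIX)
        backbone.append((n_new, ca_new, c_new))

    n_index = c_index = -1
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        res_first = i == 0
        res_last = i == n_res - 1
        q_n = 1.0 if res_first else 0.0
        if res_first:
            n_index = len(atoms)
        atoms.append(("N", n_i, q_n, 0.17))
        if res_first:
            # NH3+ hydrogens, staggered about the N-CA bond
            for k, dih in enumerate((60.0, 180.0, 300.0)):
                h = _place(c_i, ca_i, n_i, _B_N_H, 109.5, dih)
                atoms.append((f"H{k + 1}", h, 0.0, 0.10))
        else:
            # amide hydrogen, trans to the carbonyl of the previous residue
            c_prev = backbone[i - 1][2]
            h = _place(backbone[i - 1][1], c_prev, n_i, _B_N_H, 119.0, 180.0)
            atoms.append(("H", h, 0.0, 0.10))
        atoms.append(("CA", ca_i, 0.0, 0.20))
        # CB methyl bead, tetrahedral off the N-CA-C plane
        cb = _place(c_i, n_i, ca_i, _B_CA_CB, _A_N_CA_CB, 240.0 + _PHI_HELIX)
        atoms.append(("CB", cb, 0.0, 0.22))
        if res_last:
            c_index = len(atoms)
        atoms.append(("C", c_i, 0.0, 0.19))
        if res_last:
            # carboxylate COO-: OXT takes the position the next backbone N
            # would occupy (chain-continuation convention), O is the
            # standard carbonyl position trans to it
            oxt = _place(backbone[i][0], ca_i, c_i, _B_C_O, 117.0, _PSI_HELIX)
            o = _place(backbone[i][0], ca_i, c_i, _B_C_O, 117.0, _PSI_HELIX + 180.0)
            atoms.append(("O", o, -0.5, 0.15))
            atoms.append(("OXT", oxt, -0.5, 0.15))
        else:
            n_next = backbone[i + 1][0]
            o = _place(n_next, ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
            atoms.append(("O", o, 0.0, 0.15))

    pos = np.array([a[1] for a in atoms])
    # orient: helix axis (largest principal component) -> z, center at origin
    pos -= pos.mean(axis=0)
    _, _, vt = np.linalg.svd(pos, full_matrices=False)
    axis_order = np.argsort(np.abs(pos @ vt.T).max(axis=0))[::-1]
    rot = vt[axis_order][::-1]  # smallest-variance axes first -> z is helix axis
    if np.linalg.det(rot) < 0:
        rot[0] *= -1
    pos = pos @ rot.T
    pos -= 0.5 * (pos.min(axis=0) + pos.max(axis=0))

    system = ChargeSystem(
        positions=pos,
        charges=np.array([a[2] for a in atoms]),
        radii=np.array([a[3] for a in atoms]),
        names=[a[0] for a in atoms],
        box_edge=None,
        group_tags=["solute"] * len(atoms),
    )
    return system, n_index, c_index


def two_state_distance_sampler(
    p_a: float = 0.2,
    mu_a: float = 0.65,
    mu_b: float = 2.1,
    sigma: float = 0.12,
    n_frames: int = 2000,
    n_replicas: int = 10,
    seed: int = 0,
) -> list[np.ndarray]:
    """Gaussian-mixture end-to-end distance series for replica analysis.

    Emulates a two-state conformational equilibrium: a compact basin at
    ``mu_a`` populated with probability ``p_a`` and an extended basin at
    ``mu_b`` with probability 1 - p_a, both with width ``sigma`` (nm).
    Returns one sample array per replica; deterministic under ``seed``.
    """
    if not 0.0 < p_a < 1.0:
        raise ValueError("p_a must be in (0, 1)")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicas):
        state = rng.random(n_frames) < p_a
        mu = np.where(state, mu_a, mu_b)
        out.append(rng.normal(mu, sigma))
    return out


_FACE_AXES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)


def orientation_sampler(
    mode: str = "isotropic",
    concentration: float = 20.0,
    n: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Unit orientation vectors: uniform on the sphere or face-locked.

    ``mode='isotropic'`` draws uniformly on the sphere.  ``mode='six-face'``
    draws from an equal-weight von Mises-Fisher mixture centered on the
    six cubic-face directions +-x, +-y, +-z with the given concentration;
    concentration -> 0 degenerates to the isotropic case.
    """
    rng = np.random.default_rng(seed)
    if mode == "isotropic" or (mode == "six-face" and concentration <= 1e-12):
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    if mode != "six-face":
        raise ValueError(f"unknown mode {mode!r}")
    kappa = float(concentration)
    centers = _FACE_AXES[rng.integers(0, 6, size=n)]
    # vMF sampling (Wood 1994 via inverse-CDF for the axial component)
    u = rng.random(n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    ang = rng.random(n) * 2.0 * np.pi
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    # orthonormal frame around each center
    ref = np.where(
        np.abs(centers[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
    )
    e1 = np.cross(centers, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(centers, e1)
    return (
        w[:, None] * centers
        + (s * np.cos(ang))[:, None] * e1
        + (s * np.sin(ang))[:, None] * e2
    )


def random_neutral_cloud(
    n_pairs: int = 4,
    box_edge: float = 2.0,
    min_sep: float = 0.25,
    seed: int = 0,
) -> ChargeSystem:
    """Random neutral configuration of +-1 e charges in a periodic box.

    Points are drawn uniformly, rejecting any candidate closer than
    ``min_sep`` (minimum image) to an accepted one; charges alternate so
    the system is exactly neutral.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_atoms = 2 * n_pairs
    pts: list[np.ndarray] = []
    guard = 0
    while len(pts) < n_atoms:
        cand = rng.random(3) * box_edge
        ok = True
        for p in pts:
            d = cand - p
            d -= box_edge * np.round(d / box_edge)
            if np.linalg.norm(d) < min_sep:
                ok = False
                break
        if ok:
            pts.append(cand)
        guard += 1
        if guard > 100000:
            raise RuntimeError("cannot place points with the requested min_sep")
    charges = np.array([1.0, -1.0] * n_pairs)
    return ChargeSystem(
        positions=np.array(pts),
        charges=charges,
        radii=np.full(n_atoms, 0.15),
        names=[f"Q{i}" for i in range(n_atoms)],
        box_edge=box_edge,
        group_tags=["solute"] * n_atoms,
    )
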