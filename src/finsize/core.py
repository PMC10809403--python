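"""Domain types, unit system and physical constants.

Units are fixed globally: lengths in nm, charges in elementary charge e,
energies in kJ/mol.  The Coulomb prefactor ``F_COULOMB`` matches the value
used by common MD unit systems so that ``F_COULOMB * q_i * q_j / r`` is a
pair energy in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "F_COULOMB",
    "K_BOLTZMANN",
    "T_DEFAULT",
    "EPS_SOLVENT_DEFAULT",
    "EPS_SOLVENT_EXPERIMENTAL",
    "GROUP_TAGS",
    "ChargeSystem",
    "PerturbationTopology",
    "RestraintSpec",
    "CorrectionResult",
    "constants_report",
    "make_charge_system",
]

#: Coulomb constant f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
F_COULOMB = 138.935458

#: Boltzmann constant in kJ mol^-1 K^-1.
K_BOLTZMANN = 0.00831446

#: Default simulation temperature (K).
T_DEFAULT = 300.0

#: Relative permittivity of the SPC-like solvent model (dimensionless).
EPS_SOLVENT_DEFAULT = 66.6

#: Experimental-water permittivity, available as an alternative.
EPS_SOLVENT_EXPERIMENTAL = 78.0

#: Recognised per-atom group memberships.
GROUP_TAGS = ("host", "solute", "coion", "solvent", "salt")


def constants_report() -> dict:
    """Constants block echoed into every JSON report."""
    return {
        "f_coulomb_kJ_mol_nm_e2": F_COULOMB,
        "k_B_kJ_mol_K": K_BOLTZMANN,
        "T_default_K": T_DEFAULT,
        "eps_solvent_default": EPS_SOLVENT_DEFAULT,
        "units": {"length": "nm", "charge": "e", "energy": "kJ/mol"},
    }


class UnsupportedGeometryError(ValueError):
    """Raised for non-cubic periodic boxes."""


class ChargeLookupError(KeyError):
    """Raised when an atom name cannot be resolved in a charge table."""


@dataclass
class ChargeSystem:
    """A set of point charges with cavity radii, optionally in a cubic box.

    Parameters
    ----------
    positions
        (n, 3) coordinates in nm.
    charges
        Per-atom charges in e.
    radii
        Per-atom cavity radii in nm (>= 0).
    names
        Per-atom labels.
    box_edge
        Cubic box edge L in nm; ``None`` means nonperiodic.
    group_tags
        Per-atom membership in one of ``GROUP_TAGS``.  Defaults to
        ``"solute"`` for every atom.
    """

    positions: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    names: list[str]
    box_edge: float | None = None
    group_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        self.radii = np.asarray(self.radii, dtype=float).reshape(n)
        if not self.names:
            self.names = [f"X{i}" for i in range(n)]
        if not self.group_tags:
            self.group_tags = ["solute"] * n
        if len(self.names) != n or len(self.group_tags) != n:
            raise ValueError("names/group_tags length does not match positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii < 0):
            raise ValueError("negative radii")
        if self.box_edge is not None and not self.box_edge > 0:
            raise ValueError("box_edge must be positive")
        bad = set(self.group_tags) - set(GROUP_TAGS)
        if bad:
            raise ValueError(f"unknown group tags: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    @property
    def periodic(self) -> bool:
        return self.box_edge is not None

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def subset(self, indices: Sequence[int]) -> "ChargeSystem":
        """A new system containing only the given atoms (box retained)."""
        idx = np.asarray(indices, dtype=int)
        return ChargeSystem(
            positions=self.positions[idx],
            charges=self.charges[idx],
            radii=self.radii[idx],
            names=[self.names[i] for i in idx],
            box_edge=self.box_edge,
            group_tags=[self.group_tags[i] for i in idx],
        )

    def group_indices(self, *tags: str) -> np.ndarray:
        """Atom indices whose group tag is in ``tags``."""
        return np.array(
            [i for i, t in enumerate(self.group_tags) if t in tags], dtype=int
        )

    def with_charges(self, charges: np.ndarray) -> "ChargeSystem":
        """Copy of the system with a replaced charge vector."""
        out = ChargeSystem(
            positions=self.positions.copy(),
            charges=np.asarray(charges, dtype=float),
            radii=self.radii.copy(),
            names=list(self.names),
            box_edge=self.box_edge,
            group_tags=list(self.group_tags),
        )
        return out


@dataclass
class PerturbationTopology:
    """End-state charge bookkeeping for a coalchemical perturbation.

    The solute charge moves from ``q_solute_a`` to ``q_solute_b`` while the
    coalchemical ion moves from ``q_ion_a`` to ``q_ion_b``; the overall box
    charges ``q_overall_a/b`` include host, environment and counter-ions.
    ``charges_a``/``charges_b`` are the full per-atom charge vectors when a
    concrete atom set is attached.
    """

    q_solute_a: float
    q_solute_b: float
    q_ion_a: float
    q_ion_b: float
    q_overall_a: float
    q_overall_b: float
    mode: str = "neutral-box"
    host_charge: float = 0.0
    counter_ion_complement: float = 0.0
    n_lambda: int = 11
    charges_a: np.ndarray | None = None
    charges_b: np.ndarray | None = None
    ion_species: str = ""

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        for name in ("charges_a", "charges_b"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def lambda_schedule(self) -> np.ndarray:
        """Equidistant lambda values on [0, 1]."""
        return np.linspace(0.0, 1.0, self.n_lambda)

    def charges_at_lambda(self, lam: float) -> np.ndarray:
        """Linear interpolation of the per-atom charge vectors."""
        if self.charges_a is None or self.charges_b is None:
            raise ValueError("topology carries no per-atom charge vectors")
        return (1.0 - lam) * self.charges_a + lam * self.charges_b

    def net_charge_at_lambda(self, lam: float) -> float:
        return (1.0 - lam) * self.q_overall_a + lam * self.q_overall_b

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "host_charge_e": self.host_charge,
            "q_solute_A_e": self.q_solute_a,
            "q_solute_B_e": self.q_solute_b,
            "q_ion_A_e": self.q_ion_a,
            "q_ion_B_e": self.q_ion_b,
            "q_overall_A_e": self.q_overall_a,
            "q_overall_B_e": self.q_overall_b,
            "counter_ion_complement_e": self.counter_ion_complement,
            "n_lambda": self.n_lambda,
            "ion_species": self.ion_species,
        }


@dataclass
class RestraintSpec:
    """Harmonic distance restraint between two atoms."""

    atom_i: int
    atom_j: int
    r0: float  # nm
    k: float  # kJ mol^-1 nm^-2

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("restraint requires two distinct atoms")
        if not self.r0 > 0:
            raise ValueError("r0 must be positive")
        if self.k < 0:
            raise ValueError("force constant must be non-negative")

    def energy(self, r: float) -> float:
        """Harmonic restraint energy 0.5 k (r - r0)^2 in kJ/mol."""
        return 0.5 * self.k * (r - self.r0) ** 2


@dataclass
class CorrectionResult:
    """Finite-size correction terms with per-snapshot breakdown.

    ``dg_dsm`` is identically zero for net-charge-conserving perturbations
    in neutral boxes and is carried only so the reported total is explicit:
    total = dg_pol + dg_dir (+ dg_dsm).
    """

    dg_pol: float = 0.0
    dg_dir: float = 0.0
    dg_dsm: float = 0.0
    per_snapshot_a: dict[str, list[float]] = field(default_factory=dict)
    per_snapshot_b: dict[str, list[float]] = field(default_factory=dict)
    stderr_pol: float = 0.0
    stderr_dir: float = 0.0

    @property
    def total(self) -> float:
        return self.dg_pol + self.dg_dir + self.dg_dsm

    @property
    def n_snapshots_a(self) -> int:
        return max((len(v) for v in self.per_snapshot_a.values()), default=0)

    @property
    def n_snapshots_b(self) -> int:
        return max((len(v) for v in self.per_snapshot_b.values()), default=0)

    def to_dict(self) -> dict:
        return {
            "dG_pol_kJ_mol": self.dg_pol,
            "dG_dir_kJ_mol": self.dg_dir,
            "dG_dsm_kJ_mol": self.dg_dsm,
            "total_kJ_mol": self.total,
            "stderr_pol_kJ_mol": self.stderr_pol,
            "stderr_dir_kJ_mol": self.stderr_dir,
            "n_snapshots": {"A": self.n_snapshots_a, "B": self.n_snapshots_b},
            "per_snapshot_A": self.per_snapshot_a,
            "per_snapshot_B": self.per_snapshot_b,
        }


def make_charge_system(
    coordinates: Sequence[tuple[str, Sequence[float]]],
    charge_table: Mapping[str, tuple[float, float]],
    box_edge: float | None = None,
    group_tags: Sequence[str] | None = None,
) -> ChargeSystem:
    """Assemble a :class:`ChargeSystem` from atom records and a charge table.

    Parameters
    ----------
    coordinates
        Sequence of ``(name, (x, y, z))`` records with coordinates in nm.
    charge_table
        Mapping ``name -> (charge_e, radius_nm)``.
    box_edge
        Cubic box edge in nm, or ``None`` for a nonperiodic system.
    group_tags
        Optional per-atom group tags.

    Raises
    ------
    ChargeLookupError
        If an atom name is missing from the table.
    """
    names, positions, charges, radii = [], [], [], []
    for name, xyz in coordinates:
        if name not in charge_table:
            raise ChargeLookupError(
                f"atom name {name!r} not found in the charge table"
            )
        q, r = charge_table[name]
        names.append(name)
        positions.append(tuple(xyz))
        charges.append(float(q))
        radii.append(float(r))
    return ChargeSystem(
        positions=np.array(positions, dtype=float).reshape(-1, 3),
        charges=np.array(charges, dtype=float),
        radii=np.array(radii, dtype=float),
        names=names,
        box_edge=box_edge,
        group_tags=list(group_tags) if group_tags is not None else [],
    )


def check_cubic_box(box_vector: Sequence[float], atol: float = 1e-6) -> float:
    """Validate that a 3-vector of box lengths describes a cube.

    Returns the edge length; raises :class:`UnsupportedGeometryError`
    otherwise.  Triclinic boxes are rejected upstream by the readers.
    """
    b = np.asarray(box_vector, dtype=float)
    if b.shape != (3,):
        raise UnsupportedGeometryError("box must be three edge lengths")
    if not (abs(b[0] - b[1]) <= atol and abs(b[0] - b[2]) <= atol):
        raise UnsupportedGeometryError(
            f"only cubic boxes are supported, got edges {b.tolist()}"
        )
    return float(b[0])
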