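"""Coordinate, table and configuration I/O.

Coordinate files are read and written through MDAnalysis (PDB and GRO
dialects); only cubic boxes are accepted.  Charge/radius tables and
distance series are plain tab-separated text handled with pandas; the
perturbation configuration is YAML; all reports are JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    ChargeSystem,
    PerturbationTopology,
    UnsupportedGeometryError,
    check_cubic_box,
    constants_report,
    make_charge_system,
)

__all__ = [
    "read_coordinates",
    "write_coordinates",
    "read_charge_table",
    "write_charge_table",
    "read_distance_series",
    "write_distance_series",
    "read_perturbation_yaml",
    "write_perturbation_yaml",
    "write_report",
]


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def read_coordinates(path: str | Path, fmt: str | None = None):
    """Read a PDB or GRO file into atom records and a box edge.

    Returns ``(records, box_edge)`` where records are ``(name, xyz_nm)``
    tuples and ``box_edge`` is the cubic edge in nm, or ``None`` when the
    file carries no box.  Non-cubic boxes are rejected.
    """
    path = Path(path)
    mda = _import_mda()
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unsupported coordinate format {fmt!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt)
        positions_nm = u.atoms.positions / 10.0  # MDAnalysis uses Angstrom
        names = [a.name for a in u.atoms]
        dims = u.dimensions
    box_edge = None
    if dims is not None and dims[:3].any():
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise UnsupportedGeometryError("non-orthorhombic box")
        box_edge = check_cubic_box(dims[:3] / 10.0, atol=1e-4)
    records = [(n, tuple(p)) for n, p in zip(names, positions_nm)]
    return records, box_edge


def write_coordinates(
    path: str | Path,
    system: ChargeSystem,
    fmt: str | None = None,
    resname: str = "MOL",
) -> None:
    """Write a ChargeSystem to PDB or GRO (positions nm -> format units)."""
    path = Path(path)
    mda = _import_mda()
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    n = system.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("names", system.names)
        u.add_TopologyAttr("resnames", [resname])
        u.add_TopologyAttr("resids", [1])
        u.atoms.positions = system.positions * 10.0
        if system.periodic:
            L = system.box_edge * 10.0
            u.dimensions = [L, L, L, 90.0, 90.0, 90.0]
        u.atoms.write(str(path))


def read_charge_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read ``name  charge_e  radius_nm`` (tab-separated with header)."""
    # keep_default_na: "NA" is a perfectly good sodium atom name
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"name", "charge_e", "radius_nm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"charge table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return {
        str(row["name"]): (float(row["charge_e"]), float(row["radius_nm"]))
        for _, row in df.iterrows()
    }


def write_charge_table(
    path: str | Path, table: dict[str, tuple[float, float]]
) -> None:
    df = pd.DataFrame(
        [(k, q, r) for k, (q, r) in table.items()],
        columns=["name", "charge_e", "radius_nm"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_distance_series(path: str | Path) -> list[np.ndarray]:
    """Read ``replica  frame  value_nm`` TSV into per-replica arrays."""
    df = pd.read_csv(path, sep="\t")
    required = {"replica", "frame", "value_nm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"distance series must have columns {sorted(required)}"
        )
    return [
        g.sort_values("frame")["value_nm"].to_numpy(dtype=float)
        for _, g in df.groupby("replica", sort=True)
    ]


def write_distance_series(path: str | Path, series: list[np.ndarray]) -> None:
    rows = [
        (r, f, float(v))
        for r, arr in enumerate(series)
        for f, v in enumerate(np.asarray(arr).ravel())
    ]
    pd.DataFrame(rows, columns=["replica", "frame", "value_nm"]).to_csv(
        path, sep="\t", index=False
    )


def write_perturbation_yaml(path: str | Path, topology: PerturbationTopology) -> None:
    doc = {
        "mode": topology.mode,
        "host_charge": topology.host_charge,
        "solute": {"qA": topology.q_solute_a, "qB": topology.q_solute_b},
        "coion": {"qA": topology.q_ion_a, "qB": topology.q_ion_b},
        "q_overall": {"A": topology.q_overall_a, "B": topology.q_overall_b},
        "counter_ion_complement": topology.counter_ion_complement,
        "n_lambda": topology.n_lambda,
        "ion_species": topology.ion_species,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_perturbation_yaml(path: str | Path) -> PerturbationTopology:
    doc = yaml.safe_load(Path(path).read_text())
    q_over = doc.get("q_overall", {})
    host = float(doc.get("host_charge", 0.0))
    sol = doc["solute"]
    ion = doc["coion"]
    qa = q_over.get("A")
    qb = q_over.get("B")
    if qa is None:
        qa = host + float(sol["qA"]) + float(ion["qA"]) + float(
            doc.get("counter_ion_complement", 0.0)
        )
    if qb is None:
        qb = host + float(sol["qB"]) + float(ion["qB"]) + float(
            doc.get("counter_ion_complement", 0.0)
        )
    return PerturbationTopology(
        q_solute_a=float(sol["qA"]),
        q_solute_b=float(sol["qB"]),
        q_ion_a=float(ion["qA"]),
        q_ion_b=float(ion["qB"]),
        q_overall_a=float(qa),
        q_overall_b=float(qb),
        mode=doc.get("mode", "neutral-box"),
        host_charge=host,
        counter_ion_complement=float(doc.get("counter_ion_complement", 0.0)),
        n_lambda=int(doc.get("n_lambda", 11)),
        ion_species=doc.get("ion_species", ""),
    )


def load_charge_system(
    coord_path: str | Path,
    charge_table_path: str | Path,
    box_edge: float | None = None,
) -> ChargeSystem:
    """Read coordinates + charge table into a ChargeSystem."""
    records, file_box = read_coordinates(coord_path)
    table = read_charge_table(charge_table_path)
    return make_charge_system(
        records, table, box_edge=box_edge if box_edge is not None else file_box
    )


def write_report(payload: dict, out: str | Path | None = None) -> str:
    """Serialize a report to JSON with the constants block attached."""
    payload = {**payload, "constants": constants_report()}
    text = json.dumps(payload, indent=2, default=_json_default)
    if out is not None:
        Path(out).write_text(text + "\n")
    return text


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
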