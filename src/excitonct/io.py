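"""File formats.

All files use eV and angstrom; conversion to the internal hartree/bohr
happens on read.  Geometries are plain XYZ, tabular data (snapshot tables,
environments) are headered CSV, fragments are YAML documents, and diabatic
models are JSON (floats round-trip exactly through repr).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ParseError
from .drf import EnvironmentSite
from .fragments import Site, ToyFragment
from .hamiltonian import BASIS_LABELS, DiabaticModel
from .ensemble import COLUMNS, SnapshotTable
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, EV_TO_HARTREE, HARTREE_TO_EV

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_snapshot_table",
    "write_snapshot_table",
    "read_coupling_table",
    "write_coupling_table",
    "read_fragment",
    "write_fragment",
    "read_model",
    "write_model",
    "read_environment",
    "write_environment",
    "read_molden_orbitals",
    "dimer_with_molden_orbitals",
]


# -- XYZ geometries ---------------------------------------------------------

def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read an XYZ file; returns (tags, positions in bohr)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError("empty XYZ file", line=1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("first line must be the atom count", line=1) from None
    if len(lines) < n + 2:
        raise ParseError(f"expected {n} coordinate lines", line=len(lines))
    tags, pos = [], []
    for k in range(n):
        parts = lines[2 + k].split()
        if len(parts) < 4:
            raise ParseError("expected: tag x y z", line=3 + k)
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError("non-numeric coordinate", line=3 + k) from None
        tags.append(parts[0])
        pos.append(xyz)
    return tags, np.asarray(pos) * ANGSTROM_TO_BOHR


def write_xyz(path, tags, positions_bohr, comment: str = "") -> None:
    pos = np.asarray(positions_bohr) * BOHR_TO_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"{len(tags)}\n{comment}\n")
        for tag, (x, y, z) in zip(tags, pos):
            fh.write(f"{tag} {float(x)!r} {float(y)!r} {float(z)!r}\n")


# -- snapshot tables ---------------------------------------------------------

def read_snapshot_table(path, set_label: str = "") -> SnapshotTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse snapshot table: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"snapshot table missing columns {missing}", line=1)
    return SnapshotTable(df, set_label=set_label or Path(path).stem)


def write_snapshot_table(path, table: SnapshotTable) -> None:
    table.records.to_csv(path, index=False)


def write_coupling_table(path, couplings: dict, value_unit: str = "eV") -> None:
    """Write a labelled coupling map {(label1, label2): value} as CSV."""
    rows = [
        {"label1": a, "label2": b, f"value_{value_unit}": float(v)}
        for (a, b), v in couplings.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_coupling_table(path, value_unit: str = "eV") -> dict:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse coupling table: {exc}") from exc
    col = f"value_{value_unit}"
    missing = [c for c in ("label1", "label2", col) if c not in df.columns]
    if missing:
        raise ParseError(f"coupling table missing columns {missing}", line=1)
    return {
        (r.label1, r.label2): float(getattr(r, col)) for r in df.itertuples()
    }


# -- fragments ---------------------------------------------------------------

def write_fragment(path, frag: ToyFragment) -> None:
    doc = {
        "label": frag.label,
        "n_occ": frag.n_occ,
        "frontier": dict(frag.frontier),
        "sites": [
            {
                "tag": s.tag,
                "position_angstrom": [float(x) for x in s.position * BOHR_TO_ANGSTROM],
                "core_charge": float(s.core_charge),
            }
            for s in frag.sites
        ],
        "basis": [
            {"site": int(i), "zeta_inv_bohr": float(z)} for i, z in frag.basis
        ],
        "orbital_energies_eV": [float(e * HARTREE_TO_EV) for e in frag.orbital_energies],
        "mo_coeffs": [[float(c) for c in row] for row in frag.mo_coeffs],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_fragment(path) -> ToyFragment:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        raise ParseError(str(exc), line=(mark.line + 1 if mark else None)) from exc
    try:
        sites = [
            Site(
                s["tag"],
                np.asarray(s["position_angstrom"], dtype=float) * ANGSTROM_TO_BOHR,
                float(s["core_charge"]),
            )
            for s in doc["sites"]
        ]
        return ToyFragment(
            label=doc["label"],
            sites=sites,
            basis=[(int(b["site"]), float(b["zeta_inv_bohr"])) for b in doc["basis"]],
            mo_coeffs=np.asarray(doc["mo_coeffs"], dtype=float),
            orbital_energies=np.asarray(doc["orbital_energies_eV"], dtype=float)
            * EV_TO_HARTREE,
            n_occ=int(doc["n_occ"]),
            frontier={k: int(v) for k, v in doc["frontier"].items()},
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed fragment document: missing {exc}") from exc


# -- diabatic models ----------------------------------------------------------

def write_model(path, model: DiabaticModel) -> None:
    doc = {
        "labels": list(model.labels),
        "H_eV": model.H.tolist(),
        "S": model.S.tolist(),
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path) -> DiabaticModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(exc.msg, line=exc.lineno) from exc
    try:
        return DiabaticModel(
            H=np.asarray(doc["H_eV"], dtype=float),
            S=np.asarray(doc["S"], dtype=float),
            labels=tuple(doc.get("labels", BASIS_LABELS)),
            provenance=doc.get("provenance", {}),
        )
    except KeyError as exc:
        raise ParseError(f"malformed model document: missing {exc}") from exc


# -- environments --------------------------------------------------------------

def write_environment(path, sites: list[EnvironmentSite]) -> None:
    rows = [
        {
            "x_angstrom": s.position[0] * BOHR_TO_ANGSTROM,
            "y_angstrom": s.position[1] * BOHR_TO_ANGSTROM,
            "z_angstrom": s.position[2] * BOHR_TO_ANGSTROM,
            "q_e": s.charge,
            "alpha_angstrom3": s.alpha * BOHR_TO_ANGSTROM**3,
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_environment(path) -> list[EnvironmentSite]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse environment table: {exc}") from exc
    required = ["x_angstrom", "y_angstrom", "z_angstrom", "q_e", "alpha_angstrom3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"environment table missing columns {missing}", line=1)
    return [
        EnvironmentSite(
            position=np.array([r.x_angstrom, r.y_angstrom, r.z_angstrom])
            * ANGSTROM_TO_BOHR,
            charge=float(r.q_e),
            alpha=float(r.alpha_angstrom3) * ANGSTROM_TO_BOHR**3,
        )
        for r in df.itertuples()
    ]


# -- Molden import --------------------------------------------------------------

def read_molden_orbitals(path) -> dict:
    """Minimal Molden reader: orbital energies, occupations, MO coefficients.

    Parses the [MO] section (s-type basis functions are sufficient for the
    toy model).  Energies are returned in hartree (Molden convention),
    coefficients as a (nbasis, norb) array in file order.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines) if ln.strip().lower().startswith("[mo]")
        )
    except StopIteration:
        raise ParseError("no [MO] section found") from None

    energies: list[float] = []
    occupations: list[float] = []
    coeff_cols: list[dict[int, float]] = []
    current: dict[int, float] | None = None
    for k in range(start + 1, len(lines)):
        ln = lines[k].strip()
        if not ln:
            continue
        if ln.startswith("["):
            break
        low = ln.lower()
        if low.startswith("ene="):
            current = {}
            coeff_cols.append(current)
            try:
                energies.append(float(ln.split("=", 1)[1]))
            except ValueError:
                raise ParseError("malformed Ene= line", line=k + 1) from None
        elif low.startswith("occup="):
            try:
                occupations.append(float(ln.split("=", 1)[1]))
            except ValueError:
                raise ParseError("malformed Occup= line", line=k + 1) from None
        elif low.startswith(("spin=", "sym=")):
            continue
        else:
            if current is None:
                raise ParseError("coefficient before first Ene= line", line=k + 1)
            parts = ln.split()
            if len(parts) != 2:
                raise ParseError("expected: index coefficient", line=k + 1)
            try:
                current[int(parts[0])] = float(parts[1])
            except ValueError:
                raise ParseError("non-numeric MO coefficient", line=k + 1) from None
    if not energies:
        raise ParseError("[MO] section contains no orbitals")
    nbasis = max(max(c) for c in coeff_cols if c)
    C = np.zeros((nbasis, len(coeff_cols)))
    for j, col in enumerate(coeff_cols):
        for i, v in col.items():
            C[i - 1, j] = v
    while len(occupations) < len(energies):
        occupations.append(0.0)
    return {
        "energies": np.asarray(energies),
        "occupations": np.asarray(occupations),
        "coefficients": C,
    }


def dimer_with_molden_orbitals(dimer, path):
    """Return a copy of a dimer with supermolecular orbitals from a Molden file.

    The file must provide as many orbitals as the dimer's union basis; the
    S' matrix is recomputed against the imported coefficients.
    """
    data = read_molden_orbitals(path)
    C = data["coefficients"]
    if C.shape != dimer.sup_coeffs.shape:
        raise InputError(
            f"Molden orbital dimensions {C.shape} do not match the dimer "
            f"basis {dimer.sup_coeffs.shape}"
        )
    order = np.argsort(data["energies"])
    new = dataclasses.replace(
        dimer,
        sup_energies=data["energies"][order],
        sup_coeffs=C[:, order],
    )
    new.Sprime = new.sup_coeffs.T @ new.ao_overlap @ new.frag_coeffs
    n_occ = int(round(np.sum(data["occupations"]) / 2.0)) or dimer.n_occ
    new.n_occ = n_occ
    return new
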