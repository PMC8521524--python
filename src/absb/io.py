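"""Readers and writers shared by all modules.

Tabular data is CSV with explicit headers (column order is irrelevant, extra
columns are preserved as metadata); structures are multi-model PDB v3 with
standard atom naming; results are JSON.  Lines starting with ``#`` in CSVs
are treated as comments (generators record their seed there).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .cest import CESTProfile
from .exceptions import RosterMismatchError, SchemaError
from .saltbridge import ConformerEnsemble
from .shift_pressure import ShiftSeries

__all__ = [
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_shift_csv",
    "write_shift_csv",
    "read_cest_csv",
    "write_cest_csv",
    "read_energy_csv",
    "write_json",
]


def _read_table(path: str | Path, required: set[str], label: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{label} file {path} is empty (no header row)") from None
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{label} file {path} missing column(s): {sorted(missing)}")
    for col in required:
        if col.endswith(("_ppm", "_bar", "_norm", "_hartree")) or col == "intensity":
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise SchemaError(
                    f"{label} file {path}: non-numeric value in column {col!r} "
                    f"at data row {int(bad[0]) + 1}"
                )
            df[col] = coerced
    if df.empty:
        warnings.warn(f"{label} file {path} has an empty data section", stacklevel=2)
    return df


# ---------------------------------------------------------------------------
# shift tables


SHIFT_COLUMNS = {"residue_index", "residue_name", "nucleus", "pressure_bar", "shift_ppm"}


def read_shift_csv(path: str | Path) -> list[ShiftSeries]:
    """Read a pressure-series shift table into ShiftSeries objects.

    Expects columns residue_index,residue_name,nucleus,pressure_bar,shift_ppm
    and optionally intensity; rows are grouped by (residue_index, nucleus).
    """
    df = _read_table(path, SHIFT_COLUMNS, "shift table")
    series = []
    for (ri, nuc), sub in df.groupby(["residue_index", "nucleus"], sort=True):
        sub = sub.sort_values("pressure_bar")
        intens = None
        if "intensity" in sub.columns and sub["intensity"].notna().all():
            intens = sub["intensity"].to_numpy(dtype=float)
        series.append(
            ShiftSeries(
                residue_index=int(ri),
                residue_name=str(sub["residue_name"].iloc[0]),
                nucleus=str(nuc),
                pressures=sub["pressure_bar"].to_numpy(dtype=float),
                shifts=sub["shift_ppm"].to_numpy(dtype=float),
                intensities=intens,
            )
        )
    return series


def write_shift_csv(
    series_list: list[ShiftSeries], path: str | Path, header_comment: str | None = None
) -> None:
    rows = []
    for s in series_list:
        for k in range(s.n_points):
            row = {
                "residue_index": s.residue_index,
                "residue_name": s.residue_name,
                "nucleus": s.nucleus,
                "pressure_bar": s.pressures[k],
                "shift_ppm": s.shifts[k],
            }
            if s.intensities is not None:
                row["intensity"] = s.intensities[k]
            rows.append(row)
    _write_csv(pd.DataFrame(rows), path, header_comment)


# ---------------------------------------------------------------------------
# CEST profiles


CEST_COLUMNS = {"offset_ppm", "intensity_norm"}


def read_cest_csv(path: str | Path) -> CESTProfile:
    """Read a CEST profile (columns offset_ppm,intensity_norm)."""
    df = _read_table(path, CEST_COLUMNS, "CEST profile")
    df = df.sort_values("offset_ppm")
    return CESTProfile(
        offsets_ppm=df["offset_ppm"].to_numpy(dtype=float),
        intensities=df["intensity_norm"].to_numpy(dtype=float),
    )


def write_cest_csv(
    profile: CESTProfile, path: str | Path, header_comment: str | None = None
) -> None:
    df = pd.DataFrame(
        {"offset_ppm": profile.offsets_ppm, "intensity_norm": profile.intensities}
    )
    _write_csv(df, path, header_comment)


# ---------------------------------------------------------------------------
# energy tables


ENERGY_COLUMNS = {"conformer_id", "group", "E_phos_hartree", "E_nonphos_hartree"}


def read_energy_csv(path: str | Path) -> pd.DataFrame:
    """Read a conformer energy table (Table-1-shaped input)."""
    return _read_table(path, ENERGY_COLUMNS, "energy table")


# ---------------------------------------------------------------------------
# multi-model PDB


def read_multimodel_pdb(path: str | Path) -> ConformerEnsemble:
    """Read a (multi-)model PDB file into a ConformerEnsemble.

    Single-model files yield an ensemble of one.  Every model must present
    the identical atom roster (residue index/name + atom name, in order);
    the first mismatch is reported.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        structure = parser.get_structure("ensemble", str(path))
    except PDBConstructionException as err:
        raise SchemaError(f"malformed PDB file {path}: {err}") from err
    rosters = []
    coords = []
    for model in structure:
        roster = []
        xyz = []
        for chain in model:
            for residue in chain:
                het, resseq, _icode = residue.id
                if het.strip():
                    continue
                for atom in residue:
                    roster.append((int(resseq), residue.resname.strip(), atom.get_name()))
                    xyz.append(atom.coord)
        rosters.append(roster)
        coords.append(np.asarray(xyz, dtype=float))
    if not rosters or not rosters[0]:
        raise SchemaError(f"PDB file {path} contains no ATOM records")
    ref = rosters[0]
    for mi, roster in enumerate(rosters[1:], start=2):
        if roster != ref:
            if len(roster) != len(ref):
                detail = f"{len(roster)} atoms vs {len(ref)} in model 1"
            else:
                k = next(i for i, (a, b) in enumerate(zip(roster, ref)) if a != b)
                detail = f"atom {k + 1}: {roster[k]} vs {ref[k]} in model 1"
            raise RosterMismatchError(
                f"PDB file {path}: model {mi} roster mismatch ({detail})"
            )
    return ConformerEnsemble(
        residue_index=np.array([r for r, _n, _a in ref]),
        residue_name=np.array([n for _r, n, _a in ref]),
        atom_name=np.array([a for _r, _n, a in ref]),
        coords=np.stack(coords),
    )


_PDB_ELEMENT = {"C": " C", "N": " N", "O": " O", "S": " S", "P": " P", "H": " H"}


def write_multimodel_pdb(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (v3 fixed columns)."""
    path = Path(path)
    with open(path, "w") as fh:
        for mi in range(ensemble.n_conformers):
            fh.write(f"MODEL     {mi + 1:4d}\n")
            serial = 1
            for k in range(ensemble.n_atoms):
                name = str(ensemble.atom_name[k])
                element = _PDB_ELEMENT.get(name[0], "  ")
                # atom names of 1-3 chars start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = ensemble.coords[mi, k]
                fh.write(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{ensemble.residue_name[k]:>3s} "
                    f"A{ensemble.residue_index[k]:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {element:>2s}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# misc


def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_json(obj, path: str | Path) -> None:
    """Write a JSON result file (numpy scalars coerced)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
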