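"""Conformer-property dataset I/O.

The on-disk format is a single HDF5 file with one group per isomer
(stoichiometry + index key, e.g. ``"C2H6O_00001"``).  Each group stores one
dataset per property, named by the canonical key strings of the published
layout (``'wb97x_dz.energy'``, ``'ccsd(t)_cbs.energy'``, ...).  Per-conformer
properties have leading dimension ``Nc`` (number of conformations); a value
that is unavailable for a given conformer is stored as NaN, and the filtered
iterator :func:`iter_data_buckets` drops conformers that are missing any of
the requested keys.

Units are stored as-is (energies in Hartree, coordinates in Angstrom, forces
in Ha/Angstrom, dipoles in e*A, atomic multipoles in a.u.); no conversion
happens at this layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import h5py
import numpy as np

__all__ = [
    "Conformation",
    "ConformerGroup",
    "SchemaReport",
    "SchemaError",
    "ParseError",
    "TABLE_SCHEMA",
    "write_dataset",
    "read_dataset",
    "iter_data_buckets",
    "validate_schema",
    "read_xyz",
    "write_xyz",
    "element_symbol",
    "atomic_number",
    "formula_of",
]


class SchemaError(ValueError):
    """A dataset or group violates the canonical layout."""


class ParseError(ValueError):
    """A text input (XYZ, component table) could not be parsed."""


# Symbols for the elements the toolkit routinely meets; H/C/N/O are the
# first-class citizens, the rest support generic XYZ round-trips.
_Z_TO_SYMBOL = {
    1: "H", 2: "He", 5: "B", 6: "C", 7: "N", 8: "O", 9: "F", 14: "Si",
    15: "P", 16: "S", 17: "Cl", 35: "Br", 53: "I",
}
_SYMBOL_TO_Z = {s: z for z, s in _Z_TO_SYMBOL.items()}


def element_symbol(z: int) -> str:
    try:
        return _Z_TO_SYMBOL[int(z)]
    except KeyError:
        raise ValueError(f"unsupported atomic number {z}") from None


def atomic_number(symbol: str) -> int:
    try:
        return _SYMBOL_TO_Z[symbol.capitalize() if len(symbol) > 1 else symbol.upper()]
    except KeyError:
        raise ValueError(f"unsupported element symbol {symbol!r}") from None


def formula_of(atomic_numbers) -> dict[str, int]:
    """Element -> count map for a list of atomic numbers."""
    counts: dict[str, int] = {}
    for z in np.asarray(atomic_numbers).ravel():
        s = element_symbol(int(z))
        counts[s] = counts.get(s, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Conformation:
    """A single molecular structure.

    Parameters
    ----------
    atomic_numbers
        Integer nuclear charges, length ``Na``.
    coordinates
        Cartesian positions, shape ``(Na, 3)``, Angstrom.
    cell
        Optional rectangular periodic cell edge lengths ``(3,)`` in Angstrom.
        Coordinates are *not* wrapped; the cell only defines the
        minimum-image metric.
    molecule_ids
        Optional per-atom monomer index (length ``Na``) for multi-molecule
        boxes.
    """

    atomic_numbers: np.ndarray
    coordinates: np.ndarray
    cell: np.ndarray | None = None
    molecule_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64).ravel()
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError(f"coordinates must be (Na, 3), got {self.coordinates.shape}")
        if len(self.atomic_numbers) != len(self.coordinates):
            raise ValueError(
                f"{len(self.atomic_numbers)} atomic numbers but "
                f"{len(self.coordinates)} coordinate rows"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=np.float64).ravel()
            if self.cell.shape != (3,) or not np.all(self.cell > 0):
                raise ValueError("cell must be 3 positive edge lengths")
        if self.molecule_ids is not None:
            self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64).ravel()
            if len(self.molecule_ids) != len(self.atomic_numbers):
                raise ValueError("molecule_ids length must equal atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def copy(self) -> "Conformation":
        return Conformation(
            self.atomic_numbers.copy(),
            self.coordinates.copy(),
            None if self.cell is None else self.cell.copy(),
            None if self.molecule_ids is None else self.molecule_ids.copy(),
        )

    def formula(self) -> str:
        counts = formula_of(self.atomic_numbers)
        return "".join(f"{s}{counts[s]}" for s in sorted(counts))


# Canonical property schema: key -> (dtype, trailing shape after Nc).
# 'atomic_numbers' is the one per-group (not per-conformer) record.
_F32, _F64, _U8 = np.dtype("float32"), np.dtype("float64"), np.dtype("uint8")
TABLE_SCHEMA: dict[str, tuple[np.dtype, tuple]] = {
    "coordinates": (_F32, ("Na", 3)),
    "atomic_numbers": (_U8, ()),
    "wb97x_dz.energy": (_F64, ()),
    "wb97x_tz.energy": (_F64, ()),
    "ccsd(t)_cbs.energy": (_F64, ()),
    "hf_dz.energy": (_F64, ()),
    "hf_tz.energy": (_F64, ()),
    "hf_qz.energy": (_F64, ()),
    "npno_ccsd(t)_dz.corr_energy": (_F64, ()),
    "npno_ccsd(t)_tz.corr_energy": (_F64, ()),
    "npno_ccsd(t)_qz.corr_energy": (_F64, ()),
    "mp2_dz.corr_energy": (_F64, ()),
    "mp2_tz.corr_energy": (_F64, ()),
    "mp2_qz.corr_energy": (_F64, ()),
    "wb97x_dz.forces": (_F32, ("Na", 3)),
    "wb97x_tz.forces": (_F32, ("Na", 3)),
    "wb97x_dz.dipole": (_F32, (3,)),
    "wb97x_tz.dipole": (_F32, (3,)),
    # 6 components ordered (xx, yy, zz, xy, xz, yz)
    "wb97x_tz.quadrupole": (_F32, (6,)),
    "wb97x_dz.cm5_charges": (_F32, ("Na",)),
    "wb97x_dz.hirshfeld_charges": (_F32, ("Na",)),
    "wb97x_tz.mbis_charges": (_F32, ("Na",)),
    "wb97x_tz.mbis_dipoles": (_F32, ("Na",)),
    "wb97x_tz.mbis_quadrupoles": (_F32, ("Na",)),
    "wb97x_tz.mbis_octupoles": (_F32, ("Na",)),
    "wb97x_tz.mbis_volumes": (_F32, ("Na",)),
}

#: Keys that describe per-conformer data (everything except atomic_numbers).
PER_CONFORMER_KEYS = tuple(k for k in TABLE_SCHEMA if k != "atomic_numbers")


def _expected_shape(key: str, nc: int, na: int) -> tuple:
    _, trailing = TABLE_SCHEMA[key]
    tail = tuple(na if t == "Na" else t for t in trailing)
    if key == "atomic_numbers":
        return (na,)
    return (nc,) + tail


@dataclass
class ConformerGroup:
    """All conformers of one isomer plus their per-conformer properties."""

    group_key: str
    atomic_numbers: np.ndarray
    properties: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers).ravel()
        self.properties = {k: np.asarray(v) for k, v in self.properties.items()}

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    @property
    def n_conformers(self) -> int:
        if "coordinates" in self.properties:
            return len(self.properties["coordinates"])
        for v in self.properties.values():
            return len(v)
        return 0

    def validate(self) -> list[str]:
        """Return a list of invariant-violation messages (empty if valid)."""
        problems = []
        nc, na = self.n_conformers, self.n_atoms
        for key, arr in self.properties.items():
            if key not in TABLE_SCHEMA:
                problems.append(f"unknown property key {key!r}")
                continue
            want = _expected_shape(key, nc, na)
            if arr.shape != want:
                problems.append(f"{key!r}: shape {arr.shape}, expected {want}")
            want_dtype = TABLE_SCHEMA[key][0]
            if arr.dtype != want_dtype:
                problems.append(f"{key!r}: dtype {arr.dtype}, expected {want_dtype}")
        return problems

    def conformation(self, index: int) -> Conformation:
        return Conformation(self.atomic_numbers, self.properties["coordinates"][index])


@dataclass
class SchemaReport:
    valid: bool
    violations: list[tuple[str, str, str]]

    def __bool__(self) -> bool:  # truthiness == validity
        return self.valid


# ---------------------------------------------------------------------------
# HDF5 read / write / validate
# ---------------------------------------------------------------------------

def write_dataset(groups: list[ConformerGroup], path) -> str:
    """Write conformer groups to ``path`` in the canonical HDF5 layout.

    Raises :class:`SchemaError` naming the offending group and key if any
    group violates the schema, and :class:`ValueError` on duplicate keys.
    """
    keys = [g.group_key for g in groups]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate group keys: {dupes}")
    for g in groups:
        problems = g.validate()
        if problems:
            raise SchemaError(f"group {g.group_key!r}: " + "; ".join(problems))
    with h5py.File(path, "w") as f:
        for g in groups:
            grp = f.create_group(g.group_key)
            grp.create_dataset("atomic_numbers", data=np.asarray(g.atomic_numbers, dtype=_U8))
            for key, arr in g.properties.items():
                grp.create_dataset(key, data=arr)
    return str(path)


def read_dataset(path) -> list[ConformerGroup]:
    """Read every group of a canonical-layout HDF5 file."""
    out = []
    with h5py.File(path, "r") as f:
        for key in f:
            grp = f[key]
            z = grp["atomic_numbers"][()]
            props = {k: grp[k][()] for k in grp if k != "atomic_numbers"}
            out.append(ConformerGroup(key, z, props))
    return out


def validate_schema(path) -> SchemaReport:
    """Check every group/dataset of ``path`` against the canonical layout."""
    violations: list[tuple[str, str, str]] = []
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open {path!r} as HDF5: {exc}") from exc
    with f:
        for gkey in f:
            grp = f[gkey]
            if not isinstance(grp, h5py.Group):
                violations.append((gkey, "", "top-level entry is not a group"))
                continue
            if "atomic_numbers" not in grp:
                violations.append((gkey, "atomic_numbers", "missing"))
                continue
            za = grp["atomic_numbers"]
            na = za.shape[0] if za.ndim == 1 else -1
            if za.ndim != 1:
                violations.append((gkey, "atomic_numbers", f"shape {za.shape}, expected (Na,)"))
            if za.dtype != _U8:
                violations.append((gkey, "atomic_numbers", f"dtype {za.dtype}, expected uint8"))
            if "coordinates" not in grp:
                violations.append((gkey, "coordinates", "missing"))
                continue
            nc = grp["coordinates"].shape[0]
            for key in grp:
                if key == "atomic_numbers":
                    continue
                ds = grp[key]
                if key not in TABLE_SCHEMA:
                    violations.append((gkey, key, "unknown property key"))
                    continue
                want_dtype, _ = TABLE_SCHEMA[key]
                want_shape = _expected_shape(key, nc, na)
                if ds.dtype != want_dtype:
                    violations.append((gkey, key, f"dtype {ds.dtype}, expected {want_dtype}"))
                if ds.shape != want_shape:
                    violations.append((gkey, key, f"shape {ds.shape}, expected {want_shape}"))
    return SchemaReport(valid=not violations, violations=violations)


def _availability_mask(arr: np.ndarray) -> np.ndarray:
    """Per-conformer boolean mask: True where the value is fully present."""
    if arr.ndim == 1:
        return ~np.isnan(arr)
    return ~np.isnan(arr).any(axis=tuple(range(1, arr.ndim)))


def iter_data_buckets(path, keys: list[str]) -> Iterator[tuple[str, np.ndarray, dict[str, np.ndarray]]]:
    """Iterate groups, keeping only conformers that have *all* requested keys.

    Yields ``(group_key, atomic_numbers, data)`` where ``data`` always
    contains ``'coordinates'`` plus the requested keys, filtered to the
    conformers for which every requested value is present (non-NaN), in the
    original conformer order.  Groups with no surviving conformer are
    skipped silently.
    """
    for key in keys:
        if key not in TABLE_SCHEMA:
            raise KeyError(
                f"unknown property key {key!r}; valid keys: {sorted(TABLE_SCHEMA)}"
            )
    wanted = [k for k in keys if k not in ("coordinates", "atomic_numbers")]
    with h5py.File(path, "r") as f:
        for gkey in f:
            grp = f[gkey]
            if any(k not in grp for k in wanted):
                continue
            coords = grp["coordinates"][()]
            mask = np.ones(len(coords), dtype=bool)
            for k in wanted:
                mask &= _availability_mask(grp[k][()])
            if not mask.any():
                continue
            data = {"coordinates": coords[mask]}
            for k in wanted:
                data[k] = grp[k][()][mask]
            yield gkey, grp["atomic_numbers"][()], data


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

_XYZ_FMT = "{:2s} {: 15.8f} {: 15.8f} {: 15.8f}\n"


def write_xyz(path, conformations: list[Conformation] | Conformation, comment: str = "") -> str:
    """Write one or more conformations as (multi-frame) XYZ."""
    if isinstance(conformations, Conformation):
        conformations = [conformations]
    with open(path, "w") as fh:
        for conf in conformations:
            fh.write(f"{conf.n_atoms}\n{comment}\n")
            for z, xyz in zip(conf.atomic_numbers, conf.coordinates):
                fh.write(_XYZ_FMT.format(element_symbol(int(z)), *xyz))
    return str(path)


def read_xyz(path) -> list[Conformation]:
    """Read a (multi-frame) XYZ file.

    Raises :class:`ParseError` with the offending line number on malformed
    input (bad atom-count line, truncated frame, unparseable atom line).
    """
    confs: list[Conformation] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # trailing blank lines
            i += 1
            continue
        try:
            na = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count, got {lines[i]!r}")
        if na <= 0:
            raise ParseError(f"line {i + 1}: invalid atom count {na}")
        if i + 2 + na > len(lines):
            raise ParseError(f"line {i + 1}: frame of {na} atoms truncated at end of file")
        zs, coords = [], []
        for j in range(na):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"line {ln + 1}: expected 'El x y z', got {lines[ln]!r}")
            sym = parts[0]
            try:
                z = int(sym) if re.fullmatch(r"\d+", sym) else atomic_number(sym)
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"line {ln + 1}: {exc}") from None
            zs.append(z)
            coords.append(xyz)
        confs.append(Conformation(zs, coords))
        i += 2 + na
    return confs
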