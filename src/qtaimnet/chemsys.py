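"""Chemistry data model, canonical pair indexing, and file I/O.

Provides the :class:`Molecule` / :class:`LocalPropertyRecord` containers,
the canonical upper-triangle enumeration of unordered atom pairs, standard
(multi-structure) XYZ reading and writing, and a newline-delimited JSON
dataset format for labeled per-atom (1P) and per-pair (2P) properties.

Conventions: atom indices are 0-based; unordered pairs are stored with
``i < j`` in row-major upper-triangle order; coordinates are Cartesian
angstroms; no periodic boundary conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Molecule",
    "PairIndex",
    "LocalPropertyRecord",
    "ParseError",
    "SchemaError",
    "ELEMENT_SYMBOLS",
    "SYMBOL_TO_Z",
    "symbol_for",
    "z_for_symbol",
    "enumerate_pairs",
    "n_pairs",
    "pair_flat_index",
    "pair_from_flat",
    "interatomic_distance",
    "read_xyz",
    "write_xyz",
    "read_dataset",
    "write_dataset",
]

# 1 a.u. of energy expressed in kcal/mol, used only when reporting.
HARTREE_TO_KCALMOL = 627.5

ELEMENT_SYMBOLS = (
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

SYMBOL_TO_Z: Dict[str, int] = {s.lower(): z for z, s in enumerate(ELEMENT_SYMBOLS) if z > 0}


class ParseError(ValueError):
    """Raised for malformed XYZ or dataset files; names the offending line."""


class SchemaError(ValueError):
    """Raised when a dataset record violates the documented schema."""


def symbol_for(z: int) -> str:
    if not 1 <= int(z) < len(ELEMENT_SYMBOLS):
        raise ValueError(f"no element symbol for Z={z}")
    return ELEMENT_SYMBOLS[int(z)]


def z_for_symbol(symbol: str) -> int:
    try:
        return SYMBOL_TO_Z[symbol.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


@dataclass(frozen=True)
class Molecule:
    """Atomic numbers plus Cartesian coordinates (angstrom)."""

    Z: Tuple[int, ...]
    R: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        Z = tuple(int(z) for z in self.Z)
        object.__setattr__(self, "Z", Z)
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[1] != 3:
            raise ValueError(f"coordinates must be M x 3, got shape {R.shape}")
        if len(Z) != R.shape[0]:
            raise ValueError(f"len(Z)={len(Z)} != coordinate rows {R.shape[0]}")
        if len(Z) < 1:
            raise ValueError("molecule must contain at least one atom")
        if any(z < 1 for z in Z):
            raise ValueError("atomic numbers must be >= 1")
        if not np.all(np.isfinite(R)):
            raise ValueError("coordinates must be finite")
        R.setflags(write=False)
        object.__setattr__(self, "R", R)

    @property
    def n_atoms(self) -> int:
        return len(self.Z)

    def distance(self, i: int, j: int) -> float:
        return interatomic_distance(self, i, j)

    def distance_matrix(self) -> np.ndarray:
        diff = self.R[:, None, :] - self.R[None, :, :]
        return np.sqrt(np.sum(diff * diff, axis=-1))


@dataclass(frozen=True)
class PairIndex:
    """Unordered atom pair (i < j) and its flat canonical position."""

    i: int
    j: int
    flat: int

    def __post_init__(self) -> None:
        if not 0 <= self.i < self.j:
            raise ValueError(f"pair requires 0 <= i < j, got ({self.i}, {self.j})")


def n_pairs(M: int) -> int:
    """Number of unordered pairs among M atoms: M(M-1)/2."""
    if M < 1:
        raise ValueError(f"atom count must be >= 1, got {M}")
    return M * (M - 1) // 2


def enumerate_pairs(M: int) -> List[PairIndex]:
    """All unordered pairs in row-major upper-triangle order.

    Flat indices run 0 .. M(M-1)/2 - 1 consecutively.
    """
    if M < 1:
        raise ValueError(f"atom count must be >= 1, got {M}")
    pairs: List[PairIndex] = []
    flat = 0
    for i in range(M):
        for j in range(i + 1, M):
            pairs.append(PairIndex(i, j, flat))
            flat += 1
    return pairs


def pair_flat_index(i: int, j: int, M: int) -> int:
    """Flat position of unordered pair (i, j) in the canonical enumeration."""
    if i == j:
        raise ValueError(f"pair indices must differ, got ({i}, {j})")
    a, b = (i, j) if i < j else (j, i)
    if not 0 <= a < b < M:
        raise ValueError(f"pair ({i}, {j}) out of range for M={M}")
    return a * M - a * (a + 1) // 2 + (b - a - 1)


def pair_from_flat(flat: int, M: int) -> Tuple[int, int]:
    """Inverse of :func:`pair_flat_index`."""
    if not 0 <= flat < n_pairs(M):
        raise ValueError(f"flat index {flat} out of range for M={M}")
    i = 0
    offset = 0
    while flat >= offset + (M - i - 1):
        offset += M - i - 1
        i += 1
    return i, i + 1 + (flat - offset)


def pair_index_arrays(M: int) -> Tuple[np.ndarray, np.ndarray]:
    """(i_idx, j_idx) integer arrays in canonical order; vectorized form."""
    iu = np.triu_indices(M, k=1)
    return iu[0], iu[1]


def interatomic_distance(molecule: Molecule, i: int, j: int) -> float:
    """Euclidean distance between atoms i and j in angstrom."""
    if i == j:
        raise ValueError(f"invalid pair: i == j == {i}")
    M = molecule.n_atoms
    if not (0 <= i < M and 0 <= j < M):
        raise ValueError(f"atom index out of range for M={M}: ({i}, {j})")
    return float(np.linalg.norm(molecule.R[i] - molecule.R[j]))


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def read_xyz(path) -> List[Molecule]:
    """Read a (multi-structure) XYZ file into a list of molecules.

    Dialect: count line, comment line, then ``Symbol x y z`` per atom,
    repeated per frame. Symbols are matched case-insensitively.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    molecules: List[Molecule] = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError:
            raise ParseError(
                f"{path}:{pos + 1}: expected an atom count, got {lines[pos]!r}"
            ) from None
        if count < 1:
            raise ParseError(f"{path}:{pos + 1}: atom count must be >= 1, got {count}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        atom_lines = lines[pos + 2 : pos + 2 + count]
        if len(atom_lines) < count:
            raise ParseError(
                f"{path}:{pos + 1}: frame declares {count} atoms but file "
                f"ends after {len(atom_lines)} atom lines"
            )
        Z: List[int] = []
        R = np.empty((count, 3), dtype=float)
        for k, line in enumerate(atom_lines):
            lineno = pos + 3 + k
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 'Symbol x y z', got {line!r}")
            try:
                Z.append(z_for_symbol(fields[0]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            try:
                R[k] = [float(v) for v in fields[1:4]]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad coordinate in {line!r}") from None
        mol_id = comment.strip() or f"frame{frame}"
        molecules.append(Molecule(tuple(Z), R, id=mol_id))
        pos += 2 + count
        frame += 1
    return molecules


def write_xyz(molecules: Iterable[Molecule], path) -> None:
    """Write molecules as a multi-structure XYZ file (round-trip safe)."""
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.n_atoms}\n{mol.id}\n")
            for z, r in zip(mol.Z, mol.R):
                fh.write(
                    f"{symbol_for(z)} {r[0]:.10f} {r[1]:.10f} {r[2]:.10f}\n"
                )


# ---------------------------------------------------------------------------
# Labeled dataset records
# ---------------------------------------------------------------------------

@dataclass
class LocalPropertyRecord:
    """A molecule with labeled per-atom (1P) and per-pair (2P) properties.

    2P arrays follow the canonical pair enumeration of :func:`enumerate_pairs`.
    Units are tagged per property name ("e" for electrons, "au" for hartree).
    """

    molecule: Molecule
    props_1p: Dict[str, np.ndarray] = field(default_factory=dict)
    props_2p: Dict[str, np.ndarray] = field(default_factory=dict)
    units: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = self.molecule.n_atoms
        P = n_pairs(M)
        for name, vals in list(self.props_1p.items()):
            arr = np.asarray(vals, dtype=float)
            if arr.shape != (M,):
                raise SchemaError(
                    f"record {self.molecule.id!r}: 1P property {name!r} has "
                    f"length {arr.size}, expected M={M}"
                )
            if not np.all(np.isfinite(arr)):
                raise SchemaError(
                    f"record {self.molecule.id!r}: 1P property {name!r} has non-finite values"
                )
            self.props_1p[name] = arr
        for name, vals in list(self.props_2p.items()):
            arr = np.asarray(vals, dtype=float)
            if arr.shape != (P,):
                raise SchemaError(
                    f"record {self.molecule.id!r}: 2P property {name!r} has "
                    f"length {arr.size}, expected M(M-1)/2={P}"
                )
            if not np.all(np.isfinite(arr)):
                raise SchemaError(
                    f"record {self.molecule.id!r}: 2P property {name!r} has non-finite values"
                )
            self.props_2p[name] = arr

    def property_values(self, name: str) -> np.ndarray:
        if name in self.props_1p:
            return self.props_1p[name]
        if name in self.props_2p:
            return self.props_2p[name]
        raise KeyError(f"record {self.molecule.id!r} has no property {name!r}")


def write_dataset(records: Iterable[LocalPropertyRecord], path) -> None:
    """Write records as newline-delimited JSON (one record per line)."""
    with open(path, "w") as fh:
        for rec in records:
            obj = {
                "id": rec.molecule.id,
                "Z": list(rec.molecule.Z),
                "R": [[float(v) for v in row] for row in rec.molecule.R],
                "props_1p": {k: [float(v) for v in a] for k, a in rec.props_1p.items()},
                "props_2p": {k: [float(v) for v in a] for k, a in rec.props_2p.items()},
                "units": dict(rec.units),
            }
            fh.write(json.dumps(obj) + "\n")


def read_dataset(path) -> List[LocalPropertyRecord]:
    """Read newline-delimited JSON records written by :func:`write_dataset`."""
    records: List[LocalPropertyRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON record: {exc}") from None
            try:
                mol = Molecule(
                    tuple(int(z) for z in obj["Z"]),
                    np.asarray(obj["R"], dtype=float),
                    id=str(obj.get("id", f"record{lineno}")),
                )
                rec = LocalPropertyRecord(
                    molecule=mol,
                    props_1p={k: np.asarray(v, float) for k, v in obj.get("props_1p", {}).items()},
                    props_2p={k: np.asarray(v, float) for k, v in obj.get("props_2p", {}).items()},
                    units={str(k): str(v) for k, v in obj.get("units", {}).items()},
                )
            except KeyError as exc:
                raise SchemaError(f"{path}:{lineno}: missing field {exc}") from None
            records.append(rec)
    return records
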