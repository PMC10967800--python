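"""Protein structures in the AlphaFold PDB dialect.

AlphaFold2 models are single-chain, single-model PDB files whose B-factor
column carries the per-residue predicted local distance difference test
(pLDDT, 0-100).  This module reads and writes that dialect, assigns van der
Waals radii, and applies the dataset inclusion filters (sequence length
100-700 residues, mean pLDDT strictly above 50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .tables import DEFAULT_VDW_RADII, STANDARD_RESIDUES

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
    "assign_radii",
    "passes_inclusion_filters",
    "read_manifest",
]

#: Class labels: highly abundant cytoplasmic = 1, extracellular = 0.
LABEL_HAC = 1
LABEL_EXTRACELLULAR = 0


class PDBParseError(ValueError):
    """Raised for a malformed ATOM/HETATM record; the message names the line."""


@dataclass
class Atom:
    """A single atom with coordinates in Angstrom.

    ``b_column`` is the value read from the PDB B-factor field, interpreted
    as pLDDT (0-100) under the AlphaFold dialect.
    """

    name: str
    element: str
    coords: np.ndarray
    b_column: float = 0.0
    vdw_radius: float | None = None

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Residue:
    """An amino-acid residue: ordered atoms plus a single pLDDT value."""

    name: str
    seq_index: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def plddt(self) -> float:
        """Residue pLDDT, preferring the CA atom's B-column."""
        ca = self.get_atom("CA")
        if ca is not None:
            return ca.b_column
        return self.atoms[0].b_column

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_RESIDUES

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def backbone(self) -> dict[str, Atom | None]:
        return {n: self.get_atom(n) for n in ("N", "CA", "C", "O")}

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class ProteinStructure:
    """An ordered collection of residues with an optional class label.

    ``label`` is 1 for highly abundant cytoplasmic (HAC) proteins and 0 for
    extracellular proteins when known.
    """

    id: str
    residues: list[Residue]
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("a structure needs at least one residue")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue seq_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def atoms(self, include_hydrogens: bool = False) -> list[Atom]:
        out: list[Atom] = []
        for r in self.residues:
            out.extend(r.atoms if include_hydrogens else r.heavy_atoms())
        return out

    def coordinates(self, include_hydrogens: bool = False) -> np.ndarray:
        atoms = self.atoms(include_hydrogens)
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)

    def radii(self, include_hydrogens: bool = False) -> np.ndarray:
        atoms = self.atoms(include_hydrogens)
        vals = [a.vdw_radius for a in atoms]
        if any(v is None for v in vals):
            raise ValueError("vdW radii not assigned; call assign_radii first")
        return np.asarray(vals, dtype=float)

    def plddt_values(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues], dtype=float)

    def mean_plddt(self) -> float:
        return float(self.plddt_values().mean())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a rigidly moved copy (used by invariance tests)."""
        new_res = []
        for r in self.residues:
            new_atoms = [
                replace(a, coords=rotation @ np.asarray(a.coords, float) + translation)
                for a in r.atoms
            ]
            new_res.append(Residue(r.name, r.seq_index, new_atoms))
        return ProteinStructure(self.id, new_res, self.label)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    if name[:2].upper() in ("SE", "FE", "ZN", "MG", "MN"):
        return name[:2].capitalize()
    return name[:1].upper()


def parse_pdb(text: str, structure_id: str = "structure", *, alphafold_dialect: bool = True) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Atoms are grouped into residues in file order.  Only the first model of
    a multi-model file is read.  Multiple chains are accepted with a warning
    and concatenated.  HETATM records are ignored.  Under the AlphaFold
    dialect the B-factor column is validated as a pLDDT in [0, 100];
    out-of-range values are clamped with a warning.
    """
    residues: list[Residue] = []
    current_key: tuple[str, int, str] | None = None
    chains_seen: set[str] = set()
    seen_atom = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.strip() == "ENDMDL":
            break
        if rec != "ATOM  ":
            continue
        seen_atom = True
        try:
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21]
            seq_index = int(line[22:26])
            coords = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            bcol = float(line[60:66]) if line[60:66].strip() else 0.0
            element = line[76:78].strip() or _guess_element(name)
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"malformed ATOM record at line {lineno}: {line!r}") from exc
        if not np.all(np.isfinite(coords)):
            raise PDBParseError(f"non-finite coordinates at line {lineno}")
        if alphafold_dialect and not (0.0 <= bcol <= 100.0):
            warnings.warn(
                f"B-factor {bcol} outside pLDDT range [0, 100] at line {lineno}; clamped",
                stacklevel=2,
            )
            bcol = min(max(bcol, 0.0), 100.0)
        chains_seen.add(chain)
        atom = Atom(name=name, element=element.capitalize(), coords=coords, b_column=bcol)
        key = (chain, seq_index, resname)
        if key != current_key:
            residues.append(Residue(name=resname, seq_index=seq_index))
            current_key = key
        residues[-1].atoms.append(atom)
    if not seen_atom:
        raise PDBParseError("no ATOM records found")
    if len(chains_seen) > 1:
        warnings.warn(
            f"multiple chains {sorted(chains_seen)} concatenated into one structure",
            stacklevel=2,
        )
    _validate_residue_plddt(residues)
    _renumber_if_needed(residues)
    return ProteinStructure(id=structure_id, residues=residues)


def _validate_residue_plddt(residues: list[Residue]) -> None:
    for r in residues:
        vals = {round(a.b_column, 2) for a in r.atoms}
        if len(vals) > 1:
            warnings.warn(
                f"residue {r.name}{r.seq_index} has non-uniform B-column values; "
                "using the CA value as its pLDDT",
                stacklevel=3,
            )


def _renumber_if_needed(residues: list[Residue]) -> None:
    # Concatenated chains may restart author numbering; renumber sequentially
    # so the strictly-increasing invariant holds.
    idx = [r.seq_index for r in residues]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        for i, r in enumerate(residues, start=1):
            r.seq_index = i


def write_pdb(s: ProteinStructure) -> str:
    """Serialize a structure to PDB text (ATOM records + TER/END)."""
    lines = []
    serial = 0
    for res in s.residues:
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = np.asarray(a.coords, dtype=float)
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s} {res.name:<3.3s} A{res.seq_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{a.b_column:6.2f}          "
                f"{a.element:>2.2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def assign_radii(
    s: ProteinStructure,
    radii_table: dict[str, float] | None = None,
    *,
    fallback: float | None = None,
) -> ProteinStructure:
    """Assign per-atom van der Waals radii in place (and return ``s``).

    Uses Bondi radii by default (C 1.70, N 1.55, O 1.52, S 1.80 Angstrom).
    An element missing from the table raises unless ``fallback`` is given.
    """
    table = dict(DEFAULT_VDW_RADII if radii_table is None else radii_table)
    missing: set[str] = set()
    for res in s.residues:
        for a in res.atoms:
            r = table.get(a.element)
            if r is None:
                if fallback is None:
                    missing.add(a.element)
                    continue
                r = fallback
            if r <= 0:
                raise ValueError(f"non-positive vdW radius for element {a.element}")
            a.vdw_radius = r
    if missing:
        raise KeyError(
            f"no vdW radius for element(s) {sorted(missing)}; "
            "extend the radii table or pass a fallback radius"
        )
    return s


def passes_inclusion_filters(
    s: ProteinStructure,
    *,
    min_length: int = 100,
    max_length: int = 700,
    min_mean_plddt: float = 50.0,
) -> tuple[bool, list[str]]:
    """Apply the dataset inclusion filters.

    A structure is kept iff its modelled residue count lies in
    [``min_length``, ``max_length``] and its mean pLDDT is strictly greater
    than ``min_mean_plddt``.  Returns (decision, list of failed-filter
    reasons).
    """
    reasons: list[str] = []
    n = len(s.residues)
    if not (min_length <= n <= max_length):
        reasons.append(f"length {n} outside [{min_length}, {max_length}]")
    mean_plddt = s.mean_plddt()
    if not mean_plddt > min_mean_plddt:
        reasons.append(f"mean pLDDT {mean_plddt:.2f} not > {min_mean_plddt}")
    return (not reasons), reasons


def read_manifest(text: str) -> dict[str, int]:
    """Parse a class-label manifest CSV (columns ``id,label``).

    Labels are ``HAC`` (-> 1) or ``extracellular`` (-> 0), case-insensitive.
    """
    import csv
    import io

    mapping = {"hac": LABEL_HAC, "extracellular": LABEL_EXTRACELLULAR}
    out: dict[str, int] = {}
    for row in csv.DictReader(io.StringIO(text)):
        label = row["label"].strip().lower()
        if label not in mapping:
            raise ValueError(f"unknown label {row['label']!r} for id {row['id']!r}")
        out[row["id"].strip()] = mapping[label]
    return out
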