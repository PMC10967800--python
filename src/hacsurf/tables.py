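"""Reference tables: vdW radii, max-ASA, hydrophobicity scale, side-chain pKa.

The residue-keyed tables ship as commented CSV files under ``hacsurf/data``
so they can be inspected and replaced; loaders cache the parsed dicts.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

#: Bondi van der Waals radii (Angstrom) for the elements found in heavy-atom
#: protein models.  Hydrogen is included for completeness although hydrogens
#: are excluded from surface computations by default.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}

#: Three-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: One-letter <-> three-letter code maps.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Negatively / positively charged residues at physiological pH (pH 7).
#: Histidine (pKa ~ 6) is excluded here but participates in the
#: Henderson-Hasselbalch net-charge computation.
NEGATIVE_RESIDUES: frozenset[str] = frozenset({"ASP", "GLU"})
POSITIVE_RESIDUES: frozenset[str] = frozenset({"LYS", "ARG"})


def _read_csv(name: str) -> list[dict[str, str]]:
    text = resources.files("hacsurf.data").joinpath(name).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    return list(csv.DictReader(lines))


@lru_cache(maxsize=None)
def max_asa_table() -> dict[str, float]:
    """Theoretical Gly-X-Gly maximum solvent-accessible areas (Angstrom^2)."""
    return {r["resname"]: float(r["max_asa"]) for r in _read_csv("max_asa_tien2013.csv")}


@lru_cache(maxsize=None)
def hydrophobicity_scale() -> dict[str, float]:
    """Eisenberg normalized consensus hydrophobicity per standard residue."""
    return {
        r["resname"]: float(r["hydrophobicity"])
        for r in _read_csv("eisenberg_consensus.csv")
    }


@lru_cache(maxsize=None)
def sidechain_pka_table() -> dict[str, tuple[float, int]]:
    """Map resname -> (pKa, charge sign of the protonated(+1)/deprotonated(-1) form)."""
    return {
        r["resname"]: (float(r["pka"]), int(r["charge_sign"]))
        for r in _read_csv("sidechain_pka.csv")
    }
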