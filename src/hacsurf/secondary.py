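"""Backbone-geometry secondary-structure assignment.

A simplified Kabsch-Sander scheme over three buckets: H (helix, with 3-10
and pi helices folded in), E (beta structure, i.e. bridge/ladder partners),
and L (loop / disordered region, everything else).  Backbone amide
hydrogens, absent from heavy-atom models, are rebuilt from the preceding
peptide's C=O direction, and hydrogen bonds are scored with the classic
electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond being assigned when E < -0.5 kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import ProteinStructure
from .surface import SurfaceMask

__all__ = [
    "SSAssignment",
    "assign_secondary_structure",
    "ss_proportions",
    "hbond_energy_matrix",
]

_Q = 0.084 * 332.0  # kcal/mol * Angstrom
_HBOND_CUTOFF = -0.5  # kcal/mol
_MIN_SEQ_SEP = 2  # donor and acceptor must be at least this far apart


@dataclass
class SSAssignment:
    """One label per residue: 'H', 'E' or 'L'."""

    labels: list[str]

    def fractions(self, selector: np.ndarray | None = None) -> tuple[float, float, float]:
        labs = np.asarray(self.labels)
        if selector is not None:
            labs = labs[np.asarray(selector, dtype=bool)]
        if len(labs) == 0:
            raise ValueError("empty residue selection")
        n = len(labs)
        return (
            float((labs == "H").sum()) / n,
            float((labs == "E").sum()) / n,
            float((labs == "L").sum()) / n,
        )


def _backbone_coords(s: ProteinStructure) -> tuple[np.ndarray, np.ndarray]:
    """(n, 4, 3) array of N, CA, C, O coordinates and a per-residue completeness mask."""
    n = len(s.residues)
    bb = np.full((n, 4, 3), np.nan)
    ok = np.zeros(n, dtype=bool)
    for i, res in enumerate(s.residues):
        atoms = res.backbone
        if all(atoms[k] is not None for k in ("N", "CA", "C", "O")):
            for j, k in enumerate(("N", "CA", "C", "O")):
                bb[i, j] = atoms[k].coords
            ok[i] = True
    return bb, ok


def hbond_energy_matrix(s: ProteinStructure) -> np.ndarray:
    """Kabsch-Sander H-bond energies E[donor, acceptor] in kcal/mol.

    Entry (i, j) scores the bond from the amide N-H of residue i to the
    carbonyl C=O of residue j.  Missing backbone atoms, chain starts
    (no rebuilt H) and prolines give +inf (no bond possible).
    """
    bb, ok = _backbone_coords(s)
    n = len(s.residues)
    energy = np.full((n, n), np.inf)
    # rebuilt amide H: N + unit vector from O(prev) to C(prev)
    h_pos = np.full((n, 3), np.nan)
    has_h = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if ok[i] and ok[i - 1] and s.residues[i].name != "PRO":
            co = bb[i - 1, 2] - bb[i - 1, 3]
            h_pos[i] = bb[i, 0] + co / np.linalg.norm(co)
            has_h[i] = True
    for i in range(n):
        if not has_h[i]:
            continue
        for j in range(n):
            if not ok[j] or abs(i - j) < _MIN_SEQ_SEP:
                continue
            r_on = np.linalg.norm(bb[j, 3] - bb[i, 0])
            if r_on > 5.2:  # beyond plausible H-bond geometry
                continue
            r_ch = np.linalg.norm(bb[j, 2] - h_pos[i])
            r_oh = np.linalg.norm(bb[j, 3] - h_pos[i])
            r_cn = np.linalg.norm(bb[j, 2] - bb[i, 0])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clash; treat as no bond
                continue
            energy[i, j] = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return energy


def assign_secondary_structure(s: ProteinStructure) -> SSAssignment:
    """Assign H/E/L per residue from backbone hydrogen-bond patterns.

    Helices are runs of at least two consecutive n->n+k turns (k = 4 for
    alpha, 3 and 5 folded into the same H bucket); beta structure comes from
    parallel and antiparallel bridge patterns.  Residues with incomplete
    backbones are labelled L with a warning.
    """
    n = len(s.residues)
    bb, ok = _backbone_coords(s)
    if (~ok).any():
        missing = [s.residues[i].seq_index for i in np.flatnonzero(~ok)]
        if len(missing) == n:
            return SSAssignment(labels=["L"] * n)
        warnings.warn(
            f"residues {missing} lack full backbones; labelled L", stacklevel=2
        )
    energy = hbond_energy_matrix(s)
    bond = energy < _HBOND_CUTOFF

    def turn(k: int) -> np.ndarray:
        t = np.zeros(n, dtype=bool)
        for i in range(n - k):
            t[i] = bond[i + k, i]
        return t

    labels = np.array(["L"] * n, dtype=object)

    # bridges -> E
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (bond[j, i - 1] and bond[i + 1, j]) or (
                bond[i, j - 1] and bond[j + 1, i]
            )
            antiparallel = (bond[i, j] and bond[j, i]) or (
                bond[j + 1, i - 1] and bond[i + 1, j - 1]
            )
            if parallel or antiparallel:
                labels[i] = "E"
                labels[j] = "E"

    # helical turns -> H (priority over E, matching DSSP's H-first summary)
    for k in (4, 3, 5):
        t = turn(k)
        for i in range(1, n - k):
            if t[i] and t[i - 1]:
                labels[i : i + k] = "H"

    labels[~ok] = "L"
    return SSAssignment(labels=list(labels))


def ss_proportions(
    ss: SSAssignment,
    mask: SurfaceMask,
    region: str = "surface",
) -> tuple[float, float, float]:
    """Fractions (h, e, l) of secondary-structure labels in one region.

    ``region`` selects surface or buried residues from the mask; the three
    fractions sum to one for a non-empty region.  An empty region returns
    NaNs with a warning.
    """
    if region not in ("surface", "buried"):
        raise ValueError("region must be 'surface' or 'buried'")
    sel = mask.surface_flag if region == "surface" else ~mask.surface_flag
    try:
        return ss.fractions(sel)
    except ValueError:
        warnings.warn(f"no residues in the {region} region; fractions undefined", stacklevel=2)
        return (float("nan"),) * 3
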