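"""Synthetic structures and feature tables for a download-free pipeline.

Two families of generators stand in for the AlphaFold-modelled proteins the
analysis was designed for:

* geometric fixtures — ideal helices, antiparallel beta hairpins, random
  coils and bare sphere clusters with known geometry and assignable pLDDT
  values, built from ideal backbone parameters (bond lengths/angles from
  Engh-Huber averages, side chains reduced to a CB pseudo-atom); and
* statistically controlled two-class descriptor tables drawn from
  class-conditional Gaussians whose default mean shifts reproduce the
  observed point-biserial correlations between each surface descriptor and
  the highly-abundant-cytoplasmic (HAC) class label.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Atom, ProteinStructure, Residue, assign_radii
from .tables import STANDARD_RESIDUES

__all__ = [
    "SyntheticSpec",
    "make_backbone_structure",
    "make_ideal_helix",
    "make_beta_hairpin",
    "make_random_coil",
    "make_sphere_cluster",
    "make_feature_table",
    "study_table_spec",
    "DESCRIPTOR_SHIFTS",
]

# Engh-Huber-style ideal backbone geometry (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_A_N_CA_CB = 110.4


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D from A, B, C."""
    ang, tor = np.deg2rad(angle), np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral CB from the backbone frame."""
    d1 = (n - ca) / np.linalg.norm(n - ca)
    d2 = (c - ca) / np.linalg.norm(c - ca)
    c12 = float(d1 @ d2)
    alpha = np.cos(np.deg2rad(_A_N_CA_CB)) / (1.0 + c12)
    w = alpha * (d1 + d2)
    perp = np.cross(d1, d2)
    perp /= np.linalg.norm(perp)
    beta = np.sqrt(max(0.0, 1.0 - float(w @ w)))
    return ca + _B_CA_CB * (w - beta * perp)


def make_backbone_structure(
    sequence: list[str] | str,
    phi: float | list[float] = -57.0,
    psi: float | list[float] = -47.0,
    omega: float = 180.0,
    plddt: float | list[float] = 90.0,
    structure_id: str = "synthetic",
    with_radii: bool = True,
) -> ProteinStructure:
    """Build a backbone (N, CA, C, O + CB pseudo-side-chain) from torsions.

    ``sequence`` is a list of three-letter codes or a one-letter string;
    ``phi``/``psi`` may be scalars or per-residue lists.  Glycine gets no CB.
    """
    from .tables import ONE_TO_THREE

    if isinstance(sequence, str):
        sequence = [ONE_TO_THREE[c] for c in sequence]
    for name in sequence:
        if name not in STANDARD_RESIDUES:
            raise ValueError(f"unknown residue {name!r} in sequence")
    n_res = len(sequence)
    phis = np.broadcast_to(np.asarray(phi, dtype=float), (n_res,))
    psis = np.broadcast_to(np.asarray(psi, dtype=float), (n_res,))
    plddts = np.broadcast_to(np.asarray(plddt, dtype=float), (n_res,))

    # seed the first three backbone atoms in a canonical pose
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(0, "N")] = np.zeros(3)
    coords[(0, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    coords[(0, "C")] = coords[(0, "CA")] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        if i > 0:
            coords[(i, "N")] = _place_atom(
                coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
                _B_C_N, _A_CA_C_N, psis[i - 1],
            )
            coords[(i, "CA")] = _place_atom(
                coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
                _B_N_CA, _A_C_N_CA, omega,
            )
            coords[(i, "C")] = _place_atom(
                coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
                _B_CA_C, _A_N_CA_C, phis[i],
            )
    for i in range(n_res):
        # carbonyl O anti to the next amide nitrogen (psi + 180)
        coords[(i, "O")] = _place_atom(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _B_C_O, _A_CA_C_O, psis[i] + 180.0,
        )
    residues = []
    for i, name in enumerate(sequence):
        atoms = [
            Atom("N", "N", coords[(i, "N")], plddts[i]),
            Atom("CA", "C", coords[(i, "CA")], plddts[i]),
            Atom("C", "C", coords[(i, "C")], plddts[i]),
            Atom("O", "O", coords[(i, "O")], plddts[i]),
        ]
        if name != "GLY":
            cb = _cb_position(coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")])
            atoms.append(Atom("CB", "C", cb, plddts[i]))
        residues.append(Residue(name=name, seq_index=i + 1, atoms=atoms))
    s = ProteinStructure(id=structure_id, residues=residues)
    if with_radii:
        assign_radii(s)
    return s


def make_ideal_helix(
    n_residues: int = 15,
    sequence: str | list[str] | None = None,
    plddt: float | list[float] = 90.0,
    structure_id: str = "ideal-helix",
) -> ProteinStructure:
    """Ideal alpha-helix (phi = -57, psi = -47, omega = 180)."""
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues")
    seq = ["ALA"] * n_residues if sequence is None else sequence
    return make_backbone_structure(
        seq, phi=-57.0, psi=-47.0, plddt=plddt, structure_id=structure_id
    )


def make_random_coil(
    n_residues: int = 20,
    seed: int = 0,
    structure_id: str = "random-coil",
) -> ProteinStructure:
    """Random-torsion coil with no systematic hydrogen bonding."""
    rng = np.random.default_rng(seed)
    # sample away from the canonical helix/sheet basins
    phis = rng.uniform(-160.0, -60.0, n_residues)
    psis = rng.uniform(-60.0, 40.0, n_residues) + rng.choice([0.0, 180.0], n_residues)
    return make_backbone_structure(
        ["GLY"] * n_residues, phi=list(phis), psi=list(psis), structure_id=structure_id
    )


def _strand_backbone(s: ProteinStructure) -> dict[str, np.ndarray]:
    out = {}
    for name in ("N", "CA", "C", "O"):
        out[name] = np.array([r.get_atom(name).coords for r in s.residues])
    return out


def _amide_h(bb: dict[str, np.ndarray]) -> np.ndarray:
    """Rebuilt amide H per residue (NaN for the chain start)."""
    n = len(bb["N"])
    h = np.full((n, 3), np.nan)
    for i in range(1, n):
        co = bb["C"][i - 1] - bb["O"][i - 1]
        h[i] = bb["N"][i] + co / np.linalg.norm(co)
    return h


def _inter_strand_energy(don: dict[str, np.ndarray], acc: dict[str, np.ndarray]) -> float:
    """Sum of negative Kabsch-Sander H-bond energies, donors -> acceptors."""
    q = 0.084 * 332.0
    h = _amide_h(don)
    total = 0.0
    for i in range(1, len(don["N"])):
        for j in range(len(acc["C"])):
            r_on = np.linalg.norm(acc["O"][j] - don["N"][i])
            if r_on > 5.2:
                continue
            r_ch = np.linalg.norm(acc["C"][j] - h[i])
            r_oh = np.linalg.norm(acc["O"][j] - h[i])
            r_cn = np.linalg.norm(acc["C"][j] - don["N"][i])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            total += min(e, 0.0)
    return total


def make_beta_hairpin(
    n_per_strand: int = 6,
    structure_id: str = "beta-hairpin",
) -> ProteinStructure:
    """Two-strand antiparallel beta sheet built by rigid docking.

    Both strands are ideal extended strands (phi = -139, psi = 135); the
    second is flipped end-over-end and docked against the first by
    minimizing the total backbone hydrogen-bond energy over rigid
    translations, which registers the antiparallel bridge pattern.
    """
    strand = make_backbone_structure(
        ["VAL"] * n_per_strand, phi=-139.0, psi=135.0, structure_id="strand"
    )
    bb = _strand_backbone(strand)
    centroid = bb["CA"].mean(axis=0)
    axis = bb["CA"][-1] - bb["CA"][0]
    axis /= np.linalg.norm(axis)
    perp = _any_perpendicular(axis)
    perp2 = np.cross(axis, perp)
    rot = _rotation_about(perp, np.pi)
    flipped0 = {k: (rot @ (v - centroid).T).T + centroid for k, v in bb.items()}

    def shifted(offset: np.ndarray) -> dict[str, np.ndarray]:
        return {k: v + offset for k, v in flipped0.items()}

    def objective(offset: np.ndarray) -> float:
        cand = shifted(offset)
        return _inter_strand_energy(cand, bb) + _inter_strand_energy(bb, cand)

    best_off, best_e = None, np.inf
    for ta in np.arange(-3.5, 3.5, 0.5):
        for theta in np.deg2rad(np.arange(0.0, 360.0, 30.0)):
            for tp in np.arange(4.0, 5.8, 0.3):
                off = ta * axis + tp * (np.cos(theta) * perp + np.sin(theta) * perp2)
                e = objective(off)
                if e < best_e:
                    best_e, best_off = e, off
    from scipy.optimize import minimize

    res = minimize(objective, best_off, method="Nelder-Mead", options={"xatol": 1e-3})
    if res.fun < best_e:
        best_off = res.x
    rot_t = rot, best_off, centroid
    residues = list(make_backbone_structure(
        ["VAL"] * n_per_strand, phi=-139.0, psi=135.0
    ).residues)
    for i, res_b in enumerate(strand.residues):
        atoms = [
            Atom(
                a.name,
                a.element,
                rot_t[0] @ (a.coords - rot_t[2]) + rot_t[2] + rot_t[1],
                a.b_column,
                a.vdw_radius,
            )
            for a in res_b.atoms
        ]
        residues.append(Residue(res_b.name, n_per_strand + 1 + i, atoms))
    out = ProteinStructure(structure_id, residues)
    assign_radii(out)
    return out


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def make_sphere_cluster(
    centers: np.ndarray | list,
    radii: float | np.ndarray | list = 1.7,
    plddt: float = 90.0,
    structure_id: str = "sphere-cluster",
) -> ProteinStructure:
    """Bare pseudo-atom cluster for surface-geometry oracles.

    Each sphere becomes one single-atom pseudo-residue (nonstandard name
    ``SPH``), bypassing every residue-type-keyed descriptor.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    rr = np.broadcast_to(np.asarray(radii, dtype=float), (len(centers),))
    residues = []
    for i, (c, r) in enumerate(zip(centers, rr)):
        atom = Atom("X", "C", np.array(c, dtype=float), plddt, vdw_radius=float(r))
        residues.append(Residue(name="SPH", seq_index=i + 1, atoms=[atom]))
    return ProteinStructure(id=structure_id, residues=residues)


# ---------------------------------------------------------------------------
# statistically controlled feature tables

#: Default class-1 (HAC) standardized mean shifts per descriptor, derived by
#: inverting the balanced-design point-biserial relation
#: r = (d/2) / sqrt(1 + d^2/4)  =>  d = 2 r / sqrt(1 - r^2)
#: from the observed descriptor-vs-label correlations (positive for the two
#: charged-area fractions, negative for hydrophobicity, the normalized
#: surface B-factor, beta-structure and disordered-region proportions and
#: roughness; the exposure degree s_sf carries no shift).
DESCRIPTOR_SHIFTS: dict[str, float] = {
    "s_phobic_avg": -1.070,
    "s_pos_area": 0.875,
    "s_neg_area": 0.492,
    "norm_s_b": -0.462,
    "s_bs": -0.468,
    "s_do": -0.205,
    "fd": -0.213,
}


@dataclass
class SyntheticSpec:
    """Generative parameters for a two-class Gaussian descriptor table."""

    names: list[str]
    class0_means: np.ndarray
    class1_means: np.ndarray
    covariance: np.ndarray
    n_class0: int = 331
    n_class1: int = 337
    seed: int = 0
    #: derived columns appended after sampling: name -> (coefficient dict, noise sd)
    derived: dict[str, tuple[dict[str, float], float]] = field(default_factory=dict)
    #: extra pure-noise columns with equal class means (exercise the
    #: nonsignificance drop)
    null_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.class0_means = np.asarray(self.class0_means, dtype=float)
        self.class1_means = np.asarray(self.class1_means, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise ValueError("covariance must be positive-definite")


def study_table_spec(
    n_class0: int = 331,
    n_class1: int = 337,
    seed: int = 0,
    shifts: dict[str, float] | None = None,
) -> SyntheticSpec:
    """Default table spec emulating the 668-protein two-class study design.

    Seven core descriptors with unit variance and the class-1 mean shifts of
    :data:`DESCRIPTOR_SHIFTS`.  The two charged-area fractions are
    positively correlated (r = 0.4, as charged surfaces grow together), so
    their derived sum ``s_charge_avg`` is highly collinear with both; the
    helix proportion ``s_ah`` trades off primarily against beta structure
    (``s_ah`` loads -1.2 on ``s_bs`` and -0.5 on ``s_do``), making it
    highly collinear within the structure category while leaving the
    conditional effects of ``s_bs`` and ``s_do`` well separated from zero.
    A null exposure-degree column ``s_sf`` has identical class means.
    """
    shifts = dict(DESCRIPTOR_SHIFTS if shifts is None else shifts)
    names = list(shifts)
    k = len(names)
    cov = np.eye(k)

    def _set_corr(a: str, b: str, r: float) -> None:
        if a in names and b in names:
            ia, ib = names.index(a), names.index(b)
            cov[ia, ib] = cov[ib, ia] = r

    _set_corr("s_pos_area", "s_neg_area", 0.4)
    charge_norm = np.sqrt(2.0 * (1.0 + 0.4))
    ah_norm = np.sqrt(1.2**2 + 0.5**2)
    derived = {
        "s_charge_avg": (
            {"s_pos_area": 1.0 / charge_norm, "s_neg_area": 1.0 / charge_norm},
            0.05,
        ),
        "s_ah": ({"s_bs": -1.2 / ah_norm, "s_do": -0.5 / ah_norm}, 0.05),
    }
    return SyntheticSpec(
        names=names,
        class0_means=np.zeros(k),
        class1_means=np.array([shifts[n] for n in names]),
        covariance=cov,
        n_class0=n_class0,
        n_class1=n_class1,
        seed=seed,
        derived=derived,
        null_columns=["s_sf"],
    )


def make_feature_table(
    spec: SyntheticSpec,
    contaminate: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a two-class Gaussian descriptor table from a spec.

    Returns (features, labels) indexed by synthetic protein ids.  With
    ``contaminate`` > 0, that many gross outliers are injected: their label
    is flipped and their features are pushed to +/- 6 SD, exercising
    influence-based outlier removal.
    """
    rng = np.random.default_rng(spec.seed)
    x0 = rng.multivariate_normal(spec.class0_means, spec.covariance, size=spec.n_class0)
    x1 = rng.multivariate_normal(spec.class1_means, spec.covariance, size=spec.n_class1)
    x = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(spec.n_class0, int), np.ones(spec.n_class1, int)])
    df = pd.DataFrame(x, columns=spec.names)
    for name, (coefs, noise_sd) in spec.derived.items():
        col = sum(c * df[src] for src, c in coefs.items())
        df[name] = col + noise_sd * rng.standard_normal(len(df))
    for name in spec.null_columns:
        df[name] = rng.standard_normal(len(df))
    ids = [f"SYN{i:04d}" for i in range(len(df))]
    df.index = pd.Index(ids, name="id")
    labels = pd.Series(y, index=df.index, name="label")
    if contaminate:
        pick = rng.choice(len(df), size=contaminate, replace=False)
        sd = df.std(ddof=0)
        for j in pick:
            labels.iloc[j] = 1 - labels.iloc[j]
            sign = np.where(labels.iloc[j] == 1, -1.0, 1.0)
            df.iloc[j] = df.mean() + 6.0 * sd * sign * np.sign(
                np.asarray(list(DESCRIPTOR_SHIFTS.get(c, 1.0) for c in df.columns))
            )
    return df, labels
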