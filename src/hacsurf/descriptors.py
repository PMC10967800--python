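"""The ten surface descriptors plus net surface charge.

Per structure the pipeline computes, at a 1.4 A water probe:

==============  =============================================================
s_phobic_avg    mean Eisenberg consensus hydrophobicity over surface residues
s_pos_area      fraction of SAS contributed by Lys/Arg
s_neg_area      fraction of SAS contributed by Asp/Glu
s_charge_avg    s_pos_area + s_neg_area
s_ah/s_bs/s_do  surface proportions of helix / beta structure / loop
s_sf            surface exposure degree, total SAS / vdW volume (1/A)
norm_s_b        mean normalized pseudo-B-factor over confident surface residues
fd              fractal-dimension roughness from the SES probe sweep
==============  =============================================================

The pseudo-B-factor chain converts AlphaFold pLDDT (0-100) to an estimated
positional error Delta = 1.5 exp[4 (0.5 - pLDDT/100)] (Angstrom), then to a
Debye-Waller-style B = 8 pi^2 Delta^2 / 3 (Angstrom^2); B values are
z-normalized over the whole structure and averaged over surface residues
whose Delta <= 1.5 A (equivalently B <= 6 pi^2 ~ 59.2, the "B <= 60" rule).
Net surface charge sums fractional Henderson-Hasselbalch protonation-state
charges of ionizable surface side chains at a given pH.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .secondary import assign_secondary_structure, ss_proportions
from .structure import ProteinStructure, passes_inclusion_filters
from .surface import (
    DEFAULT_FD_RADII,
    SasaResult,
    SurfaceMask,
    classify_surface_residues,
    fractal_dimension,
    protein_volume,
    shrake_rupley_sasa,
    surface_exposure_degree,
)
from .tables import (
    NEGATIVE_RESIDUES,
    POSITIVE_RESIDUES,
    hydrophobicity_scale,
    sidechain_pka_table,
)

__all__ = [
    "DescriptorVector",
    "plddt_to_rmsd",
    "rmsd_to_b",
    "normalized_surface_b",
    "avg_surface_hydrophobicity",
    "charged_area_fractions",
    "net_surface_charge",
    "compute_descriptor_vector",
    "build_feature_table",
    "RMSD_INCLUSION_CUTOFF",
]

logger = logging.getLogger(__name__)

#: Surface B-factors are averaged only over residues whose estimated
#: positional error is at most this (Angstrom); equals B <= 6 pi^2 ~ 59.2.
RMSD_INCLUSION_CUTOFF = 1.5


def plddt_to_rmsd(plddt):
    """Estimated positional error Delta (A) from pLDDT (0-100).

    Delta = 1.5 * exp(4 * (0.5 - pLDDT/100)); strictly decreasing, with
    Delta = 1.5 exactly at pLDDT 50.
    """
    p = np.asarray(plddt, dtype=float)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("pLDDT must lie in [0, 100]")
    out = 1.5 * np.exp(4.0 * (0.5 - p / 100.0))
    return float(out) if np.isscalar(plddt) else out


def rmsd_to_b(delta):
    """Pseudo-B-factor (A^2) from positional error: B = 8 pi^2 Delta^2 / 3."""
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("delta must be non-negative")
    out = 8.0 * np.pi**2 * d**2 / 3.0
    return float(out) if np.isscalar(delta) else out


def normalized_surface_b(
    s: ProteinStructure,
    mask: SurfaceMask,
    rmsd_cutoff: float = RMSD_INCLUSION_CUTOFF,
) -> float:
    """Mean normalized pseudo-B-factor over confident surface residues.

    B is z-scored with the mean and population standard deviation over ALL
    residues of the structure; the average is then taken over surface
    residues with Delta <= ``rmsd_cutoff``.  Returns NaN (with a warning)
    when no surface residue passes the filter; returns 0 when every residue
    shares one pLDDT (zero variance).
    """
    delta = plddt_to_rmsd(s.plddt_values())
    b = rmsd_to_b(delta)
    sigma = float(b.std(ddof=0))
    if sigma == 0.0:
        warnings.warn("all pLDDT equal; normalized B-factors set to 0", stacklevel=2)
        b_norm = np.zeros_like(b)
    else:
        b_norm = (b - b.mean()) / sigma
    included = mask.surface_flag & (delta <= rmsd_cutoff)
    if not included.any():
        warnings.warn("no confident surface residue; norm_s_b undefined", stacklevel=2)
        return float("nan")
    return float(b_norm[included].mean())


def avg_surface_hydrophobicity(
    s: ProteinStructure,
    mask: SurfaceMask,
    scale: dict[str, float] | None = None,
    sasa: SasaResult | None = None,
) -> float:
    """Unweighted mean hydrophobicity of surface residues.

    Uses the Eisenberg normalized consensus scale by default; passing
    ``sasa`` switches to a SASA-weighted mean.  Nonstandard residues are
    skipped; an empty surface yields NaN with a warning.
    """
    sc = hydrophobicity_scale() if scale is None else scale
    vals, weights = [], []
    for i, res in enumerate(s.residues):
        if mask.surface_flag[i] and res.name in sc:
            vals.append(sc[res.name])
            weights.append(sasa.per_residue_area[i] if sasa is not None else 1.0)
    if not vals:
        warnings.warn("no standard surface residues; hydrophobicity undefined", stacklevel=2)
        return float("nan")
    return float(np.average(vals, weights=weights))


def charged_area_fractions(
    sasa: SasaResult, s: ProteinStructure
) -> tuple[float, float, float]:
    """(s_pos_area, s_neg_area, s_charge_avg): charged fractions of the SAS.

    At physiological pH the negative set is Asp/Glu and the positive set
    Lys/Arg (His, pKa ~ 6, is mostly neutral and excluded).  Fractions are
    of the total SAS over standard residues.
    """
    total = pos = neg = 0.0
    for i, res in enumerate(s.residues):
        if not res.is_standard:
            continue
        a = sasa.per_residue_area[i]
        total += a
        if res.name in POSITIVE_RESIDUES:
            pos += a
        elif res.name in NEGATIVE_RESIDUES:
            neg += a
    if total <= 0:
        raise ValueError("total SAS is zero")
    return pos / total, neg / total, (pos + neg) / total


def net_surface_charge(
    s: ProteinStructure,
    mask: SurfaceMask,
    pH: float = 7.0,
    pka_table: dict[str, tuple[float, int]] | None = None,
) -> float:
    """Net charge (elementary charges) of ionizable surface side chains.

    Henderson-Hasselbalch fractional charges: a basic group contributes
    +1 / (1 + 10^(pH - pKa)), an acidic group -1 / (1 + 10^(pKa - pH)).
    Chain termini are excluded.
    """
    table = sidechain_pka_table() if pka_table is None else pka_table
    ionizable = {"ASP", "GLU", "CYS", "TYR", "LYS", "ARG", "HIS"}
    net = 0.0
    for i, res in enumerate(s.residues):
        if not mask.surface_flag[i] or res.name not in ionizable:
            continue
        if res.name not in table:
            raise KeyError(f"no pKa for ionizable residue {res.name}")
        pka, sign = table[res.name]
        if sign > 0:
            net += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            net -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return net


@dataclass
class DescriptorVector:
    """The ten surface descriptors plus net surface charge for one protein."""

    id: str
    s_phobic_avg: float
    s_pos_area: float
    s_neg_area: float
    s_charge_avg: float
    s_ah: float
    s_bs: float
    s_do: float
    s_sf: float
    norm_s_b: float
    fd: float
    net_surface_charge: float
    label: int | None = None

    DESCRIPTOR_NAMES = (
        "s_phobic_avg", "s_pos_area", "s_neg_area", "s_charge_avg",
        "s_ah", "s_bs", "s_do", "s_sf", "norm_s_b", "fd",
    )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "id"}

    def is_complete(self) -> bool:
        return not any(np.isnan(getattr(self, n)) for n in self.DESCRIPTOR_NAMES)


def compute_descriptor_vector(
    s: ProteinStructure,
    *,
    probe_radius: float = 1.4,
    surface_threshold: float = 0.30,
    fd_radii: np.ndarray | None = None,
    voxel: float = 0.5,
    n_sphere_points: int = 960,
    pH: float = 7.0,
    enforce_filters: bool = True,
) -> DescriptorVector:
    """Compute all descriptors for one structure.

    SAS-based descriptors use the given water probe; roughness uses the SES
    probe sweep (1.0-3.6 A by default).  With ``enforce_filters`` the
    structure must pass the dataset inclusion filters first.
    """
    if enforce_filters:
        ok, reasons = passes_inclusion_filters(s)
        if not ok:
            raise ValueError(f"structure {s.id} fails inclusion filters: {reasons}")
    sasa = shrake_rupley_sasa(s, probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    mask = classify_surface_residues(s, sasa, threshold=surface_threshold)
    ss = assign_secondary_structure(s)
    h, e, l = ss_proportions(ss, mask, "surface")
    pos, neg, tot = charged_area_fractions(sasa, s)
    volume = protein_volume(s, voxel=voxel)
    profile = fractal_dimension(s, radii=DEFAULT_FD_RADII if fd_radii is None else fd_radii, voxel=voxel)
    return DescriptorVector(
        id=s.id,
        s_phobic_avg=avg_surface_hydrophobicity(s, mask),
        s_pos_area=pos,
        s_neg_area=neg,
        s_charge_avg=tot,
        s_ah=h,
        s_bs=e,
        s_do=l,
        s_sf=surface_exposure_degree(sasa.total, volume),
        norm_s_b=normalized_surface_b(s, mask),
        fd=profile.fd,
        net_surface_charge=net_surface_charge(s, mask, pH=pH),
        label=s.label,
    )


def build_feature_table(
    structures: list[ProteinStructure],
    labels: dict[str, int] | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Descriptor table (one row per protein) plus an exclusion log.

    Structures failing the inclusion filters or yielding any undefined
    descriptor are excluded with a logged reason.  Rows are ordered by
    protein id so rebuilding from the same inputs is bit-identical.
    """
    rows, excluded = [], {}
    for s in sorted(structures, key=lambda x: x.id):
        if labels is not None and s.label is None:
            s.label = labels.get(s.id)
        ok, reasons = passes_inclusion_filters(s)
        if not ok:
            excluded[s.id] = "; ".join(reasons)
            logger.info("excluded %s: %s", s.id, excluded[s.id])
            continue
        vec = compute_descriptor_vector(s, enforce_filters=False, **kwargs)
        if not vec.is_complete():
            excluded[s.id] = "undefined descriptor"
            logger.info("excluded %s: undefined descriptor", s.id)
            continue
        rows.append({"id": s.id, **vec.as_dict()})
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("id")
    return df, excluded
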