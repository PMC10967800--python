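# Methods

`hacsurf` quantifies what the *surface* of a protein looks like to its
environment — how hydrophobic, how charged, how structured, how flexible and
how rough it is — and uses those quantities to separate highly abundant
cytoplasmic (HAC) proteins from extracellular ones with interpretable
statistics. This note records the models, the numerical choices, and what
the synthetic generators do and do not emulate.

## Input model

Structures are single-model, single-chain PDB files in the AlphaFold dialect:
the B-factor column stores the per-residue predicted local distance
difference test (pLDDT, 0–100). Residue pLDDT is read from the CA atom;
out-of-range values are clamped with a warning. Hydrogens are kept in the
data model but excluded from every surface computation (AlphaFold models are
heavy-atom). HETATM content is ignored. Dataset inclusion requires a
modelled length of 100–700 residues and mean pLDDT strictly above 50;
"sequence length" is the modelled residue count, which coincides with
sequence length for full-length predicted models.

## Surfaces

Two surface definitions drive the descriptors:

* **Solvent-accessible surface (SAS)** — traced by the centre of a 1.4 Å
  water probe rolling over van der Waals spheres (Bondi radii: C 1.70,
  N 1.55, O 1.52, S 1.80 Å). Computed by the Shrake–Rupley method with a
  deterministic golden-spiral lattice of 960 test points per atom. The
  lattice is anchored to a molecule-fixed frame (principal axes of the atom
  cloud, eigenvector signs fixed by the farthest-atom direction), so areas
  are invariant under rigid motions up to floating point rather than only to
  lattice resolution. For clouds with degenerate principal axes the
  laboratory frame is used. Isolated-sphere areas are exact by construction;
  an overlapping pair agrees with a 10⁵-point Monte-Carlo rejection oracle
  to ≈0.03%.

* **Solvent-excluded (Connolly) surface (SES)** — the SAS displaced inward
  by the probe radius; equivalently the boundary of the morphological
  closing of the vdW volume by the probe ball. Estimated on a voxel grid
  (default 0.5 Å): the signed field min_i(|x−cᵢ|−rᵢ) defines the SAS volume;
  a Euclidean distance transform gives each interior voxel's distance to the
  solvent; a narrow band around the target level set is refined by
  minimizing |x−w|−(f(w)−probe) over candidate solvent voxels w, which is
  tight because f(w)−probe is the exact distance from an outside point to a
  union of spheres; the SES is extracted by marching cubes at the
  probe-radius level. Accuracy against closed forms: single sphere −2% at
  voxel 0.5, −0.3% at 0.25; fused pair vs the analytic Connolly area
  (spherical caps + torus seam) −1.2% at 0.5, −0.1% at 0.25. The estimate
  converges as the voxel shrinks; voxel must not exceed the probe radius.

**Surface residues.** A residue is "surface" when its SAS is ≥30% of its
maximal SAS in an extended Gly-X-Gly tripeptide. The denominators are the
published theoretical maxima (Tien et al. 2013), shipped as a data file; a
`computed` mode builds the tripeptide with ideal backbone geometry and
measures it directly, but with CB-only pseudo-side-chains it underestimates
bulky residues and is used only as a cross-check for small ones.
Nonstandard residues have no reference and are flagged buried with a
warning; they are kept for geometry but excluded from residue-keyed
descriptors and SAS-fraction denominators.

## Descriptors

Ten per-protein descriptors (plus one reporting quantity):

| name | meaning | notes |
|---|---|---|
| `s_phobic_avg` | mean Eisenberg normalized-consensus hydrophobicity of surface residues | residue-count weighted; a SASA-weighted variant is available |
| `s_pos_area`, `s_neg_area` | fractions of total SAS from Lys/Arg and Asp/Glu | His excluded (pKa≈6, mostly neutral at pH 7); whole-residue SAS |
| `s_charge_avg` | their sum | |
| `s_ah`, `s_bs`, `s_do` | surface proportions of helix / beta structure / loop | sum to 1 on a non-empty surface |
| `s_sf` | exposure degree = total SAS / vdW-envelope volume (Å⁻¹) | volume from voxel counting |
| `norm_s_b` | mean normalized pseudo-B-factor of confident surface residues | below |
| `fd` | fractal-dimension roughness | below |
| `net_surface_charge` | Henderson–Hasselbalch net charge of surface side chains | reported, not a modelling feature |

**Pseudo-B-factors.** pLDDT converts to an estimated positional error
Δ = 1.5·exp[4(0.5 − pLDDT/100)] Å and then to a Debye–Waller-style
B = 8π²Δ²/3 Å². The map is strictly decreasing in confidence and sends the
pLDDT = 50 threshold exactly to Δ = 1.5 Å, i.e. B = 6π² ≈ 59.2 (the
conventional "B ≤ 60"). B is z-scored with the mean and *population* SD over
all residues of the structure (the whole-structure normalization); the
descriptor is the mean z-score over surface residues with Δ ≤ 1.5. All-equal
pLDDT yields 0 by convention; no confident surface residue yields an
undefined descriptor and the protein is excluded with a logged reason.

**Roughness.** FD = 2 − d(log A_ses)/d(log R), evaluated by finite
differences of base-10 logarithms over the inclusive probe sweep
1.0–3.6 Å in steps of 0.2 (14 areas, 13 differences, first pair (1.0, 1.2));
FD is their arithmetic mean. The log base cancels in the ratio. A smooth
sphere gives FD = 2 (measured 2.007 at voxel 0.5); physically meaningful
values lie in [2, 3].

**Net charge.** Fractional protonation-state charges at pH 7:
+1/(1+10^(pH−pKa)) for basic groups, −1/(1+10^(pKa−pH)) for acidic ones,
over surface residues only, termini excluded; side-chain pKa set
D 3.65, E 4.25, C 8.5, Y 10.07, K 10.53, R 12.5, H 6.0.

## Secondary structure

A simplified Kabsch–Sander assignment over three buckets. Amide hydrogens
are rebuilt from the preceding carbonyl direction; H-bonds are scored with
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol and assigned when
E < −0.5. Runs of ≥2 consecutive n→n+4 turns give H (3₁₀ and π turns are
folded into H); parallel/antiparallel bridge patterns give E; everything
else is L. "Disordered region" is operationalized as the loop label L; a
configuration switch to low-pLDDT segments is deliberately *not* asserted as
the original intent. Residues with incomplete backbones are L with a
warning. The assignment is geometry-only and rigid-motion invariant; it does
not reproduce any particular viewer's assignment bit-exactly.

## Statistics

**Screening.** Each descriptor's point-biserial correlation with the 0/1
label (Pearson r, t-test with n−2 df) must be significant at α = 0.05.
Within each descriptor category, while any pair has |r| ≥ 0.8 (a
conventional cut; the source analysis states only "highly correlated"), the
member with the largest mean absolute within-category correlation is
dropped; ties break by name. Constant columns drop with a warning.

**Outliers.** An unpenalized logistic fit on the z-scored table supplies
Cook's distances and internally studentized Pearson residuals (statsmodels
influence measures). Observations with D > 4/n *and* |residual| > 2 — highly
influential and outlying simultaneously — are removed, in a single pass.

**Inference vs prediction.** Two distinct logistic fits: unpenalized MLE
(statsmodels GLM/Binomial, IRLS to 1e-8) for Wald inference — SE from the
inverse Fisher information, odds ratio exp(β), 95% CI exp(β±1.96·SE); and a
cross-validated, optionally L2-regularized fit inside the model comparison.
Complete separation is detected (saturated fitted probabilities or diverging
coefficients) and raised as an error for inference; the CLI then skips the
inference table rather than failing the run. Across repeated splits the
report averages β and Wald SE over splits and also reports the across-split
SD of β, since the published convention is ambiguous between the two.

**Model comparison.** Per repeat (default seeds 0–4): stratified 80/20
split, scaler fit on the training portion only, per-algorithm grid search
(KNN k∈{3..15}; RF trees∈{100,300}, depth∈{None,5,10}; RBF-SVM
C∈{0.1,1,10}, γ∈{scale,0.01,0.1}; LR C∈{0.01,0.1,1,10}) by 5-fold CV
accuracy, refit on the full training set, then accuracy and trapezoidal
ROC-AUC on the held-out fifth.

## Synthetic data

The generators replace the AlphaFold-downloaded dataset:

* **Geometric fixtures** — ideal helices (φ=−57°, ψ=−47°), extended-strand
  antiparallel hairpins (rigid-docked by minimizing inter-strand H-bond
  energy), random coils and bare sphere clusters, built by
  natural-extension-reference-frame placement with Engh–Huber-style bond
  geometry and CB pseudo-side-chains. They have exactly known geometry and
  assignable pLDDT, so every descriptor has an oracle; they are *not*
  physically realistic proteins — no rotamers, no packing, no compact core —
  so surface/buried contrasts and absolute descriptor values do not emulate
  globular statistics, only the defined math.
* **Feature tables** — class-conditional Gaussians over the seven screened
  descriptors. Default class-1 mean shifts invert the balanced-design
  point-biserial relation d = 2r/√(1−r²) from the observed
  descriptor-vs-label correlations (positive for both charged-area
  fractions, negative for the rest), with the study's class sizes 331/337.
  The charged pair is correlated at r = 0.4, making the derived total-charge
  column collinear with its category (|r|≈0.84); the helix proportion loads
  (−1.2, −0.5) on (beta, loop), making it the most collinear structure
  descriptor (|r|≈0.92) while keeping beta and loop conditionally
  identifiable; a null exposure-degree column has equal class means. This
  reproduces the observed screening outcome (three drops) and the two
  positive / five negative coefficient-sign pattern. Passing tests on these
  tables demonstrates the pipeline's statistical behaviour under the
  designed signal, not the real proteome's effect sizes.

## Problem sizes and numerical choices in the test suite

Statistical pattern tests (screening outcome, sign recovery) run at
n = 2000/class: the weakest designed signal (|r| ≈ 0.10, so |β| ≈ 0.2,
SE ≈ 0.1 at the study's n = 668) sits near 2 SE at study scale, where the
all-seven-signs event and p < 0.05 significance are intrinsically
borderline; consistency of the estimator is the property asserted, so it is
tested in the consistent regime. Orchestration (CLI) tests use voxel 0.8 Å
and 2 split repeats with 3-fold CV on ~100-residue fixtures; accuracy
claims always use voxel ≤ 0.5 on small closed-form fixtures. The Gaussian
Bayes-accuracy check uses d = 1.683 (Bayes accuracy Φ(d/2) ≈ 0.80) at
n = 5000 with compact grids.

## Known limitations

* SES accuracy degrades near deep creases where the narrow-band bound is
  not tight; the default 0.5 Å voxel carries ≈1–2% area error.
* The computed Gly-X-Gly mode underestimates bulky side chains (CB-only).
* Secondary structure is a three-bucket simplification; bridge detection
  uses rebuilt hydrogens and inherits their idealization.
* Henderson–Hasselbalch charges ignore termini, coupling between sites and
  local environment shifts.
* Multimeric assemblies, mmCIF input and NMR multi-model files are out of
  scope; only the first model of a multi-model file is read.
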