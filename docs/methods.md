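# Methods

This note documents the models, estimators, numerical choices, and the
scope of the synthetic-data generators. It states how each quantity is
computed; every number quoted here is produced by the test suite or the
analysis drivers at run time.

## Gaussian shape and color scoring

Each heavy atom contributes a spherical Gaussian p·exp(−α r²) with
amplitude p = 2.7 and width α fixed so the Gaussian integrates to the
atom's van der Waals sphere volume, α = π (3p / 4πr³)^(2/3). By default
all heavy atoms share one radius of 1.70 Å ("radii off" mode, exposed as a
parameter); hydrogens never contribute to shape. The overlap volume of two
molecules is the first-order (pairwise) sum of Gaussian product integrals

V_AB = Σ_ij p² (π/(α_i+α_j))^{3/2} exp(−α_i α_j d_ij²/(α_i+α_j)),

with pairs truncated once their contribution falls below 1e-12 of peak.
Self-overlaps V_AA use the same formula, so the shape Tanimoto
V_AB/(V_AA+V_BB−V_AB) is exactly 1 for a molecule overlaid on itself,
which in turn pins the self-combo at 2 for any featured molecule. Color
scoring applies the identical machinery to pharmacophore points (default
radius 1.0 Å), restricted to same-kind pairs; when either feature set is
empty the color Tanimoto is 0 by convention, so a featureless molecule has
self-similarity 1, not 2.

Pharmacophore typing is data-driven (`data/color_features.yaml`): SMARTS
patterns for donors/acceptors (anchored on the heteroatom) and for ionic
groups (placed at the matched-group centroid, claiming their atoms so a
carboxylate is one anion rather than an anion plus two acceptors), SSSR
centroids for rings, and connected carbon clusters with no heteroatom
neighbor (minimum size 2, centroid-placed) for hydrophobes. Ionization
reflects pH 7.4. Explicit hydrogens are required; implicit-H input is
rejected rather than silently miscounting donors. No parity with any
proprietary feature assigner is claimed.

Overlay optimization seeds Nelder–Mead refinement of the 6-dof rigid pose
(rotation vector + translation, objective = combo) from the inertial-frame
alignment of query to reference, its three 180° axis flips, the raw
identity pose, and (n_starts − 5) seeded random rotations; the returned
score is never below any unrefined start, and ties break by shape
Tanimoto, then molecule id at the library level. On ≤5-atom toys the
optimizer agrees with an exhaustive 10°-rotation × 0.1 Å-translation grid
search to better than 0.01 combo (test suite); n_starts = 16 keeps a
~20-heavy-atom overlay under a second.

## Assay estimators

All nonlinear fits are unweighted least squares (`scipy.optimize.curve_fit`)
with data-driven initialization; standard errors are square roots of the
Jacobian-covariance diagonal at the optimum.

**Dose–response.** y = bottom + (top−bottom)/(1 + (x/IC50)^h), fitted in
log10 concentration with top, bottom, h free (h < 0 solutions are folded
into the equivalent h > 0 parameterization). Responses are normalized to
the vehicle-control mean beforehand. IC50s outside the tested range are
flagged extrapolated, and compounds with IC50 > 1000 µM or extrapolated
fits are classified inactive. Constant responses raise an error rather
than fitting.

**MST binding.** The exact quadratic 1:1 isotherm at known labeled-target
concentration T (nM, converted to µM internally):
fb = ((L+T+K) − √((L+T+K)² − 4LT))/2T, Fnorm = f_free + (f_bound−f_free)·fb.
K is fitted in log space with generous bounds; a fit pinned at its bounds
is flagged. As T → 0 the isotherm approaches the hyperbola L/(L+K) with a
leading deviation of order T/K (so ~1e-4 at T = K/1000 — the limit is
asymptotic, not exact at finite T).

**Melting temperature.** The F350/F330 ratio is formed pointwise (hence
invariant to any common rescaling of both channels), smoothed with a
Savitzky–Golay filter (window 11 points, order 3) and differentiated with
the same filter; the derivative extremum (either sign) flags the
transition and its location. Sub-grid localization then fits
baseline + slope·T + A·logistic((T−Tm)/w) to the ratio and reports the
fitted Tm, which is exactly the derivative extremum of that model. A pure
pointwise-derivative localization was rejected on precision grounds:
differentiation amplifies channel noise so strongly that even whole-peak
fitting of the derivative carries ~0.3 °C scatter at 0.5% channel noise,
while the ratio-curve fit achieves ~0.06 °C, as the recovery suite
measures. A 3-point parabolic fallback covers degenerate peaks; fits with
insignificant amplitude (< 5 residual SDs) or out-of-range midpoints raise
"no transition detected". ΔTm is the signed difference complex − apo.

**STD epitope mapping.** Per proton, effect = I_sat/I_0 (the package's
literal convention) or (I_0−I_sat)/I_0 (`convention="difference"`, the more
common literature definition — both ship because usage varies); relative
values are 100·effect/effect(reference), reference either the largest
effect or a named proton, in which case values above 100% are legitimate.

**pKa.** δ(pH) = δ_base + (δ_acid−δ_base)/(1 + 10^(pH−pKa)) per reporter
proton. Flat series and fits whose midpoint leaves the titrated range are
errors. The estimate is direction-invariant (rising or falling curves).
The protonated fraction at pH is 1/(1+10^(pH−pKa)).

## Epitope detection

Contacts use strict < cutoff (default 4.0 Å) between ligand and protein
heavy atoms (cKDTree candidate search, exact distance confirmation; the
test suite checks exact agreement with an all-pairs loop). A frame is
bound when its fingerprint covers ≥ 5 distinct residues. Bound-frame
fingerprints, encoded as binary residue vectors, are clustered by
average-linkage agglomeration on Jaccard distances with a distance cut of
0.7; these three settings are exposed in config since the field's practice
varies. Occupancy is the percentage of all trajectory frames in a cluster
(fractions of simulation time; a bound-only denominator is available), and
per-residue contact frequencies plus user-designated hot-spot flags are
reported per epitope.

Density grids superpose each bound frame's protein Cα atoms onto a
reference (first frame by default) by quaternion-based least squares,
apply the fit to the ligand atoms, and count atoms in cubic voxels
(default 1 Å). Internal protein symmetry is handled by explicit rigid
operators: each point is replaced by its canonical image — the
lexicographically smallest coordinate tuple over the operator group
(identity always included) — so each atom counts exactly once and the
total equals bound frames × ligand heavy atoms under any folding.
Superposed coordinates are snapped at 1e-6 Å before binning so
voxel-corner points bin stably. Grids are written in OpenDX text format.
Fingerprints can be canonicalized across symmetric chains by an explicit
chain map before clustering.

## Permeability

1/P_eff = ∫ exp(ΔG(z)/k_BT)/D(z) dz with trapezoidal quadrature, z
converted from Å to cm; ΔG in kcal/mol (k_B = 0.0019872 kcal/mol/K,
default T = 300 K), D constant 1e-5 cm²/s by default or a per-grid-point
profile. Profiles must return to ~0 (|ΔG| ≤ 0.5 kcal/mol) at both ends —
the water-phase reference — and integration bounds default to the z-range
where |ΔG| > 0.1 kcal/mol. The constant-D choice biases the raw integral,
which is exactly why reported values pass through the PAMPA calibration:
an OLS map on the log10 scale fitted to reference pairs. The shipped
default calibration is reconstructed from the five published
lead-compound pairs (the original nine-compound reference set lives in
supplementary material that is not machine-readable); its slope 0.270 and
intercept −5.306 reproduce each published PAMPA-scale value to ≤ 0.006 log
units. Classification bands: high > 4.7e-6 cm/s;
low-to-medium 7e-7–2.1e-6 cm/s (inclusive); the open interval between is
reported as medium_high_gap; below 7e-7 is low. Input uncertainties on
log P_eff/PMF propagate through the linear map as |slope|·se.

## Synthetic-data generators

All generators draw from a single `numpy.random.default_rng(seed)` stream,
write byte-identical outputs under a fixed seed, and record their planted
truths in a JSON manifest; round-trip tests read truths only from
manifests. Defaults encode the study designs: 8 log-spaced concentrations
on [1, 450] µM in triplicate (dose–response); 16-point 1:1 serial dilution
from 1 mM with 100 nM labeled target, in triplicate (MST); 20–95 °C at
0.5 °C steps read out as F350/F330 (melting); pH 2–13 in 0.5 steps
(titration); 1000-frame trajectories with planted epitope fractions
13.2%/10.1% (diffusion); nine-pair calibration sets.

Noise models are deliberately simple: additive Gaussian on responses,
multiplicative per fluorescence channel, additive on chemical shifts.
The melting generator writes F330 as a constant-level channel and
F350 = F330 × ratio(T) with ratio = linear baseline + logistic transition;
an additive linear baseline does not move the logistic-derivative
extremum, so the planted Tm is exactly the true Tm of the curve. The
`width` parameter is the FWHM of the first-derivative peak (the span the
transition visibly occupies, default 2 °C), not the logistic scale.

The mock protein is a parametric four-helix bundle (Cα plus one pseudo
side-chain atom per residue, four chains arranged with exact rotational
symmetry so a C2 operator maps chains A/B onto C/D) — adequate for contact
geometry and superposition, nothing more. Bound frames park one ligand
atom ~1 Å outside each planted residue's side-chain atom with rigid-body
jitter; unbound frames place the ligand ≥ 25 Å away. The generator
verifies its own construction frame by frame (every bound frame contacts
≥ 5 residues including the full planted set, epitopes never bleed into
each other, unbound frames contact < 5) and the protein is rigid across
frames. What passing tests therefore show is that the *analysis* machinery
is correct on data satisfying its assumptions; they do not show robustness
to conformational flexibility, overlapping or diffuse binding sites,
correlated instrument drift, baseline curvature, or non-Gaussian noise —
real data can and do violate all of these.

## Numerical and design choices

- Seeds are explicit everywhere; per-molecule screening seeds derive from
  the base seed plus library index, and pipeline stages draw child seeds
  from a `SeedSequence` so stages are independently reproducible.
- The library screen reports feature-assignment failures per molecule and
  skips them; it never drops molecules silently.
- Degenerate inputs fail loudly: empty molecules, non-finite coordinates,
  bondless molecules at feature typing, < 3-atom or rank-deficient
  superpositions, flat titrations, profiles not referenced to water.
- `run_pipeline` validates configs against the full default tree and
  rejects unknown keys by their dotted path; summaries exclude wall times
  (those go to the log) so reruns are byte-identical under a fixed seed.
- Tm recovery at the default design measures ~0.06 °C scatter (sd) per
  curve; IC50 ~7.6% and K_D ~3.5% relative scatter at their default noise
  levels; pKa ~0.027 — in each case the fit-reported standard errors match
  the observed scatter, i.e. the estimators sit at their information
  limits on well-specified data.

## Known limitations

- Shape scoring is first-order Gaussian overlap; higher-order intersection
  corrections and conformer ensembles (the screening upstream of this
  package) are out of scope, so absolute scores are not comparable to
  proprietary implementations — rankings on rigid molecules are.
- The epitope clustering defaults (Jaccard/average/0.7) are declared, not
  derived; different cuts merge or split diffuse epitopes.
- Permeability assumes a constant diffusivity unless a D(z) profile is
  supplied, and the shipped calibration rests on five published pairs.
- The pKa model is single-site; multi-site titrations need per-site fits
  on separated reporter protons.
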