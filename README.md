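# leadscope

A tested, reusable pipeline for the computational side of a small-molecule
lead-finding campaign against a protein–protein interaction target: the
NHR2 tetramerization domain of the RUNX1/ETO fusion protein that drives
t(8;21) acute myeloid leukemia. Hit finding for this target proceeds by
ligand-based virtual screening from a known inhibitor scaffold, followed by
cell-viability and biophysical validation (nanoDSF, MST, STD NMR, NMR pKa
titration), molecular-dynamics-based binding-epitope detection, and
membrane-permeability prediction. `leadscope` implements every one of
those analysis steps as library code with a CLI and seeded synthetic-data
generators, so the whole workflow runs and is testable end to end with no
external data.

## What it computes

**Shape/pharmacophore screening** (`chemlib`, `shape_screen`). Molecular
shape is a sum of atom-centered first-order Gaussians (Grant–Pickup, each
atom Gaussian integrating to its vdW sphere volume; shared 1.70 Å heavy-atom
radius by default). For molecules A, B under a rigid overlay the shape
Tanimoto is

    ST(A,B) = V_AB / (V_AA + V_BB − V_AB),

and the same Gaussian-overlap Tanimoto over typed pharmacophore points
(donor, acceptor, anion, cation, hydrophobe, ring — SMARTS-driven, rules as
editable YAML) gives the color Tanimoto CT. The **Tanimoto-Combo** score
ST + CT ∈ [0, 2] ranks a library against a template after rigid-overlay
optimization (inertial starts + axis flips + seeded random rotations,
Nelder–Mead refinement of the 6-dof pose on the combo objective), with a
threshold census and a programmatic pharmacophore-anchor check in place of
visual inspection.

**Assay fitting** (`assay_fits`). Dose–response IC50 by a four-parameter
logistic on log concentration with vehicle (DMSO) normalization; apparent
K_D from MST titrations by the exact quadratic 1:1 isotherm
fb = ((L+T+K) − √((L+T+K)² − 4LT))/2T at known labeled-target
concentration; nanoDSF melting temperature as the first-derivative extremum
of the F350/F330 ratio (Savitzky–Golay derivative for detection, two-state
model fit of the ratio for sub-grid localization) and signed ΔTm; per-proton
STD effects I_sat/I_0 normalized to a reference proton; pKa by the
Henderson–Hasselbalch equation δ(pH) = δ_base + (δ_acid−δ_base)/(1+10^(pH−pKa))
with the protonated fraction 1/(1+10^(pH−pKa)). Standard errors come from
the Jacobian covariance at the optimum.

**Epitope detection** (`epitope_mapper`). From free-ligand-diffusion
trajectories (multi-model PDB): per-frame residue contact fingerprints
(heavy-atom distance strictly < 4 Å), a bound-frame filter (≥ 5 distinct
residues), symmetry-aware ligand heavy-atom density grids after per-frame
Cα superposition (OpenDX output), agglomerative clustering of bound-frame
fingerprints (Jaccard distance, average linkage) into binding epitopes, and
occupancies as percent of all trajectory frames with hot-spot residue
flagging (W498/W502-style).

**Permeability** (`permeability`). The inhomogeneous solubility–diffusion
model: 1/P_eff = ∫ exp(ΔG(z)/k_BT)/D(z) dz across the membrane, with ΔG(z)
a PMF referenced to water and D constant (1e-5 cm²/s) by default; computed
log10(P_eff/P_0) values are calibrated to the PAMPA scale by OLS against
reference compounds (the published five lead-compound pairs ship as the
default calibration) and classified into the published bands
(high > 4.7e-6 cm/s; low-to-medium 7e-7–2.1e-6 cm/s).

**Synthetic data** (`synthetic_data`). Seeded, manifest-writing generators
for every input: perturbed analog libraries, 8-point triplicate
dose–response curves on [1, 450] µM, 16-point 1:1 MST dilutions with 100 nM
target, 20–95 °C melting ramps, pH 2–13 titrations in 0.5 steps,
free-ligand-diffusion trajectories with planted contact epitopes around a
parametric four-helix bundle, and parametric PMF profiles plus calibration
sets.

## Worked example

```bash
python analysis/04_predict_membrane_permeability.py
```

prints (abridged):

```
calibration: slope 0.270, intercept -5.306, residual sd 0.005 log10 units (n=5)
compound  log_peff_pmf  log_peff_pampa_printed  log_peff_pampa_fit peff_cm_s         class
     M23          0.56                   -5.16              -5.154  7.01e-06          high
   M23_H         -4.22                   -6.45              -6.447  3.57e-07           low
     M27          0.75                   -5.10              -5.103  7.89e-06          high
   M27_H         -2.95                   -6.10              -6.104  7.87e-07 low_to_medium
     M10          0.83                   -5.08              -5.081  8.29e-06          high
```

Reading: the five printed calibration pairs are internally coherent — the
OLS line reproduces every printed PAMPA-scale log permeability to within
0.02 log units — and exponentiating the calibrated values places the
neutral leads (M23, M27, M10) in the highly permeable band while the
protonated species are low-to-medium (M27_H) or low (M23_H) permeable,
which is the physical rationale for the leads' improved cellular potency.

The other drivers follow the same pattern:
`analysis/01_screen_synthetic_library.py` (a zero-noise analog scores the
combo maximum of 2.000 and scores decay with coordinate noise),
`analysis/02_fit_biophysical_assays.py` (planted IC50 33 → fitted
35.6 ± 3.5 µM; K_D 39 → 40.7 ± 1.8 µM; Tm 74.5 → 74.57 °C; ΔTm −1.6 →
−1.69 °C; pKa 6.69 → 6.733 ± 0.025, protonated fraction 0.146 at pH 7.5),
and `analysis/03_map_binding_epitopes.py` (planted epitope occupancies
13.2%/10.1% recovered exactly from 233 bound frames of 1000).

There is also a single `leadscope` executable wrapping the same library
(`leadscope screen|fit|epitope|perm|simulate|run`); e.g.
`leadscope simulate mst_titration --seed 7 --out sim/ && leadscope fit mst
--in sim/mst_titration.csv --out kd.json`.

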