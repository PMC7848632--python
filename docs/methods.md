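# Methods

## The problem

In neurodegenerative disease, atrophy replaces parenchymal tissue with
CSF-like free water. Conventional single-compartment DTI is biased by this
partial-volume contamination: free water inflates the apparent mean
diffusivity (MD) and deflates the fractional anisotropy (FA), so
"microstructural" abnormalities near atrophic tissue may only reflect
tissue loss. This package implements the dual-compartment alternative and
the voxel-wise group analysis built on it, together with a synthetic
multi-shell cohort generator that has the statistical structure such a
study assumes (a patient group with focal atrophy, diffuse microstructural
change, and a clinical severity score tied to cerebellar tissue loss).

## Signal models

Single compartment (conventional):

    S_i = S0 * exp(-b_i : D)

where `b_i : D` is the full double contraction of volume *i*'s b-matrix
`b_i = bval_i * g_i g_i^T` with the symmetric diffusion tensor D.

Dual compartment:

    S_i = S0 * ( f_par * exp(-b_i : D_par) + (1 - f_par) * exp(-3e-3 * bval_i) )

The free-water compartment is isotropic with fixed diffusivity
3e-3 mm^2/s (free water at 37 C), so the only new parameters are the
parenchymal volume fraction `f_par` (reported as pVF) and the parenchymal
tensor `D_par` (whose FA and MD are reported as pFA and pMD). The
fractions sum to one by construction; `f_CSF` is never stored. Separating
two exponentials requires at least two distinct nonzero shells; the
default acquisition (10 x b0, 10 x b300, 60 x b1100 s/mm^2) satisfies
this, and single-shell schemes are rejected as unidentifiable.

## Fitting

Both models are fit by unweighted nonlinear least squares on magnitude
signals (no Rician likelihood; this is a documented limitation — at the
SNRs simulated here the resulting bias in f_par is below 0.01). The
implementation is a vectorised Levenberg-Marquardt with analytic
Jacobians that fits whole volumes in batches; because b-matrices are
rank one, the tensor exponent and its gradient reduce to `q = b |L^T g|^2`
with L the Cholesky factor of the (scaled) tensor, avoiding per-voxel
matrix products.

Constraints and numerical choices:

- `f_par` is optimised through a logistic transform (always in (0,1));
  `D_par` through its Cholesky factor (always PSD). The diffusivity cap —
  each eigenvalue of D_par at most 3e-3 mm^2/s, i.e. the parenchymal
  compartment is slower than free water in every direction — is enforced
  by spectral clipping of the final estimate; at the tissue diffusivities
  simulated here the cap is inactive during optimisation.
- The dual fit is multi-modal near the f_par = 1 boundary, so it is
  multi-started from f_par in {0.5, 0.7, 0.9, 1.0}, with the tensor
  initialised from the log-linear (OLS on log signals) single-compartment
  fit and S0 from the b0 mean. Best residual sum of squares wins; ties go
  to the larger f_par (the parsimonious near-single-compartment solution).
- A pure free-water voxel makes f_par unidentifiable (D_par -> D_CSF fits
  any fraction exactly), so the f_par = 0 boundary — where the model is
  linear in S0 — is evaluated explicitly and accepted whenever it fits as
  well as the interior optimum. Such voxels report f_par = 0 with a zero
  tensor (FA of the zero tensor is defined as 0).
- Signals are floored at 1e-6 of the per-voxel b0 mean before the
  log-linear initialiser; voxels where no start converges fall back to
  the log-linear estimate with f_par = 1 and are flagged in the QC map,
  never silently imputed.

Internally diffusivities are scaled to um^2/ms and b-values to ms/um^2 so
the optimiser works on O(1) quantities; the public API uses mm^2/s and
s/mm^2 throughout.

## Morphometry

Atrophy is quantified from each subject's displacement field u(x) (voxel
units) defining the forward subject-to-template map phi(x) = x + u(x).
The log of the Jacobian determinant of phi (central differences in the
interior, one-sided at the boundary; no smoothing) is the logJ map;
logJ < 0 means the subject is locally smaller than the template. The
forward-map convention was chosen so that this reading matches the
interpretation of lower logJ as local tissue loss; warp estimation itself
(tensor registration) is out of scope — synthetic subjects share one grid
and warps are generator outputs.

## Voxel-wise inference

Group comparisons are OLS GLMs per voxel (intercept, group indicator with
patients = 1, age; plus TICV for logJ), with the t-statistic of the group
contrast signed patient-minus-control. Spatial inference uses TFCE with
the method's published defaults (E = 0.5, H = 2, 100 integration steps,
26-connectivity), enhancing the positive and negative directions
separately; FWE control at alpha = 0.05 comes from the permutation
distribution of the maximum TFCE score over the analysis mask, with
nuisance covariates handled by Freedman-Lane (permute nuisance-model
residuals, add back the nuisance fit, re-estimate). P-values are
`(1 + #{perm max >= observed}) / (n_perm + 1)`, floored at 1/(n_perm+1);
the two one-sided tests are each controlled at the nominal level on
their own. Hedge's g maps use the pooled s.d. and the small-sample
correction J = 1 - 3/(4(n1+n2) - 9); zero-variance voxels report g = 0.

Anisotropy metrics (FA, pFA) are analysed only in white matter, defined
as template voxels with FA strictly greater than 0.2 (the template being
the mean FA over control fits); all other metrics use the whole-brain
(all-tissue) mask. Per-ROI tables report Qvoxels (significant voxels /
ROI voxels inside the analysis mask — the denominator matches the mask in
which peaks are defined), with signed peak t and peak g taken over the
whole in-mask ROI (first voxel in scan order on ties); the main table
lists ROIs with Qvoxels >= 0.1 (inclusive), the full table everything.

## Clinical correlation

In patients, each metric (pMD, pFA, pVF, logJ) averaged over brainstem,
cerebellum, and cerebrum (pFA over the WM portion only) is correlated
with the SARA ataxia score by Pearson's r with the two-sided slope-test
p-value. The 12 tests plus the optional post-hoc whole-brain pFA test
form a single Benjamini-Hochberg FDR family of 13, with the family size
recorded in the output; the whole-brain region is the union of the three
anatomical regions. A sensitivity mode repeats the analysis including
asymptomatic (score-zero) patients instead of excluding them.

## The synthetic cohort

The phantom is schematic, not anatomical; each region exists so that a
specific contrast has a dedicated compartment: an ellipsoidal cerebrum
(GM shell, WM core, central thalamus) for deep/diffuse effects, a
cerebellar sphere (GM shell, WM core) and brainstem cylinder for focal
effects, CSF everywhere else, and a CSF-adjacent ring (tissue voxels with
a face neighbour in CSF) where parenchymal loss is allowed to occur.

Ground truth defaults: WM eigenvalues (1.5, 0.35, 0.35)e-3 mm^2/s
(FA 0.73) with principal directions along region axes, f_par 0.95; GM
isotropic 0.8e-3, f_par 0.90; CSF f_par 0. A smooth multiplicative
jitter field (bounded at 5%) provides between-subject and within-region
variability; it scales the whole eigenvalue triple so truth FA classes
(WM >= 0.4, GM <= 0.2) are preserved.

Patient effects, drawn per subject around their means: a -0.25 (s.d.
0.05) f_par drop restricted to CSF-adjacent cerebellar/brainstem voxels;
a +10% (s.d. 3%) diffusivity scaling brain-wide; a -0.08 (s.d. 0.02) WM
FA reduction at preserved MD (deviatoric shrinkage). Out-of-bound values
are clipped and counted. The magnitudes are synthetic — the study this
emulates reports no effect sizes in physical units — and were chosen once
for detectability at n = 14 + 13 with the permutation test.

Atrophy warps are radial contractions centred on the cerebellum +
brainstem centroid (patients: contraction 0.15, s.d. 0.03; controls: 0,
s.d. 0.02), with a compact radial taper and an additional
distance-to-region taper (4 voxels). The proximity taper matters: a
purely radial compact field must place its volume-compensating expansion
shell somewhere, and without the taper that shell lands in deep cerebral
WM and produces a spurious diffuse logJ group difference. With it, both
contraction and compensation stay in the cerebellar/brainstem
neighbourhood and surrounding CSF, and generated warps are verified
invertible (all Jacobian determinants positive).

DWI is the dual-compartment forward model with S0 = 1000 plus Rician
noise (magnitude MRI), SNR defined as S0/sigma at b0 in WM; cohort
default SNR 40. SARA is generated from the *truth* cerebellar
CSF-adjacent mean f_par (slope -80 per unit fraction, noise s.d. 4.7,
tuned once for a population correlation near -0.65), floored at 0.5 so
all patients are symptomatic — generating from truth rather than fitted
values keeps the downstream correlation test non-circular. Age is uniform
on 16-64 years and TICV normal (1.5e6 +/- 1.2e5 mm^3), independent of
group by default; a confounded-age mode exists for covariate-adjustment
tests.

What the generator does not emulate: real anatomy, partial-volume mixing
beyond the two-compartment model, registration error (all subjects share
one grid), eddy/motion/susceptibility artifacts, and spatially
correlated noise. Passing tests therefore demonstrate correctness of the
estimators and inference under the model's own assumptions, not
robustness to real-data artifacts.

## Known limitations and scale choices

- FA has a positive noise floor at low anisotropy: for isotropic voxels
  the fitted pFA is biased upward (~0.05 at SNR 30). This is a property
  of FA itself; accuracy claims are therefore phrased in medians or
  restricted to anisotropic tissue.
- Unweighted least squares on magnitude data ignores the Rician noise
  floor; negligible at the simulated SNRs, increasingly wrong below
  SNR ~ 10.
- Problem sizes used by the test suite and the acceptance script — a
  32^3 default grid (24^3 for per-module tests), 150-250 permutations,
  40-100 null cohorts on a 12^3 grid — were chosen so the whole suite
  runs on a single CPU in minutes; all thresholds are stated with the
  matching binomial slack.
- Whether the original analysis weighted NLS residuals, shared S0
  between models, or applied Hedge's small-sample correction is not
  documented there; this package uses unweighted residuals, independent
  S0 per model, and the correction, and states so here.
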