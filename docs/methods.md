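# Methods

## Signal model

Each voxel's free induction decay is modeled as a sum of exponentially
damped complex sinusoids (Lorentzian lines in the frequency domain):

s(t) = e^{iφ₀} Σ_g a_g Σ_{l∈g} r_l e^{−d_g t} e^{i2π f_l t} + ε(t)

with ε circular complex Gaussian noise (standard deviation `noise_sigma`
per real channel). Lines are organised in nine metabolite groups
(12 lines): six singlets — PE 6.78, PC 6.24, Pi ≈ 4.9, GPE 3.50,
GPC 2.94, PCr 0.00 ppm — and the three ATP resonances as doublets at
−2.53 (γ), −7.52 (α) and ≈ −16.1 ppm (β) split by J = 16.3 Hz. All
shifts are referenced to PCr = 0 ppm, upfield negative, with
ppm = Hz / spectrometer frequency (51.7 MHz default, ³¹P at 3 T;
dwell time 1/6000 s, 1024 points — plausible receiver settings for a
whole-brain CSI block, configurable).

β-ATP is physically a triplet; the doublet keeps the canonical 12-line
count while retaining multiplet structure, and every reported "β-ATP
position" is the amplitude-weighted group center, which a symmetric
splitting leaves unchanged. Whether NAD(H) or a β-ATP triplet belongs
in the basis is a known ambiguity of 12-line decompositions; the basis
is data, not code, and can be replaced wholesale.

## Calibration curves

pMg = 4.24 − log₁₀[(18.58 + δβ)^0.42 / (−15.74 − δβ)^0.84] on
δβ ∈ (−18.58, −15.74) ppm, and
pH = 6.706 − 0.0307·[Mg] + log₁₀[(δPi − 3.245)/(5.778 − δPi)] on
δPi ∈ (3.245, 5.778) ppm. Conventions adopted here:

* [Mg] enters the pH curve in mmol/L of free Mg²⁺ ([Mg²⁺] =
  10^(3−pMg)), the unit of the underlying in vitro calibration.
* pH is always computed with *that voxel's* Mg concentration, never a
  cohort average; the order pMg → [Mg] → pH is fixed because the pMg
  curve is Mg-free.
* Both curves are strictly monotone and map their open intervals onto
  all of ℝ, so inversion (used by the simulator to place peaks for a
  requested truth) is exact: closed form for pH, Brent root solve
  (xtol 10⁻¹²) for pMg.

## Fitting

Prior knowledge is enforced by construction: the optimizer sees one
(amplitude, frequency, damping) triple per *group* plus a single shared
zero-order phase, and line parameters are derived from them (fixed
amplitude ratios, fixed J offsets, shared damping). Equality
constraints therefore hold to machine precision in every returned fit.
First-order phase is fixed at zero (short-TE acquisition); per-line
phase deviations are deliberately not modeled to avoid degeneracy.

Estimation is `scipy.optimize.least_squares` (trust-region reflective)
on the stacked real/imaginary residual with an analytic Jacobian;
frequency bounds are the per-group prior windows, damping is bounded in
[0.2, 100] Hz, amplitudes are nonnegative. Tolerances are 10⁻¹² so
noiseless signals are recovered to ≈ 10⁻⁶ relative or better.

Initialization searches the magnitude spectrum with a matched multiplet
comb: every candidate center bin in the group's prior window is scored
by the ratio-weighted magnitude at center + J offsets. This prevents a
doublet from locking one line onto its partner's peak — the failure
mode of a naive per-line argmax when the window is wide. Windows
default to ±0.3 ppm; the Pi and β-ATP windows span their full
calibration intervals (±1.25 / ±1.40 ppm) because those two positions
carry the physiology and may sit far from the literature prior. If a
window holds no local maximum (e.g. an empty signal), the prior shift
itself is used with zero amplitude.

Standard errors are Cramér–Rao lower bounds: σ̂²·(JᵀJ)⁻¹ at the
optimum, with σ̂ estimated from the last 10 % of the *fit residual*.
The residual tail (rather than the raw FID tail) is used because at
1024 points × 1/6000 s the acquisition window is only 0.17 s and
10–12 Hz damping leaves ~20 % of the signal in the tail; the residual
is signal-free wherever the model fits, and identical to the raw tail
when the tail truly contains no signal. Rank deficiency of JᵀJ is
detected by SVD and reported per parameter.

## Quality screening

A voxel enters statistics only if its fit converged, the relative
amplitude CRLBs of PCr, Pi and β-ATP are ≤ 20 %, their dampings lie in
[1, 40] Hz, and the PCr SNR (fitted time-domain PCr amplitude over the
per-channel noise SD) is ≥ 3. All thresholds are configuration; the
reason codes enumerate every violated criterion. Shifts that escape a
calibration interval demote the voxel (`"formula domain"`) rather than
raising — out-of-domain shifts are a data-quality outcome.

## Synthetic cohorts

`CohortSpec` emulates the target study design: 13 patients
(7 vasospasm / 6 control), the published distribution of aneurysm
locations (AComm 5, PComm 3, MCA 2, ACA 2, ICA 1) and treatments
(9 clipping / 4 coiling), and ≥ 4 voxels per hemisphere in each of the
BA/ACA/MCA/PCA territories (32 voxels/patient, 416 total). Hunt & Hess
grades and affected sides are plausible assignments, not published
patient-level data.

Ground truth is hierarchical Gaussian: patient mean ~ N(group mean,
between-patient SD), voxel ~ N(patient mean, within-patient SD),
truncated to a broad physiological band (pMg 2.9–4.7, pH 6.4–7.6) so
derived shifts stay inside the calibration intervals. Defaults: control
pMg 3.70 (0.200 mM) / pH 7.00; vasospasm pMg 3.835 (0.146 mM) /
pH 7.0675; between-patient SD 0.06 pMg and 0.03 pH; within-patient SD
0.10 pMg and 0.05 pH; noise σ = 0.05 (PCr SNR 20). The group
separation is ≈ 2.2 between-patient SD — a large effect, chosen once so
that the 7-vs-6 exact rank-sum design retains ~85–90 % power, the
regime in which group differences reach significance at n = 13. All
randomness flows from the single `seed` through one generator;
identical specs are bit-identical.

What the simulator does **not** emulate: k-space CSI encoding and
spatial point-spread (voxel FIDs are generated directly), B₀
inhomogeneity and eddy-current artifacts, baseline distortions from
broad membrane phospholipids, partial-volume mixing across voxel
boundaries, and any spatial correlation of Mg/pH beyond the patient
mean. Passing tests therefore demonstrate correctness of the
quantification and statistics chain on model-conformant data, not
robustness to every in vivo artifact.

Large replicate studies (e.g. 200-cohort power checks) use
`simulate_cohort(..., synthesize_waveforms=False)` +
`truth_to_measurements`, i.e. the statistical pipeline runs on the
generator's ground truth without re-fitting 416 spectra per replicate;
shift-recovery fidelity is established separately by the fitting tests
(noiseless round-trip < 10⁻³; at SNR 10, mean |δβ| error ≪ 0.05 ppm).

## Statistics

* Two groups: Mann–Whitney rank-sum, exact permutation null when the
  combined sample is ≤ 20 and tie-free, else the tie-corrected normal
  approximation. (A signed-rank test is not applicable: the groups are
  independent and unequal.) Note the exact test is conservative at
  7 vs 6 — the discrete U distribution puts the attained size at
  60/1716 ≈ 0.035 for nominal α = 0.05.
* \>2 groups: Kruskal–Wallis with tie correction; Dunn pairwise
  z-tests on pooled mean ranks, Holm-adjusted by default
  (none/Bonferroni configurable).
* ROC: AUC by the Mann–Whitney identity (half-credit ties); cutoff at
  the greatest Youden J over observed thresholds, ties broken toward
  the lowest threshold. The positive direction is fixed a priori per
  marker (Mg: lower is positive; pH: higher is positive) and never
  auto-flipped to force AUC ≥ 0.5, which would manufacture optimism.
* Aggregation unit: patient means (voxel pooling available as a
  sensitivity mode) to avoid pseudo-replication. Scopes: cumulative,
  affected side (midline aneurysms excluded with a logged reason), and
  affected territory, which for a lateral artery is restricted to the
  affected hemisphere so the scopes nest. Patients with < 4 passing
  voxels in a required hemisphere are flagged, never imputed; empty
  selections drop the patient with a recorded reason.
* α = 0.05 two-sided throughout.

## Known limitations

* The fitter assumes the data-generating model (Lorentzian lines,
  white complex noise); real spectra violate this to varying degrees.
* CRLBs are lower bounds under the same assumption and can understate
  uncertainty when the model is misspecified.
* The default quality thresholds are common practice, not a validated
  consensus; they are configuration.
* Vendor file formats are out of scope; the JSON-lines/CSV interchange
  is the boundary.
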