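# p31vaso

Voxel-wise cerebral magnesium and pH from phosphorus-31 MR spectroscopy
(31P-MRS), with cohort-level statistics for predicting clinically relevant
vasospasm after aneurysmal subarachnoid hemorrhage (aSAH).

## The problem

After aSAH, delayed cerebral ischemia caused by vasospasm is a leading
cause of poor outcome, and predicting which patients will develop
clinically relevant vasospasm is an open clinical question. 31P-MRS
measures phosphorus metabolites in vivo and, indirectly, two candidate
biomarkers per brain voxel:

* **free Mg²⁺** from the chemical-shift difference δβ between the β-ATP
  resonance and phosphocreatine (PCr, the 0 ppm reference):

  pMg = 4.24 − log₁₀[ (18.58 + δβ)^0.42 / (−15.74 − δβ)^0.84 ],
  [Mg²⁺] = 10^(3 − pMg) mmol/L

* **intracellular pH** from the inorganic-phosphate shift δPi, corrected
  for that voxel's Mg:

  pH = 6.706 − 0.0307·[Mg] + log₁₀[ (δPi − 3.245) / (5.778 − δPi) ]

This package implements the complete analysis chain as a tested library:

1. **`p31vaso.simulate`** — synthetic chemical-shift-imaging cohorts:
   voxel free induction decays (FIDs) built from a 12-line Lorentzian
   metabolite basis (PME, Pi, PDE, PCr, ATP multiplets) with known
   ground-truth (pMg, pH) per voxel, plus a 13-patient cohort manifest
   (7 vasospasm / 6 control) mirroring a published aSAH cohort.
2. **`p31vaso.fitting`** — AMARES-style prior-knowledge time-domain
   nonlinear least squares: multiplet constraints enforced by a reduced
   parameterization, analytic Jacobian, Cramér–Rao lower-bound standard
   errors, and quality screening (CRLB, linewidth, PCr SNR).
3. **`p31vaso.quantify`** — δβ/δPi → pMg → [Mg²⁺] → pH per voxel.
4. **`p31vaso.stats`** — patient-level aggregation over three anatomical
   scopes (cumulative, affected side, affected arterial territory),
   exact Mann–Whitney rank-sum comparisons, Kruskal–Wallis + Dunn for
   Hunt & Hess strata, and ROC analysis with Youden-J cutoffs.
5. **`p31vaso.io` / CLI** — JSON-lines spectra, CSV manifests, and the
   `p31vaso simulate|fit|analyze|run` commands.

## Worked example

```python
from p31vaso import (
    CohortSpec, default_basis, simulate_fid, fit_amares, quality_filter,
    quantify_voxel, simulate_cohort, truth_to_measurements, run_analysis,
)
from p31vaso.calibration import invert_pmg_to_delta_beta, invert_ph_to_delta_pi, mg_from_pmg

# one voxel: ground truth pMg 3.80 (0.158 mM), pH 7.05, PCr SNR 20
db = invert_pmg_to_delta_beta(3.80)
dpi = invert_ph_to_delta_pi(7.05, mg_from_pmg(3.80))
fid = simulate_fid(default_basis(), delta_beta=db, delta_pi=dpi,
                   noise_sigma=0.05, seed=1)
fit = fit_amares(fid, default_basis())
m = quantify_voxel(fit, quality_filter(fit))
print(f"true delta_beta {db:.3f} ppm -> fitted {m.delta_beta_ppm:.3f} ppm")
print(f"recovered pMg {m.pmg:.3f}  [Mg2+] {m.mg_mM:.3f} mM  pH {m.ph:.3f}  "
      f"QC pass: {m.quality_pass}")

# a 13-patient cohort (7 vasospasm / 6 control) compared at patient level
_, manifest, truth = simulate_cohort(CohortSpec(seed=1), synthesize_waveforms=False)
report = run_analysis(truth_to_measurements(truth, manifest), manifest)
for marker in ("Mg", "pH"):
    blk = report["scopes"]["cumulative"]["markers"][marker]
    print(f"{marker}: vasospasm median {blk['vasospasm']['median']:.4g} vs "
          f"control {blk['control']['median']:.4g}, p = {blk['p_value']:.4f}, "
          f"AUC = {blk['roc']['auc']:.2f}")
```

prints

```
true delta_beta -16.202 ppm -> fitted -16.202 ppm
recovered pMg 3.801  [Mg2+] 0.158 mM  pH 7.050  QC pass: True
Mg: vasospasm median 0.1497 vs control 0.2123, p = 0.0012, AUC = 1.00
pH: vasospasm median 7.074 vs control 6.976, p = 0.0140, AUC = 0.90
```

The single-voxel fit recovers the β-ATP shift to three decimals at SNR 20,
and the cohort analysis detects the injected group difference — lower Mg
and higher pH in the vasospasm group — by the exact rank-sum test on
patient means, with the ROC direction fixed a priori per marker (low Mg
positive, high pH positive).

The same pipeline runs end to end from the shell:

```sh
p31vaso run --config demo.json --seed 1 --out results/demo
```

with `demo.json` like `{"out": "results/demo", "simulate": true}`; it
writes `spectra.jsonl`, `fits.csv`, `quality.csv`, `measurements.csv`
and `report.json`.

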