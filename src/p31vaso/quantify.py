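"""Voxel-wise Mg and pH from fitted chemical shifts.

The two biomarkers derive from shift *differences* against the PCr
reference, so they are invariant to any common frequency offset left
by the fitter:

* delta_beta = (beta-ATP group center) - (PCr position), ppm; feeds the
  pMg calibration, then [Mg2+] = 10**(3 - pMg) mM.
* delta_pi = (Pi position) - (PCr position), ppm; feeds the pH
  calibration together with *this voxel's* Mg concentration.

The computation order is fixed — pMg, then [Mg2+], then pH — because
the pH curve consumes the magnesium concentration while the pMg curve
is Mg-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .basis import BETA_ATP_GROUP, PCR_GROUP, PI_GROUP
from .calibration import (
    DEFAULT_CONSTANTS,
    CalibrationConstants,
    CalibrationDomainError,
    mg_from_pmg,
    ph_from_shift,
    pmg_from_shift,
)
from .fitting import QualityResult, SpectralFit

__all__ = ["VoxelMeasurement", "delta_beta", "delta_pi", "quantify_voxel"]


@dataclass(frozen=True)
class VoxelMeasurement:
    """Per-voxel biomarker estimates; the unit of all downstream statistics.

    A voxel that failed spectrum-quality screening, or whose shifts
    fall outside a calibration's admissible interval, carries
    ``quality_pass=False`` and must not enter group statistics; its
    biomarker fields may be NaN.
    """

    voxel_id: str
    patient_id: str
    hemisphere: str
    territory: str
    delta_beta_ppm: float
    delta_pi_ppm: float
    pmg: float
    mg_mM: float
    ph: float
    quality_pass: bool
    quality_reasons: tuple[str, ...] = ()


def delta_beta(fit: SpectralFit) -> float:
    """beta-ATP-to-PCr shift difference, ppm (negative physiologically).

    The "beta-ATP peak" of a multiplet model is the amplitude-weighted
    mean frequency of the group's lines — what a single-peak reading of
    the multiplet would report.
    """
    return fit.group_center_ppm(BETA_ATP_GROUP) - fit.group_center_ppm(PCR_GROUP)


def delta_pi(fit: SpectralFit) -> float:
    """Pi-to-PCr shift difference, ppm (positive physiologically)."""
    return fit.group_center_ppm(PI_GROUP) - fit.group_center_ppm(PCR_GROUP)


def quantify_voxel(
    fit: SpectralFit,
    qc: QualityResult,
    *,
    hemisphere: str = "left",
    territory: str = "MCA",
    patient_id: str = "patient-0",
    constants: CalibrationConstants = DEFAULT_CONSTANTS,
) -> VoxelMeasurement:
    """One voxel's biomarker set from a completed fit and its QC verdict.

    A QC-passing fit whose shifts escape a calibration domain is
    demoted to ``quality_pass=False`` with reason ``"formula domain"``
    rather than raising: out-of-domain shifts are a data-quality
    outcome, not a programming error.
    """
    db = delta_beta(fit)
    dpi = delta_pi(fit)
    reasons = list(qc.reasons)
    pmg = mg = ph = math.nan
    passed = qc.passed
    try:
        pmg = pmg_from_shift(db, constants)
        mg = mg_from_pmg(pmg)
        ph = ph_from_shift(dpi, mg, constants)
    except CalibrationDomainError:
        if passed:
            passed = False
            reasons.append("formula domain")
    return VoxelMeasurement(
        voxel_id=fit.voxel_id,
        patient_id=patient_id,
        hemisphere=hemisphere,
        territory=territory,
        delta_beta_ppm=db,
        delta_pi_ppm=dpi,
        pmg=pmg,
        mg_mM=mg,
        ph=ph,
        quality_pass=passed,
        quality_reasons=tuple(reasons),
    )
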