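"""Synthetic 31P-CSI cohorts with known ground-truth Mg and pH.

Patient scans of this kind are not publicly deposited, so validation of
the quantification pipeline rests on synthesis: every voxel's free
induction decay (FID) is generated from the same damped-sinusoid model
the fitter assumes, with the Pi and beta-ATP positions placed by
inverting the pH and pMg calibration curves at a known ground truth.

The cohort generator emulates the study design this pipeline targets:
13 patients with aneurysmal subarachnoid hemorrhage, 7 of whom went on
to develop clinically relevant vasospasm, scanned with at least four
voxels per hemisphere in each of the BA/ACA/MCA/PCA arterial
territories.  Ground truth is drawn hierarchically — a patient-level
mean around the group mean, voxel-level values around the patient mean
— so that between-patient and within-patient (voxel) variability are
controlled separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BETA_ATP_GROUP, PCR_GROUP, PI_GROUP, MetaboliteBasis, default_basis
from .calibration import (
    DEFAULT_CONSTANTS,
    CalibrationConstants,
    invert_ph_to_delta_pi,
    invert_pmg_to_delta_beta,
    mg_from_pmg,
    pmg_from_shift,
    ph_from_shift,
)

__all__ = [
    "FreeInductionDecay",
    "CohortSpec",
    "simulate_fid",
    "simulate_cohort",
    "default_patient_table",
    "truth_to_measurements",
    "HEMISPHERES",
    "TERRITORIES",
]

HEMISPHERES = ("left", "right")
TERRITORIES = ("BA", "ACA", "MCA", "PCA")

#: ppm span the receiver must cover on each side of the carrier (PCr)
_REQUIRED_HALF_SPAN_PPM = 20.0


@dataclass(frozen=True)
class FreeInductionDecay:
    """One voxel's complex time-domain signal plus acquisition metadata.

    ``spectrometer_frequency`` is the 31P carrier in MHz; chemical
    shifts in ppm are frequency offsets in Hz divided by it, with PCr
    at 0 and upfield shifts negative.  ``truth`` optionally records the
    (pmg, ph, delta_beta, delta_pi) used to synthesize the voxel.
    """

    samples: np.ndarray
    dwell_time: float
    spectrometer_frequency: float
    voxel_id: str = "voxel-0"
    patient_id: str = "patient-0"
    hemisphere: str = "left"
    territory: str = "MCA"
    truth: dict[str, float] | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=complex)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 256:
            raise ValueError("samples must be a 1-D array with >= 256 points")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.spectrometer_frequency <= 0:
            raise ValueError("spectrometer_frequency must be positive")
        half_span = 0.5 / (self.dwell_time * self.spectrometer_frequency)
        if half_span < _REQUIRED_HALF_SPAN_PPM:
            raise ValueError(
                "spectral width too narrow: covers +-"
                f"{half_span:.1f} ppm, needs the [-20, +10] ppm span"
            )
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.territory not in TERRITORIES:
            raise ValueError(f"territory must be one of {TERRITORIES}")

    @property
    def n_points(self) -> int:
        return int(self.samples.size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_time


def _line_table(
    basis: MetaboliteBasis,
    delta_beta: float,
    delta_pi: float,
    amplitudes: dict[str, float] | None,
) -> list[tuple[str, float, float, float]]:
    """(group, line amplitude, center ppm, J offset Hz) with Pi/beta-ATP moved."""
    amps = dict(basis.group_amplitudes)
    if amplitudes:
        amps.update(amplitudes)
    rows = []
    for line in basis.lines:
        if line.group == BETA_ATP_GROUP:
            center = delta_beta
        elif line.group == PI_GROUP:
            center = delta_pi
        else:
            center = line.shift_ppm
        rows.append((line.group, amps[line.group] * line.rel_amplitude, center, line.j_offset_hz))
    return rows


def simulate_fid(
    basis: MetaboliteBasis | None = None,
    *,
    delta_beta: float = -16.3,
    delta_pi: float = 4.93,
    amplitudes: dict[str, float] | None = None,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
    n_points: int = 1024,
    dwell_time: float = 1.0 / 6000.0,
    spectrometer_frequency: float = 51.7,
    phase0: float = 0.0,
    constants: CalibrationConstants = DEFAULT_CONSTANTS,
    voxel_id: str = "voxel-0",
    patient_id: str = "patient-0",
    hemisphere: str = "left",
    territory: str = "MCA",
) -> FreeInductionDecay:
    """Synthesize one voxel FID from the damped-sinusoid model.

    The signal is s(t) = exp(i*phase0) * sum_k a_k exp(-d_k t)
    exp(i 2 pi f_k t) plus circular complex Gaussian noise of standard
    deviation ``noise_sigma`` per real channel.  The beta-ATP and Pi
    group centers are placed at the requested shifts; all other groups
    sit at their basis priors.

    Raises
    ------
    ValueError
        If ``delta_beta`` or ``delta_pi`` falls outside the open
        admissible interval of its calibration curve.
    """
    basis = basis if basis is not None else default_basis()
    lo_b, hi_b = constants.delta_beta_interval
    lo_p, hi_p = constants.delta_pi_interval
    if not lo_b < delta_beta < hi_b:
        raise ValueError(f"delta_beta={delta_beta} outside open interval ({lo_b}, {hi_b})")
    if not lo_p < delta_pi < hi_p:
        raise ValueError(f"delta_pi={delta_pi} outside open interval ({lo_p}, {hi_p})")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    t = np.arange(n_points) * dwell_time
    signal = np.zeros(n_points, dtype=complex)
    for group, amp, center_ppm, j_hz in _line_table(basis, delta_beta, delta_pi, amplitudes):
        f_hz = center_ppm * spectrometer_frequency + j_hz
        d = basis.damping_hz[group]
        signal += amp * np.exp((-d + 2j * math.pi * f_hz) * t)
    signal *= np.exp(1j * phase0)

    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, n_points) + 1j * rng.normal(
            0.0, noise_sigma, n_points
        )

    pmg = pmg_from_shift(delta_beta, constants)
    ph = ph_from_shift(delta_pi, mg_from_pmg(pmg), constants)
    return FreeInductionDecay(
        samples=signal,
        dwell_time=dwell_time,
        spectrometer_frequency=spectrometer_frequency,
        voxel_id=voxel_id,
        patient_id=patient_id,
        hemisphere=hemisphere,
        territory=territory,
        truth={"pmg": pmg, "ph": ph, "delta_beta": delta_beta, "delta_pi": delta_pi},
    )


# -- cohort -----------------------------------------------------------------

# Published cohort composition: (aneurysm location, treatment,
# Hunt & Hess grade, affected side, vasospasm?).  Locations: AComm x5,
# PComm x3, MCA x2, ACA x2, ICA x1; clipping 9 / coiling 4; 7 of 13
# with vasospasm.  Grades and sides are plausible assignments (not
# published at patient level).
_PATIENTS = (
    ("AComm", "clipping", 3, "right", True),
    ("AComm", "clipping", 2, "left", True),
    ("AComm", "clipping", 4, "right", True),
    ("AComm", "coiling", 3, "left", False),
    ("AComm", "clipping", 1, "right", False),
    ("PComm", "coiling", 2, "left", True),
    ("PComm", "clipping", 3, "right", False),
    ("PComm", "coiling", 5, "left", True),
    ("MCA", "clipping", 2, "right", True),
    ("MCA", "clipping", 3, "left", False),
    ("ACA", "clipping", 4, "right", True),
    ("ACA", "coiling", 2, "left", False),
    ("ICA", "clipping", 1, "right", False),
)

_AFFECTED_TERRITORY = {"AComm": "ACA", "ACA": "ACA", "MCA": "MCA", "ICA": "MCA", "PComm": "PCA"}


def default_patient_table() -> pd.DataFrame:
    """Patient-level table mirroring the published cohort composition."""
    rows = [
        {
            "patient_id": f"P{idx + 1:02d}",
            "group": "vasospasm" if vaso else "control",
            "aneurysm_location": loc,
            "hunt_hess": hh,
            "treatment": tx,
            "affected_side": side,
            "affected_territory": _AFFECTED_TERRITORY[loc],
        }
        for idx, (loc, tx, hh, side, vaso) in enumerate(_PATIENTS)
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Ground truth is hierarchical: patient mean ~ Normal(group mean,
    between_sd), voxel value ~ Normal(patient mean, within_sd), with
    draws truncated to a broad physiological band so the derived shifts
    stay inside the calibration intervals.

    Default effect sizes place the vasospasm group at lower Mg (higher
    pMg) and higher pH, about 2.2 between-patient standard deviations
    apart — a large effect, calibrated so the 7-vs-6 rank-sum design
    retains useful power, and consistent with group differences that
    reach significance at n = 13.
    """

    n_vasospasm: int = 7
    n_control: int = 6
    pmg_mean_vasospasm: float = 3.835  # ~0.146 mM free Mg2+
    pmg_mean_control: float = 3.70     # ~0.200 mM free Mg2+
    pmg_between_sd: float = 0.06
    pmg_within_sd: float = 0.10
    ph_mean_vasospasm: float = 7.0675
    ph_mean_control: float = 7.00
    ph_between_sd: float = 0.03
    ph_within_sd: float = 0.05
    voxels_per_hemisphere: int = 4     # per territory
    territories: tuple[str, ...] = TERRITORIES
    noise_sigma: float = 0.05          # per real channel; PCr amplitude is 1
    seed: int = 0
    # truncation band for truth draws (pMg, pH)
    pmg_band: tuple[float, float] = (2.9, 4.7)
    ph_band: tuple[float, float] = (6.4, 7.6)

    def __post_init__(self) -> None:
        if self.n_vasospasm + self.n_control < 2:
            raise ValueError("need at least 2 patients in total")
        if self.voxels_per_hemisphere < 4:
            raise ValueError("voxels_per_hemisphere must be >= 4")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        bad = [t for t in self.territories if t not in TERRITORIES]
        if bad:
            raise ValueError(f"unknown territories: {bad}")
        for name, mean, band in (
            ("pmg_mean_vasospasm", self.pmg_mean_vasospasm, self.pmg_band),
            ("pmg_mean_control", self.pmg_mean_control, self.pmg_band),
            ("ph_mean_vasospasm", self.ph_mean_vasospasm, self.ph_band),
            ("ph_mean_control", self.ph_mean_control, self.ph_band),
        ):
            if not (math.isfinite(mean) and band[0] <= mean <= band[1]):
                raise ValueError(f"{name}={mean} outside the admissible band {band}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      band: tuple[float, float]) -> float:
    if sd == 0:
        return float(np.clip(mean, *band))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if band[0] <= x <= band[1]:
            return float(x)
    return float(np.clip(mean, *band))  # pragma: no cover - 3+ sd band


def simulate_cohort(
    spec: CohortSpec,
    basis: MetaboliteBasis | None = None,
    *,
    synthesize_waveforms: bool = True,
) -> tuple[list[FreeInductionDecay], pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns ``(fids, manifest, truth)``: the voxel FIDs (empty when
    ``synthesize_waveforms`` is False, which keeps only the ground-truth
    draws — useful for statistical power studies that do not exercise
    the spectral fitter), a voxel-level cohort manifest, and the
    ground-truth table with per-voxel pMg, Mg, pH and shifts.

    All randomness flows from ``spec.seed`` through one generator, so
    identical specs give bit-identical outputs.
    """
    basis = basis if basis is not None else default_basis()
    rng = np.random.default_rng(spec.seed)

    patients = default_patient_table()
    n_total = spec.n_vasospasm + spec.n_control
    if (spec.n_vasospasm, spec.n_control) != (7, 6):
        # Rebuild a patient table of the requested size by cycling the
        # published composition per group.
        vaso_pool = patients[patients.group == "vasospasm"].to_dict("records")
        ctrl_pool = patients[patients.group == "control"].to_dict("records")
        rows = []
        for i in range(spec.n_vasospasm):
            rows.append(dict(vaso_pool[i % len(vaso_pool)]))
        for i in range(spec.n_control):
            rows.append(dict(ctrl_pool[i % len(ctrl_pool)]))
        for i, row in enumerate(rows):
            row["patient_id"] = f"P{i + 1:02d}"
        patients = pd.DataFrame(rows)

    fids: list[FreeInductionDecay] = []
    manifest_rows: list[dict] = []
    truth_rows: list[dict] = []

    for patient in patients.itertuples(index=False):
        if patient.group == "vasospasm":
            pmg_mu, ph_mu = spec.pmg_mean_vasospasm, spec.ph_mean_vasospasm
        else:
            pmg_mu, ph_mu = spec.pmg_mean_control, spec.ph_mean_control
        patient_pmg = _truncated_normal(rng, pmg_mu, spec.pmg_between_sd, spec.pmg_band)
        patient_ph = _truncated_normal(rng, ph_mu, spec.ph_between_sd, spec.ph_band)

        v = 0
        for territory in spec.territories:
            for hemisphere in HEMISPHERES:
                for _ in range(spec.voxels_per_hemisphere):
                    v += 1
                    voxel_id = f"{patient.patient_id}-V{v:03d}"
                    pmg = _truncated_normal(rng, patient_pmg, spec.pmg_within_sd, spec.pmg_band)
                    ph = _truncated_normal(rng, patient_ph, spec.ph_within_sd, spec.ph_band)
                    db = invert_pmg_to_delta_beta(pmg)
                    mg = mg_from_pmg(pmg)
                    dpi = invert_ph_to_delta_pi(ph, mg)
                    if synthesize_waveforms:
                        fids.append(
                            simulate_fid(
                                basis,
                                delta_beta=db,
                                delta_pi=dpi,
                                noise_sigma=spec.noise_sigma,
                                seed=rng,
                                voxel_id=voxel_id,
                                patient_id=patient.patient_id,
                                hemisphere=hemisphere,
                                territory=territory,
                            )
                        )
                    manifest_rows.append(
                        {
                            "patient_id": patient.patient_id,
                            "group": patient.group,
                            "aneurysm_location": patient.aneurysm_location,
                            "hunt_hess": patient.hunt_hess,
                            "treatment": patient.treatment,
                            "affected_side": patient.affected_side,
                            "affected_territory": patient.affected_territory,
                            "voxel_id": voxel_id,
                            "hemisphere": hemisphere,
                            "territory": territory,
                        }
                    )
                    truth_rows.append(
                        {
                            "voxel_id": voxel_id,
                            "patient_id": patient.patient_id,
                            "pmg": pmg,
                            "mg_mM": mg,
                            "ph": ph,
                            "delta_beta_ppm": db,
                            "delta_pi_ppm": dpi,
                        }
                    )

    return fids, pd.DataFrame(manifest_rows), pd.DataFrame(truth_rows)


def truth_to_measurements(truth: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Voxel measurement table taken directly from the ground truth.

    Bypasses spectral fitting (every voxel passes quality control);
    used to study the statistical pipeline in isolation.
    """
    merged = truth.merge(
        manifest[["voxel_id", "hemisphere", "territory"]], on="voxel_id", validate="1:1"
    )
    return pd.DataFrame(
        {
            "voxel_id": merged.voxel_id,
            "patient_id": merged.patient_id,
            "hemisphere": merged.hemisphere,
            "territory": merged.territory,
            "delta_beta_ppm": merged.delta_beta_ppm,
            "delta_pi_ppm": merged.delta_pi_ppm,
            "pmg": merged.pmg,
            "mg_mM": merged.mg_mM,
            "ph": merged.ph,
            "quality_pass": True,
        }
    )
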