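"""File formats and the end-to-end pipeline.

Interchange is deliberately plain-text: voxel spectra travel as a
JSON-lines file (one header record with the acquisition settings, then
one record per voxel with complex samples as [re, im] pairs), and
everything tabular — cohort manifest, fitted peaks, quality verdicts,
voxel measurements — as UTF-8 comma-separated CSV with a mandatory
header row.  Vendor spectroscopy formats are out of scope; converting
into this interchange is the caller's responsibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .basis import MetaboliteBasis, default_basis
from .fitting import FitConfig, QualityCriteria, QualityResult, SpectralFit, fit_amares, quality_filter
from .quantify import quantify_voxel
from .simulate import CohortSpec, FreeInductionDecay, simulate_cohort
from .stats import StatsConfig, run_analysis

__all__ = [
    "SpectraFormatError",
    "write_spectra",
    "read_spectra",
    "fits_to_frames",
    "measurements_to_frame",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("p31vaso")


class SpectraFormatError(ValueError):
    """Malformed spectrum file; message carries the line number."""


def write_spectra(fids: list[FreeInductionDecay], path: str | Path) -> None:
    """Write voxel FIDs as JSON-lines with a leading header record."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = {"record": "header", "format": "p31vaso-spectra", "version": 1}
        if fids:
            header["dwell_time"] = fids[0].dwell_time
            header["spectrometer_frequency_mhz"] = fids[0].spectrometer_frequency
            header["n_points"] = fids[0].n_points
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for fid in fids:
            rec = {
                "record": "voxel",
                "voxel_id": fid.voxel_id,
                "patient_id": fid.patient_id,
                "hemisphere": fid.hemisphere,
                "territory": fid.territory,
                "dwell_time": fid.dwell_time,
                "spectrometer_frequency_mhz": fid.spectrometer_frequency,
                "samples": [[float(z.real), float(z.imag)] for z in fid.samples],
            }
            if fid.truth is not None:
                rec["truth"] = {k: float(v) for k, v in fid.truth.items()}
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_spectra(path: str | Path) -> list[FreeInductionDecay]:
    """Read a spectrum JSON-lines file; failures name the line and field."""
    path = Path(path)
    fids: list[FreeInductionDecay] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                rec = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise SpectraFormatError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            kind = rec.get("record")
            if lineno == 1:
                if kind != "header":
                    raise SpectraFormatError("line 1: expected a header record")
                continue
            if kind != "voxel":
                raise SpectraFormatError(f"line {lineno}: expected a voxel record, got {kind!r}")
            for fld in ("voxel_id", "dwell_time", "spectrometer_frequency_mhz", "samples"):
                if fld not in rec:
                    raise SpectraFormatError(f"line {lineno}: missing field {fld!r}")
            try:
                samples = np.array([complex(re, im) for re, im in rec["samples"]])
                fids.append(
                    FreeInductionDecay(
                        samples=samples,
                        dwell_time=rec["dwell_time"],
                        spectrometer_frequency=rec["spectrometer_frequency_mhz"],
                        voxel_id=rec["voxel_id"],
                        patient_id=rec.get("patient_id", "unknown"),
                        hemisphere=rec.get("hemisphere", "left"),
                        territory=rec.get("territory", "MCA"),
                        truth=rec.get("truth"),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise SpectraFormatError(f"line {lineno}: {exc}") from exc
    if not fids:
        log.warning("%s: no voxel records (header-only file?)", path)
    return fids


def fits_to_frames(
    fits: list[SpectralFit], qcs: list[QualityResult]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fitted peaks (one row per voxel per line) and quality verdicts."""
    peak_rows = [
        {
            "voxel_id": fit.voxel_id,
            "label": p.label,
            "group": p.group,
            "amplitude": p.amplitude,
            "frequency_ppm": p.frequency_ppm,
            "damping_hz": p.damping_hz,
            "phase_rad": p.phase_rad,
            "amplitude_se": p.amplitude_se,
            "frequency_se_ppm": p.frequency_se_ppm,
            "damping_se_hz": p.damping_se_hz,
        }
        for fit in fits
        for p in fit.peaks
    ]
    qc_rows = [
        {
            "voxel_id": fit.voxel_id,
            "quality_pass": qc.passed,
            "reasons": ";".join(qc.reasons),
            "pcr_snr": qc.pcr_snr,
            "converged": fit.converged,
            "rss": fit.rss,
            "noise_sigma": fit.noise_sigma,
        }
        for fit, qc in zip(fits, qcs)
    ]
    return pd.DataFrame(peak_rows), pd.DataFrame(qc_rows)


def measurements_to_frame(measurements) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "voxel_id": m.voxel_id,
            "patient_id": m.patient_id,
            "hemisphere": m.hemisphere,
            "territory": m.territory,
            "delta_beta_ppm": m.delta_beta_ppm,
            "delta_pi_ppm": m.delta_pi_ppm,
            "pmg": m.pmg,
            "mg_mM": m.mg_mM,
            "ph": m.ph,
            "quality_pass": m.quality_pass,
            "quality_reasons": ";".join(m.quality_reasons),
        }
        for m in measurements
    )


class PipelineConfig(BaseModel):
    """Strict-schema configuration of an end-to-end run.

    When ``simulate`` is true a synthetic cohort is generated with
    ``seed``; otherwise ``spectra`` and ``manifest`` must point at
    existing files.  Unknown keys are rejected.
    """

    model_config = ConfigDict(extra="forbid")

    out: str
    simulate: bool = True
    seed: int = 0
    spectra: str | None = None
    manifest: str | None = None
    noise_sigma: float = 0.05
    n_vasospasm: int = 7
    n_control: int = 6
    voxels_per_hemisphere: int = Field(default=4, ge=4)
    territories: tuple[str, ...] = ("BA", "ACA", "MCA", "PCA")
    qc_max_rel_crlb: float = 0.20
    qc_min_pcr_snr: float = 3.0
    adjustment: str = "holm"
    aggregation_unit: str = "patient_mean"

    def validated_paths(self) -> None:
        if not self.simulate:
            for name in ("spectra", "manifest"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(f"{name} is required when simulate is false")
                if not Path(value).exists():
                    raise ValueError(f"{name} path does not exist: {value}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    basis: MetaboliteBasis | None = None,
    fit_config: FitConfig = FitConfig(),
) -> dict:
    """simulate (optional) -> fit -> quantify -> analyze, artifacts on disk.

    Writes spectra.jsonl (when simulating), manifest.csv, truth.csv,
    fits.csv, quality.csv, measurements.csv, report.json and a
    run_manifest.json echoing the configuration with SHA-256 hashes of
    every written artifact.  Fixed inputs give byte-identical outputs.
    """
    config.validated_paths()
    basis = basis if basis is not None else default_basis()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        spec = CohortSpec(
            n_vasospasm=config.n_vasospasm,
            n_control=config.n_control,
            voxels_per_hemisphere=config.voxels_per_hemisphere,
            territories=config.territories,
            noise_sigma=config.noise_sigma,
            seed=config.seed,
        )
        fids, manifest, truth = simulate_cohort(spec, basis)
        write_spectra(fids, out / "spectra.jsonl")
        manifest.to_csv(out / "manifest.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    else:
        fids = read_spectra(config.spectra)
        manifest = pd.read_csv(config.manifest)
    log.info("pipeline: %d voxel spectra, %d manifest rows", len(fids), len(manifest))

    criteria = QualityCriteria(
        max_rel_crlb=config.qc_max_rel_crlb, min_pcr_snr=config.qc_min_pcr_snr
    )
    fits, qcs, measurements = [], [], []
    for fid in fids:
        fit = fit_amares(fid, basis, config=fit_config)
        qc = quality_filter(fit, criteria)
        fits.append(fit)
        qcs.append(qc)
        measurements.append(
            quantify_voxel(
                fit, qc,
                hemisphere=fid.hemisphere,
                territory=fid.territory,
                patient_id=fid.patient_id,
            )
        )
    n_fail = sum(not qc.passed for qc in qcs)
    log.info("quality screening: %d/%d voxels excluded", n_fail, len(qcs))

    peaks_df, qc_df = fits_to_frames(fits, qcs)
    peaks_df.to_csv(out / "fits.csv", index=False)
    qc_df.to_csv(out / "quality.csv", index=False)
    meas_df = measurements_to_frame(measurements)
    meas_df.to_csv(out / "measurements.csv", index=False)

    stats_config = StatsConfig(
        adjustment=config.adjustment, aggregation_unit=config.aggregation_unit
    )
    report = run_analysis(meas_df, manifest, stats_config)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    artifacts = sorted(p.name for p in out.iterdir() if p.name != "run_manifest.json")
    run_manifest = {
        "config": config.model_dump(),
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
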