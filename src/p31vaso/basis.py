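"""The 12-line metabolite basis of a brain 31P spectrum, and CSI voxel geometry.

The in vivo phosphorus spectrum of brain is modeled as 12 Lorentzian
(exponentially damped) sinusoids organised in nine metabolite groups:
six singlets — phosphoethanolamine (PE), phosphocholine (PC), inorganic
phosphate (Pi), glycerophosphoethanolamine (GPE), glycerophosphocholine
(GPC), phosphocreatine (PCr) — and the three ATP resonances modeled as
doublets with a fixed phosphorus-phosphorus J-splitting.  PCr defines
the 0 ppm reference; shifts upfield of PCr are negative.

Lines inside a multiplet group are rigidly coupled: they share one
damping, keep fixed frequency offsets (the J-splitting) and fixed
amplitude ratios.  Fitting therefore estimates one (amplitude,
frequency, damping) triple per *group*, never per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralLine",
    "MetaboliteBasis",
    "VoxelGeometry",
    "default_basis",
    "PCR_GROUP",
    "PI_GROUP",
    "BETA_ATP_GROUP",
]

PCR_GROUP = "PCr"
PI_GROUP = "Pi"
BETA_ATP_GROUP = "bATP"

#: phosphorus-phosphorus J coupling of the ATP multiplets, Hz
DEFAULT_J_HZ = 16.3

# Admissible open intervals of the Mg/pH calibrations (ppm vs PCr); the
# basis invariants keep the Mg- and pH-reporting groups inside them.
_BETA_ATP_INTERVAL = (-18.58, -15.74)
_PI_INTERVAL = (3.245, 5.778)


@dataclass(frozen=True)
class SpectralLine:
    """One Lorentzian line of the basis.

    ``shift_ppm`` is the prior chemical shift of the line's *group
    center* relative to PCr; ``j_offset_hz`` displaces the individual
    line from that center (0 for singlets, +-J/2 for doublets).
    ``rel_amplitude`` is the line's fixed share of the group amplitude.
    """

    label: str
    group: str
    shift_ppm: float
    rel_amplitude: float = 1.0
    j_offset_hz: float = 0.0


@dataclass(frozen=True)
class MetaboliteBasis:
    """Prior knowledge for simulation and constrained fitting.

    Parameters
    ----------
    lines
        The Lorentzian lines; the default basis has exactly 12.
    damping_hz
        Default damping (decay rate, Hz) per group; lines in a group
        always share it.
    search_window_ppm
        Half-width of the frequency prior window per group.  The Pi and
        beta-ATP windows span their full calibration intervals because
        those positions carry the physiology; all other groups stay
        near their literature shift.
    group_amplitudes
        Default relative group amplitudes used by the simulator
        (PCr = 1).
    """

    lines: tuple[SpectralLine, ...]
    damping_hz: dict[str, float]
    search_window_ppm: dict[str, float]
    group_amplitudes: dict[str, float]

    def __post_init__(self) -> None:
        groups = self.group_labels
        missing = [g for g in groups if g not in self.damping_hz]
        if missing:
            raise ValueError(f"damping_hz missing groups: {missing}")
        if PCR_GROUP in groups:
            pcr = self.group_center(PCR_GROUP)
            if pcr != 0.0:
                raise ValueError(f"PCr group center must be 0.0 ppm, got {pcr}")
        if BETA_ATP_GROUP in groups:
            lo, hi = _BETA_ATP_INTERVAL
            c = self.group_center(BETA_ATP_GROUP)
            if not lo < c < hi:
                raise ValueError(
                    f"beta-ATP center {c} ppm outside open interval ({lo}, {hi})"
                )
        if PI_GROUP in groups:
            lo, hi = _PI_INTERVAL
            c = self.group_center(PI_GROUP)
            if not lo < c < hi:
                raise ValueError(f"Pi center {c} ppm outside open interval ({lo}, {hi})")

    @property
    def group_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for line in self.lines:
            if line.group not in seen:
                seen.append(line.group)
        return tuple(seen)

    def group_lines(self, group: str) -> tuple[SpectralLine, ...]:
        out = tuple(line for line in self.lines if line.group == group)
        if not out:
            raise KeyError(f"basis has no group {group!r}")
        return out

    def group_center(self, group: str) -> float:
        """Amplitude-weighted mean prior shift of a group, ppm."""
        lines = self.group_lines(group)
        w = np.array([ln.rel_amplitude for ln in lines])
        s = np.array([ln.shift_ppm for ln in lines])
        return float(np.average(s, weights=w))

    def with_group_shift(self, group: str, center_ppm: float) -> "MetaboliteBasis":
        """Copy of the basis with one group's center moved to ``center_ppm``."""
        lines = tuple(
            SpectralLine(ln.label, ln.group, center_ppm, ln.rel_amplitude, ln.j_offset_hz)
            if ln.group == group
            else ln
            for ln in self.lines
        )
        return MetaboliteBasis(
            lines, dict(self.damping_hz), dict(self.search_window_ppm),
            dict(self.group_amplitudes),
        )


def default_basis(j_hz: float = DEFAULT_J_HZ) -> MetaboliteBasis:
    """The default 12-line brain 31P basis.

    Prior shifts (ppm vs PCr) follow standard in vivo phosphorus
    literature values: PE 6.78, PC 6.24, Pi ~4.9 (pH dependent),
    GPE 3.50, GPC 2.94, PCr 0.0, gamma-ATP -2.53, alpha-ATP -7.52,
    beta-ATP -16.1 (Mg dependent); ATP groups are doublets split by
    ``j_hz``.  Physically beta-ATP is a triplet; the doublet keeps the
    total line count at 12 while retaining multiplet structure, and the
    reported "beta-ATP peak" is always the group's amplitude-weighted
    center, which is unaffected by the symmetric splitting.
    """
    half = j_hz / 2.0
    lines = (
        SpectralLine("PE", "PE", 6.78),
        SpectralLine("PC", "PC", 6.24),
        SpectralLine("Pi", PI_GROUP, 4.90),
        SpectralLine("GPE", "GPE", 3.50),
        SpectralLine("GPC", "GPC", 2.94),
        SpectralLine("PCr", PCR_GROUP, 0.0),
        SpectralLine("gATP_1", "gATP", -2.53, 0.5, -half),
        SpectralLine("gATP_2", "gATP", -2.53, 0.5, +half),
        SpectralLine("aATP_1", "aATP", -7.52, 0.5, -half),
        SpectralLine("aATP_2", "aATP", -7.52, 0.5, +half),
        SpectralLine("bATP_1", BETA_ATP_GROUP, -16.10, 0.5, -half),
        SpectralLine("bATP_2", BETA_ATP_GROUP, -16.10, 0.5, +half),
    )
    damping = {
        "PE": 10.0, "PC": 10.0, PI_GROUP: 10.0, "GPE": 10.0, "GPC": 10.0,
        PCR_GROUP: 10.0, "gATP": 12.0, "aATP": 12.0, BETA_ATP_GROUP: 12.0,
    }
    # Pi and beta-ATP windows cover the calibration intervals; others
    # are tight literature priors.
    windows = {
        "PE": 0.3, "PC": 0.3, PI_GROUP: 1.25, "GPE": 0.3, "GPC": 0.3,
        PCR_GROUP: 0.3, "gATP": 0.4, "aATP": 0.4, BETA_ATP_GROUP: 1.40,
    }
    amplitudes = {
        "PE": 0.35, "PC": 0.30, PI_GROUP: 0.50, "GPE": 0.40, "GPC": 0.45,
        PCR_GROUP: 1.00, "gATP": 0.70, "aATP": 0.75, BETA_ATP_GROUP: 0.60,
    }
    return MetaboliteBasis(lines, damping, windows, amplitudes)


@dataclass(frozen=True)
class VoxelGeometry:
    """CSI acquisition geometry: field of view and encoding matrix.

    Defaults reproduce a whole-brain 3D CSI block: 240 x 240 x 200 mm
    field of view on an 8 x 8 x 8 matrix, i.e. 30 x 30 x 25 mm voxels.
    """

    fov_mm: tuple[float, float, float] = (240.0, 240.0, 200.0)
    matrix: tuple[int, int, int] = (8, 8, 8)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fov_mm) or any(m <= 0 for m in self.matrix):
            raise ValueError("fov_mm and matrix entries must be positive")

    @property
    def voxel_dimensions_mm(self) -> tuple[float, float, float]:
        return tuple(f / m for f, m in zip(self.fov_mm, self.matrix))
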