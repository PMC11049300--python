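"""Prior-knowledge time-domain fitting of 31P free induction decays.

The voxel signal is modeled as a sum of exponentially damped complex
sinusoids (Lorentzian lines after Fourier transform),

    s(t) = exp(i phi0) * sum_g a_g * sum_{l in g} r_l
           exp(-d_g t) exp(i 2 pi f_l t),

where groups g are the metabolite multiplets of the basis: lines in a
group share one damping d_g and one amplitude scale a_g, keep fixed
amplitude ratios r_l and fixed frequency offsets (the J-splitting)
around the group center f_g, and a single zero-order phase phi0 is
shared by all lines.  These prior-knowledge constraints are enforced by
construction — the optimizer only ever sees the reduced parameter
vector [phi0, (a_g, f_g, d_g) per group] — so they hold exactly in
every returned fit.

Estimation is bounded trust-region nonlinear least squares on the
stacked real/imaginary residual with an analytic Jacobian.  Standard
errors are Cramer-Rao lower bounds from the Gauss-Newton approximation
of the Fisher information at the optimum, scaled by a noise estimate
taken from the tail of the fit residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .basis import BETA_ATP_GROUP, PCR_GROUP, PI_GROUP, MetaboliteBasis
from .simulate import FreeInductionDecay

__all__ = [
    "PeakEstimate",
    "SpectralFit",
    "QualityCriteria",
    "QualityResult",
    "FitConfig",
    "initialize_fit",
    "fit_amares",
    "quality_filter",
]


@dataclass(frozen=True)
class PeakEstimate:
    """Fitted parameters of one basis line with CRLB standard errors."""

    label: str
    group: str
    amplitude: float
    frequency_ppm: float
    damping_hz: float
    phase_rad: float
    amplitude_se: float = math.nan
    frequency_se_ppm: float = math.nan
    damping_se_hz: float = math.nan
    phase_se_rad: float = math.nan


@dataclass(frozen=True)
class SpectralFit:
    """Result of fitting the full basis to one voxel FID."""

    voxel_id: str
    peaks: tuple[PeakEstimate, ...]
    rss: float
    noise_sigma: float
    converged: bool
    iterations: int
    rank_deficient_params: tuple[str, ...] = ()

    def peak(self, label: str) -> PeakEstimate:
        for p in self.peaks:
            if p.label == label:
                return p
        raise KeyError(f"fit has no line labelled {label!r}")

    def group_peaks(self, group: str) -> tuple[PeakEstimate, ...]:
        out = tuple(p for p in self.peaks if p.group == group)
        if not out:
            raise KeyError(f"fit has no group {group!r}")
        return out

    def group_amplitude(self, group: str) -> float:
        return float(sum(p.amplitude for p in self.group_peaks(group)))

    def group_center_ppm(self, group: str) -> float:
        """Amplitude-weighted mean frequency of a multiplet group, ppm."""
        peaks = self.group_peaks(group)
        w = np.array([p.amplitude for p in peaks])
        f = np.array([p.frequency_ppm for p in peaks])
        if w.sum() <= 0:
            return float(f.mean())
        return float(np.average(f, weights=w))


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings and parameter bounds."""

    max_nfev: int = 600
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    damping_bounds_hz: tuple[float, float] = (0.2, 100.0)
    init_damping_hz: float = 10.0
    # fraction of trailing FID points treated as signal-free for the
    # residual-based noise estimate
    noise_tail_fraction: float = 0.10


# -- reduced parameterization ----------------------------------------------
# x = [phi0, a_0, f_0, d_0, a_1, f_1, d_1, ...] over basis groups


def _group_line_arrays(basis: MetaboliteBasis, f0_mhz: float):
    """Per group: relative amplitudes and J offsets (in ppm)."""
    out = []
    for g in basis.group_labels:
        lines = basis.group_lines(g)
        rel = np.array([ln.rel_amplitude for ln in lines])
        off_ppm = np.array([ln.j_offset_hz / f0_mhz for ln in lines])
        out.append((g, lines, rel, off_ppm))
    return out


def _model_and_parts(x, t, groups, f0_mhz):
    """Model s(t) plus the per-group components a_g * m_g needed by the Jacobian."""
    phi0 = x[0]
    phase = np.exp(1j * phi0)
    parts = []
    s = np.zeros_like(t, dtype=complex)
    for k, (_, _, rel, off_ppm) in enumerate(groups):
        a, f, d = x[1 + 3 * k : 4 + 3 * k]
        m = np.zeros_like(t, dtype=complex)
        for r, off in zip(rel, off_ppm):
            f_hz = (f + off) * f0_mhz
            m += r * np.exp((-d + 2j * math.pi * f_hz) * t)
        am = a * m
        parts.append((m, am))
        s += am
    return phase * s, phase, parts


def _residual_fn(x, t, y, groups, f0_mhz):
    s, _, _ = _model_and_parts(x, t, groups, f0_mhz)
    r = s - y
    return np.concatenate([r.real, r.imag])


def _jacobian_fn(x, t, y, groups, f0_mhz):
    s, phase, parts = _model_and_parts(x, t, groups, f0_mhz)
    n = t.size
    jac = np.empty((2 * n, 1 + 3 * len(groups)))

    def put(col, dz):
        jac[:n, col] = dz.real
        jac[n:, col] = dz.imag

    put(0, 1j * s)  # d/dphi0
    for k, (_, _, _, _) in enumerate(groups):
        m, am = parts[k]
        put(1 + 3 * k, phase * m)                                  # d/da
        put(2 + 3 * k, phase * (2j * math.pi * f0_mhz) * t * am)   # d/df (ppm)
        put(3 + 3 * k, phase * (-t) * am)                          # d/dd
    return jac


def initialize_fit(
    fid: FreeInductionDecay,
    basis: MetaboliteBasis,
    config: FitConfig = FitConfig(),
) -> np.ndarray:
    """Starting values from a magnitude-spectrum peak search.

    Each group's frequency starts at the magnitude-spectrum argmax
    inside the group's prior window (each multiplet line is searched
    around its own prior position and the candidates are combined,
    weighted by relative amplitude); if the window holds no local
    maximum the prior shift itself is used.  Amplitudes are read off
    the peak height through the discrete Lorentzian peak gain; damping
    starts at ``config.init_damping_hz`` and phases at zero.

    Raises
    ------
    ValueError
        If the FID's spectral window does not cover a line's prior
        shift (the offending line is named).
    """
    f0 = fid.spectrometer_frequency
    n = fid.n_points
    dwell = fid.dwell_time
    freqs_ppm = np.fft.fftshift(np.fft.fftfreq(n, d=dwell)) / f0
    mag = np.abs(np.fft.fftshift(np.fft.fft(fid.samples)))
    d0 = config.init_damping_hz
    # DFT peak gain of a damped exponential sampled at the line frequency
    gain = (1.0 - math.exp(-d0 * dwell * n)) / (1.0 - math.exp(-d0 * dwell))

    bin_ppm = (1.0 / (dwell * n)) / f0
    groups = _group_line_arrays(basis, f0)
    x0 = [0.0]
    for g, lines, rel, off_ppm in groups:
        window = basis.search_window_ppm[g]
        prior_center = basis.group_center(g)
        for line, off in zip(lines, off_ppm):
            prior_line = line.shift_ppm + off
            if prior_line < freqs_ppm[0] or prior_line > freqs_ppm[-1]:
                raise ValueError(
                    f"spectral window [{freqs_ppm[0]:.1f}, {freqs_ppm[-1]:.1f}] ppm "
                    f"does not cover the prior shift of line {line.label!r} "
                    f"({prior_line:.2f} ppm)"
                )
        # matched multiplet comb: score every candidate center bin by the
        # rel-amplitude-weighted magnitude at center + J offsets, so a
        # doublet cannot lock one line onto its partner's peak
        cand = np.flatnonzero(np.abs(freqs_ppm - prior_center) <= window)
        bin_offsets = [int(round(off / bin_ppm)) for off in off_ppm]
        scores = np.zeros(cand.size)
        for r, boff in zip(rel, bin_offsets):
            scores += r * mag[np.clip(cand + boff, 0, n - 1)]
        best = int(np.argmax(scores))
        is_local_max = (
            0 < best < cand.size - 1
            and scores[best] >= scores[best - 1]
            and scores[best] >= scores[best + 1]
            and scores[best] > 0
        )
        if is_local_max:
            center0 = float(freqs_ppm[cand[best]])
            k = int(np.argmax(rel))
            peak_idx = int(np.clip(cand[best] + bin_offsets[k], 0, n - 1))
            amp0 = float(mag[peak_idx] / (gain * rel[k]))
        else:
            center0, amp0 = prior_center, 0.0
        x0.extend([amp0, center0, d0])
    return np.asarray(x0)


def fit_amares(
    fid: FreeInductionDecay,
    basis: MetaboliteBasis,
    init: np.ndarray | None = None,
    config: FitConfig = FitConfig(),
) -> SpectralFit:
    """Fit the constrained damped-sinusoid model to one voxel FID.

    Non-convergence is not an exception: the fit is returned with
    ``converged=False`` and screened out downstream by
    :func:`quality_filter`.
    """
    f0 = fid.spectrometer_frequency
    t = fid.times
    y = fid.samples
    groups = _group_line_arrays(basis, f0)
    x0 = initialize_fit(fid, basis, config) if init is None else np.asarray(init, float)

    lo = [-math.pi - 1.0]
    hi = [math.pi + 1.0]
    for g, lines, _, _ in groups:
        window = basis.search_window_ppm[g]
        center = basis.group_center(g)
        lo.extend([0.0, center - window, config.damping_bounds_hz[0]])
        hi.extend([np.inf, center + window, config.damping_bounds_hz[1]])
    lo, hi = np.array(lo), np.array(hi)
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    result = least_squares(
        _residual_fn,
        x0,
        jac=_jacobian_fn,
        bounds=(lo, hi),
        args=(t, y, groups, f0),
        method="trf",
        ftol=config.ftol,
        xtol=config.xtol,
        gtol=config.gtol,
        max_nfev=config.max_nfev,
    )
    x = result.x
    converged = result.status > 0

    # noise from the tail of the residual (assumed signal-free there)
    s, _, _ = _model_and_parts(x, t, groups, f0)
    resid = s - y
    n_tail = max(8, int(round(config.noise_tail_fraction * t.size)))
    tail = resid[-n_tail:]
    sigma = float(np.std(np.concatenate([tail.real, tail.imag])))

    # CRLB: covariance = sigma^2 (J^T J)^-1 on the reduced parameters
    jac = _jacobian_fn(x, t, y, groups, f0)
    jtj = jac.T @ jac
    u, sv, vt = np.linalg.svd(jtj)
    tol = sv.max() * max(jtj.shape) * np.finfo(float).eps if sv.size else 0.0
    rank_deficient: list[str] = []
    param_names = ["phi0"]
    for g, _, _, _ in groups:
        param_names += [f"a:{g}", f"f:{g}", f"d:{g}"]
    if sv.size and sv.min() <= tol:
        null_mask = sv <= tol
        null_space = vt[null_mask].T
        involved = np.any(np.abs(null_space) > 1e-8, axis=1)
        rank_deficient = [nm for nm, flag in zip(param_names, involved) if flag]
    inv = (vt.T * np.where(sv > tol, 1.0 / np.where(sv > 0, sv, 1.0), 0.0)) @ u.T
    se = sigma * np.sqrt(np.clip(np.diag(inv), 0.0, np.inf))

    phi0 = float(x[0])
    phi0_wrapped = math.remainder(phi0, 2 * math.pi)
    if phi0_wrapped <= -math.pi:
        phi0_wrapped += 2 * math.pi

    peaks = []
    for k, (g, lines, rel, off_ppm) in enumerate(groups):
        a, f, d = x[1 + 3 * k : 4 + 3 * k]
        a_se, f_se, d_se = se[1 + 3 * k : 4 + 3 * k]
        for line, r, off in zip(lines, rel, off_ppm):
            peaks.append(
                PeakEstimate(
                    label=line.label,
                    group=g,
                    amplitude=float(a * r),
                    frequency_ppm=float(f + off),
                    damping_hz=float(d),
                    phase_rad=phi0_wrapped,
                    amplitude_se=float(a_se * r),
                    frequency_se_ppm=float(f_se),
                    damping_se_hz=float(d_se),
                    phase_se_rad=float(se[0]),
                )
            )

    return SpectralFit(
        voxel_id=fid.voxel_id,
        peaks=tuple(peaks),
        rss=float(result.cost * 2.0),
        noise_sigma=sigma,
        converged=converged,
        iterations=int(result.nfev),
        rank_deficient_params=tuple(rank_deficient),
    )


@dataclass(frozen=True)
class QualityCriteria:
    """Spectrum-quality screening thresholds.

    Screening follows common in vivo MRS practice: a fit is usable when
    the optimizer converged, the amplitudes of the reporting-critical
    resonances (PCr, Pi, beta-ATP) are estimated with relative CRLB at
    or below ``max_rel_crlb``, their linewidths are physiological, and
    the PCr signal-to-noise ratio (fitted time-domain PCr amplitude
    over the per-channel noise standard deviation) is at least
    ``min_pcr_snr``.
    """

    max_rel_crlb: float = 0.20
    damping_range_hz: tuple[float, float] = (1.0, 40.0)
    min_pcr_snr: float = 3.0
    require_convergence: bool = True
    key_groups: tuple[str, ...] = (PCR_GROUP, PI_GROUP, BETA_ATP_GROUP)

    def __post_init__(self) -> None:
        if self.max_rel_crlb <= 0 or self.damping_range_hz[0] <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.min_pcr_snr < 1:
            raise ValueError("min_pcr_snr must be >= 1")


@dataclass(frozen=True)
class QualityResult:
    passed: bool
    reasons: tuple[str, ...]
    pcr_snr: float


def quality_filter(fit: SpectralFit, criteria: QualityCriteria = QualityCriteria()) -> QualityResult:
    """Screen a completed fit; every violated criterion is reported."""
    reasons: list[str] = []
    if criteria.require_convergence and not fit.converged:
        reasons.append("non-convergence")

    snr = math.inf
    pcr_amp = fit.group_amplitude(PCR_GROUP)
    if fit.noise_sigma > 0:
        snr = pcr_amp / fit.noise_sigma
    if snr < criteria.min_pcr_snr:
        reasons.append("snr")

    for group in criteria.key_groups:
        peaks = fit.group_peaks(group)
        amp = fit.group_amplitude(group)
        se = sum(p.amplitude_se for p in peaks)
        if amp <= 0 or not math.isfinite(se) or se > criteria.max_rel_crlb * amp:
            reasons.append(f"crlb:{group}")
        lo, hi = criteria.damping_range_hz
        d = peaks[0].damping_hz
        if not lo <= d <= hi:
            reasons.append(f"damping:{group}")

    return QualityResult(passed=not reasons, reasons=tuple(reasons), pcr_snr=snr)
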