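"""Chemical-shift calibrations for intracellular free Mg2+ and pH.

Two empirical calibration curves map 31P chemical-shift differences
(both referenced to phosphocreatine at 0 ppm) onto physiology:

* ``pmg_from_shift`` — the beta-ATP-to-PCr shift difference (delta_beta,
  ppm, physiologically near -16) onto pMg, the negative decadic
  logarithm of the molar free Mg2+ concentration.
* ``ph_from_shift`` — the Pi-to-PCr shift difference (delta_pi, ppm,
  physiologically near +4.9) onto intracellular pH, with a small linear
  correction for the free Mg2+ concentration in mmol/L.

Both curves are strictly monotone on their open admissible shift
intervals, so they admit exact inverses: a closed form for pH and a
bracketed root solve for pMg.  The inverses are what the synthetic-data
generator uses to place peaks for a requested (pMg, pH) ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "CalibrationConstants",
    "CalibrationDomainError",
    "DEFAULT_CONSTANTS",
    "pmg_from_shift",
    "mg_from_pmg",
    "ph_from_shift",
    "invert_ph_to_delta_pi",
    "invert_pmg_to_delta_beta",
]


class CalibrationDomainError(ValueError):
    """A chemical shift fell outside the calibration's admissible interval."""


@dataclass(frozen=True)
class CalibrationConstants:
    """Constants of the Mg and pH calibration curves.

    The pMg curve is

        pMg = pmg_offset - log10[ (pmg_a + db)^pmg_p / (-pmg_b - db)^pmg_q ]

    on db in (-pmg_a, -pmg_b), and the pH curve is

        pH = ph_offset - ph_mg_slope * [Mg]
             + log10[ (dpi - ph_lo) / (ph_hi - dpi) ]

    on dpi in (ph_lo, ph_hi), with [Mg] the free Mg2+ concentration in
    mmol/L.  Defaults are the published in vivo calibration; override
    only through explicit configuration.
    """

    pmg_offset: float = 4.24
    pmg_a: float = 18.58
    pmg_b: float = 15.74
    pmg_p: float = 0.42
    pmg_q: float = 0.84
    ph_offset: float = 6.706
    ph_mg_slope: float = 0.0307
    ph_lo: float = 3.245
    ph_hi: float = 5.778

    def __post_init__(self) -> None:
        if not self.ph_lo < self.ph_hi:
            raise ValueError("ph_lo must be < ph_hi")
        if not self.pmg_a > self.pmg_b:
            raise ValueError("pmg_a must be > pmg_b")

    @property
    def delta_beta_interval(self) -> tuple[float, float]:
        """Open admissible interval for delta_beta, ppm."""
        return (-self.pmg_a, -self.pmg_b)

    @property
    def delta_pi_interval(self) -> tuple[float, float]:
        """Open admissible interval for delta_pi, ppm."""
        return (self.ph_lo, self.ph_hi)


DEFAULT_CONSTANTS = CalibrationConstants()


def pmg_from_shift(
    delta_beta: float, constants: CalibrationConstants = DEFAULT_CONSTANTS
) -> float:
    """pMg from the beta-ATP-to-PCr shift difference in ppm.

    Strictly decreasing on the open interval (-18.58, -15.74): a
    beta-ATP peak closer to PCr means more ATP is Mg-bound, i.e. higher
    free Mg2+ and lower pMg.

    Raises
    ------
    CalibrationDomainError
        If ``delta_beta`` lies on or outside the interval boundary,
        where the logarithm is singular.
    """
    lo, hi = constants.delta_beta_interval
    if not (lo < delta_beta < hi):
        raise CalibrationDomainError(
            f"delta_beta={delta_beta!r} ppm outside the admissible open "
            f"interval ({lo}, {hi}) ppm"
        )
    return constants.pmg_offset - (
        constants.pmg_p * math.log10(constants.pmg_a + delta_beta)
        - constants.pmg_q * math.log10(-constants.pmg_b - delta_beta)
    )


def mg_from_pmg(pmg: float) -> float:
    """Free Mg2+ in mmol/L from pMg: 10**(3 - pMg).

    pMg is -log10 of the *molar* concentration; the factor 10**3
    converts mol/L to mmol/L.
    """
    return 10.0 ** (3.0 - pmg)


def ph_from_shift(
    delta_pi: float,
    mg_mM: float,
    constants: CalibrationConstants = DEFAULT_CONSTANTS,
) -> float:
    """pH from the Pi-to-PCr shift difference (ppm) and free Mg2+ (mM).

    Strictly increasing in ``delta_pi`` over (3.245, 5.778) and
    strictly decreasing in ``mg_mM``.

    Raises
    ------
    CalibrationDomainError
        If ``delta_pi`` lies on or outside the interval boundary.
    """
    lo, hi = constants.delta_pi_interval
    if not (lo < delta_pi < hi):
        raise CalibrationDomainError(
            f"delta_pi={delta_pi!r} ppm outside the admissible open "
            f"interval ({lo}, {hi}) ppm"
        )
    if mg_mM < 0:
        raise ValueError("mg_mM must be >= 0")
    return (
        constants.ph_offset
        - constants.ph_mg_slope * mg_mM
        + math.log10((delta_pi - lo) / (hi - delta_pi))
    )


def invert_ph_to_delta_pi(
    ph: float,
    mg_mM: float,
    constants: CalibrationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Pi-to-PCr shift (ppm) that yields ``ph`` at the given Mg2+ (mM).

    Closed form: with r = 10**(pH - ph_offset + ph_mg_slope*[Mg]),
    delta_pi = (ph_lo + ph_hi * r) / (1 + r), which maps every finite
    pH into the open interval (ph_lo, ph_hi).
    """
    if not (math.isfinite(ph) and math.isfinite(mg_mM)):
        raise ValueError("ph and mg_mM must be finite")
    if mg_mM < 0:
        raise ValueError("mg_mM must be >= 0")
    r = 10.0 ** (ph - constants.ph_offset + constants.ph_mg_slope * mg_mM)
    return (constants.ph_lo + constants.ph_hi * r) / (1.0 + r)


def invert_pmg_to_delta_beta(
    pmg: float,
    constants: CalibrationConstants = DEFAULT_CONSTANTS,
    xtol: float = 1e-12,
    maxiter: int = 200,
) -> float:
    """beta-ATP-to-PCr shift (ppm) whose calibrated pMg equals ``pmg``.

    The forward curve has no closed-form inverse; since it is strictly
    decreasing and spans all of R over the open shift interval, the
    root is found by bracketed bisection (Brent's method) just inside
    the interval.

    Raises
    ------
    RuntimeError
        On convergence failure, reporting the bracketing interval.
    """
    if not math.isfinite(pmg):
        raise ValueError("pmg must be finite")
    lo, hi = constants.delta_beta_interval
    eps = 1e-13 * (hi - lo)
    a, b = lo + eps, hi - eps

    def objective(db: float) -> float:
        return pmg_from_shift(db, constants) - pmg

    try:
        root = brentq(objective, a, b, xtol=xtol, maxiter=maxiter)
    except RuntimeError as exc:  # pragma: no cover - requires pathological input
        raise RuntimeError(
            f"pMg inversion did not converge in {maxiter} iterations on the "
            f"bracket [{a}, {b}] ppm"
        ) from exc
    return float(root)
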